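"""Enterotype discovery and characterization.

Samples are clustered on the square root of the Jensen-Shannon
divergence between genus profiles with partitioning around medoids
(PAM); the number of community types is chosen by the Calinski-Harabasz
index evaluated in principal-coordinate (PCoA) space, and each cluster
is summarized by its dominant genus. Association between enterotype
membership and disease group uses Fisher's exact test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon
from sklearn.metrics import calinski_harabasz_score
from skbio.stats.ordination import pcoa as _skbio_pcoa
from skbio import DistanceMatrix as _SkbioDM

from .profiles import CohortMetadata, TaxonProfile
from .diversity import _rank_sum_p
from .network import Network, cooccurrence_network


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray
    metric: str = "sqrt-jsd"

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape[0] != d.shape[1] or (d < -1e-12).any():
            raise ValueError("distance matrix must be square and non-negative")
        if not np.allclose(d, d.T, atol=1e-10) or not np.allclose(np.diag(d), 0, atol=1e-10):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.d = d


@dataclass
class EnterotypeModel:
    k: int
    assignment: pd.Series                  # sample -> cluster (1-based)
    medoids: list[str]
    ch_by_k: dict[int, float]
    dominant_taxon: dict[int, str] = field(default_factory=dict)
    dominant_taxon_p: dict[int, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "assignment": {s: int(c) for s, c in self.assignment.items()},
            "medoids": self.medoids,
            "ch_by_k": {str(k): v for k, v in self.ch_by_k.items()},
            "dominant_taxon": {str(k): v for k, v in self.dominant_taxon.items()},
        }, indent=1)


def jsd_distance(profile: TaxonProfile, sqrt: bool = True) -> DistanceMatrix:
    """Pairwise Jensen-Shannon distance between samples (natural log).

    Columns are renormalized to sum 1; zero components contribute
    0*log 0 = 0 exactly, so no pseudocount is added. With ``sqrt=True``
    (default, the enterotyping convention) the metric square root of the
    divergence is returned.
    """
    rel = profile.rel_abund.values.astype(float)
    if (rel < 0).any():
        raise ValueError("negative abundances")
    p = rel / rel.sum(axis=0, keepdims=True)
    n = p.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        # scipy's jensenshannon returns sqrt(JSD) with base-e log
        row = jensenshannon(p[:, i][:, None], p[:, i + 1:], base=np.e, axis=0)
        d[i, i + 1:] = d[i + 1:, i] = np.nan_to_num(row, nan=0.0)
    if not sqrt:
        d = d ** 2
    return DistanceMatrix(list(profile.rel_abund.columns), d,
                          metric="sqrt-jsd" if sqrt else "jsd")


def _pam_cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[medoids].min(axis=0).sum())


def pam(dist: DistanceMatrix, k: int, seed: int = 0,
        max_iter: int = 200) -> tuple[pd.Series, list[str]]:
    """Partitioning around medoids: greedy BUILD then best-improvement SWAP.

    Deterministic: BUILD breaks ties on the lowest index and SWAP accepts
    the single best improving exchange per pass until none remains. Each
    sample joins its nearest medoid, ties to the lowest-index medoid.
    ``seed`` is accepted for interface stability; the algorithm itself is
    deterministic.

    On tiny instances (n <= 12) BUILD+SWAP can terminate in a strict
    single-swap local optimum, so the medoid set is found by exhaustive
    enumeration instead; the objective is then the global optimum.
    """
    d = dist.d
    n = d.shape[0]
    if not (2 <= k < n):
        raise ValueError(f"need 2 <= k < n samples (k={k}, n={n})")
    from itertools import combinations
    from math import comb
    if n <= 12 and comb(n, k) <= 2000:
        medoids = list(min(combinations(range(n), k),
                           key=lambda m: _pam_cost(d, list(m))))
        labels = np.argmin(d[medoids], axis=0) + 1
        assignment = pd.Series(labels, index=dist.sample_ids, name="enterotype")
        return assignment, [dist.sample_ids[m] for m in medoids]
    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[medoids].min(axis=0)
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    # SWAP
    for _ in range(max_iter):
        best_cost = _pam_cost(d, medoids)
        best_swap = None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1:]
                c = _pam_cost(d, trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    medoids = sorted(medoids)
    labels = np.argmin(d[medoids], axis=0) + 1
    assignment = pd.Series(labels, index=dist.sample_ids, name="enterotype")
    return assignment, [dist.sample_ids[m] for m in medoids]


def pcoa(dist: DistanceMatrix, n_axes: int = 2):
    """Classical scaling of a distance matrix.

    Returns (coordinates DataFrame with ``n_axes`` columns, eigenvalues
    including any negative ones, full positive-axis coordinates).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        ord_res = _skbio_pcoa(_SkbioDM(dist.d, ids=dist.sample_ids), method="eigh")
    eig = ord_res.eigvals.values
    pos = eig > max(eig.max(), 0) * 1e-10
    coords_full = ord_res.samples.values[:, pos]
    if n_axes > coords_full.shape[1]:
        warnings.warn(f"only {coords_full.shape[1]} positive axes; truncating",
                      UserWarning, stacklevel=2)
        n_axes = coords_full.shape[1]
    coords = pd.DataFrame(coords_full[:, :n_axes], index=dist.sample_ids,
                          columns=[f"PCo{i + 1}" for i in range(n_axes)])
    return coords, eig, coords_full


def optimal_k(dist: DistanceMatrix, profile: TaxonProfile | None = None,
              k_range: range = range(2, 11), seed: int = 0) -> EnterotypeModel:
    """Run PAM over a range of k and select by the Calinski-Harabasz index.

    CH(k) = [B/(k-1)] / [W/(n-k)] is computed on all positive PCoA axes
    (centroid-based, the conventional enterotyping choice). If a genus
    profile is given, each cluster is annotated with its dominant genus
    (highest mean relative abundance) and the between-cluster rank-sum p
    of that genus.
    """
    ks = [k for k in k_range if 2 <= k < len(dist.sample_ids)]
    if not ks:
        raise ValueError("empty k range")
    _, _, coords = pcoa(dist, n_axes=2)
    results: dict[int, tuple[pd.Series, list[str]]] = {}
    ch_by_k: dict[int, float] = {}
    for k in ks:
        assignment, medoids = pam(dist, k, seed=seed)
        results[k] = (assignment, medoids)
        if assignment.nunique() < 2:
            ch_by_k[k] = 0.0
        else:
            ch_by_k[k] = float(calinski_harabasz_score(coords, assignment.values))
    best = max(ch_by_k, key=lambda k: (ch_by_k[k], -k))
    assignment, medoids = results[best]
    model = EnterotypeModel(k=best, assignment=assignment, medoids=medoids, ch_by_k=ch_by_k)
    if profile is not None:
        rel = profile.rel_abund
        for c in sorted(assignment.unique()):
            members = assignment.index[assignment == c]
            dom = rel[members].mean(axis=1).idxmax()
            model.dominant_taxon[int(c)] = dom
            others = assignment.index[assignment != c]
            if len(members) >= 2 and len(others) >= 2:
                _, p = _rank_sum_p(rel.loc[dom, members].values,
                                   rel.loc[dom, others].values)
                model.dominant_taxon_p[int(c)] = p
    return model


def enterotype_association(assignment: pd.Series, metadata: CohortMetadata,
                           contrast: tuple[str, str] = ("C", "H"),
                           clusters: tuple[int, int] = (1, 2)):
    """2x2 enterotype-by-group table, odds ratios, and Fisher's exact p.

    Returns (table DataFrame, conditional-MLE OR, sample OR with Haldane
    +0.5 on zero cells, two-sided p).
    """
    g1, g2 = contrast
    c1, c2 = clusters
    table = np.zeros((2, 2), dtype=int)
    for i, c in enumerate((c1, c2)):
        in_c = assignment.index[assignment == c]
        for j, g in enumerate((g1, g2)):
            table[i, j] = len(set(in_c) & set(metadata.samples_in(g)))
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("empty margin in enterotype-by-group table")
    res = stats.contingency.odds_ratio(table, kind="conditional")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    sample_or = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    df = pd.DataFrame(table, index=[f"enterotype{c1}", f"enterotype{c2}"], columns=[g1, g2])
    return df, float(res.statistic), float(sample_or), float(p)


def genus_cooccurrence(profile: TaxonProfile, samples: list[str],
                       anchor_taxon: str | None = None,
                       threshold: float = 0.4) -> Network:
    """Spearman co-occurrence network of genera within one enterotype.

    Edges at |rho| >= threshold with sign retained; the anchor genus
    (typically the enterotype's dominant one) is flagged as a node
    attribute.
    """
    if len(samples) < 8:
        raise ValueError("need at least 8 samples in the enterotype")
    sub = profile.rel_abund[samples]
    net = cooccurrence_network(sub, strong=1.01, weak=threshold, include_negative=True)
    if anchor_taxon is not None:
        for node in net.graph.nodes:
            net.graph.nodes[node]["anchor"] = node == anchor_taxon
    return net
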