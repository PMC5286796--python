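"""Co-occurrence networks and clinical-index correlations.

Features (co-abundance gene groups or genera) become nodes; edges carry
the Spearman correlation of their abundance vectors, tiered as strong
(rho > 0.8) or weak (0.7 <= rho <= 0.8) following the display
convention of the analysis this package reproduces. Correlations with
clinical indices use pairwise-complete samples and Holm step-down
multiplicity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import CohortMetadata


@dataclass
class Network:
    """Undirected feature graph; edges carry rho, sign, and tier."""

    graph: nx.Graph

    def edges(self) -> pd.DataFrame:
        rows = [(u, v, d["rho"], d["tier"], d["sign"])
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["u", "v", "rho", "tier", "sign"])

    def write_edges(self, path) -> None:
        self.edges().to_csv(path, sep="\t", index=False)

    def write_nodes(self, path) -> None:
        rows = [(n, *[d.get(k) for k in ("size", "enrichment", "anchor")])
                for n, d in self.graph.nodes(data=True)]
        pd.DataFrame(rows, columns=["node", "size", "enrichment", "anchor"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def read_edges(cls, path) -> "Network":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.u, row.v, rho=float(row.rho), tier=row.tier, sign=int(row.sign))
        return cls(g)


def _spearman_matrix(df: pd.DataFrame) -> np.ndarray:
    ranks = df.rank(axis=1).values
    return np.corrcoef(ranks)


def cooccurrence_network(abundances: pd.DataFrame, strong: float = 0.8,
                         weak: float = 0.7, include_negative: bool = False,
                         node_sizes: dict | None = None,
                         node_enrichment: dict | None = None) -> Network:
    """Build the Spearman co-occurrence network of abundance features.

    Positive edges with rho > ``strong`` are tiered "strong", those with
    ``weak`` <= rho <= ``strong`` are "weak". Negative correlations are
    kept (tiered by |rho|, sign -1) only when ``include_negative`` is
    set, mirroring the convention of drawing positive edges only.
    """
    if abundances.shape[1] < 8:
        raise ValueError("need at least 8 samples")
    if abundances.shape[0] < 2:
        raise ValueError("need at least 2 features")
    sds = abundances.std(axis=1)
    if (sds == 0).any():
        warnings.warn(f"excluding {int((sds == 0).sum())} constant feature(s)",
                      UserWarning, stacklevel=2)
    df = abundances.loc[sds > 0]
    rho = _spearman_matrix(df)
    g = nx.Graph()
    feats = list(df.index)
    for i, f in enumerate(feats):
        g.add_node(f,
                   size=None if node_sizes is None else node_sizes.get(f),
                   enrichment=None if node_enrichment is None else node_enrichment.get(f))
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            r = rho[i, j]
            mag, sign = abs(r), int(np.sign(r)) or 1
            if sign < 0 and not include_negative:
                continue
            if mag > strong:
                tier = "strong"
            elif mag >= weak:
                tier = "weak"
            else:
                continue
            g.add_edge(feats[i], feats[j], rho=float(r), tier=tier, sign=sign)
    return Network(g)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for Spearman rho at tiny n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    perms = np.array(list(permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - ry.mean()
    num = pc @ rxc
    den = np.sqrt((rxc ** 2).sum() * (pc ** 2).sum(axis=1))
    rhos = np.abs(num / den)
    return float((rhos >= obs - 1e-12).mean())


def spearman_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a t-approximate p for n >= 10, exact below."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = float(stats.spearmanr(x, y).statistic)
    if len(x) >= 10:
        p = float(stats.spearmanr(x, y).pvalue)
    else:
        p = _spearman_exact_p(x, y)
    return rho, p


def clinical_correlation(cag_abundances: pd.DataFrame, metadata: CohortMetadata,
                         indices: list[str] | None = None, adjust: str = "Holm",
                         alpha: float = 0.05, min_n: int = 8) -> pd.DataFrame:
    """Spearman correlation of each feature with each clinical index.

    Samples missing a given index are dropped pairwise; indices with
    fewer than ``min_n`` non-missing values are skipped with a warning.
    Holm step-down correction is applied across all (feature, index)
    pairs; pairs significant at ``alpha`` are flagged.
    """
    if indices is None:
        indices = [c for c in metadata.CLINICAL if c in metadata.table.columns]
    shared = [s for s in cag_abundances.columns if s in metadata.table.index]
    rows = []
    for idx_name in indices:
        vals = metadata.table.loc[shared, idx_name].astype(float)
        ok = vals.notna()
        if ok.sum() < min_n:
            warnings.warn(f"clinical index {idx_name!r} has <{min_n} values; skipped",
                          UserWarning, stacklevel=2)
            continue
        for feat in cag_abundances.index:
            x = cag_abundances.loc[feat, vals.index[ok]].values
            rho, p = spearman_test(x, vals[ok].values)
            rows.append((feat, idx_name, rho, p, int(ok.sum())))
    out = pd.DataFrame(rows, columns=["feature", "index", "rho", "p_raw", "n"])
    if len(out):
        method = {"Holm": "holm", "BH": "fdr_bh"}[adjust]
        reject, p_adj, *_ = multipletests(out["p_raw"].values, alpha=alpha, method=method)
        out["p_adj"] = p_adj
        out["significant"] = reject
    return out
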