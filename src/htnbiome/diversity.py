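"""Within-sample diversity, gene rarefaction, and group-difference testing.

Shannon index is computed on renormalized genus profiles (natural log by
default). Gene rarefaction draws samples with replacement and counts the
distinct genes present in at least one drawn sample, 100 draws per
sampling depth. Differential testing uses the two-sided Wilcoxon
rank-sum test (exact when sample sizes and ties allow) with
Benjamini-Hochberg or Holm multiplicity correction, and the
tie-corrected Kruskal-Wallis test for three-group contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import CohortMetadata, TaxonProfile


@dataclass
class DiversityResult:
    shannon: pd.Series           # per-sample H
    log_base: str                # "e" or "2"


@dataclass
class RarefactionCurve:
    sample_counts: list[int]
    mean_genes: np.ndarray       # expected distinct present genes at each k
    per_draw: np.ndarray         # draws x k
    n_draws: int


def shannon_index(profile: TaxonProfile, log_base: str = "e") -> DiversityResult:
    """Shannon H = -sum p_i log p_i over nonzero p_i, per sample."""
    rel = profile.rel_abund.values.astype(float)
    if (rel < 0).any():
        raise ValueError("negative abundances")
    totals = rel.sum(axis=0)
    if (totals == 0).any():
        bad = profile.rel_abund.columns[totals == 0][0]
        raise ValueError(f"sample {bad!r} has no nonzero taxa")
    p = rel / totals
    log = np.log2 if log_base == "2" else np.log
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * log(np.where(p > 0, p, 1.0)), 0.0)
    h = pd.Series(-terms.sum(axis=0), index=profile.rel_abund.columns, name="shannon")
    return DiversityResult(shannon=h, log_base=log_base)


def rarefaction_curve(present: pd.DataFrame, ks: list[int], n_draws: int = 100,
                      seed: int | None = 0) -> RarefactionCurve:
    """Distinct genes identified from k samples drawn with replacement.

    A gene counts as identified if present in at least one drawn sample;
    drawing with replacement may repeat samples, so k may exceed the
    number of distinct samples.
    """
    if present.size == 0:
        raise ValueError("empty presence matrix")
    if min(ks) < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    mat = present.values.astype(bool)
    n = mat.shape[1]
    per_draw = np.empty((n_draws, len(ks)), dtype=int)
    for j, k in enumerate(ks):
        for d in range(n_draws):
            idx = rng.integers(0, n, size=k)
            per_draw[d, j] = mat[:, idx].any(axis=1).sum()
    return RarefactionCurve(sample_counts=list(ks), mean_genes=per_draw.mean(axis=0),
                            per_draw=per_draw, n_draws=n_draws)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) statistic and p.

    Exact enumeration when n1+n2 <= 20 without ties, otherwise normal
    approximation with tie and continuity correction.
    """
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def differential_features(matrix: pd.DataFrame | TaxonProfile, metadata: CohortMetadata,
                          contrast: tuple[str, str] = ("C", "H"),
                          adjust: str = "BH") -> pd.DataFrame:
    """Per-feature two-sided rank-sum test between two groups.

    Returns a table with columns feature, contrast, statistic, p_raw,
    p_adj, direction (sign of median difference, second group minus
    first) and a ``constant`` flag for features identical across both
    groups (assigned p = 1).
    """
    df = matrix.rel_abund if isinstance(matrix, TaxonProfile) else matrix
    g1, g2 = contrast
    s1 = [s for s in metadata.samples_in(g1) if s in df.columns]
    s2 = [s for s in metadata.samples_in(g2) if s in df.columns]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for feat in df.index:
        x, y = df.loc[feat, s1].values.astype(float), df.loc[feat, s2].values.astype(float)
        const = np.ptp(np.concatenate([x, y])) == 0
        if const:
            stat, p = float(len(x) * len(y) / 2), 1.0
        else:
            stat, p = _rank_sum_p(x, y)
        direction = int(np.sign(np.median(y) - np.median(x)))
        rows.append((feat, f"{g1}-vs-{g2}", stat, p, direction, const))
    out = pd.DataFrame(rows, columns=["feature", "contrast", "statistic",
                                      "p_raw", "direction", "constant"])
    method = {"BH": "fdr_bh", "Holm": "holm"}[adjust]
    out["p_adj"] = multipletests(out["p_raw"].values, method=method)[1]
    out["adjust_method"] = adjust
    return out[["feature", "contrast", "statistic", "p_raw", "p_adj",
                "direction", "constant", "adjust_method"]]


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p with k-1 df."""
    labels = pd.unique(np.asarray(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 distinct groups")
    arrs = [np.asarray(values)[np.asarray(groups) == g] for g in labels]
    if any(len(a) == 0 for a in arrs):
        raise ValueError("empty group")
    if np.ptp(np.asarray(values, dtype=float)) == 0:
        return 0.0, 1.0
    stat, p = stats.kruskal(*arrs)
    return float(stat), float(p)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row (x - mean) / sd with sample sd (ddof=1); constant rows dropped."""
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} zero-variance row(s)",
                      UserWarning, stacklevel=2)
    kept = matrix.loc[~const]
    return kept.sub(mean[~const], axis=0).div(sd[~const], axis=0)
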