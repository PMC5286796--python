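"""Serum-metabolite statistics and metabolite-taxon coupling.

Differential metabolites are those with a PLS-DA variable influence on
projection (VIP) above 1.5 and a two-sample t-test p below 0.05 on peak
intensities. PLS-DA is fitted by NIPALS on autoscaled intensities with
one-hot group responses; VIP_j = sqrt(p * sum_a SS_a (w_ja/||w_a||)^2 /
sum_a SS_a) where SS_a is the Y-variance captured by component a, so
sum_j VIP_j^2 = p.

Metabolite-taxon association first prunes collinear taxa (one random
representative per |Spearman r| >= 0.9 cluster), then fits a
bidirectional AIC-stepwise linear model per metabolite over the
representatives, and reports the Spearman correlation of the metabolite
with each retained taxon, signed by the model coefficient; pairs with
|r| < 0.4 are suppressed from the display table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .profiles import CohortMetadata


@dataclass
class PlsdaModel:
    n_components: int
    weights: np.ndarray        # p x A, each column unit norm
    scores: np.ndarray         # n x A
    y_loadings: np.ndarray     # q x A
    ss: np.ndarray             # Y-variance explained per component
    feature_ids: list[str]
    vip: pd.Series | None = None


def autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and unit-variance scale columns; returns (scaled, keep mask).

    Zero-variance columns cannot be autoscaled and are dropped with a
    warning.
    """
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)",
                      UserWarning, stacklevel=2)
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Xs, keep


def plsda_fit(X: pd.DataFrame, y: pd.Series, n_components: int = 2,
              tol: float = 1e-10, max_iter: int = 500) -> PlsdaModel:
    """NIPALS PLS2 on autoscaled samples-by-features X and one-hot y.

    Deterministic start: the score surrogate u is initialized from the
    first response column each component.
    """
    classes = sorted(pd.unique(y))
    Y = np.column_stack([(y.values == c).astype(float) for c in classes])
    Y = Y - Y.mean(axis=0)
    Xs, keep = autoscale(X.values.astype(float))
    feats = list(X.columns[keep])
    n, p = Xs.shape
    if n_components > min(n - 1, p):
        raise ValueError("n_components exceeds the rank bound of X")
    Xa, Ya = Xs.copy(), Y.copy()
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    ss = np.zeros(n_components)
    for a in range(n_components):
        u = Ya[:, 0].copy()
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = Xa.T @ u
            w /= np.linalg.norm(w)
            t = Xa @ w
            q = Ya.T @ t / (t @ t)
            u = Ya @ q / (q @ q)
            if np.linalg.norm(t - t_old) < tol:
                break
            t_old = t
        p_load = Xa.T @ t / (t @ t)
        Xa = Xa - np.outer(t, p_load)
        Ya = Ya - np.outer(t, q)
        W[:, a], T[:, a], Q[:, a] = w, t, q
        ss[a] = (t @ t) * (q @ q)       # Y sum of squares captured
    model = PlsdaModel(n_components=n_components, weights=W, scores=T,
                       y_loadings=Q, ss=ss, feature_ids=feats)
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PlsdaModel) -> pd.Series:
    """Variable influence on projection; satisfies sum(VIP^2) = p."""
    W, ss = model.weights, model.ss
    p = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn ** 2 @ ss) / ss.sum())
    return pd.Series(vip, index=model.feature_ids, name="vip")


def differential_metabolites(table: pd.DataFrame, metadata: CohortMetadata,
                             contrast: tuple[str, str] = ("C", "H"),
                             vip_min: float = 1.5, p_max: float = 0.05,
                             n_components: int = 2, welch: bool = True
                             ) -> pd.DataFrame:
    """Select features with VIP > vip_min and t-test p < p_max.

    Returns the full per-feature table (vip, p, direction of the case
    group relative to control, selected flag).
    """
    g1, g2 = contrast
    s1 = [s for s in metadata.samples_in(g1) if s in table.columns]
    s2 = [s for s in metadata.samples_in(g2) if s in table.columns]
    if len(s1) < 3 or len(s2) < 3:
        raise ValueError("need at least 3 samples per group")
    sub = table[s1 + s2]
    y = pd.Series(["a"] * len(s1) + ["b"] * len(s2), index=s1 + s2)
    n_var = int((sub.std(axis=1, ddof=1) > 0).sum())
    n_comp = min(n_components, len(y) - 1, n_var)
    model = plsda_fit(sub.T, y, n_components=n_comp)
    vip = model.vip.reindex(table.index)
    rows = []
    for feat in table.index:
        x1 = table.loc[feat, s1].values.astype(float)
        x2 = table.loc[feat, s2].values.astype(float)
        if np.ptp(np.concatenate([x1, x2])) == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(x1, x2, equal_var=not welch).pvalue)
        rows.append((feat, p, int(np.sign(x2.mean() - x1.mean()))))
    out = pd.DataFrame(rows, columns=["feature", "p_raw", "direction"]).set_index("feature")
    out["vip"] = vip
    out["selected"] = (out["vip"] > vip_min) & (out["p_raw"] < p_max)
    out["contrast"] = f"{g1}-vs-{g2}"
    return out


def prune_collinear(taxa: pd.DataFrame, rho_prune: float = 0.9,
                    seed: int = 0) -> list[str]:
    """One random representative per cluster of |Spearman r| >= rho_prune taxa."""
    ranks = taxa.rank(axis=1).values
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks ** 2).sum(axis=1))
    norms[norms == 0] = 1.0
    rho = (ranks / norms[:, None]) @ (ranks / norms[:, None]).T
    adj = csr_matrix(np.abs(rho) >= rho_prune)
    _, labels = connected_components(adj, directed=False)
    rng = np.random.default_rng(seed)
    reps = []
    for c in np.unique(labels):
        members = list(taxa.index[labels == c])
        reps.append(members[rng.integers(len(members))])
    return sorted(reps, key=list(taxa.index).index)


def _aic(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    """AIC of an OLS fit with intercept; returns (aic, coefficients)."""
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(((y - design @ beta) ** 2).sum())
    k = design.shape[1]
    return n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1), beta[1:]


def stepwise_ols(y: np.ndarray, X: pd.DataFrame) -> dict[str, float]:
    """Bidirectional AIC-minimizing stepwise linear model.

    Returns the retained predictors and their coefficients (empty dict
    when no predictor improves on the intercept-only model).
    """
    selected: list[str] = []
    current, _ = _aic(y, np.empty((len(y), 0)))
    while True:
        best = (current, None, None)
        for col in X.columns:
            if col in selected:
                continue
            trial = selected + [col]
            aic, _ = _aic(y, X[trial].values)
            if aic < best[0] - 1e-10:
                best = (aic, "add", col)
        for col in selected:
            trial = [c for c in selected if c != col]
            aic, _ = _aic(y, X[trial].values)
            if aic < best[0] - 1e-10:
                best = (aic, "drop", col)
        if best[1] is None:
            break
        current = best[0]
        if best[1] == "add":
            selected.append(best[2])
        else:
            selected.remove(best[2])
    if not selected:
        return {}
    _, beta = _aic(y, X[selected].values)
    return dict(zip(selected, map(float, beta)))


def metabolite_taxon_association(metabolites: pd.DataFrame, taxa: pd.DataFrame,
                                 rho_prune: float = 0.9, display_min: float = 0.4,
                                 seed: int = 0) -> pd.DataFrame:
    """Coefficient-signed Spearman coupling of metabolites to taxa.

    Pipeline: prune collinear taxa; AIC-stepwise linear model per
    metabolite over the representatives; for each retained taxon report
    sign(coefficient) * |Spearman r|; suppress pairs below
    ``display_min`` (column ``shown``). Metabolites for which stepwise
    retains nothing are omitted.
    """
    shared = [s for s in metabolites.columns if s in taxa.columns]
    if len(shared) < 8:
        raise ValueError("need at least 8 common samples")
    met = metabolites[shared]
    tax = taxa[shared]
    reps = prune_collinear(tax, rho_prune=rho_prune, seed=seed)
    Xrep = tax.loc[reps].T
    Xrep = (Xrep - Xrep.mean()) / Xrep.std(ddof=1).replace(0, 1.0)
    rows = []
    for m in met.index:
        yv = met.loc[m].values.astype(float)
        ys = (yv - yv.mean()) / (yv.std(ddof=1) or 1.0)
        coefs = stepwise_ols(ys, Xrep)
        for taxon, beta in coefs.items():
            r = float(stats.spearmanr(yv, tax.loc[taxon].values).statistic)
            scaled = float(np.sign(beta) * abs(r))
            rows.append((m, taxon, scaled, r, beta, abs(scaled) >= display_min))
    return pd.DataFrame(rows, columns=["metabolite", "taxon", "scaled_r",
                                       "rho", "coef", "shown"])


def read_metabolites(path) -> pd.DataFrame:
    """Features-by-samples intensity CSV; first column feature id."""
    return pd.read_csv(path, index_col=0)


def write_metabolites(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="feature_id")
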