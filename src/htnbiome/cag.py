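"""Co-abundance gene groups (CAGs).

Marker genes are scored with an odds ratio contrasting high/low
abundance (dichotomized at the gene's median) between two sample groups
with the third excluded; OR > 2 calls a feature enriched in the case
group and OR < 0.5 depleted. Marker genes are then clustered into CAGs
as connected components of the Spearman rho >= 0.7 gene graph,
keeping components of at least 50 genes. CAG abundance pools member
reads over member bases, and tracer-gene alignments assign each CAG a
species (90% of genes at 95% identity, 70% query overlap) or genus
(80% of genes at 85% identity) label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .profiles import CohortMetadata, GeneAbundanceMatrix

OR_ENRICHED = 2.0
OR_DEPLETED = 0.5

SPECIES_GENE_FRACTION = 0.90
SPECIES_IDENTITY = 95.0
SPECIES_OVERLAP = 70.0
GENUS_GENE_FRACTION = 0.80
GENUS_IDENTITY = 85.0


@dataclass
class EnrichmentCall:
    feature_id: str
    contrast: str
    odds_ratio: float
    call: str  # enriched | depleted | neutral


@dataclass
class CAG:
    cag_id: str
    gene_ids: list[str]
    abundance: pd.Series | None = None
    tracer_rank: str | None = None
    tracer_taxon: str | None = None
    enrichment: EnrichmentCall | None = None

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def gene_or_score(values: pd.Series, metadata: CohortMetadata,
                  contrast: tuple[str, str] = ("C", "H")) -> float:
    """Odds ratio of high/low abundance between two groups.

    The abundance vector is dichotomized at its median over the
    contrast's samples (values <= median are "low"); the 2x2 table of
    group-by-level gets a Haldane +0.5 on every cell when any cell is
    zero. The third group's samples never enter the table.
    """
    ctrl_g, case_g = contrast
    ctrl = [s for s in metadata.samples_in(ctrl_g) if s in values.index]
    case = [s for s in metadata.samples_in(case_g) if s in values.index]
    if not ctrl or not case:
        raise ValueError(f"contrast {contrast} has an empty group")
    pooled = values[ctrl + case].astype(float)
    med = pooled.median()
    high = pooled > med
    a = float(high[case].sum())          # case high
    b = float(len(case) - a)             # case low
    c = float(high[ctrl].sum())          # control high
    d = float(len(ctrl) - c)             # control low
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def classify_enrichment(odds_ratio: float, feature_id: str = "",
                        contrast: str = "") -> EnrichmentCall:
    """Strict thresholds: OR > 2 enriched, OR < 0.5 depleted, else neutral."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if odds_ratio > OR_ENRICHED:
        call = "enriched"
    elif odds_ratio < OR_DEPLETED:
        call = "depleted"
    else:
        call = "neutral"
    return EnrichmentCall(feature_id, contrast, odds_ratio, call)


def marker_genes(genes: GeneAbundanceMatrix, metadata: CohortMetadata,
                 contrast: tuple[str, str] = ("C", "H")) -> pd.DataFrame:
    """OR score and enrichment call for every gene under one contrast."""
    eff = genes.effective_depth()
    label = f"{contrast[0]}-vs-{contrast[1]}"
    rows = []
    for g in eff.index:
        orr = gene_or_score(eff.loc[g], metadata, contrast)
        rows.append((g, label, orr, classify_enrichment(orr).call))
    return pd.DataFrame(rows, columns=["gene_id", "contrast", "or", "call"]).set_index("gene_id")


def build_cags(depth: pd.DataFrame, rho_min: float = 0.7,
               min_size: int = 50) -> list[CAG]:
    """Cluster genes into CAGs as components of the rho >= rho_min graph.

    Connected components with at least ``min_size`` genes become CAGs
    (smaller ones are discarded); membership is deterministic and
    invariant to gene order. CAGs are numbered by descending size, ties
    by first member gene id.
    """
    if depth.shape[1] < 8:
        raise ValueError("need at least 8 samples for stable rank correlations")
    if depth.shape[0] < min_size:
        raise ValueError(f"need at least {min_size} genes")
    ranks = depth.rank(axis=1).values
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks ** 2).sum(axis=1))
    norms[norms == 0] = 1.0
    ranks /= norms[:, None]
    rho = ranks @ ranks.T
    adj = csr_matrix(rho >= rho_min)
    n_comp, labels = connected_components(adj, directed=False)
    cags = []
    for c in range(n_comp):
        members = sorted(depth.index[labels == c])
        if len(members) >= min_size:
            cags.append(members)
    cags.sort(key=lambda m: (-len(m), m[0]))
    return [CAG(cag_id=f"CAG-{i + 1:03d}", gene_ids=m) for i, m in enumerate(cags)]


def cag_abundance(cag: CAG, genes: GeneAbundanceMatrix) -> pd.Series:
    """Length-weighted mean depth: pooled member reads per pooled base."""
    counts = genes.counts.loc[cag.gene_ids]
    total_len = genes.gene_length.loc[cag.gene_ids].sum()
    ab = counts.sum(axis=0) / total_len
    ab.name = cag.cag_id
    return ab


def assign_cag_taxonomy(cag: CAG, gene_annotations: pd.DataFrame
                        ) -> tuple[str, str] | None:
    """Tracer-gene taxonomy of a CAG from per-gene best-genome alignments.

    ``gene_annotations`` is gene-indexed with columns taxon, identity,
    overlap (one best alignment per gene-genome pair; when DNA and
    protein identities both exist callers supply the smaller). A species
    needs >= 90% of member genes at >= 95% identity and >= 70% overlap;
    otherwise a genus needs >= 80% of member genes at >= 85% identity.
    Among qualifying taxa the highest gene fraction wins; exact ties
    leave the CAG unassigned.
    """
    ann = gene_annotations.loc[gene_annotations.index.intersection(cag.gene_ids)]
    size = cag.size
    if not len(ann):
        return None
    for rank, frac_min, id_min, ov_min in (
            ("species", SPECIES_GENE_FRACTION, SPECIES_IDENTITY, SPECIES_OVERLAP),
            ("genus", GENUS_GENE_FRACTION, GENUS_IDENTITY, None)):
        ok = ann["identity"] >= id_min
        if ov_min is not None:
            ok &= ann["overlap"] >= ov_min
        fracs = ann.loc[ok].groupby("taxon").size() / size
        fracs = fracs[fracs >= frac_min]
        if len(fracs):
            top = fracs.max()
            winners = fracs.index[fracs == top]
            if len(winners) > 1:
                return None
            return rank, str(winners[0])
    return None


def cag_enrichment(cag_abundances: pd.DataFrame, metadata: CohortMetadata,
                   contrast: tuple[str, str] = ("C", "H")) -> list[EnrichmentCall]:
    """OR score and enrichment call per CAG abundance vector."""
    label = f"{contrast[0]}-vs-{contrast[1]}"
    calls = []
    for cid in cag_abundances.index:
        orr = gene_or_score(cag_abundances.loc[cid], metadata, contrast)
        calls.append(classify_enrichment(orr, feature_id=cid, contrast=label))
    return calls


def cag_table(cags: list[CAG]) -> pd.DataFrame:
    """Summary TSV-ready table: id, size, tracer taxonomy, OR, call."""
    rows = []
    for c in cags:
        e = c.enrichment
        rows.append((c.cag_id, c.size, c.tracer_rank, c.tracer_taxon,
                     None if e is None else e.odds_ratio,
                     None if e is None else e.call))
    return pd.DataFrame(rows, columns=["cag_id", "size", "tracer_rank",
                                       "tracer_taxon", "or", "call"])


def membership_table(cags: list[CAG]) -> pd.DataFrame:
    rows = [(c.cag_id, g) for c in cags for g in c.gene_ids]
    return pd.DataFrame(rows, columns=["cag_id", "gene_id"])
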