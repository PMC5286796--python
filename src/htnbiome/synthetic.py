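"""Synthetic hypertension-cohort generator.

Emulates the statistical structure the downstream analysis assumes:
three sample groups (normotensive control C, pre-hypertension P,
hypertension H), genus profiles drawn from a log-normal model with two
latent community modes each dominated by a distinct genus
(*Prevotella*-like vs *Bacteroides*-like), blocks of strongly
co-abundant catalogue genes per genus, group-dependent
enrichment/depletion of designated disease/healthy genera, serum
metabolite features rank-coupled to chosen genera, and group-shifted
blood-pressure covariates. Ground-truth labels are returned for
parameter-recovery testing.

The generator draws relative abundances directly; it does not simulate
reads, sequencing error, or zero-inflation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import CohortMetadata, GeneAbundanceMatrix, TaxonProfile, length_normalize

# genus name pools; the first two double as the dominant genera of the two
# community modes (mode 1 Prevotella-dominated, mode 2 Bacteroides-dominated)
_MODE_DOMINANTS = ["Prevotella", "Bacteroides"]
_DISEASE_POOL = ["Klebsiella", "Enterobacter", "Porphyromonas", "Actinomyces",
                 "Desulfovibrio", "Fusobacterium"]
_HEALTHY_POOL = ["Faecalibacterium", "Roseburia", "Bifidobacterium",
                 "Oscillibacter", "Coprococcus", "Butyrivibrio"]


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults follow a typical three-group hypertension cohort design:
    41 controls, 56 pre-hypertensive, 99 hypertensive samples, two
    community modes, disease genera enriched 4-fold and healthy genera
    depleted 4-fold in the two disease groups.
    """

    n_control: int = 41
    n_phtn: int = 56
    n_htn: int = 99
    n_taxa: int = 20
    genes_per_taxon: int = 60
    n_noise_genes: int = 200
    enterotype_modes: int = 2
    enrichment_effect: float = 4.0
    depletion_effect: float = 0.25
    within_taxon_correlation: float = 0.8
    n_metabolites: int = 60
    n_coupled_metabolites: int = 10
    metabolite_coupling: float = 0.7
    seed: int = 0
    # secondary knobs (log scale unless noted)
    taxon_sigma: float = 1.0           # log-normal sd of taxon abundances
    dominance_boost: float = 5.0       # log boost of the mode's dominant genus
    # asymmetric by design: few genera overgrow in disease while many
    # control-associated genera are depleted, which also lowers disease-group
    # evenness (Shannon) relative to controls
    n_disease_taxa: int = 4
    n_healthy_taxa: int = 11
    mode1_weight_control: float = 0.27  # P(mode 1 | control)
    mode1_weight_disease: float = 0.47  # P(mode 1 | pHTN or HTN)
    # grand-mean mapped reads per gene; the default corresponds to millions
    # of mapped reads per sample, i.e. deep shotgun sequencing
    mean_count: float = 10000.0

    def validate(self) -> None:
        counts = dict(n_control=self.n_control, n_phtn=self.n_phtn, n_htn=self.n_htn,
                      n_taxa=self.n_taxa, genes_per_taxon=self.genes_per_taxon,
                      enterotype_modes=self.enterotype_modes,
                      n_metabolites=self.n_metabolites)
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1 (got {v})")
        if self.n_noise_genes < 0 or self.n_coupled_metabolites < 0:
            raise ValueError("gene/metabolite counts must be non-negative")
        if not (0 < self.depletion_effect < 1 < self.enrichment_effect):
            raise ValueError("need 0 < depletion_effect < 1 < enrichment_effect")
        if not (0 < self.within_taxon_correlation <= 1):
            raise ValueError("within_taxon_correlation must be in (0, 1]")
        if not (0 <= self.metabolite_coupling <= 1):
            raise ValueError("metabolite_coupling must be in [0, 1]")
        if self.enterotype_modes > 2 and self.n_taxa < self.enterotype_modes:
            raise ValueError("need at least one taxon per community mode")
        if self.n_coupled_metabolites > self.n_metabolites:
            raise ValueError("more coupled metabolites than metabolites")


@dataclass
class GroundTruth:
    """Latent structure of a generated cohort, for recovery tests."""

    taxon_of_gene: dict[str, str]          # gene -> taxon, or "noise"
    true_enterotype: dict[str, int]        # sample -> mode (1-based)
    disease_taxa: set[str]
    healthy_taxa: set[str]
    coupled_pairs: set[tuple[str, str]]    # (metabolite, taxon)

    def __post_init__(self) -> None:
        if self.disease_taxa & self.healthy_taxa:
            raise ValueError("disease and healthy taxa must be disjoint")

    def to_json(self) -> str:
        return json.dumps({
            "taxon_of_gene": self.taxon_of_gene,
            "true_enterotype": self.true_enterotype,
            "disease_taxa": sorted(self.disease_taxa),
            "healthy_taxa": sorted(self.healthy_taxa),
            "coupled_pairs": sorted(map(list, self.coupled_pairs)),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(d["taxon_of_gene"], d["true_enterotype"],
                   set(d["disease_taxa"]), set(d["healthy_taxa"]),
                   {tuple(p) for p in d["coupled_pairs"]})


@dataclass
class Cohort:
    """Bundle of everything one synthetic cohort produces."""

    genes: GeneAbundanceMatrix
    taxa: TaxonProfile
    metadata: CohortMetadata
    metabolites: pd.DataFrame            # features x samples intensities
    gene_annotation: pd.DataFrame        # gene_id-indexed: taxon, rank, identity, overlap
    truth: GroundTruth
    config: CohortConfig


def _taxon_names(cfg: CohortConfig) -> list[str]:
    names = list(_MODE_DOMINANTS[:max(cfg.enterotype_modes, 1)])
    # interleave so small cohorts still carry both disease and healthy genera
    pool = [g for pair in zip(_DISEASE_POOL, _HEALTHY_POOL) for g in pair]
    for i in range(cfg.n_taxa - len(names)):
        names.append(pool[i] if i < len(pool) else f"Genus_{i - len(pool) + 1:02d}")
    return names[:cfg.n_taxa]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cohort. Identical config (incl. seed) gives identical output."""
    config.validate()
    if config.genes_per_taxon < 50:
        warnings.warn("genes_per_taxon < 50: co-abundance groups cannot reach "
                      "the 50-gene minimum, CAG recovery is impossible by design",
                      UserWarning, stacklevel=2)
    rng = np.random.default_rng(config.seed)
    n = config.n_control + config.n_phtn + config.n_htn
    samples = [f"S{i + 1:04d}" for i in range(n)]
    groups = np.array(["C"] * config.n_control + ["P"] * config.n_phtn + ["H"] * config.n_htn)

    taxa = _taxon_names(config)
    dominants = taxa[:config.enterotype_modes] if config.enterotype_modes > 1 else []
    candidates = [t for t in taxa if t not in dominants]
    disease = set(t for t in candidates if t in _DISEASE_POOL)
    healthy = set(t for t in candidates if t in _HEALTHY_POOL)
    disease = set(sorted(disease)[:config.n_disease_taxa])
    healthy = set(sorted(healthy)[:config.n_healthy_taxa])
    # top up from generic names if the pools were too small
    rest = [t for t in candidates if t not in disease | healthy]
    while len(disease) < min(config.n_disease_taxa, len(candidates) // 2) and rest:
        disease.add(rest.pop(0))
    while len(healthy) < min(config.n_healthy_taxa, len(candidates) // 2) and rest:
        healthy.add(rest.pop(0))

    # latent community mode per sample (group-linked only via mixing weight)
    if config.enterotype_modes == 1:
        mode = np.ones(n, dtype=int)
    elif config.enterotype_modes == 2:
        p1 = np.where(groups == "C", config.mode1_weight_control,
                      config.mode1_weight_disease)
        mode = np.where(rng.random(n) < p1, 1, 2)
    else:
        mode = rng.integers(1, config.enterotype_modes + 1, size=n)

    # log-normal genus abundances
    base_mu = rng.normal(0.0, 1.0, size=config.n_taxa)
    logab = base_mu[:, None] + config.taxon_sigma * rng.normal(size=(config.n_taxa, n))
    for m, dom in enumerate(dominants, start=1):
        logab[taxa.index(dom)] += config.dominance_boost * (mode == m)
    is_disease_sample = np.isin(groups, ("P", "H"))
    for t in disease:
        logab[taxa.index(t)] += np.log(config.enrichment_effect) * is_disease_sample
    for t in healthy:
        logab[taxa.index(t)] += np.log(config.depletion_effect) * is_disease_sample
    ab = np.exp(logab)
    rel = ab / ab.sum(axis=0, keepdims=True)
    taxa_df = pd.DataFrame(rel, index=taxa, columns=samples)

    # gene catalogue: co-abundant blocks per taxon + independent noise genes.
    # Gene depths track the *unnormalized* taxon abundances (absolute load
    # varies per sample), so genes of unrelated taxa stay uncorrelated;
    # genus profiles recovered from genes are renormalized downstream.
    gene_ids, gene_taxon, blocks = [], [], []
    log_rel = logab
    # Spearman target -> Pearson on the latent normal scale
    r = 2.0 * np.sin(np.pi * min(config.within_taxon_correlation, 0.999) / 6.0)
    for ti, t in enumerate(taxa):
        ids = [f"{t}_g{j + 1:03d}" for j in range(config.genes_per_taxon)]
        gene_ids += ids
        gene_taxon += [t] * len(ids)
        v = np.var(log_rel[ti])
        noise_sd = np.sqrt(max(v, 1e-12) * (1.0 - r) / max(r, 1e-6))
        factors = 10.0 ** rng.uniform(-1.0, 0.0, size=len(ids))  # one decade
        noise = noise_sd * rng.normal(size=(len(ids), n))
        blocks.append(np.exp(log_rel[ti][None, :] + noise) * factors[:, None])
    for j in range(config.n_noise_genes):
        gene_ids.append(f"noise_g{j + 1:04d}")
        gene_taxon.append("noise")
        mu = rng.normal(-3.0, 1.0)
        blocks.append(np.exp(mu + rng.normal(size=(1, n))))
    depth = np.vstack(blocks)

    lengths = pd.Series(rng.integers(300, 3001, size=len(gene_ids)).astype(float),
                        index=gene_ids, name="length")
    # mapped-read counts: Poisson around depth * length, scaled to mean_count
    lam = depth * lengths.values[:, None]
    lam *= config.mean_count / lam.mean()
    counts = pd.DataFrame(rng.poisson(lam), index=gene_ids, columns=samples)
    genes = length_normalize(counts, lengths)

    # per-gene best-genome annotation feeding tracer-gene taxonomy:
    # genus-level quality (identity ~92%) so CAGs resolve to genus, not species
    annotated = rng.random(len(gene_ids)) < 0.95
    ann_rows = []
    for g, t, keep in zip(gene_ids, gene_taxon, annotated):
        if t == "noise" or not keep:
            continue
        ann_rows.append((g, t, "genus",
                         float(np.clip(rng.normal(92.0, 2.0), 80.0, 99.9)),
                         float(np.clip(rng.normal(78.0, 6.0), 40.0, 100.0))))
    annotation = pd.DataFrame(ann_rows, columns=["gene_id", "taxon", "rank",
                                                 "identity", "overlap"]).set_index("gene_id")

    # metabolites: Gaussian-copula coupling to chosen genera on the rank scale
    met_ids = [f"M{i + 1:03d}{'p' if i % 2 == 0 else 'n'}" for i in range(config.n_metabolites)]
    targets = sorted(disease) + sorted(healthy) + [t for t in taxa if t not in disease | healthy]
    coupled_pairs: set[tuple[str, str]] = set()
    inten = np.empty((config.n_metabolites, n))
    rc = 2.0 * np.sin(np.pi * config.metabolite_coupling / 6.0)
    for i, mid in enumerate(met_ids):
        mu, sd = rng.normal(11.0, 1.0), 0.6
        if i < config.n_coupled_metabolites:
            t = targets[i % len(targets)]
            z = stats.norm.ppf(stats.rankdata(rel[taxa.index(t)]) / (n + 1))
            sign = 1.0 if i % 2 == 0 else -1.0
            latent = sign * rc * z + np.sqrt(1 - rc ** 2) * rng.normal(size=n)
            coupled_pairs.add((mid, t))
        else:
            latent = rng.normal(size=n)
        inten[i] = np.exp(mu + sd * latent)
    metabolites = pd.DataFrame(inten, index=met_ids, columns=samples)

    # clinical covariates: blood pressure shifted by group, the rest shared
    sbp = np.select([groups == "C", groups == "P"], [rng.normal(117, 6, n),
                    rng.normal(132, 4, n)], rng.normal(152, 10, n))
    dbp = np.select([groups == "C", groups == "P"], [rng.normal(76, 6, n),
                    rng.normal(85, 3, n)], rng.normal(95, 8, n))
    meta = pd.DataFrame({
        "group": groups, "sbp": np.round(sbp, 1), "dbp": np.round(dbp, 1),
        "bmi": np.round(rng.normal(25.0, 3.0, n), 1),
        "fbg": np.round(rng.normal(5.3, 0.8, n), 2),
        "tc": np.round(rng.normal(4.9, 0.9, n), 2),
        "tg": np.round(rng.normal(1.6, 0.7, n).clip(0.3), 2),
        "ldl": np.round(rng.normal(2.9, 0.8, n).clip(0.5), 2),
    }, index=pd.Index(samples, name="sample_id"))

    truth = GroundTruth(
        taxon_of_gene=dict(zip(gene_ids, gene_taxon)),
        true_enterotype=dict(zip(samples, map(int, mode))),
        disease_taxa=disease, healthy_taxa=healthy, coupled_pairs=coupled_pairs)
    return Cohort(genes=genes, taxa=TaxonProfile(taxa_df, rank="genus", normalized_over="all"),
                  metadata=CohortMetadata(meta), metabolites=metabolites,
                  gene_annotation=annotation, truth=truth, config=config)


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write all cohort tables as plain text; round-trips via `profiles` readers."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.tsv",
        "gene_lengths": out / "gene_lengths.tsv",
        "gene_taxonomy": out / "gene_taxonomy.tsv",
        "taxa": out / "taxa.tsv",
        "metadata": out / "metadata.tsv",
        "metabolites": out / "metabolites.csv",
        "truth": out / "truth.json",
    }
    cohort.genes.counts.to_csv(paths["genes"], sep="\t", index_label="gene_id")
    cohort.genes.gene_length.rename("length").to_csv(
        paths["gene_lengths"], sep="\t", index_label="gene_id")
    cohort.gene_annotation.to_csv(paths["gene_taxonomy"], sep="\t", index_label="gene_id")
    cohort.taxa.rel_abund.to_csv(paths["taxa"], sep="\t", index_label="taxon")
    cohort.metadata.table.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    cohort.metabolites.to_csv(paths["metabolites"], index_label="feature_id")
    paths["truth"].write_text(cohort.truth.to_json())
    return paths
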