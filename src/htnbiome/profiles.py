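"""Abundance profiles from gene counts and taxonomic annotation.

Builds the two substrates of the whole analysis: a length-normalized
gene-depth matrix with a per-sample presence mask, and taxon
relative-abundance profiles obtained by summing the depth of annotated
genes. Also implements the genus prevalence/abundance filter and
LCA-based taxonomic assignment of genes from alignment-hit tables.

All matrices are pandas DataFrames with features as rows and samples as
columns; readers/writers use plain tab-separated text with one header
line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VALID_RANKS = ("species", "genus", "family", "order", "class", "phylum", "kingdom", "root")

#: minimum catalogue gene length in bases
MIN_GENE_LENGTH = 100

#: a gene needs at least this many mapped reads to count as present in a sample
PRESENCE_MIN_READS = 2


@dataclass
class GeneAbundanceMatrix:
    """Length-normalized gene depths (reads per base) with presence mask.

    ``counts`` holds the raw mapped-read counts the depths were derived
    from; downstream pooled abundances (co-abundance groups) need them.
    A gene not present in a sample (fewer than 2 mapped reads)
    contributes zero to every downstream sum regardless of its depth.
    """

    counts: pd.DataFrame
    depth: pd.DataFrame
    present: pd.DataFrame
    gene_length: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.depth.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.depth.columns)

    def effective_depth(self) -> pd.DataFrame:
        """Depth with absent (count < 2) entries zeroed."""
        return self.depth.where(self.present, 0.0)


@dataclass
class TaxonProfile:
    """Per-sample relative abundances of taxa at one rank."""

    rel_abund: pd.DataFrame
    rank: str = "genus"
    #: "annotated" if columns were renormalized over annotated gene mass only
    normalized_over: str = "annotated"
    #: unannotated depth fraction per sample (side channel, not in rel_abund)
    unannotated: pd.Series | None = None

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.rel_abund.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rel_abund.columns)


@dataclass
class CohortMetadata:
    """Sample group labels (C/P/H) plus optional clinical indices."""

    table: pd.DataFrame

    GROUPS = ("C", "P", "H")
    CLINICAL = ("sbp", "dbp", "bmi", "fbg", "tc", "tg", "ldl")

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise ValueError("metadata must have a 'group' column")
        bad = set(self.table["group"]) - set(self.GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    def samples_in(self, *groups: str) -> list[str]:
        return list(self.table.index[self.table["group"].isin(groups)])


@dataclass
class AlignmentHit:
    """One protein-alignment hit of a catalogue gene against a reference taxon."""

    gene_id: str
    subject_taxon_id: str
    evalue: float
    identity: float = 100.0
    overlap: float = 100.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")
        if not (0 <= self.identity <= 100 and 0 <= self.overlap <= 100):
            raise ValueError("identity and overlap are percentages in [0, 100]")


@dataclass
class TaxonomyTree:
    """Rooted taxonomy: taxon_id -> (parent_id, rank, name)."""

    nodes: dict[str, tuple[str, str, str]]
    root: str

    def __post_init__(self) -> None:
        for tid, (_, rank, _) in self.nodes.items():
            if rank not in VALID_RANKS:
                raise ValueError(f"invalid rank {rank!r} for taxon {tid!r}")
        for tid in self.nodes:
            self.path_to_root(tid)  # raises if disconnected

    def path_to_root(self, taxon_id: str) -> list[str]:
        """Node ids from ``taxon_id`` up to and including the root."""
        path = [taxon_id]
        seen = {taxon_id}
        while path[-1] != self.root:
            if path[-1] not in self.nodes:
                raise KeyError(f"taxon {path[-1]!r} not in tree")
            parent = self.nodes[path[-1]][0]
            if parent in seen:
                raise ValueError(f"cycle at taxon {parent!r}")
            path.append(parent)
            seen.add(parent)
        return path


def length_normalize(read_counts: pd.DataFrame, gene_length: pd.Series) -> GeneAbundanceMatrix:
    """Convert mapped-read counts to per-base depth and mark presence.

    depth[g, s] = count[g, s] / length[g]; a gene is present in a sample
    when it has at least 2 mapped reads there.
    """
    counts = read_counts.astype(float)
    if (counts.values < 0).any():
        raise ValueError("read counts must be non-negative")
    missing = counts.index.difference(gene_length.index)
    if len(missing):
        raise KeyError(f"no gene length for: {', '.join(map(str, missing[:5]))}")
    lengths = gene_length.loc[counts.index].astype(float)
    if (lengths < MIN_GENE_LENGTH).any():
        short = lengths.index[lengths < MIN_GENE_LENGTH]
        raise ValueError(f"gene length below catalogue minimum ({MIN_GENE_LENGTH} b): {short[0]}")
    depth = counts.div(lengths, axis=0)
    present = counts >= PRESENCE_MIN_READS
    return GeneAbundanceMatrix(counts=read_counts.copy(), depth=depth,
                               present=present, gene_length=lengths)


def taxon_profile(genes: GeneAbundanceMatrix, gene_taxonomy: pd.Series,
                  rank: str = "genus") -> TaxonProfile:
    """Sum present-gene depths per taxon and renormalize over annotated mass.

    Genes absent from ``gene_taxonomy`` are unannotated; their depth mass
    is reported per sample in the profile's ``unannotated`` side channel
    and excluded from the relative abundances.
    """
    if rank not in VALID_RANKS:
        raise ValueError(f"invalid rank {rank!r}")
    eff = genes.effective_depth()
    annotated = eff.index.intersection(gene_taxonomy.index)
    if len(annotated) == 0:
        raise ValueError(f"no genes annotated at rank {rank!r}")
    summed = eff.loc[annotated].groupby(gene_taxonomy.loc[annotated]).sum()
    total = eff.sum(axis=0)
    annotated_mass = summed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = summed.div(annotated_mass, axis=1).fillna(0.0)
        unannot = (1.0 - annotated_mass / total).fillna(0.0)
    return TaxonProfile(rel_abund=rel, rank=rank, normalized_over="annotated",
                        unannotated=unannot)


def filter_taxa(profile: TaxonProfile, min_mean_abund: float = 1e-4,
                min_prevalence: int = 6, renormalize: bool = False) -> TaxonProfile:
    """Keep taxa with mean relative abundance >= threshold that occur in
    at least ``min_prevalence`` samples.

    Columns are not renormalized by default so abundances stay comparable
    with the unfiltered profile; pass ``renormalize=True`` to rescale.
    """
    rel = profile.rel_abund
    keep = (rel.mean(axis=1) >= min_mean_abund) & ((rel > 0).sum(axis=1) >= min_prevalence)
    if not keep.any():
        raise ValueError("all taxa removed by filter")
    out = rel.loc[keep]
    if renormalize:
        out = out.div(out.sum(axis=0), axis=1)
    return TaxonProfile(rel_abund=out, rank=profile.rank,
                        normalized_over=profile.normalized_over,
                        unannotated=profile.unannotated)


def lca(tree: TaxonomyTree, taxon_ids: list[str]) -> str:
    """Lowest common ancestor of a set of taxa in a rooted tree.

    If the set contains a taxon and its own ancestor, the ancestor wins.
    """
    paths = [tree.path_to_root(t) for t in set(taxon_ids)]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # first node on any root-ward path that all share = deepest common node
    for node in paths[0]:
        if node in common:
            return node
    return tree.root


def assign_gene_lca(hits: list[AlignmentHit], tree: TaxonomyTree,
                    evalue_factor: float = 10.0) -> str:
    """Assign one gene by LCA over its near-best alignment hits.

    Hits with e-value within ``evalue_factor`` times the best hit's
    e-value are retained; the gene gets the LCA of their subject taxa.
    """
    if not hits:
        raise ValueError("at least one hit required")
    for h in hits:
        if h.subject_taxon_id not in tree.nodes:
            raise KeyError(f"subject taxon {h.subject_taxon_id!r} not in taxonomy tree")
    best = min(h.evalue for h in hits)
    retained = [h.subject_taxon_id for h in hits if h.evalue <= evalue_factor * best]
    return lca(tree, retained)


# ---------------------------------------------------------------------------
# plain-text readers / writers (TSV, one header line, no quoting)

def read_gene_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gene_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_gene_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene_id")


def read_gene_taxonomy(path) -> pd.DataFrame:
    """Per-gene best-genome annotation: taxon, rank, identity, overlap."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_taxon_profile(path, rank: str = "genus") -> TaxonProfile:
    rel = pd.read_csv(path, sep="\t", index_col=0)
    return TaxonProfile(rel_abund=rel, rank=rank)


def write_taxon_profile(profile: TaxonProfile, path) -> None:
    profile.rel_abund.to_csv(path, sep="\t", index_label="taxon")


def read_metadata(path) -> CohortMetadata:
    return CohortMetadata(pd.read_csv(path, sep="\t", index_col=0))


def write_metadata(meta: CohortMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_hits(path) -> dict[str, list[AlignmentHit]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[AlignmentHit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene_id, []).append(
            AlignmentHit(row.gene_id, row.subject_taxon, float(row.evalue),
                         float(row.identity), float(row.overlap)))
    return out
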