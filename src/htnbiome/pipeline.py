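"""End-to-end orchestration of the analysis stages.

Runs profiles -> diversity -> enterotype -> CAGs -> networks ->
metabolome -> classifier on either a synthetic cohort or input tables,
writing each stage's artifacts plus a manifest with the seed, the
parameter values, and a checksum per artifact. A rerun with the same
configuration is bit-identical.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([seed, stage_index])`` so any stage can be
reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cag as cag_mod
from . import classifier as clf_mod
from . import diversity as div_mod
from . import enterotype as ent_mod
from . import metabolome as met_mod
from . import network as net_mod
from . import profiles as prof_mod
from .synthetic import CohortConfig, generate_cohort, write_cohort

STAGES = ("simulate", "profiles", "diversity", "enterotype", "cag",
          "network", "metabolome", "classifier")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    outdir: str = "htnbiome_run"
    seed: int = 0
    # either a synthetic cohort config...
    synthetic: CohortConfig | None = None
    # ...or paths to input tables (genes.tsv etc., see synthetic.write_cohort)
    input_dir: str | None = None
    # stage toggles
    run_metabolome: bool = True
    run_classifier: bool = True
    # thresholds (analysis defaults)
    min_mean_abund: float = 1e-4
    min_prevalence: int = 6
    cag_rho_min: float = 0.7
    cag_min_size: int = 50
    network_strong: float = 0.8
    network_weak: float = 0.7
    vip_min: float = 1.5
    t_p_max: float = 0.05
    rho_prune: float = 0.9
    display_min: float = 0.4
    rf_trees: int = 200
    cv_folds: int = 10
    cv_trials: int = 5
    n_boot: int = 500
    restrict_cags_to_markers: bool = True

    def validate(self) -> None:
        if self.synthetic is None and self.input_dir is None:
            raise ValueError("need either a synthetic config or an input directory")


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global one; stable across runs."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(msg: str) -> None:
    print(f"[htnbiome] {msg}", file=sys.stderr)


def _load_inputs(input_dir: str):
    d = Path(input_dir)
    counts = prof_mod.read_gene_counts(d / "genes.tsv")
    lengths = prof_mod.read_gene_lengths(d / "gene_lengths.tsv")
    genes = prof_mod.length_normalize(counts, lengths)
    annotation = prof_mod.read_gene_taxonomy(d / "gene_taxonomy.tsv")
    metadata = prof_mod.read_metadata(d / "metadata.tsv")
    met_path = d / "metabolites.csv"
    metabolites = met_mod.read_metabolites(met_path) if met_path.exists() else None
    return genes, annotation, metadata, metabolites


def run_all(config: RunConfig) -> dict:
    """Execute every enabled stage; returns the run manifest (also written)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "parameters": {
        k: v for k, v in asdict(config).items() if k not in ("synthetic",)},
        "stages": {}, "artifacts": {}}
    if config.synthetic is not None:
        manifest["parameters"]["synthetic"] = asdict(config.synthetic)
    artifacts: dict[str, Path] = {}

    def _done(stage: str, t0: float, paths: dict[str, Path]) -> None:
        artifacts.update(paths)
        manifest["stages"][stage] = sorted(paths)
        _log(f"stage {stage} done in {time.perf_counter() - t0:.1f}s")

    try:
        # --- simulate / load -------------------------------------------------
        t0 = time.perf_counter()
        if config.synthetic is not None:
            cohort = generate_cohort(config.synthetic)
            paths = write_cohort(cohort, out / "cohort")
            genes, annotation = cohort.genes, cohort.gene_annotation
            metadata, metabolites = cohort.metadata, cohort.metabolites
            _done("simulate", t0, {f"cohort/{k}": v for k, v in paths.items()})
        else:
            genes, annotation, metadata, metabolites = _load_inputs(config.input_dir)
            _done("simulate", t0, {})

        # --- profiles --------------------------------------------------------
        t0 = time.perf_counter()
        profile = prof_mod.taxon_profile(genes, annotation["taxon"], rank="genus")
        filtered = prof_mod.filter_taxa(profile, config.min_mean_abund,
                                        config.min_prevalence)
        p1 = out / "genus_profile.tsv"
        prof_mod.write_taxon_profile(filtered, p1)
        _done("profiles", t0, {"genus_profile": p1})

        # --- diversity -------------------------------------------------------
        t0 = time.perf_counter()
        sseed = stage_seed(config.seed, "diversity")
        shannon = div_mod.shannon_index(filtered)
        n = len(metadata.sample_ids)
        ks = sorted({max(1, round(x)) for x in np.linspace(1, n, 10)})
        rare = div_mod.rarefaction_curve(genes.present, ks, n_draws=100, seed=sseed)
        diff = pd.concat([div_mod.differential_features(filtered, metadata, c)
                          for c in (("C", "P"), ("C", "H"))])
        kw_stat, kw_p = div_mod.kruskal_wallis(shannon.shannon.values,
                                               metadata.group.loc[shannon.shannon.index].values)
        paths = {"shannon": out / "shannon.tsv", "rarefaction": out / "rarefaction.tsv",
                 "differential_genera": out / "differential_genera.tsv"}
        shannon.shannon.to_frame().assign(group=metadata.group).to_csv(
            paths["shannon"], sep="\t", index_label="sample_id")
        pd.DataFrame(rare.per_draw, columns=[f"k={k}" for k in rare.sample_counts]).to_csv(
            paths["rarefaction"], sep="\t", index_label="draw")
        diff.to_csv(paths["differential_genera"], sep="\t", index=False)
        manifest["shannon_kruskal"] = {"statistic": kw_stat, "p": kw_p}
        _done("diversity", t0, paths)

        # --- enterotype ------------------------------------------------------
        t0 = time.perf_counter()
        sseed = stage_seed(config.seed, "enterotype")
        dist = ent_mod.jsd_distance(filtered)
        model = ent_mod.optimal_k(dist, filtered, seed=sseed)
        coords, eig, _ = ent_mod.pcoa(dist, n_axes=2)
        assoc = {}
        for c in (("C", "P"), ("C", "H")):
            try:
                _, or_mle, _, p = ent_mod.enterotype_association(model.assignment,
                                                                 metadata, contrast=c)
                assoc[f"{c[0]}-vs-{c[1]}"] = {"odds_ratio": or_mle, "fisher_p": p}
            except ValueError:
                assoc[f"{c[0]}-vs-{c[1]}"] = None
        paths = {"enterotypes": out / "enterotypes.json", "pcoa": out / "pcoa.tsv"}
        paths["enterotypes"].write_text(model.to_json())
        coords.to_csv(paths["pcoa"], sep="\t", index_label="sample_id")
        et1 = model.assignment.index[model.assignment == 1]
        if len(et1) >= 8:
            anchor = model.dominant_taxon.get(1)
            net1 = ent_mod.genus_cooccurrence(filtered, list(et1), anchor_taxon=anchor)
            paths["enterotype1_network"] = out / "enterotype1_network.tsv"
            net1.write_edges(paths["enterotype1_network"])
        manifest["enterotype_association"] = assoc
        manifest["enterotype_k"] = model.k
        _done("enterotype", t0, paths)

        # --- CAGs ------------------------------------------------------------
        t0 = time.perf_counter()
        markers = cag_mod.marker_genes(genes, metadata, contrast=("C", "H"))
        marked = markers.index[markers["call"] != "neutral"]
        depth = genes.effective_depth()
        cag_input = depth.loc[marked] if config.restrict_cags_to_markers else depth
        cags = cag_mod.build_cags(cag_input, rho_min=config.cag_rho_min,
                                  min_size=config.cag_min_size)
        for c in cags:
            c.abundance = cag_mod.cag_abundance(c, genes)
            tax = cag_mod.assign_cag_taxonomy(c, annotation)
            if tax is not None:
                c.tracer_rank, c.tracer_taxon = tax
        cag_ab = pd.DataFrame({c.cag_id: c.abundance for c in cags}).T
        calls = cag_mod.cag_enrichment(cag_ab, metadata, contrast=("C", "H"))
        for c, call in zip(cags, calls):
            c.enrichment = call
        paths = {"cag_table": out / "cags.tsv", "cag_members": out / "cag_members.tsv",
                 "cag_abundance": out / "cag_abundance.tsv"}
        cag_mod.cag_table(cags).to_csv(paths["cag_table"], sep="\t", index=False)
        cag_mod.membership_table(cags).to_csv(paths["cag_members"], sep="\t", index=False)
        cag_ab.to_csv(paths["cag_abundance"], sep="\t", index_label="cag_id")
        manifest["n_marker_genes"] = int(len(marked))
        manifest["n_cags"] = len(cags)
        _done("cag", t0, paths)

        # --- networks --------------------------------------------------------
        t0 = time.perf_counter()
        paths = {}
        if len(cags) >= 2:
            net = net_mod.cooccurrence_network(
                cag_ab, strong=config.network_strong, weak=config.network_weak,
                node_sizes={c.cag_id: c.size for c in cags},
                node_enrichment={c.cag_id: c.enrichment.call for c in cags})
            paths["cag_network"] = out / "cag_network.tsv"
            net.write_edges(paths["cag_network"])
        clin = net_mod.clinical_correlation(cag_ab, metadata)
        paths["clinical_correlation"] = out / "clinical_correlation.tsv"
        clin.to_csv(paths["clinical_correlation"], sep="\t", index=False)
        _done("network", t0, paths)

        # --- metabolome ------------------------------------------------------
        selected_met = None
        if config.run_metabolome and metabolites is not None:
            t0 = time.perf_counter()
            sseed = stage_seed(config.seed, "metabolome")
            diff_met = pd.concat([
                met_mod.differential_metabolites(metabolites, metadata, c,
                                                 vip_min=config.vip_min,
                                                 p_max=config.t_p_max)
                for c in (("C", "P"), ("C", "H"))])
            selected_met = sorted(set(diff_met.index[diff_met["selected"]]))
            assoc_df = met_mod.metabolite_taxon_association(
                metabolites.loc[selected_met] if selected_met else metabolites.iloc[:0],
                filtered.rel_abund, rho_prune=config.rho_prune,
                display_min=config.display_min, seed=sseed)
            paths = {"differential_metabolites": out / "differential_metabolites.tsv",
                     "metabolite_taxon": out / "metabolite_taxon.tsv"}
            diff_met.to_csv(paths["differential_metabolites"], sep="\t",
                            index_label="feature")
            assoc_df.to_csv(paths["metabolite_taxon"], sep="\t", index=False)
            manifest["n_differential_metabolites"] = len(selected_met)
            _done("metabolome", t0, paths)

        # --- classifier ------------------------------------------------------
        if config.run_classifier:
            t0 = time.perf_counter()
            sseed = stage_seed(config.seed, "classifier")
            blocks = [cag_ab]
            vset = "CAGs"
            if config.run_metabolome and metabolites is not None:
                blocks.append(metabolites)
                vset = "CAGs+metabolites"
            X = pd.concat(blocks).T
            aucs = {}
            paths = {}
            for contrast in (("C", "H"), ("C", "P"), ("P", "H")):
                samp = metadata.samples_in(*contrast)
                samp = [s for s in samp if s in X.index]
                ysub = metadata.group.loc[samp]
                rep = clf_mod.classify(
                    X.loc[samp], ysub, seed=sseed, folds=config.cv_folds,
                    trials=config.cv_trials, n_estimators=config.rf_trees,
                    n_boot=config.n_boot,
                    contrast=f"{contrast[0]}-vs-{contrast[1]}", variable_set=vset)
                name = f"classifier_{contrast[0]}{contrast[1]}"
                paths[name] = out / f"{name}.json"
                paths[name].write_text(json.dumps(rep.to_json_dict(), indent=1))
                aucs[rep.contrast] = {"auc": rep.auc, "ci": list(rep.auc_ci)}
            manifest["classifier_auc"] = aucs
            _done("classifier", t0, paths)
    except Exception as exc:
        manifest["failed_stage"] = next(
            (s for s in STAGES if s not in manifest["stages"]), "unknown")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(
            f"pipeline aborted in stage {manifest['failed_stage']!r}: {exc}") from exc

    manifest["artifacts"] = {k: _sha256(p) for k, p in sorted(artifacts.items())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
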