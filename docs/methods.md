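# Methods

`htnbiome` re-implements, as a reusable and tested pipeline, the
statistical workflow that links gut-metagenome structure to
pre-hypertension (pHTN) and hypertension (HTN): gene-level abundance
profiling, diversity and rarefaction, enterotype discovery, odds-ratio
gene enrichment and co-abundance gene groups (CAGs), co-occurrence and
clinical networks, a cross-validated random-forest disease classifier,
and metabolite–taxon coupling. Because suitable real cohorts are
not freely redistributable, the package ships a synthetic-cohort
generator with ground-truth labels; every quantitative
claim the test suite makes is a property of the method evaluated on
those generated cohorts, not a reproduction of any clinical result.

## Abundance profiles

Gene depth is mapped reads divided by gene length (reads per base); a
gene counts as present in a sample only with ≥ 2 mapped reads, and
absent genes contribute zero to every downstream sum. Taxon profiles sum
the depth of present, annotated genes per taxon and renormalize over the
annotated mass only; the unannotated fraction is reported in a side
channel rather than folded into the denominator (configurable). Genus
profiles are filtered to genera with mean relative abundance ≥ 1e-4
present in ≥ 6 samples, and columns are *not* renormalized after
filtering, so Shannon and correlation analyses see the original
abundances (a `renormalize` flag exists).

Gene taxonomy from alignment-hit tables keeps hits with e-value ≤ 10×
the best hit's and assigns the lowest common ancestor of the retained
subject taxa in a rooted taxonomy; a retained taxon together with its
own ancestor resolves to the ancestor.

## Diversity and group testing

Shannon diversity uses natural log by default (log2 available) on the
renormalized per-sample genus vector. Gene rarefaction draws k samples
uniformly *with replacement* and counts genes present in at least one
drawn sample, 100 draws per k. Two-group differences use the two-sided
Wilcoxon rank-sum test — exact enumeration when n₁+n₂ ≤ 20 without
ties, otherwise the tie- and continuity-corrected normal approximation —
with Benjamini–Hochberg (default) or Holm adjustment. Three-group
contrasts use the tie-corrected Kruskal–Wallis statistic against χ²(k−1).
Row Z-scores use the sample standard deviation (ddof = 1); constant rows
are dropped with a warning.

## Enterotypes

Between-sample distance is the square root of the Jensen–Shannon
divergence (natural log; 0·log 0 := 0, no pseudocount), the established
enterotyping metric; plain JSD is available by flag. Clustering is
partitioning around medoids: deterministic greedy BUILD followed by
best-improvement SWAP until no exchange lowers the objective. On tiny
instances (n ≤ 12) the medoid set is found by exhaustive enumeration
instead, because single-swap local optima exist there and the exact
optimum is cheap. The number of clusters is chosen by the
Calinski–Harabasz index computed on all positive principal-coordinate
axes (centroids need a Euclidean embedding; classical scaling provides
one). PCoA reports negative eigenvalues but never uses them. Cluster ×
group association uses the two-sided Fisher exact test, with both the
conditional-MLE odds ratio and the sample odds ratio (Haldane +0.5 on
zero cells).

## Co-abundance gene groups

A gene's OR score dichotomizes its abundance at the median over the two
contrasted groups (ties are "low"; the third group is always excluded
from the table) and computes the 2×2 odds ratio with Haldane +0.5 when
any cell is zero. OR > 2 calls a feature enriched, OR < 0.5 depleted,
boundaries exclusive. Marker genes (non-neutral calls) are clustered by
Spearman ρ ≥ 0.7: CAGs are the connected components of that gene graph
with ≥ 50 members, a rule chosen for determinism and order-invariance
over agglomerative alternatives; the chaining risk of single-linkage-like
components is acknowledged and bounded in practice by the high threshold.
CAG abundance pools member read counts over member bases (length-weighted
mean depth). Tracer-gene taxonomy assigns a species when ≥ 90% of member
genes align to it at ≥ 95% identity and ≥ 70% query overlap, else a genus
at ≥ 80% of genes and ≥ 85% identity; among qualifying taxa the highest
fraction wins and exact ties stay unassigned. DNA and protein identities
are collapsed to a single per-gene identity (callers supply the smaller).

## Networks

Feature co-occurrence networks carry Spearman correlations as edges,
tiered strong (ρ > 0.8) and weak (0.7 ≤ ρ ≤ 0.8); only positive edges
are exported by default, matching the display convention, while negative
edges can be retained with their sign. Clinical correlations (SBP, DBP,
BMI, FBG, TC, TG, LDL) drop missing values pairwise, use a
t-approximate Spearman p for n ≥ 10 and exact permutation below, and
apply Holm step-down across all (feature, index) pairs.

## Classifier

The disease classifier is a random forest (500 trees by default, √p
features per split, unlimited depth). The sample set is split 80/20 with
stratification; variable ranking — permutation importance on accuracy,
i.e. mean decrease in accuracy — and subset-size selection by repeated
stratified 10-fold cross-validation (5 trials) happen strictly inside
the training partition, so the held-out test set never informs
selection. The selected size is the error-curve argmin capped at 1000.
The refit model is scored on the test set by ROC/AUC with a stratified
bootstrap percentile confidence interval (2000 reps by default). A
label-permutation harness reruns the entire pipeline per replicate to
calibrate the null AUC.

## Metabolome

PLS-DA is fitted by NIPALS (PLS2, deterministic start from the first
one-hot response column, tolerance 1e-10) on autoscaled intensities;
VIP_j = √(p · Σₐ SSₐ (w_ja/‖wₐ‖)² / Σₐ SSₐ) with SSₐ the Y sum of
squares captured by component a, so Σ VIP² = p identically. Differential
metabolites need VIP > 1.5 and Welch t-test p < 0.05 (pooled-variance
flag available). Metabolite–taxon association prunes collinear taxa
(one random representative per |Spearman r| ≥ 0.9 cluster), fits a
bidirectional AIC-stepwise linear model per metabolite over the
representatives, and reports sign(coefficient)·|Spearman r| per retained
taxon, suppressing |r| < 0.4 from the display table. Sign-only
coefficient scaling keeps reported values in [−1, 1]; AIC was chosen as
the stepwise criterion because none is canonical for this procedure.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
at realistic cohort group sizes (41 control / 56 pHTN / 99 HTN by
default):

- **Genus profiles**: log-normal abundances (σ = 1.0) with two latent
  community modes, each dominated by a distinct genus
  (*Prevotella*-like vs *Bacteroides*-like) via a +5 log-mean boost.
  Mode membership is independent of disease except through a mixing
  weight (P(mode 1) = 0.27 in controls, 0.47 in disease groups),
  reproducing the disease-skewed mode occupancy qualitatively.
- **Group effects**: designated disease genera (4 by default) are
  multiplied 4-fold and healthy genera (up to 11 by default) 0.25-fold
  in pHTN/HTN samples. The asymmetry — few overgrowing genera against
  many depleted control-associated ones — also lowers disease-group
  evenness, so genus-level Shannon diversity is lower in disease on
  average. pHTN and HTN share one generating distribution, which is what
  makes them classifiable against controls but mutually
  near-inseparable.
- **Gene catalogue**: each genus carries a block of genes whose depths
  track the genus's *unnormalized* load times a frozen per-gene factor
  (log-uniform over one decade) times log-normal noise calibrated — via
  the Gaussian-copula rank correction r = 2 sin(πρ/6) — to hit the
  target within-taxon Spearman ρ (default 0.8) in expectation. Using the
  unnormalized load keeps genes of unrelated taxa uncorrelated. Read
  counts are Poisson around depth × length, scaled to 10⁴ mean reads per
  gene (≈10⁷ mapped reads per sample, the deep-shotgun regime; much
  shallower coverage lets Poisson noise fragment rare genera's CAGs).
- **Metabolites**: coupled features follow a Gaussian copula on the rank
  scale of their target genus's relative abundance, achieving |Spearman
  ρ| ≈ the coupling parameter regardless of marginal shape; signs
  alternate; remaining features are independent log-normals.
- **Clinical indices**: SBP/DBP are group-shifted Gaussians consistent
  with the defining BP ranges of the three groups; BMI/FBG/TC/TG/LDL are
  group-independent.

What the generator does **not** emulate: raw reads and sequencing error,
assembly artifacts, compositional zero-inflation, covariate confounding
(age, sex, BMI structure), or batch effects. Passing recovery tests
therefore demonstrates the pipeline's correctness and operating
characteristics under its own assumptions, not performance on real
stool metagenomes.

## Evaluation design and problem sizes

Recovery experiments run at desk scale, chosen once: enterotype recovery
on 100 cohorts of 80 samples × 10 genera; CAG recovery on 100 cohorts of
5 genera × 100 genes (+50 noise genes, 80 samples); enrichment
calibration on 500 null genes and ~1000 4-fold-effect genes at 40
samples/group; classifier checks on one default-sized cohort with a
30-replicate permutation null; coupling recovery on 15 cohorts of 24
metabolites (8 coupled at 0.7).

Coupling recovery deliberately uses cohorts with a single community mode
and no group effects: with those on, group enrichment and the
mode-dominance normalization factor induce *genuine* secondary
metabolite–taxon correlations above the 0.4 display threshold, which the
display rule is designed to show; counting them as false pairs would
measure the generator's correlation structure, not the recovery
procedure.

## Numerical and degenerate-input conventions

Zero-variance features are dropped with warnings wherever a correlation
or autoscaling is undefined; constant features under test receive p = 1
and a flag. Assignment ties in PAM go to the lowest-index medoid; CAG
ids order by descending size. The pipeline fans a single global seed out
to per-stage seeds via `SeedSequence([seed, stage_index])`, so reruns
are bit-identical and stages are independently reproducible.

## Known limitations

- Connected-component clustering can chain distinct genomes through
  shared-regulation genes at ρ just above 0.7; the deliberately high
  threshold mitigates but does not eliminate this.
- The OR-score construction (median dichotomization) is one faithful
  reading of an under-specified procedure; it is isolated behind a
  single function so presence/absence or quantile variants can be
  swapped in.
- Exact Spearman permutation p-values are used only below n = 10;
  between 10 and ~30 the t-approximation is mildly anti-conservative.
- PLS-DA components are capped by the rank bound min(n−1, p); no
  orthogonalized (OPLS) variant is provided since all quantitative
  filters run through VIP.
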