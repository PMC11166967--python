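# Methods

## The generative model behind the synthetic study

`simdata` emulates a multi-mission rodent skin experiment: three missions
partitioned into ten flight-vs-ground data subsets by diet (2) × skin site
(2) for mission 1, skin site (2) for mission 2, and strain (2) × duration
(2) for mission 3, with a configurable number of replicates per condition
group (default 6 per group, 120 samples in all).

Counts are gamma–Poisson (negative binomial) draws

    K_gj ~ NB(mean = s_j · μ_g · 2^{L_gj},  Var = μ + α(μ_g)·μ²)

with

* baseline means μ_g log-normal: ln μ_g ~ N(4.0, 1.5²), i.e. a median
  count around 55 with a long right tail. No public depth/abundance
  characterization exists for the motivating datasets, so these are
  conventional bulk RNA-seq values chosen once and not revisited.
* dispersion trend α(μ) = a₀/μ + a₁ with defaults a₀ = 0.01, a₁ = 0.1 —
  a typical mean–dispersion relationship with asymptotic biological CV²
  of 0.1.
* size factors s_j log-uniform on [0.5, 2], a typical library-size spread.
* planted log2 offsets L: per-subset DE genes add ±log2FC to the flight
  group of their subset (cross-mission genes are planted in one subset of
  each mission); co-expression modules add loading×f_m with a shared
  standard-normal latent factor f_m per sample; synergy genes add a
  latent z drawn as described below.

One global seed streams per-stage sub-seeds (baseline, size factors,
latents, synergy, counts) through a counter, so a fixed
(design, params, effects, seed) tuple reproduces the matrix bit for bit.

**Synergy planting.** A synergy pair (a, b) is defined by the label rule
P(flight | z_a, z_b) = σ(c·z_a·z_b) with c = 3 by default: the product form
makes each gene exactly uninformative on its own (the marginals of z given
the label remain standard normal by symmetry) while the pair is strongly
informative jointly. The stand-alone benchmark generator
(`simulate_synergy_dataset`) draws the latents first and samples the label
from the rule. Inside a fixed flight/ground design the labels are given,
so `simulate_counts` instead rejection-samples (z_a, z_b) from N(0,1)²
conditioned on each sample's label — the joint law matches the rule with
a balanced prior, and the marginal symmetry (hence non-predictivity of
single genes) is preserved.

**What the generator does not emulate.** Library-size/abundance
correlations, gene–gene correlation beyond the planted modules, batch
structure, GC/length biases, outlier counts, and any real biology of skin.
Passing recovery tests therefore demonstrates that the statistical
machinery recovers the effects it models, not that it would behave
identically on the deposited mission data.

## Differential expression

Per data subset, flight is contrasted with ground:

1. **Filtering.** Genes with the spike-in prefix `ERCC-` are removed
   first, then genes whose number of samples with a nonzero count is below
   the smallest condition-group size. (The order is immaterial to the
   result; "smallest group" is the only per-subset-well-defined reading of
   a minimum-detection rule.) No further filtering happens downstream —
   every tested gene is reported, with no outlier-based p removal and no
   mean-expression independent filtering.
2. **Normalization.** Median-of-ratios size factors against the geometric
   mean of genes detected in every sample, rescaled to geometric mean 1.
   When no gene is positive everywhere, `pseudo_reference=True` uses
   positive-count geometric means and positive-count medians.
3. **Dispersion.** Raw per-gene dispersions by method of moments on
   normalized counts pooled within condition groups, with the Poisson term
   corrected by E[1/s]; a non-negative least-squares fit of
   α(μ) = a₀/μ + a₁ across genes (one MAD-based re-fit to resist
   outliers); the working dispersion is the arithmetic blend
   w·raw + (1−w)·trend (default w = 0.5), floored at 1e-8. Raw moments
   below the floor (variance < mean) are floored rather than dropped.
   The arithmetic blend (not log-scale) keeps floor-level raw values from
   collapsing the final dispersion below the trend.
4. **Wald test.** Per-gene NB GLM with log link, design
   (intercept + condition), offsets log s_j and the final dispersion held
   fixed, fitted by damped IRLS (vectorized across genes; agreement with
   `statsmodels` GLM to ~1e-6). log2FC = β̂/ln 2, SE from the observed
   information, t = log2FC/SE, two-sided normal p, BH adjustment. Fits
   that diverge (a condition group of all zeros) are capped at
   |β| = 30 and reported with their capped estimate; fits that fail to
   converge otherwise are flagged and their p set missing (and excluded
   from the BH denominator, since missing p-values cannot be ranked).

**Calibration.** Under the generator's null (no planted effects, 2,000
genes, n = 6/6) the pooled rejection rate at p < 0.05 is ≈ 0.05–0.06 and
the p-distribution is uniform (KS ≈ 0.015); with 10% planted DE at
|log2FC| = 2 the FDR ≤ 0.1 call set shows an observed false-discovery
proportion ≈ 0.1 and sensitivity ≈ 0.98. These are recomputed by the test
suite and `scripts/acceptance.py`, not quoted from anywhere.

**A note on scale invariance.** Multiplying one sample's counts by k
multiplies its size factor by k and leaves normalized counts unchanged up
to a single global constant — that is exact and tested. The Wald *estimate*
is not exactly invariant: the NB likelihood weights samples by depth, so a
deeper copy of a sample shifts per-gene MLEs slightly (any
likelihood-based implementation behaves this way). The invariance claim is
therefore stated, and tested, at the normalization level.

## Consensus calling

Pure set logic over per-subset FDR columns, with an inclusive threshold
(FDR ≤ 0.1 is significant). A gene absent from a subset's tested universe
counts as not significant there; effect direction is not required to agree
across subsets (the motivating cross-mission gene lists mix directions).
Cross-mission genes need ≥ 1 significant subset in each of ≥ 2 distinct
missions. All three operations (multi-subset list, cross-mission list,
exact-membership upset counts) are verified against brute-force
enumeration on random tables.

## Enrichment

* **ORA**: upper-tail hypergeometric p for the overlap of a query with
  each set restricted to the universe; sets are tested only when their
  restricted size is *strictly* greater than `min_size` (so the documented
  "size > 15" and "size > 1" modes read literally); BH across tested sets.
* **GSEA (preranked)**: genes ordered by Wald t-score descending, ties
  broken by gene id for determinism. Members add |t|^w (w = 1 by default,
  the prerank convention) normalized over the set; non-members subtract
  1/(N−K); ES is the running sum at its maximal |deviation|. The null
  permutes gene labels (equivalently, draws random same-size member sets;
  masks are shared across sets of equal size for speed) — matching the
  preranked setting where no phenotype columns exist. p is sign-matched:
  (1 + #{same-sign perms with |ES*| ≥ |ES|}) / (1 + #same-sign perms);
  NES = ES / mean|same-sign permuted ES|. The leading edge is the set
  members at ranks up to the extremum (from the extremum down for
  negative ES).

## Gene modules

Run on log2(normalized count + 1). Filters compose uniqueness → variance:
first drop genes whose modal value (after rounding to 6 decimals — exact
float equality is meaningless on processed values) occurs in strictly more
than a quarter of samples, then keep genes with sample variance (ddof = 1)
≥ 1.7. The scale of the variance cut is not canonical; both the threshold
and the scale are configurable, with the log2 default documented here.
Gene rows are z-scored before embedding so distances reflect co-variation
rather than baseline abundance. The embedding contract is pluggable: UMAP
(seeded, default) or an exact PCA projection; clustering is HDBSCAN
(scikit-learn implementation) on the 2-D coordinates — the stated goal of
the reduction is clustering, not display — with labels remapped to be
contiguous from 0 and noise at −1. Cluster annotation runs ORA per cluster
(noise excluded) against each supplied collection at FDR ≤ 0.05.

## Two-gene models

The search grammar is a fixed, open family of six forms (single, additive,
interaction, product, Gaussian bump, tanh — 2 to 5 parameters each),
chosen to express smooth one- and two-region decision boundaries.
Exhaustive enumeration of every unordered pair × form (plus single-gene
forms) replaces any stochastic/evolutionary search: determinism and
testability at desk scale were judged more valuable than search-space
breadth. Fits maximize the L2-penalized Bernoulli likelihood (λ = 1e-3,
unpenalized intercept) — Newton iterations for the convex
linear-in-features forms (batched across all candidate pairs), multi-start
L-BFGS with analytic gradients for the two non-convex forms (a batched
Adam sweep during screening).

Ranking is by cross-validated AUC — stratified 5-fold, per-fold AUCs
averaged. Per-fold averaging (rather than pooling out-of-fold scores into
one ranking) avoids mixing fold-specific score calibrations of the
non-linear forms, which otherwise biases the estimate downward. Ties break
toward lower complexity, then lower log-loss. Two guards keep the
exhaustive search honest and tractable:

* only the `cv_top` (default 50) screening leaders by training AUC are
  re-scored by cross-validation; every candidate is still fitted and
  ranked, but the expensive CV is restricted to models that could
  plausibly win;
* because the final ranking maximizes over many noisy CV estimates, the
  reported `auc_cv` of the returned models is re-estimated on a fresh set
  of folds after selection — the selected order is kept, but the numbers
  shown are free of winner's-curse bias. On an all-noise pool of 50 genes
  at n = 80 the reported top CV-AUC stays below 0.75 despite ~6,000
  candidates.

AUC uses the Mann–Whitney midrank formulation throughout. Inputs are
z-scored inside each fit (per training fold during CV), which makes
CV-AUC invariant to affine rescaling of the expression inputs.
`select_mrmr` greedily prefers models sharing no genes among those within
an AUC tolerance of the leader. Decision boundaries are exported as
probability rasters over the observed range ± 10%; the 0.5 contour is the
level set of the raster.

## Upstream regulators

For a signed knowledge base of regulator→target edges and one subset's DE
table: targets significant at FDR ≤ 0.1 with nonzero log2FC form the
overlap; a target is consistent when sign(log2FC) equals the edge sign;
z = (n_consistent − n_inconsistent)/√n_overlap. Targets with log2FC
exactly 0 have undefined sign and are excluded from both counts and the
overlap. Overlap enrichment is Fisher's exact upper tail on the 2×2 of
significance × target membership over the tested universe, BH-adjusted
across regulators. Calls are activated (z > 1), inhibited (z < −1), both
requiring adjusted p < 0.05, with strict inequalities. Regulators with an
empty overlap are omitted (logged). Only this simple consistency z is
implemented; confidence-weighted edges and regulator–regulator cascades
are out of scope (a weighted z is a natural extension point). The
regulator×subset z matrix is ordered by complete-linkage agglomeration on
Euclidean distances of the unstandardized z-scores; missing entries are
imputed as 0 with a logged count, and tie-breaking follows scipy's
deterministic input-order convention.

## Pipeline and problem sizes

`spaceskin run` executes dge → consensus → {enrichment, modules, pairs,
regulators} from one YAML config (exactly one of input paths or a
simulation block; unknown keys rejected by name; stage prerequisites
enforced before any computation). Defaults: DEG FDR ≤ 0.1, consensus at
≥ 2 subsets / ≥ 2 missions, GSEA size > 15 with 1,000 permutations,
module variance ≥ 1.7, regulator calls |z| > 1 & adjusted p < 0.05. The
manifest records versions, seed, parameters, input checksums and per-stage
record counts (every filter logs genes in/out); identical config + seed
reproduce byte-identical TSVs.

Validation problem sizes were chosen for single-CPU runs: 2,000 genes ×
12 samples for calibration/recovery sweeps (5 seeds), 2,000 genes × 120
samples for module recovery (10 seeds), n = 80 with 50 decoys for the
synergy search (10 planted + 10 null seeds), 600 genes for the end-to-end
determinism run. The recovery results quoted anywhere in this repository
are produced by `tests/` and `scripts/acceptance.py` at exactly these
sizes.

## Known limitations

* Only intercept + condition designs are tested; covariates are carried in
  the sample table but not modeled. No likelihood-ratio tests, no log2FC
  shrinkage, no outlier refitting.
* The dispersion shrinkage weight (0.5) is a simple documented choice, not
  an empirical-Bayes fit.
* GSEA p-values are plain permutation estimates; no multilevel refinement
  for very small p.
* The two-gene grammar is a deliberate open stand-in for proprietary
  symbolic-regression search; it will not reproduce any specific
  commercial engine's models or printed AUCs, and models never exceed two
  genes.
* The regulator stage ships no knowledge-base content; edge tables are
  user-supplied or synthetic.
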