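# Methods

## Scope and data model

`immunosig` operates on a genes × samples expression table
(`ExpressionMatrix`) carrying an explicit scale flag — `linear` for
nonnegative counts/intensities, `log2` after transformation — plus
optional per-sample annotations (cancer type, cohort).  Survival data
travel as a per-sample table with positive time, a 0/1 event flag, and
covariates; gene sets as GMT (with an optional `GENE|WEIGHT` token
dialect); dendrograms as ultrametric newick.

## Preprocessing

**Upper-quartile normalization.** "Generally detected" genes are those
with value ≥ `detection_count` (default 1) in ≥ `detection_fraction`
(default 0.75) of samples; each sample is divided by its 75th
percentile over that gene set and multiplied by the cohort mean of
those percentiles so magnitudes stay count-like.  Pure division would
be equally valid; the rescale constant is recorded in the normalization
log so either convention can be recovered.  A sample whose
detected-gene upper quartile is zero is an error naming the sample.

**Probe collapse.** When several probes map to one gene, the probe with
the greatest detection level — operationalized as the largest mean
value across the cohort, the simplest monotone summary — is retained;
ties go to the lexicographically smallest probe id, and the chosen map
is returned for logging.  Note the choice must be made *before* gene
centering (centering zeroes the means the rule compares).

**Log2 and centering.** `log2(x + 1)` by default (the pseudocount
avoids −∞ on counts); per-gene mean centering is required before gene
clustering and refuses linear-scale input.

**Stratified subsampling.** Up to `cap` (default 200) samples per
cancer type, drawn uniformly without replacement with a seeded
generator, so no single large cohort dominates a pan-cancer clustering.

## Clustering

Genes (and samples) are agglomerated under correlation distance
`d = 1 − Pearson r` with **centroid linkage**: the dissimilarity
between clusters is the correlation distance between their mean
profiles, recomputed from the raw profiles after every merge.  Centroid
linkage under a non-Euclidean dissimilarity admits no exact
Lance–Williams recursion, so recomputation is the only self-consistent
definition; average linkage (mean pairwise distance, Lance–Williams
update) is available as an alternative.  Consequences and choices:

- **Inversions.** Centroid heights can decrease (merging correlated
  genes sharpens the centroid, raising its correlation with the rest of
  the module).  Decreasing heights are flattened up to the previous
  height and logged; flat runs of equal heights inside tight modules
  are therefore expected.
- **Determinism.** Ties in the minimum distance (within 1e−12) break on
  the lexicographically smallest pair of cluster representatives (the
  smallest leaf label in each cluster), making the merge sequence
  deterministic and invariant to input order.  Constant profiles are
  rejected by name, since their correlation is undefined.
- **Complexity.** Only distances to the newly formed cluster change per
  merge, so clustering is O(n²) distance evaluations; the test suite
  checks merge-for-merge agreement with an O(n³) full-rescan oracle.

**Module extraction** cuts the gene tree at a height or a cluster
count; clusters of at least `min_size` genes become modules annotated
with their dominant immunome classes (most frequent class among
members, from a 22-class LM22-style taxonomy shipped as an editable
placeholder GMT).  When no cut is given, the 25th percentile of merge
heights is used and flagged — a convention, not an estimate.  In
practice a height cut between the within-module merge heights (~0.1–0.2
at within-correlation 0.8–0.9) and the background level (~1) separates
planted modules exactly; a *count* cut is unreliable on
correlation-distance trees because all cross-module and
module-background distances concentrate near 1, leaving the late merge
order to noise.

**Focus set and sample partition.** The focus set is the union of genes
from modules whose dominant classes intersect the requested classes, in
sorted order.  Samples are re-clustered on the (centered) focus
submatrix and cut at k = 2; the cluster with the higher mean log2 focus
expression is labelled immune-active.  Whether two groups genuinely
exist is judged by Ashman's D on per-sample mean focus expression
(`D = |m_A − m_B| / sqrt((s_A² + s_B²)/2)`, conventional bimodality
threshold D ≥ 2): below it the cohort is treated as a single degenerate
group and labelled active with a warning; an exact mean tie labels the
larger cluster active.  Correlation-profile sample clustering is
genuinely fragile — when the immune-activity signal has little
across-gene variance, or module factors happen to dominate, the k = 2
cut can split on a module axis instead of activity.  The simulator's
per-gene shift heterogeneity (below) reflects the across-gene amplitude
variation that real infiltration programs have and that this step
depends on.

## Scoring

Raw score: `S_j = Σ_g w_g x_gj / Σ_g w_g` on log2 values.  Weights
default to 1 (the assumption-free reading of a "weighted average" with
no published weight table) and can be overridden per gene through the
GMT weight dialect.  Up to 10% of a signature's genes may be missing
from a matrix (weights renormalized, event logged) — cross-platform
cohorts rarely carry every gene — beyond which scoring fails listing
the absentees.

Standardization: `Z_j = (2 S_j − (q15 + q85)) / (q85 − q15)` with
percentiles from the linear-interpolation quantile estimator (recorded
in metadata; the estimator choice matters only at small n).  For an
approximately Gaussian score distribution `q85 − q15 ≈ 2.07 σ`, so
sd(Z) ≈ 0.97 — one unit of Z is about one cohort standard deviation.
Per-cohort re-standardization is the default; the fitted (q15, q85) are
stored so a frozen transform can be applied to held-out samples in
deployment.

Ratio signatures are raw-score differences (log2 of a geometric-mean
ratio, so shifts common to both signatures cancel), then standardized.
Forming the ratio before standardizing is the default order; the
opposite order can be composed from the public functions if wanted.
Median dichotomization sends exact ties to Low (logged) and is also
used for single-gene stratifiers such as COL2A1, where no published
cutoff exists.

## Survival analysis

The Cox partial likelihood is maximized by damped Newton iterations on
the analytic gradient and Hessian (step halving keeps the likelihood
non-decreasing; design columns are centered for conditioning, which
leaves β unchanged).  Convergence at max |score| < 1e−9 or
|Δ log-lik| < 1e−10, at most 100 iterations; |β| > 15 at any point is
reported as monotone likelihood / complete separation (no penalized
fallback is provided).  Ties: **Breslow** by default — matching the
default of SAS PROC PHREG, the reference implementation for this style
of analysis — with Efron optional; the two agree exactly when event
times are distinct.  Standard errors come from the inverse observed
information; all inference is Wald (per-term z, joint χ² per
categorical block, HR CI `exp(β ± 1.96 SE)`).  No proportional-hazards
diagnostics are computed.

Categorical covariates are reference-coded: stage against the lowest
stage, cytoreduction against Suboptimal (so the reported HR is Optimal
vs Suboptimal, with Unknown as a third level), receptor/mutation status
against the unexposed level.  Stage significance is reported as the
joint block test — a multi-level class variable has no single HR.

`build_model` fits signature + age (years, untransformed) + stage +
cytoreduction (+ optional extras); when the cytoreduction block's joint
Wald p exceeds 0.10 the model is refit without it, and both fits plus
the decision are retained.  Kaplan–Meier curves use the product-limit
estimator with censoring marks; the High/Low contrast is summarized by
a univariable Cox fit on the group indicator (Low as reference).

## Synthetic cohorts

The generator emulates the cohort features the pipeline depends on, at
desk scale:

- **Structure.** `n_types` cancer types (default 3) × `samples_per_type`
  (default 100); per-gene log2 baselines ~ Uniform(3, 9) with per-type
  offsets ~ N(0, 0.5²) (the cancer-type effect); background genes add
  independent N(0, noise_sd²) noise (noise_sd default 1.0 log2 units).
- **Modules.** Gene g in module m deviates by
  `noise_sd·(√ρ·f_mj + √(1−ρ)·ε_gj)` with a per-sample latent factor
  f_mj, so the expected pairwise within-module correlation is ρ
  (default 0.8).  Defaults mirror the packaged signatures: 57-gene
  cytotoxic-lymphocyte, 3-gene CXCR3-ligand, 4-gene M2-macrophage
  modules.
- **Immune activity.** Each sample is active with probability
  `active_fraction` (default 0.4); active samples gain
  `active_shift · u_g` log2 units on module genes, with per-gene
  amplitudes u_g ~ Uniform(0.5, 1.5) drawn once.  Heterogeneous
  amplitudes matter: a per-module-constant shift is an across-gene
  constant that Pearson profile correlation cannot see, so uniform
  shifts would make correlation-based sample partitioning blind to
  activity regardless of effect size.  Default shifts: 2.0
  (lymphocyte and trafficking modules), 1.0 (macrophage module, which
  tracks activity only weakly).
- **Counts.** Reported expression is `round(2^log2)`, so the
  upper-quartile normalizer sees realistic input; the generating log2
  matrix, module membership, active flags and true scores stay in the
  truth record.  True raw/standardized scores are computed with the
  package's own scoring code (uniform weights) on the generating
  matrix, so recovery tests compare like with like.
- **Survival.** Inverse-transform sampling of a Weibull baseline:
  `T = scale·(−log U / exp(lp))^(1/shape)` with shape 1.2, scale 3
  (years; median ≈ 2.2 years at lp = 0), and
  `lp = Σ_s β_s Z_s + covariate effects`.  Default β gives the
  trafficking:macrophage ratio a hazard ratio of 0.6 per standardized
  unit.  Age ~ N(57, 11²) clipped to [30, 90] (entering lp centered),
  stage multinomial (6/82/12% for ≤2/3/4), cytoreduction
  (69/6/25% Optimal/Suboptimal/Unknown); default covariate effects are
  0.015/year for age, 0.3/0.6 for stage 3/4, 0 for cytoreduction.
  Censoring is administrative only, at `censor_time` (default 5 years,
  ~12–16% censored under the defaults) — right-censoring without
  inventing a dropout mechanism.

**What the simulator does not model:** library-size variation and
count overdispersion, tumor purity, batch effects, copy-number or
mutational covariates, competing risks, and informative censoring.
Passing recovery tests therefore shows the pipeline's statistics are
implemented correctly under a proportional-hazards, latent-factor
world; it does not certify performance on real cohorts, where the
immune-activity signal is entangled with purity and platform effects.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 120–400 samples and 20–130
genes, 200-replicate calibration/coverage loops, and 100 random
small-matrix oracle comparisons — sizes at which every statistical
check is stable and the full suite runs in minutes on one CPU.
Quantiles are linear-interpolation throughout (scoring, cohort
summaries).  Correlations are clipped to [−1, 1] before forming
distances; exponentials in the partial likelihood are globally shifted
to avoid overflow.  Seeds propagate from a single integer: the
simulator derives independent expression/survival streams, and the
pipeline derives per-stage seeds by hashing the stage name with the
global seed, so stages are individually re-runnable.

## Known limitations

- Centroid linkage with correlation distance is non-monotone by
  construction; flattened inversions mean heights inside tight modules
  are not unique merge heights.
- The k = 2 sample partition assumes one dominant activity axis; with
  several strong uncorrelated programs it can split on the wrong one
  (the Ashman's-D guard only detects the fully degenerate case).
- The Cox solver handles moderate dimensionality (tens of columns);
  there is no penalization, stratification, time-varying covariates or
  frailty.
- Packaged CLIS/M2TAM/immunome memberships are placeholders at the
  published set sizes, meant to be replaced for real analyses; results
  on real data depend on the actual membership lists used.
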