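# Methods

This note documents the models implemented in `natalmeth`, the design
choices made where the methodology was genuinely open, the synthetic
cohort the tests run on, and the limits of what those tests demonstrate.

## Synthetic cohort generator

The generator (`synthetic_cohort`) emulates a matched neonatal
case–control methylation study with genome-wide genotypes. It is
first-class, tested code: every downstream module is validated against
cohorts it produces, with known injected truth.

**Genotypes.** Each sample carries two haplotypes; each haplotype is a
latent standard-Gaussian AR(1) process along the variant lattice with
lag-one correlation `ld_rho`, thresholded at the allele-frequency
quantile Φ⁻¹(f_j). Dosage is the sum of the two haplotype alleles. This
is the simplest generator with a tunable adjacent-variant r² and exact
marginal allele frequencies; it does not produce realistic haplotype
block structure or recombination hotspots. Allele frequencies are drawn
uniformly from `maf_range` (default 0.05–0.5). Missing calls are
injected completely at random at 1% by default.

**Sample sheet and matching.** Samples come in pairs sharing sex, birth
month, birth year and urbanicity; gestational age is matched within a
configurable window (`ga_match_tol`, default ±1 week — the matching
tolerance is exposed as a parameter rather than fixed, since "as close
as possible" matching has no canonical width). Marginal distributions
are calibrated to a late-1990s Danish birth cohort: gestational age
N(39.6, 1.77) weeks, birth weight N(3525, 560) g, days-to-sampling
N(6.08, 3.24) clipped at 1, birth years 1998–2002 with the observed
frequencies, five urbanicity levels. Case status is assigned within each
pair to the member with the higher genetic liability (causal-variant
burden plus standard logistic noise), which induces the case–control
PRS separation downstream scans should detect. Maternal smoking is then
drawn at 29.0% for cases and 21.2% for controls.

**GWAS summary statistics.** Per-variant estimates are drawn around the
true effects with the analytic quantitative-trait standard error
SE_j = 1/√(2 f_j (1−f_j) n_gwas) (default n_gwas = 45,162), so SE scales
as 1/√n and null p-values are uniform.

**Methylome.** β = clip(ωB + mQTL + PRS + smoking + batch + GA-trend +
noise, 0, 1). The cell-type reference B (default 6 types) is drawn once
per seed from Beta(2, 2) and held fixed; per-sample fractions ω come
from a blood-like Dirichlet (concentration 60 × [0.55, 0.20, 0.09, 0.07,
0.05, 0.04]). Effects are injected on the beta scale (effect sizes in
the field are reported in percent methylation): mQTL terms add
effect × dosage, PRS terms add effect × (score − mean score), smoking
terms add a constant offset in exposed samples. Batch offsets are
N(0, 0.003) per plate × CpG and per-CpG gestational-age slopes
N(0, 0.0005). The score used for PRS-linked injection is computed
through the package's own clump-and-score pipeline (p_T = 1), so the
downstream scan's exposure is exactly the injected one; this mirrors
real practice, where scores are computed once upstream of sample
filtering. When intensities are simulated, total intensity is drawn per
sample and probe (log-normal sample scale around 12,000, which puts
median channel intensities comfortably above the QC threshold for clean
samples), M = β(T + 100), U = T − M, and the authoritative beta is
recomputed as M/(M + U + 100). Sex-chromosome probes (40 X, 20 Y by
default) are bimodal by true sex to support the sex check. Detection
p-values are < 0.05 for good entries with a small configurable failure
fraction; ten bisulfite control scores per sample are N(95, 2.5); the 65
genotyping probes mirror the first 65 genotyped variants (β = d/2 plus
N(0, 0.02) noise).

What the generator does **not** emulate: realistic haplotype panels,
probe-type-specific intensity distributions and dye biases, spatial
plate effects, trio structure, or genuine cell-type reference data.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under the assumed generative model, not
performance on real arrays.

## QC pipeline

Steps run in a fixed order (intensity, bisulfite, plate controls,
duplicates, sex, genotype concordance, detection p) but every step is
evaluated on the full input, so each failing sample carries the reasons
of all steps it fails and the result is order-independent. Choices worth
recording:

- All "<" thresholds are strict: a median intensity of exactly 2500 or a
  bisulfite median of exactly 80 passes.
- The detection-p sample and probe criteria are evaluated simultaneously
  on the input matrix, not sequentially, matching the behavior of the
  standard array-QC filter and making the result independent of
  evaluation order.
- Duplicate correlation (0.95) and genotype-concordance (0.9) thresholds
  are defaults with no canonical published value; both are parameters.
- The sex check runs classical (Torgerson) MDS on Euclidean distances —
  equivalent to the first principal component of the centered probe
  matrix — separately for X and Y probes, splits the first coordinate
  with 2-means, assigns each cluster the majority reported sex (ties
  resolve toward the reported label), and flags disagreements on either
  chromosome. The procedure is invariant to the arbitrary sign of the
  coordinate.
- Plate-control verification (step 3) is a presence check only: no plate
  map format is defined.
- Normalization is probe-type-wise quantile normalization of the
  methylated and unmethylated channels to the mean empirical
  distribution, a simplified variant of the standard intensity-based
  method that omits the background-equalization pre-step. Rank order
  within sample and probe type is preserved exactly; with a single
  sample it is the identity.
- Retention is reported as 100 × retained/input to one decimal.

## Predictors and deconvolution

Linear scores are affine in beta under the identity transform. The age
calibration F(x) = (1+A)eˣ − 1 for x ≤ 0 and (1+A)x + A otherwise
(adult age A = 20) follows the published form of chronological-age
clocks. Coefficient CpGs absent from the data are dropped with a warning
(an absent column has no cohort values to impute from); NaN entries at
present CpGs are imputed with the cohort mean so scores remain
comparable across samples. The smoking score is computed on beta values
(whether M-values were ever intended is unstated in the source
literature; beta is assumed and flagged here).

Deconvolution solves the nonnegative least-squares projection per sample
(scipy's NNLS active-set routine; the contract is the optimum, not the
algorithm). No sum-to-one equality is imposed — the row sum is reported
as a QC column instead. On noiseless mixtures recovery is exact to
1e-8; with iid noise of sd 0.02 on 50 CpGs and 6 cell types the RMSE
stays below 0.05 (measured ≈ 0.012).

Two-group comparisons use Welch's unequal-variance t-test throughout;
no variance-equality assumption is made anywhere.

## PRS construction

Clumping is greedy: variants with p ≤ clump_p1 are visited in ascending
p (ties broken by chromosome, then position); each index variant removes
not-yet-retained variants with p ≤ clump_p2 within clump_kb kilobases
whose dosage r² exceeds clump_r2 (defaults 1, 1, 500 kb, 0.1). r² is the
squared Pearson correlation of dosages within the analysis sample — no
external LD reference panel is used (whether the original analyses used
in-sample or reference LD is unstated; in-sample is implemented).
Scores are raw weighted sums (standardization left to downstream
models); selection at each threshold uses strict p < p_T; alleles are
harmonized to the genotype effect allele by flipping the weight sign
when the summary-statistic orientation is reversed, which makes
orientation a true no-op; missing dosages are mean-imputed (2f) inside
the sum while the count of non-missing genotypes is carried as a
covariate.

## EWAS engine

One vectorized OLS core drives all scans: coefficients from the normal
equations, per-CpG residual variance, t statistics against n − p degrees
of freedom. Betas are analyzed untransformed. Birth month and year are
treated as categorical indicators (they are reported as categories);
gestational age and birth weight as continuous. Missing covariates are
handled by complete-case analysis with per-CpG n reported. Collinear
design columns are pruned greedily left-to-right (intercept, exposure,
interaction, covariates) so the exposure always survives; dropped
columns are reported. All six cell-composition proportions are entered,
relying on the collinearity pruning to drop one if they sum to a
constant. Zero-variance CpGs are skipped and listed.

Iterative SNP conditioning adds dosages as covariates in ascending GWAS
p-value order ("order of significance" is read as the GWAS ordering,
since the variants are defined by the GWAS; a different ordering can be
passed), records the score term's p after each addition, and stops once
it exceeds `stop_p` (default 0.05). The power calculator is the standard
normal approximation Φ(−z_{α/2} + δ/SE) + Φ(−z_{α/2} − δ/SE) with
SE = sd√(1/n₁ + 1/n₂); a reported > 90%-power claim for a
0.3-percentage-point difference at meta-analysis scale is reproducible
only conditional on an assumed per-CpG methylation sd — at sd 1.2% the
calculator gives ≈ 92%, and the quantity is treated as a parameterized
property rather than a fixed constant.

## Meta-analysis, sign tests, DMRs

Fisher's method uses natural logs with p clamped at 1e-300; combination
is restricted to CpGs present in at least two cohorts. The pooled effect
is inverse-variance fixed-effects (the simplest estimator consistent
with reporting a pooled mean difference); random-effects models are out
of scope. The sign test is the exact two-sided binomial against 0.5;
because its p-values are discrete it is conservative (super-uniform)
under the null — its type-I rate is at or below nominal rather than its
p-values being exactly uniform. The selection threshold for "top" loci
defaults to 5e-5 with a `top_k` alternative; no canonical count exists.

The regional scan anchors a window of width `window_bp` (default 1000)
at each CpG per chromosome, collapses duplicate member sets, and scores
windows with ≥ `min_cpgs` members by Brown's method: the Fisher
statistic referred to a scaled chi-square whose scale and degrees of
freedom come from the Kost–McDermott polynomial approximation to
cov(−2 ln pᵢ, −2 ln pⱼ) evaluated at the empirical correlation of the
member CpGs' betas. With independent members this reduces exactly to
Fisher; with perfectly correlated members the window counts as a single
test. The underlying published DMR procedure's internals are not fully
specified; Brown's correlated Fisher is adopted as a documented
interpretation. Window-level multiple testing is Bonferroni over tested
windows.

## mQTL scan and colocalization

The cis window is ±500 kb, inclusive at the boundary, on 1-based
positions ('chr' prefixes are normalized away; BED output converts to
0-based half-open). The matrix scan residualizes both methylation and
dosages against the covariates (intercept, sex, five genetic PCs by
convention) via a QR projection, converts residual correlations to t
statistics with n − q − 1 degrees of freedom, and recovers slopes and
SEs — by the Frisch–Waugh theorem this equals per-pair OLS, verified to
1e-8 against an independent oracle. Expected (imputed-mean) dosages are
used for missing calls; beta values, not M-values, are the outcome
(both conventions are unstated in the source literature; flags exist).
Monomorphic variants are skipped and counted. Per-pair significance is
reported against 1e-13, but all pairs are emitted with their p.

Colocalization uses Wakefield log approximate Bayes factors,
log ABF = ½log(1−r) + z²r/2 with r = W/(V+W), prior effect sd √W = 0.2
for quantitative traits and 0.15 for case–control (log-odds) traits, and
priors p1 = p2 = 1e-4, p12 = 1e-5 (the published defaults of the
standard implementation; all are parameters). The five hypothesis
weights — H0: 1, H1: p1·ΣBF₁, H2: p2·ΣBF₂, H3: p1p2·Σ_{j≠k}BF₁ⱼBF₂ₖ,
H4: p12·ΣBF₁ⱼBF₂ⱼ — are accumulated entirely in log space (the H3 cross
term via a log-difference), so posteriors are overflow-free and sum to
1 ± 1e-12 even with z ≈ 40 signals; with a single shared variant H3 is
exactly 0. If the GWAS side supplies only p, frequency and N, the
estimate variance is reconstructed from the z-score and the analytic SE
(a documented approximation). Region analysis considers CpGs within
±250 kb (inclusive) of each index variant and reports PP3+PP4 > 0.99
(support) and PP4/PP3 > 1 (shared-variant preference).

## Problem sizes and numerical choices

The acceptance script works at the study's own scale where that is
cheap: QC bookkeeping on 1316 samples; effect recovery in 1263-sample
cohorts with 2000 CpGs and 150 variants over 50 replicate seeds
(noise sd 0.01, representing residual post-normalization technical
noise of order 1% beta units); colocalization regions of 100 variants at
n = 5000 with causal z ≈ 8; calibration checks at 10⁴ replicates. The
unit-test suite uses smaller cohorts (n = 60–2000) chosen so each check
retains its statistical meaning. Simulation-based assertions use fixed
seeds and binomial/Poisson confidence margins rather than point
equalities. Effect-recovery summaries pool per-replicate estimates by
inverse variance, the efficient combination given that a single
replicate's slope SE is large relative to a −0.0014 beta-unit effect.

## Known limitations

- In-sample LD for clumping; no reference-panel mode.
- The quantile normalization omits the background-equalization pre-step
  of the full published method.
- Brown's method relies on the beta-correlation approximation to the
  covariance of log p-values; its family-wise error control is verified
  empirically on null simulations, not analytically.
- The colocalization model assumes at most one causal variant per trait
  per region.
- Conditional scans use observed (imputed-expectation) dosages; hard
  re-calling is not implemented.
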