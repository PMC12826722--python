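# Methods

This note records the statistical model behind each stage of egaclock,
the defaults and why they were chosen, what the synthetic cohorts do and
do not emulate, and the numerically delicate corners.

## Data model

The central object is a `MethylationDataset`: a probes × samples matrix
tagged as beta (proportion methylated, in [0,1]) or M (log2 logit,
M = log2(β/(1−β))), aligned row-wise with a probe manifest (chromosome,
1-based position, QC flags, gene/category annotation) and column-wise
with a sample table (GA in days, sex, race, exposures). Analyses run on
the M scale, where methylation differences are closer to homoskedastic;
betas of exactly 0/1 are clamped to [1e-6, 1−1e-6] before the logit so
the transform stays finite (noted in the QC report).

## Probe QC and normalization

A probe is removed when it (a) exceeded the detection-p threshold
(default 0.05) in more than `detection_fail_fraction_max` of samples —
default 0, i.e. any failing sample removes the probe, the strictest
reading of a detection filter, configurable upward; (b) carries a SNP at
its 3' or 5' end; (c) sits on a sex chromosome; or (d) is flagged
off-target. Quantile normalization operates on betas before the M
transform (normalize, then logit): each column's sorted values are
replaced by the across-column mean of order statistics, ties receiving
the mean of their tied ranks' reference values, which makes the result
deterministic and rank-preserving. Plain quantile normalization is used
rather than a probe-type-aware variant; the two differ only when probe
chemistries are heterogeneous, which the synthetic cohorts do not model.

## Latent factors

Unmeasured structure (cell composition, batch) is estimated by
residualizing the sample × probe matrix on the known covariates and
taking top left singular vectors of the residual as factor scores. Two
details matter:

- **Choosing K (parallel analysis).** The k-th observed singular value
  is compared with k-th singular values of matrices in which each
  probe's residuals are independently permuted across samples. Permuted
  columns are re-projected onto the covariate-orthogonal subspace and
  rescaled to their original norms — without this the null singular
  values are biased low by roughly q/n (q covariates, n samples) and
  the test over-selects. Significance uses the exact permutation rule
  p = (1 + #{null ≥ observed})/(B + 1) ≤ 0.05, which requires B ≥ 19
  permutations (default B = 20) and has correct finite-sample size,
  unlike an interpolated 95th percentile.
- **Outcome protection.** When the GA vector is passed as `outcome`, it
  joins the residualization design, so estimated factors are orthogonal
  to GA in-sample. With a dense causal signal (hundreds of CpGs
  tracking GA) the unprotected SVD's leading factors include the GA
  direction itself, and adjusting for them destroys the association
  scan — in a 5,000-probe experiment the hit count fell from 179 to 1.
  The clock pipeline therefore uses the protected flavor. The flip
  side: confounding that is collinear with GA cannot be removed by a
  GA-orthogonal factor, so the protected flavor leaves such bias in
  place; the unprotected flavor removes it (this is what the
  inflation-reduction check exercises) at the cost of absorbing true
  signal. This is an inherent identifiability tradeoff; methods that
  resolve it jointly model the outcome and confounders, which is out of
  scope here and documented as an approximation.

Sign convention: each factor is flipped so its largest-magnitude probe
loading is positive, making runs bit-reproducible.

## EWAS

Per probe, OLS of M-values on intercept, GA (days), a sex dummy, race
dummies (largest category as reference — the reference does not affect
the GA coefficient), and latent factor scores. t = estimate/SE with
n − rank(X) degrees of freedom, two-sided p. Because the design is
shared by all complete-data probes, the scan is one batched
least-squares solve; probes with missing values fall back to
complete-case per-probe fits, and zero-variance or rank-deficient
probes are flagged rather than aborting the run. Multiple testing uses
Benjamini–Hochberg (step-up; NaNs excluded from m). Calibration is
summarized by genomic inflation λ = median(χ²)/0.4549, where the χ²
are the p-values' inverse upper-tail transforms; λ ≈ 1 on null data,
while true widespread signal legitimately pushes λ above 1.

## Region calling

The region stage treats EWAS p-values as a spatial process:

1. **ACF**: Pearson correlation of z = Φ⁻¹(1−p) over intra-chromosome
   probe pairs, binned by distance (default 50-bp bins to 1 kb); bins
   with fewer than 10 pairs are flagged and set to 0.
2. **Smoothing**: each site's p is replaced by a Stouffer–Liptak
   combination over neighbors within ±1 kb, z_comb = Σz/√(Σσ_ij), with
   σ from the ACF bin of each pairwise distance; non-positive-definite
   σ matrices are repaired by eigenvalue clipping (flagged).
3. **Runs**: maximal stretches of smoothed p < 0.05 with inter-probe
   gaps ≤ 1 kb and at least two probes become candidate regions; the
   region p combines the members' raw EWAS p-values under the ACF σ.
4. **Search-space correction**: Šidák, 1 − (1−p)^(T/ℓ), where ℓ is the
   region span and T the total probe-covered span (positions ± window,
   unioned per chromosome) — the effective search space, not the genome
   length. Computed via expm1/log1p to stay accurate for small p.
5. **FDR** over the Šidák-corrected region p-values, threshold 0.05.

Defaults (seed 0.05, window/gap 1 kb, 50-bp ACF bins) follow the
original comb-p convention and are all config-exposed. Coordinates are
1-based inclusive in TSV output and 0-based half-open in BED.

## Annotation and enrichment

Nearest gene = minimal |TSS distance| on the probe's chromosome, ties
alphabetical. Category precedence: promoter bands measured strictly
upstream of the TSS (≤1 kb, 1–2 kb, 2–3 kb) > 5' UTR > 3' UTR > 1st
exon > other exon > 1st intron > other intron > downstream (≤300 bp
past the gene end) > distal intergenic; every probe gets exactly one
category, determined against its single nearest gene. Gene models carry
explicit UTR intervals (the synthetic generator places the 5' UTR in
the leading half of the first exon and the 3' UTR in the trailing half
of the last, a simplification that keeps the category logic exercised
without a CDS model).

Category enrichment: with N array probes, K in a category, and n
significant, the observed count x is tested one-sided both ways,
p_over = P(X ≥ x) and p_under = P(X ≤ x), X ~ hypergeometric — the two
tests share the mass at x. Gene-set enrichment restricts a one-sided
Fisher exact test (hypergeometric upper tail) to the array's annotated
gene background; user-supplied GMT files stand in for proprietary
pathway databases.

## The clock

Training follows a fixed procedure: (1) an 80/20 split — test size
floor(0.2·n), reproducing the 313/78 split of a 391-sample cohort;
(2) EWAS on training samples only, keeping CpGs with q < 0.05;
(3) elastic net over the selected CpGs, minimizing
(1/2n)‖y − Xβ − Zγ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²) with the covariate
block Zγ (intercept, sex, race, latent factors) unpenalized. Because
the penalty touches only β, the optimum is exactly an elastic net on
Z-residualized y and X (Frisch–Waugh–Lovell), with γ recovered by least
squares afterwards; λ = 0 therefore reduces to OLS exactly. α defaults
to 0.5 (neutral between lasso and ridge; config-exposed), λ to the
minimizer of 5-fold CV MSE over a 100-point log grid, deterministic
given the seed; CpG columns are standardized internally and
coefficients returned on the original scale. (4) Five-fold CV inside
training yields per-sample EGA; samples whose |residual| exceeds 20×
the mean absolute residual are dropped and the model refit once (the
mean of absolute residuals, since signed residuals average ≈ 0 and
would make the rule degenerate). (5) The final model predicts the test
set, using test samples' own covariates with the training γ and latent
scores projected through the training loadings.

Whole-cohort EGA uses the same machinery in five-fold CV: folds are
assigned on the sorted sample ids (so results are invariant to input
order), and each fold's EWAS, feature selection, latent factors and fit
see only the training 4/5 — no leakage, verified by a byte-identity
test under test-label shuffling. EGAA = EGA − GA, positive meaning
epigenetically "older" than the chronological estimate.

Agreement metrics: Pearson r; R² as squared correlation of observed
with predicted ("variance explained"); ICC as the two-way
absolute-agreement single-measures coefficient from the two-column
ANOVA decomposition (this variant penalizes systematic bias, which is
the point of comparing a predictor to a gold standard); Bland–Altman
mean difference with limits mean ± 1.96·SD of the differences.

## Exposure models

Single-exposure models are unadjusted OLS, dummy-coded against declared
reference levels (vaginal delivery, unmarried, male, "No"), with the
term's overall F-test p and BH-FDR across the 22 exposures within each
outcome (GA, EGA, EGAA); complete cases per model. Constant exposures
are untestable and skipped in the batch runner (a degenerate outcome
still raises). Backward selection starts from all candidates on the
complete-case-across-all rows (n fixed so AIC is comparable), computes
AIC = n·ln(RSS/n) + 2k omitting additive constants, and greedily drops
the whole term (all dummy levels at once) whose removal most decreases
AIC until no drop helps.

## Synthetic cohorts

The generator emulates a term-birth cord-blood methylation study. GA is
truncated-normal (mean 274.02, SD 11.02, range 210–300 days — the
cohort mean/SD plus plausible clinical bounds spanning pre- to
post-term). M-values are baseline + slope·(GA − mean) + latent loadings
+ sex/race shifts on 2% probe subsets + probe-specific Gaussian noise;
baselines are drawn so betas concentrate in (0.05, 0.95), avoiding
M-value blow-up. Defaults: 391 samples, 45,954 probes, 5% causal CpGs
with slopes ~ Normal(0, 0.02 M-units/day), noise SD uniform on
(0.2, 0.6) M-units, three latent factors with loadings ~ Normal(0, 0.1)
and configurable GA correlation (latent scores are drawn jointly with
GA in z-space, so `confounding_strength` is exactly the latent–GA
correlation). Per-(probe,sample) detection failures occur at 1e-5 — on
a ~400-sample cohort the any-sample QC rule then removes ~0.4% of
probes, the scale of detection attrition on real arrays. Separate RNG
sub-streams drive each component, so e.g. setting the causal effect SD
to zero reproduces the pure-null matrix bit for bit.

Exposures: 22 columns (continuous, binary, and multi-level categorical)
with marginals shaped like a diverse birth cohort. Effects on GA are
imposed by tilting: categorical level probabilities are exponentially
tilted in GA, P(level|GA) ∝ π·exp(δ·(GA−μ)/σ²), which shifts the
conditional GA mean of a level by δ days relative to the reference to
first order; continuous exposures gain a δ·σ_x²·(GA−μ)/σ² component
giving a GA-on-X slope of δ. Defaults plant a −4.38-day planned
C-section effect, +3.29 unplanned, and +2.28 days per birth-weight
z-unit. GA truncation makes the tilt slightly approximate; recovered
effects land within a few percent of the configured values.

What the generator does **not** emulate: probe-type chemistry
differences, cell-type mixtures (no cell counts existed in the
motivating setting), spatially correlated *null* methylation (probes
are independent given the factors, so the DMR null is conservative),
non-Gaussian effect-size distributions, and missing exposure patterns
beyond what tests construct explicitly. Passing tests therefore show
the machinery is correct and calibrated under this model, not that any
particular biological cohort would yield the same numbers.

## Problem sizes and determinism

The shipped checks use cohorts of 200–500 samples and 1,500–5,000
probes, with 20 replicate cohorts for region-recovery rates and 30 for
exposure-effect recovery — sizes at which every Monte-Carlo tolerance
asserted is several standard errors wide while the whole suite stays
interactive. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical config and seed give
bit-identical matrices, fits, and output files.

## Known limitations

- The latent-factor estimator cannot simultaneously protect the outcome
  and remove outcome-collinear confounding (see above); users must pick
  the flavor matching their design.
- Category enrichment treats probes as exchangeable; CpG density per
  gene varies on real arrays, which can bias gene-level enrichment.
- The elastic-net CV residualizes covariates on the full training set
  before the internal λ search, a standard but slightly optimistic
  shortcut; the outer CV and held-out test metrics are unaffected.
- Extremely small combined p-values are reported at float precision;
  Šidák and Stouffer–Liptak computations clip inputs at 1e-15.
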