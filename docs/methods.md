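# Methods

This note records the models the package implements, the reasoning
behind the open design choices, the synthetic-data generator's
assumptions, and the numerical conventions that tests rely on.

## Mixed models and the REML engine

All adjustment and prediction models are linear mixed models with a
covariance structure that is linear in its parameters,
V(θ) = Σₖ θₖ Vₖ, where each Vₖ is the contribution of one random term:
a grouped factor (ZZ′), a diagonal weight structure, a kernel term
(ZKZ′), or an arbitrary dense symmetric matrix (used for the trait
blocks of the bivariate models).  The engine (`specblup.reml`)
maximizes the REML log-likelihood by Newton steps on the average
information matrix with step halving, an EM-flavoured fallback when
the AI step is not an ascent direction, and an expanding line search
that accelerates the slow crawl which otherwise occurs when a weakly
identified variance (for example a two-level flight-date effect)
drifts toward an infinite-variance asymptote.  Variances are floored
at 1e-10 × var(y) and capped at 1e6 × var(y); a component held at
either bound with an outward gradient is treated as an active
constraint and excluded from the step.  Convergence requires a
relative log-likelihood change below 1e-10 (or three consecutive
sub-1e-6 relative gains, which indicates a likelihood ridge).
Covariance parameters (the off-diagonals of the unstructured 2×2 trait
matrices) are unbounded; after every accepted step each 2×2 block is
projected onto the PSD cone by shrinking its covariance.

The implementation is dense: every iteration factorizes the n×n
marginal covariance of the observations.  That is deliberate — the
target data volumes (thousands of plots, hundreds of genotypes) fit
comfortably, and dense algebra keeps the exact trace computations that
the AI updates need.  It would be the wrong engine for, say, national
animal-breeding evaluations.

### Adjustment models

* **Across environments (phenotypes).**  Genotype fixed (cell-means
  coding, so the fixed-effect covariance is directly the BLUE
  variance-covariance matrix); location, year, year×location and the
  three genotype interactions random; trial, replicate-within-trial
  and block-within-replicate random with a separate variance per
  environment; residual variance heterogeneous per environment.
  σ²_g for heritability comes from a second fit with genotype random,
  as the corresponding fixed-genotype model has no genetic variance.
* **Within environment.**  Genotype fixed; trial, trial·rep and
  trial·rep·block random.  One-plot-per-genotype layouts are
  saturated, and the BLUE is returned as the plot value directly.
* **Bands, stage 1 (per environment).**  Genotype fixed; date and all
  date interactions random; the compound-symmetric correlation of the
  two flight dates on a plot is implemented as a plot-level random
  effect shared across dates plus an independent residual.  This
  device cannot represent a *negative* between-date correlation; with
  two dates such a fit degenerates to independent errors, which the
  engine reaches by driving the plot variance to its floor.  A test
  verifies that the device and a direct 2×2 within-plot covariance
  parameterization reach the same maximized REML log-likelihood.
  Single-date environments (or single-date analyses) drop the date
  terms.
* **Bands, stage 2 (across environments).**  Genotype fixed;
  environment and genotype×environment random; the residual diagonal
  is fixed at the inverse stage-1 Smith weights with one estimated
  scale.  Smith weights are the diagonal of the inverted
  variance-covariance matrix of the stage-1 means — the diagonal
  approximation; the full matrix is discarded beyond its diagonal.
  With one observation per genotype×environment cell the G×E and
  scaled-residual variances are separated only by the spread of the
  weights; the engine's ridge handling (stagnation rule) makes these
  fits converge reliably.

### Heritability, outliers, arithmetic

Entry-mean heritability is h² = σ²_g / (σ²_g + v̄/2) with v̄ the mean
variance of a difference between adjusted genotype means, computed
from the full BLUE covariance matrix.  Outlier screening fits the
across-environment model with genotype random, robustly standardizes
the conditional residuals (median centring, 1.4826·MAD scaling),
converts to two-sided normal p-values and applies Bonferroni–Holm at a
familywise α of 0.05; this is a faithful-in-spirit implementation of
the re-scaled-MAD ("M4r") screen, not a line-by-line reproduction of
its original description.  Plots flagged for DMY also lose their
spectral records.  DMY = FMY × DMC / 100 exactly.

## Kernels

Marker QC is two-pass: drop markers with >10% missing entries or
minor allele frequency <0.05, impute the remaining missing dosages
with the rounded per-marker mean, then re-filter on MAF (imputation
can push a marker across the threshold).  Mean imputation replaces the
LD-based imputer used with real array data; it is isolated behind
`filter_markers` so a stronger imputer can be swapped in, and all
synthetic data are complete anyway.  G is VanRaden method 1 with
allele frequencies estimated from the data, which forces G's row sums
to zero.  H = DD′ standardizes each band's BLUEs with the n−1 SD
denominator — fixed and documented because trace(H) = (n−1)·b is a
test invariant.  H is not rescaled to unit mean diagonal; the kernel
variance component absorbs the scale.  Any kernel entering a REML fit
is PSD-repaired by a ridge of 1e-6 × mean diagonal when its smallest
eigenvalue is negative.

Whether band standardization should use all genotypes or training-set
statistics inside cross-validation is genuinely ambiguous; the package
standardizes over all genotypes (matching how the kernels are
constructed once for the full panel), and the no-leakage guarantee is
defined on the *response*: validation DMY never reaches a training
computation, which the validation layer asserts structurally and the
tests verify by corruption-invariance.

## Penalized band selection

The elastic-net objective is the glmnet parameterization
(1/2n)‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖²), solved by cyclic coordinate
descent with an active-set strategy (full sweeps refresh the active
set, inner sweeps iterate the nonzero coordinates); the inner loop is
numba-compiled.  Convergence: maximum coefficient change < 1e-7.  The
λ path descends log-spaced from λ_max (the smallest λ with an all-zero
Lasso solution) over 100 points to λ_max/1000; λ is tuned by seeded
tenfold cross-validation, and for the elastic net α is tuned by an
outer CV over a user grid with ties resolved toward the sparser
(larger) α.  Selection runs are one penalized fit per training
resample (default 100 resamples of 80% of the genotypes, run count
configurable), and a band is selected when its recovery rate strictly
exceeds 40%.  The response is the across-environment DMY BLUE; the
predictors are the stage-2 band BLUEs — i.e. exactly the stage-3
inputs.  Selection is unweighted.  If no band clears the threshold at
small problem sizes, the pipeline falls back to the most-recovered
bands with a logged warning, so H_vsel always exists.

## Prediction models

Univariate fits put the stage weights into a fixed diagonal residual
with one estimated scale.  The bivariate models are fitted unweighted
(the weighted variant is available via the `weights` argument).  The
seven (co)variance parameters of the full bivariate model — 2×2 C_K,
2×2 C_H and 2×2 R, with the appropriate blocks dropped for the reduced
models — are estimated by the same AI-REML engine using dense trait-
block components.  Predictions for genotypes without a phenotype are
Gaussian conditional expectations, E[g|y] = Cov(g, y) V⁻¹ (y − Xβ̂);
for bivariate fits the observed secondary-trait records of masked
genotypes sit in the training rows, so the conditioning uses them —
this is the mechanism by which spectral/secondary data improve
prediction of unphenotyped candidates, and it is also why HBLUP can
predict genotypes with no yield record at all (spectra exist for
everyone).  When G and H are nearly identical (kernel correlation
>0.99) the split of genetic variance between them is unidentified; the
multi-kernel fit warns and returns the (well-defined) sum.

## Validation

S1 uses repeated random k-fold partitions (fold sizes differ by at
most one) or fixed training-set sizes with the remainder as
validation; guards require k ≤ n/3 and TRN ≤ n−3 so every validation
set supports a correlation.  The selected-fraction evaluation ranks
validation genotypes by predicted DMY, extracts the top 10/20/30/40%,
and averages their observed DMY and PH BLUEs over iterations; ranking
ties break by a stable sort on genotype id.  S2 rebuilds the spectral
kernel per combination from the training environments only — stage-1
means are reused (they are per-environment quantities), but the
stage-2 combination is recomputed on the training subset, a
conservative choice that guarantees the held-out environment
contributes nothing to the kernel.  The DMY training response is
likewise the weighted combination of the training environments'
within-environment BLUEs, and the validation target is the held-out
environment's within-environment BLUEs.  Summary standard errors are
SD/√reps across repetitions.  Post-hoc mean-separation tests are out
of scope; raw per-repetition abilities are exported instead.

## The synthetic-data generator

The generator emulates the study conditions end to end with these
default choices (one RNG stream per operation, derived from the master
seed by fixed offsets, so stages can be regenerated independently):

* **Genome / population.**  Markers are placed uniformly on 7
  chromosomes (rye karyotype) with a per-interval recombination
  probability set so each chromosome averages 1.5 crossovers per
  meiosis.  RILs descend from a round-robin chain of biparental
  founder crosses followed by four generations of selfing with
  recombination, leaving the expected 0.5⁴ residual heterozygosity per
  initially heterozygous locus.  Tester effects of the testcross are
  absorbed into the genotype breeding value.  A configurable fraction
  of markers (default 10%) carries additive bivariate effects; because
  linkage leaves few independent genome segments, the realized DMY–PH
  breeding-value correlation is set exactly to the configured value by
  a Gram–Schmidt step that keeps both traits linear in the markers.
* **Phenotypes.**  Plot DMY (dt/ha) and PH (cm) are genotype BV +
  location/year/interaction effects + trial/replicate/block effects +
  environment-specific Gaussian error; DMC is drawn around 35% and FMY
  back-computed so DMY = FMY × DMC / 100 holds exactly.  The G×E and
  error variances are calibrated from the target entry-mean
  heritabilities: the target difference-variance v̄/2 =
  σ²_g(1−h²)/h² is split half to G×E and half to plot error, with the
  G×E budget spread over L×G, Y×G and L×Y×G (30/30/40) and the
  calibration accounting for how each term averages into a genotype
  mean (σ²_LG/L + σ²_YG/Y + σ²_LYG/LY).  Per-environment error SDs
  spread ±20% around the calibrated value with the mean variance on
  target.  Design effects (trial/rep/block) add realistic nuisance
  variation that the adjustment must remove; they slightly inflate v̄,
  so realized heritability estimates sit a few points below the
  nominal target — the recovery tests allow for this.  Optionally,
  selected environments draw their G×E effects independently
  ("decorrelated environments"), emulating a site that ranks genotypes
  unlike all others.
* **Spectra.**  Normalized reflectance = a smooth canopy profile
  (sigmoid red-edge jump from ~0.1 to ~0.5) + a DMY-linked genetic
  signal (Gaussian loading bump centred at 750 nm, width 30 nm, with a
  latent genotype score that is a noisy version of the DMY breeding
  value) + a smooth DMY-unrelated genetic background (cosine basis with
  per-genotype coefficients, shaped by an envelope that dips just past
  the red edge so band heritability varies along the spectrum) +
  smooth genotype-by-environment deviations + date effects + plot-level
  brightness offsets + noise.  The noise per plot×band is split into a
  component shared across the two flight dates and an independent
  remainder so the between-date error correlation equals the
  configured compound-symmetry value by construction.  Amplitudes are
  set so plot-level band–DMY correlations stay below ~0.3 and peak at
  the red edge, and mean band heritability lands near 0.7 with a wide
  spread.  Spectral noise is Gaussian on the normalized-reflectance
  scale and values are not clipped to [0, 1] (the analysis
  standardizes bands anyway).  Spatial (row–column) trends are not
  simulated, and no reference-panel imaging is emulated — the NormHyp
  normalization is a tabular division available in `specblup.io`.

What passing tests on this generator do and do not show: they verify
the statistical machinery end to end against known truth — estimator
exactness, parameter recovery, model orderings, leakage freedom.  They
do not certify performance on real spectra, whose band correlations,
non-Gaussian artefacts (cloud shadows, soil background) and marker LD
structure are richer than the emulation.

## Problem sizes

The default test suite and the acceptance script run scaled-down
versions of the emulated study, chosen as the smallest sizes at which
the statistical properties under test are comfortably visible: 50–250
genotypes, 3–16 bands, 6–8 environments, 8–25 Monte-Carlo replicates
depending on the check.  Tolerances follow the statistical claim (for
example ±0.1 on a mean heritability over replicates, one Monte-Carlo
SE on ordering margins), not the problem size.

## Known limitations

* No spatial or autoregressive error models; no VanRaden methods 2/3,
  dominance or Gaussian kernels; no Bayesian shrinkage predictors.
* The stage-2 weighting uses the diagonal Smith approximation; no
  alternative weighting schemes are implemented.
* The outlier screen approximates the published M4r procedure.
* Dense REML limits single fits to a few thousand observations.
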