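# Methods

## The spectral invasion phenotype

A boundary is an ordered closed polygon {(x_v, y_v)}, v = 0…V−1, in pixel
units with periodic indexing ((x_−1, y_−1) ≡ (x_{V−1}, y_{V−1})). Boundaries
are stored open; a duplicated terminal vertex is dropped on read and
consecutive duplicate vertices are collapsed, after which V ≥ 3 is required.
The contour length L is the sum of Euclidean edge lengths including the
wrap-around edge. The polygon is resampled to M points at equal arc spacing
L/M by linear interpolation along the polyline, starting at vertex 0 (no
canonical re-phasing is attempted: the phenotype is start-point invariant,
so the choice is immaterial). M defaults to 256 and must be even; halving M
to 128 changes the phenotype of smooth shapes by under 5%, which is the
package's resolution-robustness check.

Area is the absolute shoelace value of the resampled polygon — orientation
is never normalized because tracing direction is arbitrary — and the
effective diameter is 2·√(area/π). Area and effective diameter are monotone
in each other, so they produce identical cohort ranks.

The DFT is the unnormalized forward transform (no 1/M), matching the
definition of the phenotype; since every reported quantity is a ratio
P_k/P_1, the normalization convention cancels. The weight
(M/π)²·sin²(πk/M)·cos²(πk/M) is applied purely in the spectral domain: the
sin² factor is the transfer function of a short spatial-domain average
(suppressing pixelation and hand-tracing jitter near the Nyquist mode,
where the weight vanishes exactly) and the (M/π)²·cos² factor is a discrete
derivative emphasizing curvature; for k ≪ M the product approaches k². The
equivalent single-factor form ¼·sin²(2πk/M) is deliberately not used so the
two filters remain visible in the code.

Degenerate cases: a boundary with no first-harmonic power (e.g. all points
coincident) has no defined phenotype and raises; a mathematically perfect
circle has w = 0, for which log₁₀ w is undefined — such organoids are
flagged with a warning and excluded from log-scale statistics rather than
floored with a pseudocount, because no natural floor exists and real traces
essentially never achieve w = 0.

## Intensity quantification

The traced boundary defines a pixel mask on the paired epifluorescence
frame: pixel (r, c) is in-mask iff its center (c + 0.5, r + 0.5) is inside
the polygon under the even–odd rule. The pixel-center even–odd rule was
chosen because it is deterministic and matches common raster fills; the
implementation is a vectorized crossing count, verified in tests against an
independent per-pixel edge-walking oracle. Total intensity divides the
in-mask sum of codes/255 by the *actual* image pixel count (1,443,520 only
for a 1040×1388 frame — the denominator is read from the image, never
hard-coded); mean intensity divides by the mask area. Rank normalization
maps cohort-wide values to (rank − 0.5)/n with average ranks for ties,
computed across all organoids of all tumors. 8-bit input is assumed; 16-bit
images are rescaled by their code maximum with a warning, and saturated
pixels receive no special treatment.

## Model selection

The three Gaussian models are scored by S_M = ln L(Θ̃) − ½ Σ_θ ln n_θ with
MLE variances dividing by n (not n − 1). The per-parameter sample count n_θ
is read literally: parameters estimated from the whole cohort (μ₀, σ₀², the
shared σ_W²) use N, per-tumor parameters (μ_t, σ_t²) use N_t. Posteriors
are a softmax of scores relative to the best model (exact, and immune to
underflow). M2 requires every included tumor to have at least two organoids
— a single observation makes its per-tumor MLE variance zero and the
likelihood singular — so bootstrap runs on cohorts containing singleton
tumors should use a minimum-organoids threshold of 2 or more. The bootstrap
resamples whole tumors uniformly with replacement (T′ draws from the T′
filtered tumors); a tumor drawn twice contributes twice under independent
group labels. Filtering precedes resampling. The default replicate count is
10,000; the tests use 200–500, which is ample for the qualitative
assertions they make.

## Variance components

Standard one-way ANOVA estimates: σ̂₀² on N − 1 df, pooled within σ̂_W² on
N − T df, between-group mean square σ̂_M² on T − 1 df with groups weighted
by N_t, and F = σ̂_M²/σ̂_W² ~ F(T−1, N−T) under equal means. The
between-tumor component is taken as σ̂_B² = σ̂₀² − σ̂_W² (the identity the
variance-components model implies) rather than the unbalanced
method-of-moments (MSB − MSW)/n̄; a sampling-noise-negative value is floored
at 0 and flagged, in which case the reported fractions are (0, 1).

## Association tests

The between-tumor test is an intercept OLS of tumor-mean phenotype on
tumor-mean factor (df = T − 2). The within-tumor test regresses deviations
through the origin; because the T tumor means are estimated from the same
data, the slope t statistic is referred to df = N − T − 1 (this is exact:
within-tumor deviations of x sum to zero per tumor, so the slope variance
is unaffected by the centering and the residual sum of squares loses one
further df to the slope). The OLS-default df = N − 1 p-value is also
reported for comparison. Tail selection ranks organoids by phenotype within
each tumor with ties broken by a stable sort on (y, organoid_id); tail size
is ⌈N_t·f⌉ (at least one organoid per tail), and when the tails would
overlap — odd N_t at f = 0.5 — the median organoid joins the lower pool.
The tails test is an intercept OLS of δy on δx in the selected subset,
without re-centering (the intercept absorbs any offset). The pooled test
averages δx per tail per tumor and compares upper vs lower pools with a
paired two-sided t test (df = tumors − 1); pairing makes it exactly
invariant to per-tumor shifts of x, so pooling raw x gives identical
results. All p-values in the package are two-sided.

At small group sizes the tails test is mildly anti-conservative (within-
tumor deviations carry −1/N_t correlations that its OLS reference
distribution ignores); at study scale (~16 organoids/tumor) the measured
null rejection rate at α = 0.05 stays within 0.05 ± 0.01.

## Power theory

All power calculations use the normal-quantile identity
Q² = (d.f.)·R²/(1−R²) = (z_I − z_II)² rather than exact noncentral-F power.
Degrees of freedom are T − 1 (between) and N − T − 1 (within); pooling
multiplies the within non-centrality by the efficiency f_P. The critical
between-tumor effect size carries the inflation factor 1 + σ_W²/(N_t·σ_B²)
from tumor-mean estimation noise; for unbalanced designs the single
organoids-per-tumor argument should be the (harmonic) mean group size — the
theory does not resolve per-tumor sizes and the package does not pretend
otherwise. `required_tumors` returns the exact smallest integer satisfying
the inequality; rounding to 1–2 significant figures is a presentation
option.

The pooling efficiency is the closed form E(f) = 2·φ(Φ⁻¹(1−f))²/f for
symmetric tail fraction f under an additive normal model — the squared
non-centrality of a pooled-tails mean-difference test relative to
individual-level regression. Its optimum on a 1% grid is f = 0.27 with
E ≈ 0.810, and the median split f = 0.5 recovers the classic
dichotomization efficiency 2/π. Simulation cross-checks in the test suite
confirm both the within-test power (±5 points at the critical R²) and the
pooled non-centrality ratio (±0.05 at f = 0.27).

## Synthetic data

The generators define the study conditions under which every statistical
claim is tested:

* **Boundaries** are perturbed circles r(θ) = r0·(1 + Σ a_m cos(mθ + φ_m))
  traced at equal angles (≥ 64 vertices; Σ|a_m| < 1 to prevent
  self-intersection), with optional vertex jitter, rotation and
  translation. Radial harmonics make the spectral content analytically
  controllable, so amplitude and mode number form a monotone invasiveness
  dial the phenotype must track.
* **Populations** realize the mixed model y_ti = μ_t + β_B·xb_t + β_W·xw_ti
  + ε_ti with μ_t ~ N(μ₀, σ_B²), ε ~ N(0, σ_W²) and a factor
  x_ti = xb_t + xw_ti whose between- and within-tumor spreads are set
  separately, so between- and within-tumor effect sizes can differ as they
  do in real cohorts. The default preset is the study scale: T = 52 tumors,
  16 organoids per tumor, total log-phenotype variance 0.2344 split
  0.278 : 0.722 between : within (σ_B² = 0.0652, σ_W² = 0.1692). The
  population mean μ₀ = 1.0 on the log₁₀ scale is a cosmetic choice (all
  recovery targets are location-invariant). `beta_for_r2` inverts
  R² = β²σx²/(β²σx² + σ²) to set an effect of prescribed size.
* **Intensity images** place a known uniform level inside the brute-force
  rasterized mask plus optional Gaussian noise, and return expected sums
  computed from the finished pixels, giving exact oracles for the intensity
  module.

What the generators deliberately do not emulate: hand-tracing bias,
textured or gradient fluorescence, optical blur, out-of-focus structures,
field-of-view truncation, and any dependence of group size on biology.
Passing tests therefore demonstrate correctness of the computations and
calibration of the statistics under the stated model — not robustness to
real-microscopy artifacts.

## Problem sizes used in the automated checks

Monte-Carlo checks run at fixed recorded seeds: estimator recovery at
52 × 16 over 500 replicates; null calibration of the four association tests
at 47 tumors × 16 organoids over 2000 replicates; within-test power at
N = 800, T = 50 over 1000 replicates; pooled efficiency at T = 100, N_t = 40
with R² = 0.01 over 1000 replicates (a small effect keeps the (1 − R²)
attenuation of the efficiency ratio negligible). The replicate counts set
the Monte-Carlo tolerances quoted in the tests.

## Known limitations

* The ImageJ ROI reader covers the polygon/freehand/traced subset with
  integer coordinates (the form manual tracing produces); sub-pixel and
  composite ROIs are out of scope.
* No REML or likelihood-ratio variance testing, single grouping level only,
  and no mixed-model joint fit of the association model — the between/within
  split is the implemented surface.
* The arithmetic-scale phenotype is supported throughout but the package's
  statistical defaults assume the log scale that model selection favors.
* Pooled-design theory assumes an additive normal trait; efficiencies for
  strongly non-normal factors (e.g. rare binary markers) are not modeled.
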