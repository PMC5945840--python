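# Methods

## Model

The package estimates the bivariate linear regression
Y = β₀ + β₁X₁ + β₂X₂ + ε at a range of time scales.  The classical OLS
estimators depend on the data only through second moments; the
scale-dependent estimators substitute DFA/DCCA fluctuation functions for
those moments.

For a series {z_t}, t = 1..N, the *profile* is the cumulative sum of the
mean-centered values, Z_t = Σ_{i≤t}(z_i − ⟨z⟩).  At window length
(scale) n the profile is cut into N_n = ⌊N/n⌋ disjoint windows from the
start and another N_n from the end — 2N_n windows altogether, so the
tail of a series whose length is not a multiple of n is never discarded
(windows from the two ends may overlap; both are kept).  In each window
a polynomial of order q (default 2) is fitted to the profile on the
abscissa 1..n, and the scale-dependent variance is

    F²_Z(n) = (1/2N_n) Σ_j (1/n) Σ_k (Z_{j,k} − Ẑ_{j,k})²

with the covariance F²_{Z₁Z₂}(n) obtained by replacing the squared
residual with the product of the two series' residuals (each series
detrended independently).  The normalization divides by n, not by a
residual degree-of-freedom count; F² is used only in ratios, where the
convention cancels.

The per-scale coefficients solve the 2×2 normal system assembled from
the six fluctuation functions of (X₁, X₂, Y):

    β̂₁(n) = (F²_{X₁Y}F²_{X₂} − F²_{X₂Y}F²_{X₁X₂}) / (F²_{X₁}F²_{X₂} − F²_{X₁X₂}²)

and symmetrically for β̂₂(n).  The scale-dependent residual series
ê_t(n) = Y_t − β̂₁(n)X₁t − β̂₂(n)X₂t, re-centered to zero mean, is fed
back through the same DFA machinery *at the same scale n*, giving
F²_ε(n); this is the only reading under which R²(n) = 1 − F²_ε(n)/F²_Y(n)
is a per-scale index.  Coefficient variances keep the global N−3
degrees-of-freedom divisor of the three-parameter regression at every
scale:

    var(β̂₁(n)) = F²_{X₂}(n)·F²_ε(n) / [(N−3)(F²_{X₁}F²_{X₂} − F²_{X₁X₂}²)].

The evaluation indices are β*_j(n) = β̂_j(n)·√(F²_{Xj}/F²_Y) (invariant
to rescaling X_j) and the elasticity η_j(n) = β̂_j(n)·⟨X_j⟩/⟨Y⟩ with raw,
uncentered means (undefined, reported NaN, when ⟨Y⟩ = 0).

R²(n) is *not* clipped to [0, 1]: DFA fluctuations are not a Euclidean
inner product on residual space, so values slightly outside the unit
interval can occur; they are reported as computed and exposed through
`DFARegressionResults.r2_flagged`.

The intercept is absorbed by profile centering and is not resolved per
scale; only the OLS baseline reports β₀.  The framework is deliberately
bivariate — more regressors would need the full m×m fluctuation matrix
and are out of scope.

## Correlation coefficients

ρ_DCCA(n) = F²_{Z₁Z₂}(n)/√(F²_{Z₁}(n)F²_{Z₂}(n)) is bounded by 1 in
magnitude (Cauchy–Schwarz on the pooled residual fields); a violation
beyond 1e−9 raises an internal-consistency error rather than being
clipped.  The partial coefficient ρ_PDCCA applies the classical inverse
correlation-matrix construction to the matrix of pairwise ρ_DCCA values:
with C the inverse of that matrix, ρ_PDCCA(i,j;n) = −C_ij/√(C_ii C_jj).
The diagonal of the ρ_DCCA matrix is set to exactly 1 before inversion
(it equals 1 analytically; forcing it avoids rounding-induced
asymmetry), the solve refuses condition numbers above 1e12, and with two
series ρ_PDCCA reduces exactly to ρ_DCCA.

## Significance machinery

Because the null distribution of t_j(n) = (β̂_j(n) − β_j)/√var(β̂_j(n))
varies with scale, critical values are Monte-Carlo: each surrogate
replicate independently permutes *all* series (destroying serial and
cross dependence — the joint null of no dependence), refits, and
contributes both coefficients' |t(n)| to a pooled null sample per scale.
The two-sided critical value t^c(n) is the empirical (1−α) quantile
(nearest-rank) of that sample; for ρ_PDCCA the curve is the one-sided
upper (1−α) quantile.  Default α = 0.01 and 10 000 shuffles; both are
parameters.  Surrogate streams are keyed by (master seed, replicate
index, series content-hash), so results are independent of argument
order and evaluation schedule, and relabeling X₁/X₂ leaves the pooled
curve numerically unchanged.  A scale where more than half the
replicates yield no finite statistic is flagged unusable rather than
reported.

In the α → 1 limit the nearest-rank quantile returns the null-sample
minimum (for |t|, a small positive number; analytically the acceptance
interval has width zero).

## Simulators

**ARFIMA(0, d, 0)** is generated as a truncated MA(∞),
X_t = Σ_{k=0}^{T−1} w_k ξ(t−k), with i.i.d. standard normal innovations
and weights w_0 = 1, w_k = w_{k−1}(k−1+d)/k — the expansion of
(1−B)^{−d}, i.e. Γ(k+d)/[Γ(d)Γ(k+1)] — so positive d gives persistent
series with Hurst exponent H = d + 1/2.  The truncation T defaults to
the series length, and T−1 extra innovations are pre-generated so every
output point uses a full-length weight window: no burn-in discard, no
startup transient.  The recursion avoids Gamma overflow at any T.

**Binomial multifractal series**: index k = 1..2^m carries
p^{m−bits(k−1)}(1−p)^{bits(k−1)} with bits(·) the binary digit-one
count; the raw cascade sums to exactly 1.  Values below a removal
threshold (default 1e−5) are replaced, in one pass over the raw values,
by Gaussian(0, 1e−4) draws — a deterministic multifractal embedded in
noise.  For p = 0.3, m = 15, exactly 2^14 cascade values survive.

**PM2.5-like fixture**: three strictly positive series built as
exp(baseline + annual sinusoid + shared ARFIMA + idiosyncratic ARFIMA).
Defaults: d = 0.3 (H ≈ 0.8, typical of hourly air-quality records),
shared:idiosyncratic amplitude 1:0.6 (pairwise correlation ≈ 0.7 on the
log scale), ±0.4 log-units annual cycle, exp(4) ≈ 55 µg/m³ median.  The
fixture reproduces positivity, skewness, seasonality, long memory and
positive cross-correlation; it does **not** emulate diurnal cycles,
missing-data patterns, measurement floors, or episodic extreme smog
events, so tests passing on it say nothing about robustness to those
features of real monitoring data.

## Validation studies and problem sizes

`dfareg.studies` packages the Monte-Carlo designs used to validate the
estimators; the test suite and `scripts/acceptance.py` run them at 100
replications (the headline claims were established at 1000; at R
replications Monte-Carlo bands widen by √(1000/R)).

* *Setting I*: X₁, X₂ independent ARFIMA(0, d, 0) of length 10 000,
  ε standard normal, Y = 1 + X₁ + 2X₂ + ε; β̂'s averaged over 30
  log-spaced scales in [10, 1000], then over replications.  Run at
  d = 0.3.
* *Setting II*: d = 0.4 for the regressors, ε itself ARFIMA with
  d_ε ∈ {−0.4, 0, 0.4}; unbiasedness per level, replicate spread
  increasing in d_ε.
* *BMF study*: the response is built from the **raw** cascade and the
  regression run on the **noise-substituted** X₁ — the substitution is
  what destroys the small-scale dependence, so β̂₁(n) is attenuated at
  small n and approaches 1 at large n while β̂₂(n) stays at 2.
  Coefficient curves are averaged over 20 noise replications (the
  cascade is deterministic; single realizations wobble at the largest
  scales, where only a handful of windows exist) on 30 log-spaced
  scales in [10, N/4], N = 2¹⁵.
* *Null-size study*: one i.i.d. Gaussian triple of length 5000
  calibrates t^c at the smallest scale (n = 10) from 1000 shuffles; 500
  fresh triples are tested against it, and the rejection rate is
  compared with α = 0.01 within binomial error.

## Numerical choices

* Detrending uses an orthonormal polynomial basis (QR of a scaled
  Vandermonde matrix) applied to all windows of a scale at once;
  residuals are `W − (W·Q)Qᵀ`.  The basis is cached per (n, order).
* The per-scale normal system is declared singular when its determinant
  is ≤ 1e−12 × F²_{X₁}F²_{X₂}; such scales are flagged (NaN, `usable`
  mask), never silently dropped.
* The default scale grid is 30 log-spaced integers between 10 and
  min(1000, N/4), deduplicated after rounding; the window count at the
  largest retained scale is then at least 8.
* Zero-variance windows are legitimate (F² = 0), e.g. constant series;
  a polynomial of the detrend order fits an affine series' profile
  exactly, so DFA(2) of an affine series is identically zero.
* Seasonal splitting labels rows by the calendar month of their
  timestamp (December joins the following winter); rows are labeled,
  never re-dated.  Missing data are rejected by default; linear
  interpolation of interior gaps up to a configurable length is opt-in.

## Known limitations

* Strictly two regressors; no lagged cross-correlations, no q-order
  multifractal generalizations, no block or phase-randomized surrogates
  (plain permutation destroys autocorrelation along with cross
  dependence — for strongly autocorrelated data the null is therefore
  "no dependence of any kind", not "no cross-dependence given the
  marginals' memory").
* Coefficient variances inherit the global N−3 divisor at all scales; an
  effective per-scale sample size could be argued but is not
  implemented.
* R²(n) outside [0, 1] is possible and only flagged.
* The elasticity is meaningful only for series with nonzero (ideally
  positive) means, as with concentration data.
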