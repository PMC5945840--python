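"""Monte-Carlo validation studies for the scale-dependent estimators.

These reproduce, at configurable replication counts, the simulation
designs used to validate the DFA-based regression:

* **Setting I** — regressors X1, X2 are independent ARFIMA(0, d, 0)
  series of length 10000, the error is standard Gaussian noise, and
  Y = 1 + X1 + 2 X2 + eps; the scale-averaged coefficient estimates over
  [10, 1000] should be unbiased at 1 and 2 for every d.
* **Setting II** — d fixed at 0.4 for the regressors while the error is
  itself ARFIMA with memory d_eps; unbiasedness should survive, with
  replicate spread growing in d_eps.
* **BMF study** — X1 is a binomial multifractal cascade whose sub-
  threshold values are replaced by noise *after* the response is built,
  so the small-scale dependence between Y and the observed X1 is
  destroyed while the large-scale dependence survives: beta1(n) is
  attenuated at small n and approaches 1 at large n, while beta2(n)
  stays at 2 throughout.
* **Null-size study** — on independent i.i.d. Gaussian triples the
  shuffle-based critical value should reject at rate alpha.

Every study takes a single master seed and spawns independent child
streams per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fluctuation import ScaleGrid
from .regression import DFARegression
from .significance import critical_curve_t, scale_t_statistics
from .simulate import ArfimaSpec, gen_arfima, bmfs_cascade

__all__ = [
    "SettingIResult",
    "BmfStudyResult",
    "setting_one",
    "setting_two",
    "bmf_study",
    "null_size_study",
]

STUDY_LENGTH = 10_000
TRUE_BETA1 = 1.0
TRUE_BETA2 = 2.0


@dataclass
class SettingIResult:
    """Per-replicate scale-averaged coefficient estimates."""

    beta1: np.ndarray
    beta2: np.ndarray

    @property
    def means(self) -> tuple[float, float]:
        return float(self.beta1.mean()), float(self.beta2.mean())

    @property
    def sds(self) -> tuple[float, float]:
        return float(self.beta1.std(ddof=1)), float(self.beta2.std(ddof=1))


@dataclass
class BmfStudyResult:
    """Replicate-averaged coefficient curves of the multifractal study."""

    grid: ScaleGrid
    beta1: np.ndarray
    beta2: np.ndarray


def _study_grid(length: int) -> ScaleGrid:
    return ScaleGrid.log_spaced(10, 1000, 30, series_length=length)


def setting_one(
    d: float,
    n_reps: int = 100,
    length: int = STUDY_LENGTH,
    seed: int | None = None,
) -> SettingIResult:
    """Unbiasedness study with ARFIMA regressors and Gaussian error."""
    grid = _study_grid(length)
    b1 = np.empty(n_reps)
    b2 = np.empty(n_reps)
    for r, child in enumerate(np.random.SeedSequence(seed).spawn(n_reps)):
        s1, s2, s3 = child.spawn(3)
        x1 = gen_arfima(ArfimaSpec(d=d, length=length, seed=s1))
        x2 = gen_arfima(ArfimaSpec(d=d, length=length, seed=s2))
        eps = np.random.default_rng(s3).standard_normal(length)
        y = 1.0 + TRUE_BETA1 * x1 + TRUE_BETA2 * x2 + eps
        fit = DFARegression(y, x1, x2).fit(grid)
        b1[r], b2[r] = fit.average_over_scales()
    return SettingIResult(beta1=b1, beta2=b2)


def setting_two(
    d_eps: float,
    n_reps: int = 100,
    length: int = STUDY_LENGTH,
    d: float = 0.4,
    seed: int | None = None,
) -> SettingIResult:
    """Robustness study: long-memory error term with parameter ``d_eps``."""
    grid = _study_grid(length)
    b1 = np.empty(n_reps)
    b2 = np.empty(n_reps)
    for r, child in enumerate(np.random.SeedSequence(seed).spawn(n_reps)):
        s1, s2, s3 = child.spawn(3)
        x1 = gen_arfima(ArfimaSpec(d=d, length=length, seed=s1))
        x2 = gen_arfima(ArfimaSpec(d=d, length=length, seed=s2))
        eps = gen_arfima(ArfimaSpec(d=d_eps, length=length, seed=s3))
        y = 1.0 + TRUE_BETA1 * x1 + TRUE_BETA2 * x2 + eps
        fit = DFARegression(y, x1, x2).fit(grid)
        b1[r], b2[r] = fit.average_over_scales()
    return SettingIResult(beta1=b1, beta2=b2)


def bmf_study(
    n_reps: int = 20,
    p: float = 0.3,
    n_levels: int = 15,
    removal_threshold: float = 1e-5,
    noise_sd: float = 1e-4,
    seed: int | None = None,
) -> BmfStudyResult:
    """Scale-dependence study on the noise-embedded binomial cascade.

    The response is built from the *raw* cascade
    (Y = 1 + X1_raw + 2 X2 + eps); sub-threshold cascade values are then
    replaced by Gaussian noise and the regression is run on the
    substituted series, so the observed X1 carries no small-scale
    information about Y.  Coefficient curves are averaged over noise
    replications (the cascade itself is deterministic).
    """
    raw = bmfs_cascade(p, n_levels)
    N = raw.size
    grid = ScaleGrid.log_spaced(10, N // 4, 30, series_length=N)
    sub_mask = raw < removal_threshold
    B1 = np.empty((n_reps, len(grid)))
    B2 = np.empty((n_reps, len(grid)))
    for r, child in enumerate(np.random.SeedSequence(seed).spawn(n_reps)):
        rng = np.random.default_rng(child)
        x2 = rng.normal(0.0, noise_sd, N)
        eps = rng.normal(0.0, noise_sd, N)
        y = 1.0 + TRUE_BETA1 * raw + TRUE_BETA2 * x2 + eps
        x1 = raw.copy()
        x1[sub_mask] = rng.normal(0.0, noise_sd, int(sub_mask.sum()))
        fit = DFARegression(y, x1, x2).fit(grid)
        B1[r] = fit.beta1
        B2[r] = fit.beta2
    return BmfStudyResult(
        grid=grid, beta1=B1.mean(axis=0), beta2=B2.mean(axis=0)
    )


def null_size_study(
    length: int = 5000,
    scale: int = 10,
    alpha: float = 0.01,
    n_shuffles: int = 1000,
    n_replicates: int = 500,
    seed: int | None = None,
) -> float:
    """Empirical rejection rate of the shuffle test on independent inputs.

    A critical value t^c is calibrated once, at the stated scale, from
    shuffled surrogates of one i.i.d. Gaussian triple; fresh independent
    triples are then tested against it.  Both coefficients contribute to
    the count, matching the pooled null used for the critical value.
    Should return approximately ``alpha``.
    """
    master = np.random.SeedSequence(seed)
    calib_ss, rep_ss = master.spawn(2)
    grid = ScaleGrid([scale])
    rng = np.random.default_rng(calib_ss)
    y0, x10, x20 = rng.standard_normal((3, length))
    curve = critical_curve_t(
        y0, x10, x20, grid, alpha=alpha, n_shuffles=n_shuffles,
        seed=int(calib_ss.generate_state(1)[0]),
    )
    t_crit = curve.values[0]
    rejections = 0
    total = 0
    for child in rep_ss.spawn(n_replicates):
        y, x1, x2 = np.random.default_rng(child).standard_normal((3, length))
        fit = DFARegression(y, x1, x2).fit(grid)
        ts = scale_t_statistics(fit)
        for t in (ts.t1[0], ts.t2[0]):
            if np.isfinite(t):
                total += 1
                rejections += abs(t) > t_crit
    return rejections / total
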