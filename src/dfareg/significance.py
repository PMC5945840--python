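"""Surrogate-shuffle significance tests for scale-dependent statistics.

At a single scale the regression t-statistic t_j(n) =
(beta_j(n) − beta0_j) / sqrt(var_j(n)) does not follow the textbook
t(N−3) law: detrended fluctuations are built from overlapping windowed
fits, so the null spread of the statistic changes with the scale.  The
remedy is Monte-Carlo: shuffle each input series independently (which
destroys serial and cross dependence while preserving the marginal
distributions), recompute the statistic on every surrogate, and read the
critical value off the empirical null at each scale.

``critical_curve_t`` does this for the regression t-statistics (pooling
the two coefficients, two-sided), ``critical_curve_pdcca`` for the
partial DCCA coefficient (one-sided upper).  One master seed spawns
independent child streams per replicate, so results do not depend on
evaluation order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .correlation import rho_pdcca
from .fluctuation import DEFAULT_DETREND_ORDER, ScaleGrid, _as_series
from .regression import DFARegression, DFARegressionResults

__all__ = [
    "ScaleTStatistics",
    "CriticalCurve",
    "scale_t_statistics",
    "shuffle_series",
    "critical_curve_t",
    "critical_curve_pdcca",
]


@dataclass
class ScaleTStatistics:
    """Scale-dependent t-statistics of the two regression coefficients.

    NaN at scales where the coefficient variance is zero or the fit was
    unusable.
    """

    grid: ScaleGrid
    t1: np.ndarray
    t2: np.ndarray


@dataclass
class CriticalCurve:
    """Per-scale Monte-Carlo critical values at confidence level 1 − alpha.

    ``kind`` is ``"t"`` (two-sided, quantile of |t| pooled over both
    coefficients) or ``"rho_pdcca"`` (one-sided upper).  ``usable`` marks
    scales where more than half of the surrogate replicates produced a
    finite statistic.
    """

    grid: ScaleGrid
    values: np.ndarray
    alpha: float
    n_shuffles: int
    kind: str
    seed: int | None
    usable: np.ndarray

    def at(self, n: int) -> float:
        return float(self.values[list(self.grid).index(int(n))])


def scale_t_statistics(
    fit: DFARegressionResults,
    null_beta1: float = 0.0,
    null_beta2: float = 0.0,
) -> ScaleTStatistics:
    """t_j(n) = (beta_j(n) − null_j) / sqrt(var_j(n)) per scale."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = (fit.beta1 - null_beta1) / np.sqrt(fit.var1)
        t2 = (fit.beta2 - null_beta2) / np.sqrt(fit.var2)
    t1 = np.where(fit.usable & (fit.var1 > 0), t1, np.nan)
    t2 = np.where(fit.usable & (fit.var2 > 0), t2, np.nan)
    return ScaleTStatistics(grid=fit.grid, t1=t1, t2=t2)


def shuffle_series(series, seed=None) -> np.ndarray:
    """Uniform random permutation of the values (multiset preserved)."""
    s = _as_series(series)
    rng = np.random.default_rng(seed)
    return rng.permutation(s)


def _series_digest(s: np.ndarray) -> int:
    """Content hash of a series, used to key its surrogate stream."""
    return int.from_bytes(hashlib.sha256(s.tobytes()).digest()[:8], "little")


def _surrogate_streams(series: list[np.ndarray], seed, n_shuffles: int):
    """Per-replicate independent permutation generators, one per series.

    Streams are keyed by (master seed, replicate index, series content),
    not by argument position, so relabeling the inputs relabels the
    surrogate statistics identically and results are independent of
    evaluation order.
    """
    digests = [_series_digest(s) for s in series]
    base = np.random.SeedSequence(seed).generate_state(n_shuffles, dtype=np.uint64)
    for r in range(n_shuffles):
        yield [
            np.random.default_rng(np.random.SeedSequence([int(base[r]), d]))
            for d in digests
        ]


def _empirical_quantile(samples: np.ndarray, q: float) -> float:
    """Nearest-rank empirical quantile (lower convention at q = 0)."""
    samples = np.sort(samples)
    k = int(np.ceil(q * samples.size))
    return float(samples[max(k - 1, 0)])


def critical_curve_t(
    y,
    x1,
    x2,
    grid: ScaleGrid,
    order: int = DEFAULT_DETREND_ORDER,
    alpha: float = 0.01,
    n_shuffles: int = 10_000,
    seed: int | None = None,
) -> CriticalCurve:
    """Shuffle-based two-sided critical curve t^c(n) for the t-statistics.

    Each surrogate replicate permutes the three series independently,
    refits the scale-dependent regression, and contributes |t_1(n)| and
    |t_2(n)| to the null sample at every scale; the critical value is the
    empirical (1 − alpha) quantile per scale.
    """
    y = _as_series(y, "y")
    x1 = _as_series(x1, "x1")
    x2 = _as_series(x2, "x2")
    if n_shuffles < 100:
        raise ValueError(f"n_shuffles={n_shuffles} < 100")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    m = len(grid)
    null_abs_t = np.empty((n_shuffles, 2, m))
    for r, rngs in enumerate(_surrogate_streams([y, x1, x2], seed, n_shuffles)):
        fit = DFARegression(
            rngs[0].permutation(y), rngs[1].permutation(x1), rngs[2].permutation(x2)
        ).fit(grid, order)
        ts = scale_t_statistics(fit)
        null_abs_t[r, 0] = np.abs(ts.t1)
        null_abs_t[r, 1] = np.abs(ts.t2)
    pooled = null_abs_t.reshape(2 * n_shuffles, m)
    values = np.full(m, np.nan)
    usable = np.zeros(m, dtype=bool)
    for i in range(m):
        col = pooled[:, i]
        col = col[np.isfinite(col)]
        if col.size <= pooled.shape[0] // 2:
            continue
        usable[i] = True
        values[i] = _empirical_quantile(col, 1 - alpha)
    return CriticalCurve(
        grid=grid,
        values=values,
        alpha=alpha,
        n_shuffles=n_shuffles,
        kind="t",
        seed=seed,
        usable=usable,
    )


def critical_curve_pdcca(
    series_list,
    pair: tuple[int, int],
    grid: ScaleGrid,
    order: int = DEFAULT_DETREND_ORDER,
    alpha: float = 0.01,
    n_shuffles: int = 10_000,
    seed: int | None = None,
) -> CriticalCurve:
    """Shuffle-based one-sided upper critical curve for rho_PDCCA(n).

    Values of the partial DCCA coefficient below this curve are not
    significantly cross-correlated at confidence level 1 − alpha.
    """
    series = [_as_series(s, f"series[{k}]") for k, s in enumerate(series_list)]
    i, j = pair
    if n_shuffles < 100:
        raise ValueError(f"n_shuffles={n_shuffles} < 100")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    m = len(grid)
    null_rho = np.full((n_shuffles, m), np.nan)
    for r, rngs in enumerate(_surrogate_streams(series, seed, n_shuffles)):
        shuffled = [g.permutation(s) for g, s in zip(rngs, series)]
        for k, n in enumerate(grid):
            try:
                null_rho[r, k] = rho_pdcca(shuffled, i, j, n, order)
            except ValueError:
                pass
    values = np.full(m, np.nan)
    usable = np.zeros(m, dtype=bool)
    for k in range(m):
        col = null_rho[:, k]
        col = col[np.isfinite(col)]
        if col.size <= n_shuffles // 2:
            continue
        usable[k] = True
        values[k] = _empirical_quantile(col, 1 - alpha)
    return CriticalCurve(
        grid=grid,
        values=values,
        alpha=alpha,
        n_shuffles=n_shuffles,
        kind="rho_pdcca",
        seed=seed,
        usable=usable,
    )
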