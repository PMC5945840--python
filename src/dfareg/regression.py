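"""Scale-dependent bivariate regression built on DFA/DCCA fluctuations.

The model is the ordinary bivariate linear regression

    Y = beta0 + beta1 * X1 + beta2 * X2 + eps

whose ordinary-least-squares estimators can be written entirely in terms
of variances and covariances of the three series.  Replacing those
(co)variances by DFA/DCCA scale-dependent fluctuation functions F²(n)
turns the single pair of coefficients into coefficient *curves*
beta1(n), beta2(n): one bivariate regression per time scale, each
describing the dependence among the detrended fluctuations at that scale.

Per scale the model also provides coefficient variances (via the DFA
fluctuation of the scale-dependent residual series, with the global N−3
degrees-of-freedom divisor), a determination coefficient R²(n), a
standardized "beta coefficient" beta*(n) and an average elasticity
eta(n).  The intercept is absorbed by profile centering and is not
resolved per scale.

Usage follows the statsmodels convention: build a :class:`DFARegression`
model from data, call :meth:`~DFARegression.fit`, inspect the returned
:class:`DFARegressionResults` (or its ``summary()`` table).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fluctuation import (
    DEFAULT_DETREND_ORDER,
    InvalidDataError,
    ScaleGrid,
    _as_series,
    compute_profile,
    detrended_residuals,
)

__all__ = [
    "CollinearityError",
    "OlsResults",
    "ols_fit",
    "DFARegression",
    "DFARegressionResults",
]

#: relative tolerance below which the per-scale normal system is singular
SINGULARITY_RTOL = 1e-12


class CollinearityError(ValueError):
    """Raised when the two regressors are (numerically) collinear."""


@dataclass
class OlsResults:
    """Ordinary bivariate OLS fit — the single-scale baseline.

    ``eta1``/``eta2`` are the average elasticities beta_j * <Xj>/<Y>;
    they are NaN when the response mean is zero (flagged by
    ``eta_defined``).
    """

    beta0: float
    beta1: float
    beta2: float
    var1: float
    var2: float
    residuals: np.ndarray
    r_squared: float
    beta_star1: float
    beta_star2: float
    eta1: float
    eta2: float
    eta_defined: bool
    nobs: int

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "beta0": self.beta0,
                "beta1": self.beta1,
                "beta2": self.beta2,
                "se1": np.sqrt(self.var1),
                "se2": np.sqrt(self.var2),
                "r_squared": self.r_squared,
                "beta_star1": self.beta_star1,
                "beta_star2": self.beta_star2,
                "eta1": self.eta1,
                "eta2": self.eta2,
                "nobs": self.nobs,
            }
        )


def ols_fit(y, x1, x2) -> OlsResults:
    """Fit the standard bivariate regression Y = b0 + b1 X1 + b2 X2 + eps.

    Coefficient variances use the N−3 residual degrees of freedom; the
    standardized coefficients are beta_j * sqrt(Var(Xj)/Var(Y)) and the
    elasticities beta_j * <Xj>/<Y> (raw, uncentered means).
    """
    y = _as_series(y, "y")
    x1 = _as_series(x1, "x1")
    x2 = _as_series(x2, "x2")
    N = y.size
    if not (x1.size == N and x2.size == N):
        raise InvalidDataError("y, x1, x2 must have equal lengths")
    if N < 4:
        raise InvalidDataError(f"need at least 4 observations, got {N}")
    X = sm.add_constant(np.column_stack([x1, x2]))
    if np.linalg.matrix_rank(X) < 3:
        raise CollinearityError("x1 and x2 are collinear (singular normal system)")
    res = sm.OLS(y, X).fit()
    beta0, beta1, beta2 = res.params
    var1, var2 = res.bse[1] ** 2, res.bse[2] ** 2
    yc = y - y.mean()
    x1c = x1 - x1.mean()
    x2c = x2 - x2.mean()
    sy2 = float(yc @ yc)
    beta_star1 = beta1 * np.sqrt(float(x1c @ x1c) / sy2)
    beta_star2 = beta2 * np.sqrt(float(x2c @ x2c) / sy2)
    eta_defined = not np.isclose(y.mean(), 0.0)
    if eta_defined:
        eta1 = beta1 * x1.mean() / y.mean()
        eta2 = beta2 * x2.mean() / y.mean()
    else:
        eta1 = eta2 = np.nan
    return OlsResults(
        beta0=float(beta0),
        beta1=float(beta1),
        beta2=float(beta2),
        var1=float(var1),
        var2=float(var2),
        residuals=np.asarray(res.resid),
        r_squared=float(res.rsquared),
        beta_star1=float(beta_star1),
        beta_star2=float(beta_star2),
        eta1=float(eta1),
        eta2=float(eta2),
        eta_defined=eta_defined,
        nobs=N,
    )


class DFARegression:
    """Scale-dependent bivariate regression model.

    Parameters
    ----------
    y, x1, x2
        Equal-length one-dimensional series: the response and the two
        regressors.

    Examples
    --------
    >>> model = DFARegression(y, x1, x2)
    >>> res = model.fit(grid=ScaleGrid.log_spaced(10, 1000, 30,
    ...                                           series_length=len(y)))
    >>> res.summary().head()
    """

    def __init__(self, y, x1, x2):
        self.y = _as_series(y, "y")
        self.x1 = _as_series(x1, "x1")
        self.x2 = _as_series(x2, "x2")
        if not (self.x1.size == self.y.size == self.x2.size):
            raise InvalidDataError("y, x1, x2 must have equal lengths")
        self.nobs = self.y.size

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, y: str, x1: str, x2: str
    ) -> "DFARegression":
        """Build the model from named columns of a DataFrame."""
        return cls(data[y].to_numpy(), data[x1].to_numpy(), data[x2].to_numpy())

    def default_grid(self, n_min: int = 10, n_max: int = 1000, num: int = 30) -> ScaleGrid:
        return ScaleGrid.log_spaced(n_min, n_max, num, series_length=self.nobs)

    def fit(
        self,
        grid: ScaleGrid | None = None,
        order: int = DEFAULT_DETREND_ORDER,
    ) -> "DFARegressionResults":
        """Estimate the coefficient curves over a grid of time scales.

        For each scale the six fluctuation functions F²_{X1}, F²_{X2},
        F²_Y, F²_{X1X2}, F²_{X1Y}, F²_{X2Y} are computed once; the
        coefficients solve the 2×2 normal system assembled from them.
        The scale-dependent residual series (re-centered to zero mean) is
        run back through DFA *at the same scale* to obtain F²_eps(n),
        from which the coefficient variances and R²(n) follow.

        Scales where the normal-system determinant is nonpositive or
        below ``SINGULARITY_RTOL`` times F²_{X1} F²_{X2} are flagged
        unusable (all outputs NaN there) rather than dropped.
        """
        if grid is None:
            grid = self.default_grid()
        N = self.nobs
        y, x1, x2 = self.y, self.x1, self.x2
        prof = [compute_profile(s) for s in (x1, x2, y)]
        m = len(grid)
        f11 = np.empty(m)
        f22 = np.empty(m)
        fyy = np.empty(m)
        f12 = np.empty(m)
        f1y = np.empty(m)
        f2y = np.empty(m)
        beta1 = np.full(m, np.nan)
        beta2 = np.full(m, np.nan)
        feps = np.full(m, np.nan)
        usable = np.zeros(m, dtype=bool)
        for i, n in enumerate(grid):
            r1, r2, ry = (detrended_residuals(p, n, order) for p in prof)
            f11[i] = np.mean(r1 * r1)
            f22[i] = np.mean(r2 * r2)
            fyy[i] = np.mean(ry * ry)
            f12[i] = np.mean(r1 * r2)
            f1y[i] = np.mean(r1 * ry)
            f2y[i] = np.mean(r2 * ry)
            det = f11[i] * f22[i] - f12[i] ** 2
            if det <= SINGULARITY_RTOL * f11[i] * f22[i]:
                continue
            usable[i] = True
            beta1[i] = (f1y[i] * f22[i] - f2y[i] * f12[i]) / det
            beta2[i] = (f2y[i] * f11[i] - f1y[i] * f12[i]) / det
            resid = y - beta1[i] * x1 - beta2[i] * x2
            resid -= resid.mean()
            re = detrended_residuals(np.cumsum(resid), n, order)
            feps[i] = np.mean(re * re)
        det_arr = f11 * f22 - f12 ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            var1 = np.where(usable, feps * f22 / det_arr / (N - 3), np.nan)
            var2 = np.where(usable, feps * f11 / det_arr / (N - 3), np.nan)
            r_squared = np.where(usable, 1.0 - feps / fyy, np.nan)
            beta_star1 = beta1 * np.sqrt(f11 / fyy)
            beta_star2 = beta2 * np.sqrt(f22 / fyy)
        ym = y.mean()
        if np.isclose(ym, 0.0):
            eta1 = np.full(m, np.nan)
            eta2 = np.full(m, np.nan)
        else:
            eta1 = beta1 * x1.mean() / ym
            eta2 = beta2 * x2.mean() / ym
        return DFARegressionResults(
            model=self,
            grid=grid,
            order=order,
            beta1=beta1,
            beta2=beta2,
            var1=var1,
            var2=var2,
            residual_fluct=feps,
            r_squared=r_squared,
            beta_star1=beta_star1,
            beta_star2=beta_star2,
            eta1=eta1,
            eta2=eta2,
            usable=usable,
            fluctuations={
                "x1": f11,
                "x2": f22,
                "y": fyy,
                "x1x2": f12,
                "x1y": f1y,
                "x2y": f2y,
            },
        )


class DFARegressionResults:
    """Per-scale estimates, variances and evaluation indices of a DFA fit.

    All curve attributes are arrays aligned with ``grid``; entries at
    unusable scales (singular per-scale normal system) are NaN and the
    boolean ``usable`` mask records them.  ``r_squared`` is reported
    exactly as computed — it can leave [0, 1] because DFA fluctuations
    are not a Euclidean inner product on residual space; ``r2_flagged``
    marks such scales.
    """

    def __init__(
        self,
        model: DFARegression,
        grid: ScaleGrid,
        order: int,
        beta1: np.ndarray,
        beta2: np.ndarray,
        var1: np.ndarray,
        var2: np.ndarray,
        residual_fluct: np.ndarray,
        r_squared: np.ndarray,
        beta_star1: np.ndarray,
        beta_star2: np.ndarray,
        eta1: np.ndarray,
        eta2: np.ndarray,
        usable: np.ndarray,
        fluctuations: dict[str, np.ndarray],
    ):
        self.model = model
        self.grid = grid
        self.order = order
        self.beta1 = beta1
        self.beta2 = beta2
        self.var1 = var1
        self.var2 = var2
        self.residual_fluct = residual_fluct
        self.r_squared = r_squared
        self.beta_star1 = beta_star1
        self.beta_star2 = beta_star2
        self.eta1 = eta1
        self.eta2 = eta2
        self.usable = usable
        self.fluctuations = fluctuations
        self.nobs = model.nobs

    @property
    def scales(self) -> np.ndarray:
        return self.grid.as_array()

    @property
    def r2_flagged(self) -> np.ndarray:
        """Scales where R²(n) fell outside [0, 1]."""
        with np.errstate(invalid="ignore"):
            return self.usable & ((self.r_squared < 0) | (self.r_squared > 1))

    def average_over_scales(
        self, n_low: int | None = None, n_high: int | None = None
    ) -> tuple[float, float]:
        """Arithmetic mean of (beta1(n), beta2(n)) over usable scales in range."""
        n_low = self.grid.n_min if n_low is None else n_low
        n_high = self.grid.n_max if n_high is None else n_high
        sel = (self.scales >= n_low) & (self.scales <= n_high) & self.usable
        if not sel.any():
            raise ValueError(
                f"no usable scales in [{n_low}, {n_high}] "
                f"(grid spans [{self.grid.n_min}, {self.grid.n_max}])"
            )
        return float(self.beta1[sel].mean()), float(self.beta2[sel].mean())

    def summary(self) -> pd.DataFrame:
        """Per-scale table: coefficients, variances, R², beta*, eta."""
        return pd.DataFrame(
            {
                "scale": self.scales,
                "beta1": self.beta1,
                "beta2": self.beta2,
                "var1": self.var1,
                "var2": self.var2,
                "r_squared": self.r_squared,
                "beta_star1": self.beta_star1,
                "beta_star2": self.beta_star2,
                "eta1": self.eta1,
                "eta2": self.eta2,
                "usable": self.usable,
            }
        )

    def ols_baseline(self) -> OlsResults:
        """The single-scale standard OLS fit of the same data."""
        return ols_fit(self.model.y, self.model.x1, self.model.x2)

    def t_statistics(self, null_beta1: float = 0.0, null_beta2: float = 0.0):
        """Scale-dependent t-statistics for the two coefficients."""
        from .significance import scale_t_statistics

        return scale_t_statistics(self, null_beta1, null_beta2)

    def plot(self, ax=None):
        """Plot the two coefficient curves against scale (log abscissa)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.scales, self.beta1, "o-", label=r"$\hat\beta_1(n)$")
        ax.plot(self.scales, self.beta2, "s-", label=r"$\hat\beta_2(n)$")
        ax.set_xscale("log")
        ax.set_xlabel("scale n")
        ax.set_ylabel("coefficient")
        ax.legend()
        return ax
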