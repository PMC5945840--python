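"""Classical partial correlation and scale-dependent (partial) DCCA coefficients.

``rho_dcca`` normalizes the DCCA covariance by the two DFA standard
fluctuations, giving a scale-dependent analogue of the Pearson
correlation.  ``rho_pdcca`` applies the classical partial-correlation
construction — the normalized negative off-diagonal of the inverse
correlation matrix — to the matrix of pairwise rho_DCCA values, removing
the linear influence of the remaining series at each scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fluctuation import (
    DEFAULT_DETREND_ORDER,
    InvalidDataError,
    ScaleGrid,
    _as_series,
    compute_profile,
    detrended_residuals,
)

__all__ = [
    "DegenerateConditioningError",
    "PartialCorrelationResult",
    "partial_pearson",
    "rho_dcca",
    "dcca_matrix",
    "rho_pdcca",
]

#: condition number above which the rho_DCCA matrix is treated as singular
CONDITION_LIMIT = 1e12


class DegenerateConditioningError(ValueError):
    """Conditioning variable(s) leave no usable partial correlation."""


@dataclass(frozen=True)
class PartialCorrelationResult:
    """Partial Pearson correlation r_{12.3} with its t-statistic.

    ``t = r * sqrt((N-3)/(1-r^2))`` on N−3 degrees of freedom; infinite
    when |r| = 1.
    """

    r: float
    t: float
    dof: int


def partial_pearson(a, b, c) -> PartialCorrelationResult:
    """Partial correlation of ``a`` and ``b`` controlling for ``c``.

    Uses the textbook identity
    r_{12.3} = (r12 − r13 r23) / sqrt((1 − r13²)(1 − r23²)).
    """
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    c = _as_series(c, "c")
    N = a.size
    if not (b.size == N and c.size == N):
        raise InvalidDataError("series must have equal lengths")
    if N < 4:
        raise InvalidDataError(f"need at least 4 observations, got {N}")
    for name, s in (("a", a), ("b", b), ("c", c)):
        if np.ptp(s) == 0:
            raise InvalidDataError(f"series {name} is constant")
    r12 = np.corrcoef(a, b)[0, 1]
    r13 = np.corrcoef(a, c)[0, 1]
    r23 = np.corrcoef(b, c)[0, 1]
    denom = (1 - r13**2) * (1 - r23**2)
    if denom <= 0:
        raise DegenerateConditioningError(
            "a or b is perfectly correlated with the conditioning series"
        )
    r = (r12 - r13 * r23) / np.sqrt(denom)
    dof = N - 3
    if abs(r) >= 1:
        t = np.inf if r > 0 else -np.inf
    else:
        t = r * np.sqrt(dof / (1 - r**2))
    return PartialCorrelationResult(r=float(r), t=float(t), dof=dof)


def _pair_fluctuations(profiles, n: int, order: int) -> np.ndarray:
    """m×m matrix of mean detrended-residual products at one scale."""
    resids = [detrended_residuals(p, n, order) for p in profiles]
    m = len(resids)
    F = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            F[i, j] = F[j, i] = np.mean(resids[i] * resids[j])
    return F


def rho_dcca(a, b, n: int, order: int = DEFAULT_DETREND_ORDER) -> float:
    """DCCA cross-correlation coefficient at scale ``n``.

    F²_{ab}(n) / sqrt(F²_a(n) F²_b(n)); lies in [−1, 1] by the
    Cauchy–Schwarz inequality of the underlying residual fields.
    """
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    if a.size != b.size:
        raise InvalidDataError("series must have equal lengths")
    F = _pair_fluctuations([compute_profile(a), compute_profile(b)], n, order)
    return _normalize_rho(F[0, 1], F[0, 0], F[1, 1])


def _normalize_rho(cov: float, var_a: float, var_b: float) -> float:
    if var_a <= 0 or var_b <= 0:
        raise InvalidDataError(
            "zero DFA variance at this scale; rho_DCCA undefined"
        )
    rho = cov / np.sqrt(var_a * var_b)
    if abs(rho) > 1 + 1e-9:
        raise AssertionError(
            f"internal inconsistency: |rho_DCCA| = {abs(rho)} exceeds 1"
        )
    return float(rho)


def dcca_matrix(series_list, n: int, order: int = DEFAULT_DETREND_ORDER) -> np.ndarray:
    """Symmetric matrix of pairwise rho_DCCA values with exact unit diagonal."""
    series = [_as_series(s, f"series[{i}]") for i, s in enumerate(series_list)]
    N = series[0].size
    if any(s.size != N for s in series):
        raise InvalidDataError("all series must have equal lengths")
    profiles = [compute_profile(s) for s in series]
    F = _pair_fluctuations(profiles, n, order)
    m = len(series)
    R = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            R[i, j] = R[j, i] = _normalize_rho(F[i, j], F[i, i], F[j, j])
    return R


def rho_pdcca(
    series_list,
    i: int,
    j: int,
    n: int,
    order: int = DEFAULT_DETREND_ORDER,
) -> float:
    """Partial DCCA coefficient between series ``i`` and ``j`` at scale ``n``.

    Builds the m×m rho_DCCA matrix of all series, inverts it, and returns
    −C_ij / sqrt(C_ii C_jj) where C is the inverse matrix.  With only two
    series this reduces exactly to rho_DCCA.  The diagonal (i == j) is 1
    by convention.
    """
    if i == j:
        return 1.0
    R = dcca_matrix(series_list, n, order)
    if np.linalg.cond(R) > CONDITION_LIMIT:
        raise DegenerateConditioningError(
            "rho_DCCA matrix is numerically singular at this scale"
        )
    C = np.linalg.inv(R)
    return float(-C[i, j] / np.sqrt(C[i, i] * C[j, j]))
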