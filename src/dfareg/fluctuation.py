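"""Core DFA/DCCA engine.

Detrended fluctuation analysis (DFA) measures the variance of a
nonstationary series at a chosen time scale ``n`` by integrating the
mean-centered series into a *profile*, splitting the profile into windows
of length ``n`` (taken from both ends of the series so no tail is
discarded), removing a low-order polynomial trend inside each window, and
averaging the squared residuals.  Detrended cross-correlation analysis
(DCCA) replaces the squared residuals by the product of the residuals of
two series, yielding a scale-dependent covariance.

These two functions — the scale-dependent variance ``F²_Z(n)`` and
covariance ``F²_{Z1 Z2}(n)`` — are the building blocks for everything else
in this package: the scale-dependent regression coefficients, the DCCA and
partial-DCCA correlation coefficients, and the surrogate significance
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "InvalidDataError",
    "InvalidScaleError",
    "ScaleGrid",
    "FluctuationSet",
    "compute_profile",
    "segment_bounds",
    "detrended_residuals",
    "dfa_variance",
    "dcca_covariance",
]

DEFAULT_DETREND_ORDER = 2


class InvalidDataError(ValueError):
    """Raised for non-finite, ragged or otherwise unusable input series."""


class InvalidScaleError(ValueError):
    """Raised when a window size is incompatible with the series length."""


def _as_series(values: Iterable[float], name: str = "series") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidDataError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise InvalidDataError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise InvalidDataError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class ScaleGrid:
    """Ordered set of integer window sizes at which fluctuations are measured.

    Parameters
    ----------
    scales
        Window sizes, in sampling units.  Stored sorted, deduplicated.
    """

    scales: tuple[int, ...]

    def __init__(self, scales: Iterable[int]):
        uniq = sorted({int(s) for s in scales})
        if not uniq:
            raise InvalidScaleError("scale grid is empty")
        if uniq[0] < 2:
            raise InvalidScaleError(f"smallest scale {uniq[0]} < 2")
        object.__setattr__(self, "scales", tuple(uniq))

    @classmethod
    def log_spaced(
        cls,
        n_min: int = 10,
        n_max: int = 1000,
        num: int = 30,
        *,
        series_length: int | None = None,
        max_fraction: float = 0.25,
    ) -> "ScaleGrid":
        """Logarithmically spaced integer scales in ``[n_min, n_max]``.

        If ``series_length`` is given, ``n_max`` is additionally capped at
        ``max_fraction`` of the length so every scale yields at least a few
        windows.  Duplicates arising from integer rounding are dropped.
        """
        if series_length is not None:
            n_max = min(n_max, int(series_length * max_fraction))
        if n_max < n_min:
            raise InvalidScaleError(
                f"n_max={n_max} < n_min={n_min} (series too short for this grid)"
            )
        raw = np.geomspace(n_min, n_max, num=num)
        return cls(np.rint(raw).astype(int))

    def __iter__(self):
        return iter(self.scales)

    def __len__(self) -> int:
        return len(self.scales)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.scales, dtype=int)

    @property
    def n_min(self) -> int:
        return self.scales[0]

    @property
    def n_max(self) -> int:
        return self.scales[-1]


@dataclass
class FluctuationSet:
    """Per-scale fluctuation values F²(n) for one series or one pair.

    ``kind`` is ``"variance"`` (DFA, nonnegative) or ``"covariance"``
    (DCCA, may be negative).
    """

    grid: ScaleGrid
    values: np.ndarray
    kind: str = "variance"
    detrend_order: int = DEFAULT_DETREND_ORDER
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError("values must align with the scale grid")
        if self.kind not in ("variance", "covariance"):
            raise ValueError(f"unknown kind {self.kind!r}")
        self._index = {n: i for i, n in enumerate(self.grid)}

    def at(self, n: int) -> float:
        """F²(n) at a single scale of the grid."""
        return float(self.values[self._index[int(n)]])


def compute_profile(series: Sequence[float]) -> np.ndarray:
    """Cumulative sum of the mean-centered series.

    The profile integrates the series once; its last element is zero up to
    rounding because the increments are centered.
    """
    z = _as_series(series)
    return np.cumsum(z - z.mean())


def segment_bounds(N: int, n: int) -> list[tuple[int, int]]:
    """Half-open index windows ``[start, stop)`` for scale ``n``.

    ``N_n = floor(N/n)`` windows are laid out from the start of the profile
    and another ``N_n`` from the end, so that when ``n`` does not divide
    ``N`` the tail of the series is still covered (windows may overlap).
    """
    N, n = int(N), int(n)
    if n > N:
        raise InvalidScaleError(f"scale n={n} exceeds series length N={N}")
    if n < 1:
        raise InvalidScaleError(f"scale n={n} < 1")
    n_seg = N // n
    forward = [(j * n, (j + 1) * n) for j in range(n_seg)]
    backward = [(N - (m + 1) * n, N - m * n) for m in range(n_seg)]
    return forward + backward


@lru_cache(maxsize=256)
def _detrend_basis(n: int, order: int) -> np.ndarray:
    """Orthonormal polynomial basis (n × (order+1)) on abscissa 1..n."""
    x = np.arange(1, n + 1, dtype=float)
    # Vandermonde in ascending powers; scaling x improves conditioning.
    X = np.vander(x / n, N=order + 1, increasing=True)
    Q, _ = np.linalg.qr(X)
    return Q


def detrended_residuals(profile: np.ndarray, n: int, order: int) -> np.ndarray:
    """Within-window residuals of a polynomial trend fit to the profile.

    Returns a ``(2*N_n, n)`` array: one row of detrended profile values per
    window (forward windows first, then backward).
    """
    profile = np.asarray(profile, dtype=float)
    n = int(n)
    if n < order + 2:
        raise InvalidScaleError(
            f"scale n={n} too small for polynomial order {order} "
            f"(need at least order + 2 = {order + 2} points)"
        )
    bounds = segment_bounds(profile.size, n)
    windows = np.stack([profile[a:b] for a, b in bounds])
    Q = _detrend_basis(n, order)
    return windows - (windows @ Q) @ Q.T


def _fluct_values(
    profiles: list[np.ndarray], grid: ScaleGrid, order: int
) -> np.ndarray:
    """Mean within-window residual products for one (a,a) or a pair (a,b)."""
    out = np.empty(len(grid))
    for i, n in enumerate(grid):
        resids = [detrended_residuals(p, n, order) for p in profiles]
        if len(resids) == 1:
            prod = resids[0] ** 2
        else:
            prod = resids[0] * resids[1]
        # Eq-style normalization: divide by n within windows, then average
        # over the 2*N_n windows.
        out[i] = prod.mean()
    return out


def dfa_variance(
    series: Sequence[float],
    grid: ScaleGrid,
    order: int = DEFAULT_DETREND_ORDER,
) -> FluctuationSet:
    """DFA-based scale-dependent variance function F²_Z(n).

    For each scale ``n`` the profile is split into ``2*floor(N/n)`` windows
    (forward and backward), a polynomial of the given order is fitted in
    each, and the squared residuals are averaged — first within windows
    (divided by ``n``) and then across windows.
    """
    profile = compute_profile(series)
    values = _fluct_values([profile], grid, order)
    # Squared residuals can dip infinitesimally below zero through rounding.
    np.maximum(values, 0.0, out=values)
    return FluctuationSet(grid, values, kind="variance", detrend_order=order)


def dcca_covariance(
    series_a: Sequence[float],
    series_b: Sequence[float],
    grid: ScaleGrid,
    order: int = DEFAULT_DETREND_ORDER,
) -> FluctuationSet:
    """DCCA-based scale-dependent covariance function F²_{Z1 Z2}(n).

    Each series is profiled and detrended independently, exactly as in
    :func:`dfa_variance`; the within-window products of the two residual
    fields are averaged.  The result may be negative (anti-correlation).
    """
    a = _as_series(series_a, "series_a")
    b = _as_series(series_b, "series_b")
    if a.size != b.size:
        raise InvalidDataError(
            f"series lengths differ: {a.size} vs {b.size}"
        )
    profiles = [compute_profile(a), compute_profile(b)]
    values = _fluct_values(profiles, grid, order)
    return FluctuationSet(grid, values, kind="covariance", detrend_order=order)
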