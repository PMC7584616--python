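"""Closed-form uncertainty of time-in-range estimates under AR(1) correlation.

Continuous glucose monitoring (CGM) metrics such as time below range (TBR)
are sample means of a dichotomized glucose process ``h_k in {0, 1}``.  When
``h_k`` is a stationary correlated Bernoulli process with hypoglycemia
probability ``p_h`` and exponentially decaying autocovariance
``cov[h_k, h_l] = alpha**|l-k| * p_h*(1-p_h)``, the standard deviation of the
estimation error ``e(n) = t(n) - p_h`` of the prefix-mean estimator ``t(n)``
has a closed form (:func:`sd_error`).  A companion closed form
(:func:`sd_error_vs_full`) gives the standard deviation of ``t(n) - t(N)``,
the error actually measurable on a finite recording of ``N`` samples where
the true ``p_h`` is replaced by the whole-trial estimate ``t(N)``; the gap
between the two is the "tail effect", quantified by
:func:`relative_discrepancy`.

All functions in this module work on dimensionless fractions; presentation
layers (tables, CLI) convert to percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARParams",
    "SamplingSpec",
    "ErrorCurve",
    "Duration",
    "sd_error",
    "sd_error_curve",
    "sd_error_vs_full",
    "sd_error_vs_full_curve",
    "relative_discrepancy",
    "min_duration",
    "uncertainty_table",
]

_VALID_SOURCES = ("theorem1", "theorem2", "empirical", "monte_carlo")


@dataclass(frozen=True)
class ARParams:
    """Parameters of the dichotomized glucose process.

    Attributes
    ----------
    p_h : float
        Probability that a sample lies in the target glycemic range
        (e.g. probability of hypoglycemia for TBR), in ``[0, 1]``.
    alpha : float
        Decay rate of the AR(1) autocovariance, in ``[0, 1)``.  ``alpha = 0``
        is the uncorrelated (binomial) limit; values near 1 describe long
        glycemic episodes spanning many consecutive samples.
    """

    p_h: float
    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_h <= 1.0):
            raise ValueError(f"p_h must lie in [0, 1], got {self.p_h!r}")
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha!r}")

    @property
    def sigma2(self) -> float:
        """Bernoulli variance ``p_h * (1 - p_h)``, at most 0.25."""
        return self.p_h * (1.0 - self.p_h)


@dataclass(frozen=True)
class SamplingSpec:
    """Sampling grid of a CGM sensor. Default: one sample every 5 minutes."""

    period_seconds: float = 300.0

    def __post_init__(self) -> None:
        if not self.period_seconds > 0:
            raise ValueError("period_seconds must be positive")

    @property
    def samples_per_day(self) -> float:
        spd = 86400.0 / self.period_seconds
        return int(spd) if spd == int(spd) else spd


@dataclass
class ErrorCurve:
    """Standard deviation of the estimation error per window length.

    ``source`` records provenance: ``theorem1`` (closed form for
    ``t(n) - p_h``), ``theorem2`` (closed form for ``t(n) - t(N)``),
    ``empirical`` (pooled sliding windows on data) or ``monte_carlo``
    (replicated simulation).  ``params`` is absent for empirical curves.
    """

    n_values: np.ndarray
    sd_values: np.ndarray
    source: str
    params: ARParams | None = None

    def __post_init__(self) -> None:
        self.n_values = np.asarray(self.n_values, dtype=int)
        self.sd_values = np.asarray(self.sd_values, dtype=float)
        if self.n_values.shape != self.sd_values.shape or self.n_values.ndim != 1:
            raise ValueError("n_values and sd_values must be 1-d arrays of equal length")
        if self.source not in _VALID_SOURCES:
            raise ValueError(f"source must be one of {_VALID_SOURCES}, got {self.source!r}")
        if self.n_values.size:
            if np.any(self.n_values < 1) or np.any(np.diff(self.n_values) <= 0):
                raise ValueError("n_values must be strictly increasing positive integers")
            if np.any(self.sd_values < 0):
                raise ValueError("sd_values must be non-negative")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n_values, "sd": self.sd_values, "source": self.source})


class Duration(NamedTuple):
    """Minimum monitoring duration, in samples and in days."""

    n_samples: int
    days: float


def _check_n(n, name: str = "n") -> np.ndarray:
    arr = np.asarray(n)
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr < 1) or np.any(arr != np.floor(arr)):
        raise ValueError(f"{name} must contain positive integers, got {n!r}")
    return arr.astype(float)


def _var_error(n: np.ndarray, params: ARParams) -> np.ndarray:
    """Variance of t(n) - p_h; vectorized over n."""
    s2, a = params.sigma2, params.alpha
    if s2 == 0.0:
        return np.zeros_like(n)
    if a == 0.0:
        return s2 / n
    # alpha**n underflows to exactly 0 for large n, which is the correct limit
    with np.errstate(under="ignore"):
        a_n = np.power(a, n)
    bracket = 1.0 + 2.0 * a / (1.0 - a) + (2.0 * a / n) * (a_n - 1.0) / (1.0 - a) ** 2
    return s2 / n * bracket


def sd_error(n: int, params: ARParams) -> float:
    """Standard deviation of the TBR estimation error ``e(n) = t(n) - p_h``.

    Closed form for a stationary AR(1) correlated Bernoulli process::

        sd[e(n)] = sqrt( p_h(1-p_h)/n * ( 1 + 2a/(1-a) + (2a/n)(a^n - 1)/(1-a)^2 ) )

    For ``alpha = 0`` this is the binomial standard error
    ``sqrt(p_h(1-p_h)/n)``; positive correlation inflates it.  Degenerate
    ``p_h`` in {0, 1} gives 0.

    Parameters
    ----------
    n : int
        Number of CGM samples in the estimation window (``>= 1``).
    params : ARParams
        Process parameters ``(p_h, alpha)``.
    """
    return float(np.sqrt(_var_error(_check_n(n), params)))


def sd_error_curve(n_values: Sequence[int], params: ARParams) -> ErrorCurve:
    """Evaluate :func:`sd_error` on a grid of window lengths."""
    n = _check_n(n_values, "n_values")
    return ErrorCurve(n, np.sqrt(_var_error(n, params)), source="theorem1", params=params)


def _var_vs_full(n: np.ndarray, N: int, params: ARParams) -> np.ndarray:
    s2, a = params.sigma2, params.alpha
    var_N = _var_error(np.asarray(float(N)), params)
    var_n = _var_error(n, params)
    with np.errstate(under="ignore"):
        cross = (
            2.0 * s2 * (a / (n * N)) * (1.0 - np.power(a, n)) * (1.0 - np.power(a, N - n))
            / (1.0 - a) ** 2
            if a > 0.0
            else np.zeros_like(n)
        )
    v = var_N + (N - 2.0 * n) / N * var_n - cross
    # cancellation near n = N can leave a tiny negative residue; the true value is >= 0
    return np.maximum(v, 0.0)


def sd_error_vs_full(n: int, N: int, params: ARParams) -> float:
    """Standard deviation of ``t(n) - t(N)``: the error measurable on a finite trial.

    On real recordings the true ``p_h`` is unknown and is replaced by the
    whole-trial estimate ``t(N)``.  The deviation ``t(n) - t(N)`` then
    systematically underestimates the true error ``t(n) - p_h`` as ``n``
    approaches ``N`` (the "tail effect"), and is exactly 0 at ``n = N``.
    Converges to :func:`sd_error` as ``N -> inf`` with ``n`` fixed.
    """
    n_arr = _check_n(n)
    _check_n(N, "N")
    if np.any(n_arr > N):
        raise ValueError(f"window length n={n} exceeds trial length N={N}")
    return float(np.sqrt(_var_vs_full(n_arr, int(N), params)))


def sd_error_vs_full_curve(n_values: Sequence[int], N: int, params: ARParams) -> ErrorCurve:
    """Evaluate :func:`sd_error_vs_full` on a grid of window lengths."""
    n = _check_n(n_values, "n_values")
    _check_n(N, "N")
    if np.any(n > N):
        raise ValueError("all window lengths must satisfy n <= N")
    return ErrorCurve(n, np.sqrt(_var_vs_full(n, int(N), params)), source="theorem2", params=params)


def relative_discrepancy(n: int, N: int, params: ARParams) -> float:
    """Relative discrepancy RD = (sd[t(n)-t(N)] - sd[e(n)]) / sd[e(n)].

    Signed measure of the tail-effect bias: always ``<= 0`` for a valid AR(1)
    process (the finite-trial error underestimates the true one) and exactly
    ``-1`` at ``n = N``.
    """
    sd_true = sd_error(n, params)
    if sd_true == 0.0:
        raise ValueError("relative discrepancy undefined: sd_error is 0 for these parameters")
    return (sd_error_vs_full(n, N, params) - sd_true) / sd_true


def min_duration(
    target_sd: float, params: ARParams, sampling: SamplingSpec = SamplingSpec()
) -> Duration:
    """Smallest window length whose predicted error SD is at or below a target.

    Searches for the minimal integer ``n`` with ``sd_error(n) <= target_sd``
    by exponential bracketing and bisection, then verifies the neighbourhood
    linearly (the ``-2*alpha/n * ...`` correction makes the curve not exactly
    monotone at very small ``n``).

    Returns
    -------
    Duration
        ``(n_samples, days)`` with ``days = n / samples_per_day``.
    """
    if not target_sd > 0.0:
        raise ValueError("target_sd must be positive")
    spd = sampling.samples_per_day

    if sd_error(1, params) <= target_sd:
        return Duration(1, 1.0 / spd)

    hi = 1
    while sd_error(hi, params) > target_sd:
        hi *= 2
        if hi > 2**34:  # sd -> 0 as n -> inf, so this is unreachable for valid params
            raise RuntimeError("bracketing failed to reach the target")
    lo = hi // 2  # sd_error(lo) > target_sd
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if sd_error(mid, params) > target_sd:
            lo = mid
        else:
            hi = mid
    n = hi
    # guard against local non-monotonicity around the bisection answer
    while n > 1 and sd_error(n - 1, params) <= target_sd:
        n -= 1
    assert sd_error(n, params) <= target_sd
    return Duration(n, n / spd)


def uncertainty_table(
    days_list: Sequence[float], params: ARParams, sampling: SamplingSpec = SamplingSpec()
) -> pd.DataFrame:
    """Trial-duration planning table: duration in days, samples, and error SD in percent.

    Each row maps a monitoring duration (days) to the number of CGM samples
    ``n = round(days * samples_per_day)`` and ``100 * sd_error(n)``.
    """
    rows = []
    for days in days_list:
        if not days > 0:
            raise ValueError(f"durations must be positive, got {days!r}")
        n = int(round(days * sampling.samples_per_day))
        rows.append((days, n, 100.0 * sd_error(n, params)))
    return pd.DataFrame(rows, columns=["days", "n_samples", "sd_percent"])
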