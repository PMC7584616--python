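"""Dichotomization of CGM traces and AR(1) parameter estimation.

A glucose trace ``g_k`` (mg/dL, fixed sampling period) is reduced to a binary
indicator ``h_k`` of membership in a glycemic range (e.g. hypoglycemia,
``g < 70``).  The fraction of ones over the whole trace is the clinical
metric (TBR, TIR, ...) and the per-subject estimate of ``p_h``.  The
correlation parameter ``alpha`` is estimated by fitting a single exponential
``alpha**tau`` to the normalized sample autocovariance of ``h_k`` with
weighted nonlinear least squares (WNLLS).  Population parameters aggregate
per-subject fits: by default the mean of the ``p_h`` estimates and the 95th
percentile of the ``alpha`` estimates (the most correlated traces dominate
the population error decay, so a high quantile is the conservative choice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .core_model import ARParams, SamplingSpec

__all__ = [
    "GlycemicRange",
    "GLYCEMIC_RANGES",
    "CGMTrace",
    "BinarySeries",
    "AutocovEstimate",
    "AlphaFit",
    "SubjectFit",
    "FitSettings",
    "dichotomize",
    "time_in_metric",
    "sample_autocov",
    "fit_alpha",
    "fit_subject",
    "population_params",
]

ALPHA_UPPER_BOUND = 0.999999


@dataclass(frozen=True)
class GlycemicRange:
    """Half-open glucose interval ``[lower, upper)`` in mg/dL.

    The indicator is 1 when ``lower <= g < upper``; a bound of ``-inf`` /
    ``+inf`` leaves that side open.  The upper-exclusive convention matches
    the clinical definitions (hypoglycemia is strictly below 70 mg/dL, so
    TBR is the range ``(-inf, 70)`` and a reading of exactly 70 counts as
    in range).
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"lower must be < upper, got [{self.lower}, {self.upper})")

    def contains(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return (values >= self.lower) & (values < self.upper)

    @classmethod
    def from_name(cls, name: str) -> "GlycemicRange":
        try:
            return GLYCEMIC_RANGES[name.lower()]
        except KeyError:
            raise ValueError(
                f"unknown glycemic range {name!r}; choose from {sorted(GLYCEMIC_RANGES)}"
            ) from None


#: Consensus glycemic ranges: time below range (<70), level-2 hypoglycemia
#: (<54), time in range [70, 180), time above range (>=180).
GLYCEMIC_RANGES = {
    "tbr": GlycemicRange(-math.inf, 70.0),
    "l2h": GlycemicRange(-math.inf, 54.0),
    "tir": GlycemicRange(70.0, 180.0),
    "tar": GlycemicRange(180.0, math.inf),
}


@dataclass
class CGMTrace:
    """Ordered glucose samples (mg/dL) at a fixed sampling period.

    ``timestamps``, if present, are seconds (monotone increasing) and must
    align with ``values``.  ``segment`` distinguishes contiguous segments of
    a subject's recording after gap splitting.
    """

    values: np.ndarray
    sampling: SamplingSpec = SamplingSpec()
    subject_id: str = ""
    timestamps: np.ndarray | None = None
    segment: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a CGM trace needs at least 2 samples in a 1-d array")
        bad = np.flatnonzero(~np.isfinite(self.values) | (self.values <= 0))
        if bad.size:
            raise ValueError(
                f"invalid glucose value {self.values[bad[0]]!r} at index {bad[0]} "
                f"(subject {self.subject_id!r})"
            )
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != self.values.shape:
                raise ValueError("timestamps must align with values")
            if np.any(np.diff(self.timestamps) <= 0):
                raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class BinarySeries:
    """Dichotomized trace ``h_k in {0, 1}``."""

    bits: np.ndarray
    sampling: SamplingSpec = SamplingSpec()
    range: GlycemicRange | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 1 or self.bits.size < 1:
            raise ValueError("bits must be a non-empty 1-d array")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must contain only 0 and 1")
        self.bits = self.bits.astype(np.uint8)

    def __len__(self) -> int:
        return self.bits.size


@dataclass
class AutocovEstimate:
    """Sample autocovariance of a binary series at consecutive lags 0..max_lag.

    ``cov_values[tau]`` uses the ``N - tau - 1`` denominator, so lag 0 is the
    ordinary unbiased sample variance.  ``normalized`` divides by lag 0.
    ``n_samples`` is the total sample count behind the estimate and
    ``n_pairs[tau]`` the number of products pooled at each lag (used as
    WNLLS weights downstream).
    """

    lags: np.ndarray
    cov_values: np.ndarray
    normalized: np.ndarray
    n_samples: int
    n_pairs: np.ndarray


@dataclass
class AlphaFit:
    """Result of the exponential-decay fit to the normalized autocovariance."""

    alpha: float
    residual_ss: float
    lags_used: int
    nonpositive_tail: bool = False  # all normalized covariances at tau >= 1 were <= 0


@dataclass
class SubjectFit:
    """Per-subject estimates: p_hat = t(N), alpha_hat from WNLLS, sigma2_hat."""

    subject_id: str
    p_hat: float
    alpha_hat: float
    sigma2_hat: float
    degenerate: bool = False
    warning: bool = False
    residual_ss: float = math.nan
    lags_used: int = 0
    n_samples: int = 0

    def to_params(self) -> ARParams:
        if self.degenerate:
            raise ValueError(f"subject {self.subject_id!r} is degenerate (p_hat={self.p_hat})")
        return ARParams(self.p_hat, self.alpha_hat)


@dataclass(frozen=True)
class FitSettings:
    """Estimation settings.

    max_lag : largest autocovariance lag fitted (default 50 samples, about
        4 h at 5-min sampling — the initial exponential decay; longer lags
        are noise-dominated).
    weights : "pairs" weighs lag tau by the number of contributing products
        (more pairs, lower estimator variance); "uniform" weighs equally.
    """

    max_lag: int = 50
    weights: str = "pairs"

    def __post_init__(self) -> None:
        if self.max_lag < 2:
            raise ValueError("max_lag must be at least 2")
        if self.weights not in ("pairs", "uniform"):
            raise ValueError("weights must be 'pairs' or 'uniform'")


def dichotomize(trace: CGMTrace, range_: GlycemicRange) -> BinarySeries:
    """Map a glucose trace to the binary indicator of a glycemic range."""
    bad = np.flatnonzero(~np.isfinite(trace.values))
    if bad.size:
        raise ValueError(f"non-finite glucose value at index {bad[0]}")
    return BinarySeries(
        range_.contains(trace.values).astype(np.uint8), trace.sampling, range_
    )


def time_in_metric(bits: BinarySeries, n: int | None = None) -> float:
    """Prefix-mean estimator t(n): fraction of the first ``n`` samples in range.

    With ``n = None`` (the full series) this is the clinical metric itself
    (TBR/TIR/... over the whole recording) and the per-subject estimate of
    ``p_h``.
    """
    N = len(bits)
    if n is None:
        n = N
    if not 1 <= n <= N:
        raise ValueError(f"n must lie in [1, {N}], got {n}")
    return float(bits.bits[:n].mean())


def _segments(bits: Union[BinarySeries, Sequence[BinarySeries]]) -> list[BinarySeries]:
    return [bits] if isinstance(bits, BinarySeries) else list(bits)


def sample_autocov(
    bits: Union[BinarySeries, Sequence[BinarySeries]], max_lag: int
) -> AutocovEstimate:
    """Sample autocovariance COV_h(tau), tau = 0..max_lag.

    The global mean is subtracted in both factors and the sum of products at
    lag ``tau`` is divided by ``(#pairs) - 1``; for a single contiguous
    series of length N that denominator is ``N - tau - 1``, so lag 0 equals
    the unbiased sample variance.

    A list of series is treated as contiguous segments of one recording
    (e.g. around sensor gaps): products are pooled per segment, never
    bridging the gap between segments.
    """
    segs = _segments(bits)
    if not segs:
        raise ValueError("need at least one series")
    lengths = np.array([len(s) for s in segs])
    if max_lag >= lengths.min() - 1:
        raise ValueError(
            f"max_lag must be < shortest segment length - 1 ({lengths.min() - 1})"
        )
    total = int(lengths.sum())
    mean = sum(int(s.bits.sum()) for s in segs) / total

    lags = np.arange(max_lag + 1)
    sums = np.zeros(max_lag + 1)
    for s in segs:
        x = s.bits.astype(float) - mean
        for tau in lags:
            sums[tau] += x[: len(x) - tau] @ x[tau:]
    n_pairs = np.array([int((lengths - tau).sum()) for tau in lags])
    cov = sums / (n_pairs - 1)
    if cov[0] <= 0.0:
        raise ValueError("degenerate (constant) series: sample variance is 0")
    return AutocovEstimate(lags, cov, cov / cov[0], total, n_pairs)


def fit_alpha(autocov: AutocovEstimate, settings: FitSettings = FitSettings()) -> AlphaFit:
    """Estimate the AR(1) decay ``alpha`` by WNLLS on the normalized autocovariance.

    Fits ``alpha**tau`` to ``COV_h(tau)/COV_h(0)`` over the available lags,
    minimizing ``sum_tau w_tau * (alpha**tau - c_tau)**2`` with weights
    ``w_tau`` proportional to the pair counts (or uniform).  The fit is on
    the linear scale: normalized covariances can be <= 0 at long lags, where
    a log transform would be undefined.  The optimizer starts from the lag-1
    normalized covariance clamped into ``[0, 0.999999]``.

    If every normalized covariance at ``tau >= 1`` is non-positive the series
    is indistinguishable from white noise and ``alpha = 0`` is returned with
    ``nonpositive_tail`` set.
    """
    lags = autocov.lags
    if lags.size < 3:
        raise ValueError("need at least 3 lags (0, 1, 2) to fit alpha")
    c = autocov.normalized
    if np.all(c[1:] <= 0.0):
        resid = float(np.sum(_weights(autocov, settings)[1:] * c[1:] ** 2))
        return AlphaFit(0.0, resid, lags.size, nonpositive_tail=True)

    w = np.sqrt(_weights(autocov, settings))
    tau = lags.astype(float)

    def residuals(a: np.ndarray) -> np.ndarray:
        with np.errstate(under="ignore"):
            return w * (np.power(a[0], tau) - c)

    x0 = float(np.clip(c[1], 0.0, ALPHA_UPPER_BOUND))
    result = least_squares(
        residuals, x0=[x0], bounds=(0.0, ALPHA_UPPER_BOUND),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not result.success:
        raise RuntimeError(f"alpha fit did not converge: {result.message}")
    return AlphaFit(float(result.x[0]), float(2.0 * result.cost), lags.size)


def _weights(autocov: AutocovEstimate, settings: FitSettings) -> np.ndarray:
    if settings.weights == "pairs":
        return autocov.n_pairs.astype(float)
    return np.ones_like(autocov.lags, dtype=float)


def fit_subject(
    trace: Union[CGMTrace, Sequence[CGMTrace]],
    range_: GlycemicRange,
    settings: FitSettings = FitSettings(),
) -> SubjectFit:
    """Estimate ``(p_h, alpha)`` for one subject.

    ``p_hat`` is the whole-recording fraction in range, ``alpha_hat`` the
    WNLLS exponential fit to the sample autocovariance, and
    ``sigma2_hat = p_hat * (1 - p_hat)``.  A list of traces is interpreted
    as contiguous segments of one subject's recording.  Subjects whose trace
    never (or always) enters the range are flagged ``degenerate``:
    ``alpha`` is then undefined and the fit is excluded from population
    aggregation.
    """
    traces = [trace] if isinstance(trace, CGMTrace) else list(trace)
    if not traces:
        raise ValueError("need at least one trace")
    subject_id = traces[0].subject_id
    segs = [dichotomize(t, range_) for t in traces]
    total = sum(len(s) for s in segs)
    p_hat = sum(int(s.bits.sum()) for s in segs) / total
    sigma2 = p_hat * (1.0 - p_hat)
    if p_hat in (0.0, 1.0):
        return SubjectFit(
            subject_id, p_hat, math.nan, sigma2,
            degenerate=True, warning=True, n_samples=total,
        )
    min_len = min(len(s) for s in segs)
    max_lag = min(settings.max_lag, min_len - 2)
    autocov = sample_autocov(segs if len(segs) > 1 else segs[0], max_lag)
    fit = fit_alpha(autocov, settings)
    return SubjectFit(
        subject_id, p_hat, fit.alpha, sigma2,
        warning=fit.nonpositive_tail, residual_ss=fit.residual_ss,
        lags_used=fit.lags_used, n_samples=total,
    )


_RULES: dict[str, Callable[[np.ndarray], float]] = {
    "mean": lambda x: float(np.mean(x)),
    "median": lambda x: float(np.median(x)),
    "p95": lambda x: float(np.percentile(x, 95.0)),  # linear-interpolation percentile
}


def population_params(
    fits: Sequence[SubjectFit],
    p_rule: str | Callable[[np.ndarray], float] = "mean",
    alpha_rule: str | Callable[[np.ndarray], float] = "p95",
) -> ARParams:
    """Aggregate per-subject fits into a single population ``(p_h*, alpha*)``.

    Defaults: mean of the ``p_hat`` distribution and 95th percentile of the
    ``alpha_hat`` distribution.  The high quantile for alpha is deliberate:
    the most correlated subjects have the slowest error decay and dominate
    the population estimation error at large ``n``.  Degenerate fits are
    excluded.
    """
    valid = [f for f in fits if not f.degenerate]
    if not valid:
        raise ValueError("no non-degenerate subject fits to aggregate")
    p_fn = _RULES[p_rule] if isinstance(p_rule, str) else p_rule
    a_fn = _RULES[alpha_rule] if isinstance(alpha_rule, str) else alpha_rule
    p_star = p_fn(np.array([f.p_hat for f in valid]))
    alpha_star = a_fn(np.array([f.alpha_hat for f in valid]))
    return ARParams(p_star, alpha_star)
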