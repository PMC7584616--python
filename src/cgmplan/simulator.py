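"""Two-state Markov chain simulator of correlated Bernoulli hypoglycemia processes.

A time-homogeneous chain with states 0 (in range) and 1 (below range) and
staying probabilities ``p00``, ``p11`` generates a stationary binary process
whose marginal probability and lag-1 autocorrelation are

    p_h   = (p00 - 1) / (p00 + p11 - 2)
    alpha = p00 + p11 - 1

so the AR(1) structure assumed by the closed-form error formulas holds
exactly, with ``cov[h_k, h_l] = alpha**|l-k| * p_h*(1-p_h)``.  The mapping is
invertible (:func:`chain_from_targets`), which lets the simulator produce
processes with *exactly known* ``(p_h, alpha)`` for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import ARParams, ErrorCurve, SamplingSpec
from .estimation import BinarySeries, CGMTrace, GlycemicRange, GLYCEMIC_RANGES

__all__ = [
    "MarkovChainParams",
    "SimulationConfig",
    "stationary_params",
    "chain_from_targets",
    "simulate_traces",
    "simulate_matrix",
    "monte_carlo_sd_curve",
    "to_cgm_trace",
]


@dataclass(frozen=True)
class MarkovChainParams:
    """Staying probabilities of the two-state chain.

    ``p00`` is the probability of remaining in range, ``p11`` of remaining
    below range; the exit probabilities are ``p01 = 1 - p00`` and
    ``p10 = 1 - p11``.  The implied lag-1 autocorrelation is
    ``p00 + p11 - 1``, which can be negative for an alternating chain; such
    chains are representable here but outside the AR(1) model class this
    package targets (see :func:`chain_from_targets`).
    """

    p00: float
    p11: float

    def __post_init__(self) -> None:
        for name, v in (("p00", self.p00), ("p11", self.p11)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")

    @property
    def alpha(self) -> float:
        return self.p00 + self.p11 - 1.0


def _alpha_ratio_form(chain: MarkovChainParams) -> float:
    # equivalent ratio form of the lag-1 autocorrelation (undefined at p11 = 1);
    # kept only as an independent cross-check of the reduced form
    p00, p11 = chain.p00, chain.p11
    return p11 * (p00 + p11 - 2.0) / (p11 - 1.0) - (p00 - 1.0) / (p11 - 1.0)


def stationary_params(chain: MarkovChainParams) -> ARParams:
    """Stationary ``(p_h, alpha)`` of a two-state chain.

    Raises for the doubly absorbing chain ``p00 = p11 = 1`` (no unique
    stationary distribution) and for negative-correlation chains
    (``p00 + p11 < 1``), which fall outside the AR(1) model class.
    """
    if chain.p00 == 1.0 and chain.p11 == 1.0:
        raise ValueError("degenerate chain: p00 = p11 = 1 has no unique stationary law")
    p_h = (chain.p00 - 1.0) / (chain.p00 + chain.p11 - 2.0)
    return ARParams(p_h, chain.alpha)


def chain_from_targets(params: ARParams) -> MarkovChainParams:
    """Invert the stationary mapping: chain with exact ``(p_h, alpha)``.

    ``p00 = 1 - p_h*(1-alpha)`` and ``p11 = alpha + p_h*(1-alpha)``;
    ``stationary_params(chain_from_targets(x)) == x`` up to rounding.
    """
    q = params.p_h * (1.0 - params.alpha)
    return MarkovChainParams(p00=1.0 - q, p11=params.alpha + q)


@dataclass(frozen=True)
class SimulationConfig:
    """Replicated-simulation settings.

    ``n_rep`` traces of ``n_samples`` correlated Bernoulli variables each,
    emulating a trial of ``n_rep`` subjects.  Each replicate draws from its
    own substream spawned from ``seed``, so results do not depend on
    replicate ordering.  The initial state is drawn from the stationary
    distribution, making the process stationary from the first sample
    (``burn_in`` defaults to 0 and exists only for sensitivity checks).
    """

    chain: MarkovChainParams
    n_samples: int
    n_rep: int
    seed: int
    burn_in: int = 0
    sampling: SamplingSpec = SamplingSpec()

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_rep < 1:
            raise ValueError("n_samples and n_rep must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")

    @classmethod
    def from_targets(
        cls, p_h: float, alpha: float, n_samples: int, n_rep: int, seed: int, **kw
    ) -> "SimulationConfig":
        return cls(chain_from_targets(ARParams(p_h, alpha)), n_samples, n_rep, seed, **kw)


def simulate_matrix(config: SimulationConfig) -> np.ndarray:
    """Simulate all replicates at once; returns a (n_rep, n_samples) uint8 array."""
    params = stationary_params(config.chain)
    total = config.n_samples + config.burn_in
    children = np.random.SeedSequence(config.seed).spawn(config.n_rep)
    u = np.empty((config.n_rep, total))
    for i, child in enumerate(children):
        u[i] = np.random.default_rng(child).random(total)
    p00, p11 = config.chain.p00, config.chain.p11
    state = np.empty((config.n_rep, total), dtype=bool)
    state[:, 0] = u[:, 0] < params.p_h  # stationary initialization
    for k in range(1, total):
        prev = state[:, k - 1]
        # stay below range w.p. p11; enter it from in-range w.p. 1 - p00
        state[:, k] = np.where(prev, u[:, k] < p11, u[:, k] >= p00)
    return state[:, config.burn_in :].astype(np.uint8)


def simulate_traces(config: SimulationConfig) -> list[BinarySeries]:
    """Simulate ``n_rep`` stationary binary traces of length ``n_samples``."""
    mat = simulate_matrix(config)
    return [BinarySeries(row, config.sampling) for row in mat]


def monte_carlo_sd_curve(config: SimulationConfig, n_values) -> ErrorCurve:
    """Replicated Monte-Carlo estimate of sd[e(n)] against the *true* p_h.

    For each window length ``n``, computes the prefix mean ``t(n; i)`` of
    every replicate, the error ``e(n; i) = t(n; i) - p_h`` with the known
    simulation ``p_h``, and the root mean square over replicates with the
    ``n_rep - 1`` denominator.
    """
    if config.n_rep < 2:
        raise ValueError("n_rep must be >= 2 for a defined sample SD")
    n_arr = np.asarray(n_values, dtype=int)
    if np.any(n_arr < 1) or np.any(n_arr > config.n_samples):
        raise ValueError("all n_values must lie in [1, n_samples]")
    params = stationary_params(config.chain)
    mat = simulate_matrix(config)
    csum = np.cumsum(mat, axis=1, dtype=float)
    t_n = csum[:, n_arr - 1] / n_arr  # (n_rep, len(n_values))
    e = t_n - params.p_h
    sd = np.sqrt((e**2).sum(axis=0) / (config.n_rep - 1))
    return ErrorCurve(n_arr, sd, source="monte_carlo", params=params)


def to_cgm_trace(
    bits: BinarySeries,
    range_: GlycemicRange = GLYCEMIC_RANGES["tbr"],
    subject_id: str = "",
) -> CGMTrace:
    """Encode a binary trace as a synthetic glucose trace.

    Each 1 becomes a representative glucose value inside the range and each
    0 one outside it, so simulated cohorts round-trip through the same CSV
    format and dichotomization path as real data.
    """
    if np.isfinite(range_.lower):
        inside = (range_.lower + range_.upper) / 2.0 if np.isfinite(range_.upper) \
            else range_.lower + 30.0
    else:
        inside = range_.upper - 10.0
    if np.isfinite(range_.upper):
        outside = range_.upper + 30.0
    else:
        outside = range_.lower - 30.0
    if inside <= 0 or outside <= 0:
        raise ValueError(f"cannot encode bits for range [{range_.lower}, {range_.upper})")
    values = np.where(bits.bits == 1, inside, outside).astype(float)
    return CGMTrace(values, bits.sampling, subject_id=subject_id)
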