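"""Shared fixtures and independent brute-force oracles.

The oracles expand the variance of (differences of) prefix means as explicit
double sums over the AR(1) covariance matrix sigma^2 * alpha**|k-l|, staying
independent of the closed forms they are used to check.
"""

import numpy as np
import pytest
from scipy.linalg import toeplitz

from cgmplan import ARParams


def oracle_sd_error(n: int, params: ARParams) -> float:
    """sqrt of (1/n^2) * sum_{k,l=1..n} sigma^2 * alpha**|k-l|."""
    cov = params.sigma2 * toeplitz(params.alpha ** np.arange(n))
    return float(np.sqrt(cov.sum() / n**2))


def oracle_sd_vs_full(n: int, N: int, params: ARParams) -> float:
    """sqrt of c' C c with c_k the weights of t(n) - t(N) and C the covariance matrix."""
    cov = params.sigma2 * toeplitz(params.alpha ** np.arange(N))
    c = np.full(N, -1.0 / N)
    c[:n] += 1.0 / n
    return float(np.sqrt(c @ cov @ c))


def naive_window_errors(bits: np.ndarray, n: int) -> np.ndarray:
    """Direct per-window averaging, the reference for the prefix-sum path."""
    x = np.asarray(bits, dtype=float)
    p_hat = x.mean()
    return np.array([x[i : i + n].mean() - p_hat for i in range(x.size - n + 1)])


@pytest.fixture(scope="session")
def population_params() -> ARParams:
    """Population parameters of the validation cohort: mean p_h, 95th-pct alpha."""
    return ARParams(0.043, 0.917)


@pytest.fixture(scope="session")
def param_grid() -> list[ARParams]:
    return [
        ARParams(p, a)
        for p in (0.1, 0.3, 0.5)
        for a in (0.0, 0.3, 0.8, 0.95)
    ]
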