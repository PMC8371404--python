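"""Small MCMC toolbox used by the hierarchical slider models.

The samplers in :mod:`focusrsa.hier` are adaptive Metropolis-within-Gibbs:
positive parameters are updated by Gaussian random walks on the log scale,
simplex-valued parameters on additive-log-ratio (ALR) coordinates, with
per-block proposal scales tuned during warmup by Robbins-Monro toward a
target acceptance rate and frozen afterwards.  All chains run in lock-step
through vectorized numpy updates (the chain axis is just another array
axis), and conditionally independent per-participant blocks are proposed
and accepted jointly in one vectorized step.

Convergence diagnostics (split R-hat) and highest-density intervals are
delegated to arviz.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "alr_forward",
    "alr_inverse",
    "log_simplex_jacobian",
    "gamma_logpdf",
    "invgamma_logpdf",
    "dirichlet_logpdf",
    "normal_logpdf_sum",
    "ScaleAdapter",
    "rhat_dict",
    "hdi_interval",
]

LOG_2PI = float(np.log(2.0 * np.pi))


def alr_forward(p: np.ndarray) -> np.ndarray:
    """Additive log-ratio coordinates of a simplex vector (last component
    is the reference): z_i = log(p_i / p_last)."""
    p = np.asarray(p, dtype=float)
    return np.log(p[..., :-1]) - np.log(p[..., -1:])


def alr_inverse(z: np.ndarray) -> np.ndarray:
    """Map ALR coordinates back to the simplex (numerically stable softmax
    of (z, 0))."""
    z = np.asarray(z, dtype=float)
    full = np.concatenate([z, np.zeros(z.shape[:-1] + (1,))], axis=-1)
    full = full - full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def log_simplex_jacobian(p: np.ndarray) -> np.ndarray:
    """log |det J| of the ALR -> simplex map: sum_i log p_i."""
    return np.log(p).sum(axis=-1)


def gamma_logpdf(x, shape, rate):
    """Gamma density in the shape-rate convention (mean = shape/rate)."""
    x = np.asarray(x, dtype=float)
    shape = np.asarray(shape, dtype=float)
    rate = np.asarray(rate, dtype=float)
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def invgamma_logpdf(x, a, b):
    x = np.asarray(x, dtype=float)
    return a * np.log(b) - gammaln(a) - (a + 1.0) * np.log(x) - b / x


def dirichlet_logpdf(p: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Dirichlet log density, broadcasting over leading axes of both
    arguments; the simplex axis is the last one."""
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    return (
        gammaln(a.sum(axis=-1))
        - gammaln(a).sum(axis=-1)
        + ((a - 1.0) * np.log(p)).sum(axis=-1)
    )


def normal_logpdf_sum(y: np.ndarray, mu: np.ndarray, sigma2, axis=-1) -> np.ndarray:
    """Sum of independent Normal log densities along ``axis``."""
    sigma2 = np.asarray(sigma2, dtype=float)
    resid2 = np.square(y - mu).sum(axis=axis)
    n = y.shape[axis] if np.ndim(y) else 1
    return -0.5 * (resid2 / sigma2 + n * (np.log(sigma2) + LOG_2PI))


class ScaleAdapter:
    """Robbins-Monro tuner for log proposal scales.

    One scale per independent accept/reject unit (arbitrary array shape).
    During warmup ``update`` nudges each log-scale toward the target
    acceptance rate with a decaying gain; after warmup the scales freeze.
    """

    def __init__(self, shape, init_scale: float = 0.3, target: float = 0.3):
        self.log_scale = np.full(shape, np.log(init_scale))
        self.target = target
        self._t = 0

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def update(self, accept_prob: np.ndarray) -> None:
        self._t += 1
        gain = self._t**-0.55
        self.log_scale += gain * (np.asarray(accept_prob) - self.target)
        np.clip(self.log_scale, np.log(1e-4), np.log(10.0), out=self.log_scale)


def rhat_dict(draws: dict) -> dict:
    """Split R-hat per named parameter; arrays are (chain, draw, ...) and
    vector parameters report the worst component."""
    import arviz as az

    out = {}
    for name, arr in draws.items():
        r = az.rhat(az.convert_to_dataset(np.asarray(arr)))["x"].values
        out[name] = float(np.nanmax(r))
    return out


def hdi_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Highest-density interval of a 1-d sample."""
    import arviz as az

    lo, hi = az.hdi(np.asarray(samples, dtype=float).ravel(), hdi_prob=prob)
    return float(lo), float(hi)
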