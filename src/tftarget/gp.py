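"""Gaussian-process prior over TF mRNA functions.

Each TF mRNA profile f_i(t) receives a squared-exponential GP prior, which
encodes the smoothness assumption that makes continuous-time activity
inference from ~10 observations well posed.  The induced prior over protein
activity p_i(t) follows deterministically through the linear translation ODE
(see :mod:`tftarget.ode`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .ode import FunctionOnGrid, ProteinParams, solve_translation

__all__ = ["GPHyperparams", "LatentTFState", "gp_cov", "sample_f_prior", "gp_loglik_f"]

#: relative jitter added to the kernel diagonal
JITTER = 1e-6


@dataclass(frozen=True)
class GPHyperparams:
    """Squared-exponential kernel hyperparameters.

    variance: marginal variance (squared expression units)
    lengthscale: correlation length (hours)
    """

    variance: float
    lengthscale: float

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("kernel variance must be non-negative")
        if self.lengthscale <= 0:
            raise ValueError("kernel lengthscale must be positive")


def gp_cov(times, hyper: GPHyperparams) -> np.ndarray:
    """Squared-exponential covariance matrix with diagonal jitter."""
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    d = (t[:, None] - t[None, :]) / hyper.lengthscale
    K = hyper.variance * np.exp(-0.5 * d * d)
    K[np.diag_indices_from(K)] += JITTER * max(hyper.variance, 1.0)
    return K


def gp_chol(times, hyper: GPHyperparams) -> np.ndarray:
    """Lower Cholesky factor of :func:`gp_cov` (used for whitened sampling)."""
    return cholesky(gp_cov(times, hyper), lower=True)


def sample_f_prior(times, hyper: GPHyperparams, seed) -> FunctionOnGrid:
    """Seeded draw of a TF mRNA function from the GP prior (zero mean)."""
    rng = np.random.default_rng(seed)
    L = gp_chol(times, hyper)
    values = L @ rng.standard_normal(len(L))
    if hyper.variance == 0:
        values = np.zeros(len(L))
    return FunctionOnGrid(times, values)


@dataclass
class LatentTFState:
    """Joint state of one TF: mRNA function, protein activity and parameters.

    The protein activity is always the deterministic translation-ODE solution
    of the current mRNA function; use :meth:`update_f` / :meth:`update_pp` to
    keep the pair consistent.
    """

    f: FunctionOnGrid
    pp: ProteinParams
    hyper: GPHyperparams
    p: FunctionOnGrid = None

    def __post_init__(self):
        if self.p is None:
            self.p = solve_translation(self.f, self.pp)

    def update_f(self, f: FunctionOnGrid):
        self.f = f
        self.p = solve_translation(f, self.pp)

    def update_pp(self, pp: ProteinParams):
        self.pp = pp
        self.p = solve_translation(self.f, pp)


def gp_loglik_f(obs_times, obs_values, obs_vars, state: LatentTFState) -> float:
    """Gaussian log-likelihood of TF mRNA observations given the latent f.

    The latent function is linearly interpolated at the observation times;
    each observation carries its own noise variance.
    """
    t = np.asarray(obs_times, dtype=float)
    y = np.asarray(obs_values, dtype=float)
    v = np.asarray(obs_vars, dtype=float)
    if np.any(v <= 0):
        raise ValueError("noise variances must be positive (apply a floor upstream)")
    grid = state.f.times
    if t.min() < grid[0] or t.max() > grid[-1]:
        raise ValueError("observation times outside the latent grid span")
    mu = state.f(t)
    r = y - mu
    return float(-0.5 * np.sum(np.log(2.0 * np.pi * v) + r * r / v))


def gp_loglik_whitened(times, hyper, nu) -> float:
    """Standard-normal log-density of whitened coefficients (prior term)."""
    nu = np.asarray(nu, dtype=float)
    return float(-0.5 * np.sum(nu * nu) - 0.5 * len(nu) * np.log(2.0 * np.pi))


def solve_from_whitened(times, hyper, nu, mean=0.0) -> FunctionOnGrid:
    """Map whitened coefficients to an mRNA function: f = mean + L nu."""
    L = gp_chol(times, hyper)
    return FunctionOnGrid(times, mean + L @ np.asarray(nu, dtype=float))


def whiten(times, hyper, f_values, mean=0.0) -> np.ndarray:
    """Inverse of :func:`solve_from_whitened` for initialisation."""
    L = gp_chol(times, hyper)
    return solve_triangular(L, np.asarray(f_values, dtype=float) - mean, lower=True)
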