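"""Deterministic ODE core for combinatorial transcriptional regulation.

Two coupled linear ODEs describe the system.  Translation converts TF mRNA
``f_i(t)`` into active protein ``p_i(t)`` with first-order decay ``delta_i``::

    dp_i/dt = f_i(t) - delta_i * p_i(t)

Transcription of a target gene ``j`` is driven by the joint activity of the
TF proteins through a sigmoidal response ``G`` in (0, 1)::

    dm_j/dt = b_j + s_j * G(p_1(t), ..., p_I(t); w_j, w_j0) - d_j * m_j(t)

Both ODEs are linear in the state variable and are integrated with their
explicit (variation-of-constants) solutions, with the driving integral
evaluated by trapezoidal quadrature on a dense time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "POSITIVITY_FLOOR",
    "ResponseWeights",
    "KineticParams",
    "ProteinParams",
    "FunctionOnGrid",
    "response_G",
    "solve_translation",
    "solve_transcription",
    "decay_integral_operator",
]

#: floor applied to protein activities before taking logs in the response
POSITIVITY_FLOOR = 1e-8


@dataclass(frozen=True)
class ResponseWeights:
    """Interaction weights of one gene against the I TFs.

    ``w[i] == 0`` means the link gene<-TF_i is absent; positive weights mean
    activation, negative repression.  ``w0`` is the bias of the sigmoid.
    """

    w: np.ndarray
    w0: float

    def __post_init__(self):
        w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if not np.all(np.isfinite(w)) or not np.isfinite(self.w0):
            raise ValueError("response weights must be finite")
        object.__setattr__(self, "w", w)


@dataclass(frozen=True)
class KineticParams:
    """Per-gene transcription kinetics.

    b: basal production rate (expression units / h), >= 0
    s: sensitivity to the TF response (expression units / h), >= 0
    d: mRNA degradation rate (1/h), > 0
    a: initial mRNA level (expression units), >= 0
    """

    b: float
    s: float
    d: float
    a: float = 0.0

    def __post_init__(self):
        if not (self.b >= 0 and self.s >= 0 and self.a >= 0):
            raise ValueError("b, s, a must be non-negative")
        if not self.d > 0:
            raise ValueError("mRNA degradation rate d must be positive")


@dataclass(frozen=True)
class ProteinParams:
    """Per-TF translation parameters: decay rate and initial protein level."""

    delta: float
    p0: float = 0.0

    def __post_init__(self):
        if not self.delta > 0:
            raise ValueError("protein degradation rate delta must be positive")
        if self.p0 < 0:
            raise ValueError("initial protein level must be non-negative")


@dataclass(frozen=True)
class FunctionOnGrid:
    """A function evaluated on a strictly increasing time grid (hours)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-d and equal length")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("grid must be strictly increasing with >= 2 points")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t):
        return np.interp(t, self.times, self.values)


def response_G(p, rw: ResponseWeights):
    """Sigmoidal response of the transcription rate to TF activities.

    G = 1 / (1 + exp(-(w0 + sum_i w_i log p_i))); activities are floored at
    ``POSITIVITY_FLOOR`` before the log.  ``p`` may be a length-I vector or an
    (I, N) array of activities on a grid (result is then length N).
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("TF activities must be finite")
    logp = np.log(np.maximum(p, POSITIVITY_FLOOR))
    if logp.ndim == 1:
        z = rw.w0 + rw.w @ logp
    else:
        z = rw.w0 + np.einsum("i,i...->...", rw.w, logp)
    # numerically stable logistic
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _decay_convolve(times, driver, rate, init):
    """Explicit solution of x' = driver(t) - rate*x on a grid by trapezoid.

    Uses the segment recurrence
    ``x_n = e^{-rate*h} x_{n-1} + h/2 (e^{-rate*h} g_{n-1} + g_n)`` which is
    the exact trapezoidal discretisation of the convolution integral and
    avoids overflowing exponentials.
    """
    h = np.diff(times)
    decay = np.exp(-rate * h)
    x = np.empty_like(driver)
    x[0] = init
    for n in range(1, len(times)):
        x[n] = decay[n - 1] * x[n - 1] + 0.5 * h[n - 1] * (
            decay[n - 1] * driver[n - 1] + driver[n]
        )
    return x


def solve_translation(f: FunctionOnGrid, pp: ProteinParams) -> FunctionOnGrid:
    """Protein activity from TF mRNA through the linear translation ODE.

    p(t) = p0 e^{-delta t} + int_0^t e^{-delta (t-u)} f(u) du.  The mRNA
    driver is clamped at zero (GP-derived functions may dip below).
    """
    fv = np.maximum(f.values, 0.0)
    p = _decay_convolve(f.times, fv, pp.delta, pp.p0)
    return FunctionOnGrid(f.times, np.maximum(p, 0.0))


def decay_integral_operator(times, rate, out_index=None):
    """Matrix C with ``(C @ g)[m] = int_0^{t_m} e^{-rate (t_m - u)} g(u) du``.

    Trapezoidal quadrature on the (possibly non-uniform) grid.  ``out_index``
    selects a subset of output rows.  Used to evaluate the transcription
    integral at many parameter proposals cheaply.
    """
    times = np.asarray(times, dtype=float)
    n = times.size
    h = np.diff(times)
    # trapezoid weight of node k in the integral up to t_m:
    #   k <  m : h_{k-1}/2 + h_k/2   (with the missing half at the ends)
    #   k == m : h_{m-1}/2           (zero for m = 0)
    left = np.concatenate(([0.0], h / 2.0))     # h_{k-1}/2
    right = np.concatenate((h / 2.0, [0.0]))    # h_k/2
    k = np.arange(n)
    w = np.where(k[None, :] < k[:, None], left + right, 0.0)
    np.fill_diagonal(w, left)
    lag = times[:, None] - times[None, :]
    C = np.exp(-rate * np.maximum(lag, 0.0)) * w
    if out_index is not None:
        C = C[np.asarray(out_index)]
    return C


def solve_transcription(
    p_all,
    rw: ResponseWeights,
    kp: KineticParams,
    out_times=None,
) -> np.ndarray:
    """Predicted target mRNA from the explicit transcription solution.

    m(t) = a e^{-d t} + (b/d)(1 - e^{-d t}) + s int_0^t e^{-d(t-u)} G(p(u)) du

    ``p_all`` is a list of ``FunctionOnGrid`` (one per TF) on a common grid.
    Values are returned at ``out_times`` (default: the grid itself) via linear
    interpolation of the grid solution.
    """
    grids = [np.asarray(p.times) for p in p_all]
    for t in grids[1:]:
        if t.shape != grids[0].shape or not np.allclose(t, grids[0]):
            raise ValueError("all TF activity functions must share one grid")
    times = grids[0]
    P = np.vstack([p.values for p in p_all])
    if P.shape[0] != rw.w.size:
        raise ValueError("number of TF activity functions must match weights")
    g = response_G(P, rw)
    t0 = times - times[0]
    decay = np.exp(-kp.d * t0)
    integral = _decay_convolve(times, g, kp.d, 0.0)
    m = kp.a * decay + (kp.b / kp.d) * (1.0 - decay) + kp.s * integral
    if out_times is None:
        return m
    out_times = np.asarray(out_times, dtype=float)
    if np.any(out_times < times[0]) or np.any(out_times > times[-1]):
        raise ValueError("out_times must lie within the grid span")
    return np.interp(out_times, times, m)
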