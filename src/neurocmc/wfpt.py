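"""Two-boundary Wiener diffusion: first-passage density, likelihood, simulator.

The drift-diffusion model (DDM) describes two-choice decisions as a Wiener
process with drift ``delta`` (evidence/s) starting at a fraction ``z`` of the
distance between an absorbing lower boundary at 0 and an upper boundary at
``theta``.  The observed response time is the first-passage time plus a
non-decision offset ``tau`` (encoding + motor latency).  Under accuracy
coding the upper boundary is the correct response.  The diffusion
coefficient is fixed at 1 (scale convention shared with the simulator, so
``delta`` and ``theta`` are expressed in units of the within-trial noise).

The density is evaluated with the classic pair of series expansions — a
small-time expansion over image charges and a large-time sine series — with
the truncation for each chosen from the analytic error bounds so that the
switch point is where the two need equally many terms.  Absolute truncation
error is kept below ``WFPT_ERR``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "DDMParams",
    "wfpt_density",
    "log_likelihood",
    "choice_probability",
    "simulate_wiener",
]

#: absolute truncation tolerance of the density series (well below MCMC noise)
WFPT_ERR = 1e-7

#: density floor used inside log-likelihoods, and the penalty slope applied
#: when rt <= tau so samplers see a finite, decreasing (not -inf) target
_LOG_FLOOR = -690.0  # log(~1e-300)
_RT_PENALTY_BASE = -20.0
_RT_PENALTY_SLOPE = 100.0


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters for one decision process.

    delta : drift rate (evidence/s); positive drives toward the upper bound.
    theta : boundary separation (> 0).
    tau   : non-decision time in seconds (>= 0).
    z     : starting point as a fraction of theta, fixed at the unbiased
            midpoint 0.5 throughout this package.
    """

    delta: float
    theta: float
    tau: float
    z: float = 0.5

    def validate(self) -> "DDMParams":
        if not (self.theta > 0):
            raise ValueError(f"boundary theta must be > 0, got {self.theta}")
        if not (self.tau >= 0):
            raise ValueError(f"non-decision time tau must be >= 0, got {self.tau}")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"start fraction z must lie in (0, 1), got {self.z}")
        return self


@njit(cache=True)
def _fpt_density_lower(t: float, v: float, a: float, w: float, err: float) -> float:
    """First-passage density at the LOWER boundary at decision time t.

    v: drift toward the upper boundary; a: boundary separation; w: start
    fraction from the lower boundary.  Series in normalized time tt = t/a^2.
    """
    if t <= 0.0:
        return 0.0
    tt = t / (a * a)

    # number of terms needed by each expansion for absolute error <= err
    if math.pi * tt * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * err) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * err * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0

    p = 0.0
    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = K // 2
        for k in range(lo, hi + 1):
            u = w + 2.0 * k
            p += u * math.exp(-u * u / (2.0 * tt))
        p /= math.sqrt(2.0 * math.pi * tt * tt * tt)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
        p *= math.pi

    f = p * math.exp(-v * a * w - v * v * t / 2.0) / (a * a)
    if f < 0.0:  # tiny negative values from truncation at extreme tails
        f = 0.0
    return f


@njit(cache=True)
def _loglik_kernel(rt, correct, delta, theta, tau, err):
    n = rt.shape[0]
    total = 0.0
    for i in range(n):
        t = rt[i] - tau[i]
        if t <= 1e-5:
            # rt at or below non-decision time: finite penalty growing with
            # the violation, so MCMC proposals remain comparable
            total += _RT_PENALTY_BASE - _RT_PENALTY_SLOPE * (1e-5 - t)
            continue
        if correct[i]:
            d = _fpt_density_lower(t, -delta[i], theta[i], 0.5, err)
        else:
            d = _fpt_density_lower(t, delta[i], theta[i], 0.5, err)
        if d < 1e-300:
            total += _LOG_FLOOR
        else:
            total += math.log(d)
    return total


def wfpt_density(t, params: DDMParams, boundary: str = "upper"):
    """Density (1/s) of first passage at the named boundary at clock time t.

    ``t`` includes the non-decision time: the density is zero for
    ``t <= tau``.  Accepts a scalar or array of times.
    """
    params.validate()
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    tarr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(tarr)
    if boundary == "upper":
        v, w = -params.delta, 1.0 - params.z
    else:
        v, w = params.delta, params.z
    for i, ti in enumerate(tarr.ravel()):
        out.ravel()[i] = _fpt_density_lower(ti - params.tau, v, params.theta, w, WFPT_ERR)
    return out[0] if np.isscalar(t) else out


def log_likelihood(rt, correct, delta, theta, tau) -> float:
    """Summed log-density of (rt, correct) pairs under per-trial parameters.

    Accuracy coding: ``correct`` trials are upper-boundary passages.  All
    parameter arguments broadcast against ``rt``.  Trials with
    ``rt <= tau`` contribute a large negative but finite penalty.
    """
    rt = np.ascontiguousarray(rt, dtype=np.float64)
    correct = np.ascontiguousarray(np.broadcast_to(correct, rt.shape), dtype=np.bool_)
    delta = np.ascontiguousarray(np.broadcast_to(delta, rt.shape), dtype=np.float64)
    theta = np.ascontiguousarray(np.broadcast_to(theta, rt.shape), dtype=np.float64)
    tau = np.ascontiguousarray(np.broadcast_to(tau, rt.shape), dtype=np.float64)
    if np.any(theta <= 0):
        raise ValueError("boundary theta must be > 0 for all trials")
    if np.any(tau < 0):
        raise ValueError("non-decision time tau must be >= 0 for all trials")
    return float(_loglik_kernel(rt, correct, delta, theta, tau, WFPT_ERR))


def choice_probability(delta: float, theta: float, z: float = 0.5) -> float:
    """Analytic probability of an upper-boundary (correct) passage.

    P(upper) = (1 - exp(-2 delta theta z)) / (1 - exp(-2 delta theta));
    for the unbiased start z = 0.5 this reduces to 1 / (1 + exp(-theta*delta)).
    """
    if abs(delta) < 1e-12:
        return z
    x = 2.0 * delta * theta
    return float(np.expm1(-x * z) / np.expm1(-x))


@njit(cache=True)
def _simulate_kernel(delta, theta, tau, z, dt, seed):
    np.random.seed(seed)
    n = delta.shape[0]
    rt = np.empty(n)
    upper = np.empty(n, np.bool_)
    sqdt = math.sqrt(dt)
    for i in range(n):
        a = theta[i]
        x = z * a
        t = 0.0
        while True:
            x_new = x + delta[i] * dt + sqdt * np.random.randn()
            t += dt
            if x_new >= a:
                upper[i] = True
                break
            if x_new <= 0.0:
                upper[i] = False
                break
            # Brownian-bridge correction: probability the path crossed a
            # boundary inside the step even though both endpoints are interior
            p_up = math.exp(-2.0 * (a - x) * (a - x_new) / dt)
            if np.random.rand() < p_up:
                upper[i] = True
                break
            p_lo = math.exp(-2.0 * x * x_new / dt)
            if np.random.rand() < p_lo:
                upper[i] = False
                break
            x = x_new
            if t > 60.0:  # pathological-parameter guard
                upper[i] = x >= z * a
                break
        rt[i] = t + tau[i]
    return rt, upper


def simulate_wiener(delta, theta, tau, n=None, z: float = 0.5, dt: float = 1e-3,
                    rng_seed: int = 0):
    """Draw (rt, correct) pairs from the diffusion process.

    Euler–Maruyama at step ``dt`` (default 1 ms) with a Brownian-bridge
    boundary-crossing check each step, which removes the leading-order
    discretization bias of the plain scheme.  Parameters may be scalars
    (with ``n`` draws) or per-trial arrays.
    """
    if n is not None:
        delta = np.full(n, float(delta))
    delta = np.ascontiguousarray(delta, dtype=np.float64)
    theta = np.ascontiguousarray(np.broadcast_to(theta, delta.shape), dtype=np.float64)
    tau = np.ascontiguousarray(np.broadcast_to(tau, delta.shape), dtype=np.float64)
    if np.any(theta <= 0) or np.any(tau < 0):
        raise ValueError("require theta > 0 and tau >= 0 for all trials")
    if not (0.0 < z < 1.0):
        raise ValueError(f"start fraction z must lie in (0, 1), got {z}")
    rt, upper = _simulate_kernel(delta, theta, tau, z, dt, int(rng_seed) % (2**31 - 1))
    return rt, upper
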