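"""Drift-diffusion model of chamber-leaving decisions.

A visit to a chamber is modelled as a Wiener diffusion with drift ``v``
between absorbing boundaries at 0 and ``a`` (within-trial diffusion
coefficient fixed at sigma = 1 evidence * s^-1/2).  The accumulator starts at
``z * a`` with relative start ``z`` in (0, 1); hitting the *upper* boundary
means "leave the chamber", so the observed visit duration is the
first-passage time (FPT) through the upper bound.  Across visits the drift is
allowed to vary: each visit draws its own drift from Normal(v, sv^2)
(classic inter-trial drift variability; ``sv`` is what the behavioural
literature on this assay calls "noise").

Boundary convention
-------------------
Some descriptions place the bounds at -a and +a; that parameterisation is an
affine relabelling of the one used here (bounds 0 and a, relative start z).
``z = 0.9`` means "start 10% of the boundary separation below the leave
bound" in both conventions.  With z = 0.9 the lower bound carries negligible
mass, which is why a one-observed-choice likelihood built from the upper
density alone is adequate.

The density is evaluated with the classic pair of series expansions
(small-time image sum / large-time eigenfunction sum), switching to
whichever needs fewer terms at the requested truncation error.  For sv > 0
the Gaussian drift mixture integrates analytically: the drift enters the
density only through exp(v*b - v^2 t / 2) (b the start-to-bound distance),
whose normal mixture is a closed-form factor.  Everything is computed in
log space so that boundary separations of hundreds of evidence units (the
regime that produces realistic multi-second visits) stay finite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss

__all__ = [
    "DDMParams",
    "FPTSamples",
    "simulate_fpt",
    "fpt_density_upper",
    "fpt_density_lower",
    "fpt_logdensity_upper",
    "prob_upper",
    "survival_upper",
    "visit_loglik",
]

SIGMA = 1.0  # within-trial diffusion coefficient, evidence * s^-1/2 (fixed)

_SERIES_ERR = 1e-8  # truncation error for the density series
_GH_NODES = 31  # Gauss-Hermite nodes for sv-mixture absorption probability


@dataclass(frozen=True)
class DDMParams:
    """Parameters of the one-choice drift-diffusion model.

    v : drift rate, evidence/s (positive drives toward the leave bound)
    sv : SD of the across-visit drift distribution, evidence/s
    a : boundary separation, evidence
    z : relative starting point in (0, 1); z=0.9 starts near the leave bound
    t0 : non-decision offset, s
    """

    v: float
    sv: float = 0.0
    a: float = 1.0
    z: float = 0.5
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"relative start z must lie in (0, 1), got {self.z}")
        if self.sv < 0:
            raise ValueError(f"drift variability sv must be >= 0, got {self.sv}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time t0 must be >= 0, got {self.t0}")


@dataclass
class FPTSamples:
    """First-passage samples: times, boundary labels and the drift draws."""

    time: np.ndarray  # passage time, s (= max_time where not absorbed)
    upper: np.ndarray  # bool, True where the upper (leave) bound was hit
    absorbed: np.ndarray  # bool, False where max_time elapsed first
    drift: np.ndarray  # per-path drift draw, evidence/s
    n_resampled: int = 0  # paths restarted because of a non-finite state

    def __len__(self) -> int:
        return self.time.size

    @property
    def boundary(self) -> np.ndarray:
        return np.where(self.upper, "upper", "lower")


def softplus(x):
    """Positivity link used for sv: log(1 + e^x), overflow-safe."""
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def softplus_inv(y):
    """Inverse of ``softplus`` for y > 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("softplus_inv requires positive input")
    return y + np.log(-np.expm1(-y))


# ---------------------------------------------------------------------------
# series machinery (drift-free part of the density)
# ---------------------------------------------------------------------------


def _logsumexp_signed(logs: np.ndarray, signs: np.ndarray, axis: int = -1):
    """log|sum(signs * exp(logs))| with the sign of the sum."""
    m = np.max(logs, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    s = np.sum(signs * np.exp(logs - m), axis=axis)
    sign = np.sign(s)
    with np.errstate(divide="ignore"):
        out = np.squeeze(m, axis=axis) + np.log(np.abs(s))
    return out, sign


def _n_terms_small(tstar: np.ndarray, err: float) -> int:
    t = np.asarray(tstar, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        bound = 2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(2.0 * err * np.sqrt(2.0 * np.pi * t)), 0.0))
    bound = np.where(2.0 * np.sqrt(2.0 * np.pi * t) * err < 1.0, np.maximum(bound, np.sqrt(t) + 1.0), 2.0)
    return int(np.ceil(np.max(bound))) if bound.size else 2


def _n_terms_large(tstar: np.ndarray, err: float) -> int:
    t = np.asarray(tstar, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        bound = np.sqrt(np.maximum(-2.0 * np.log(np.pi * t * err), 0.0) / (np.pi**2 * t))
    bound = np.where(np.pi * t * err < 1.0, np.maximum(bound, 1.0 / (np.pi * np.sqrt(t))), 1.0 / (np.pi * np.sqrt(t)))
    return int(np.ceil(np.max(bound))) if bound.size else 1


def _log_f0(tstar: np.ndarray, w: float, err: float = _SERIES_ERR, want_dt: bool = False):
    """Drift-free FPT density f0(t*, w) on the unit-boundary scale, in log space.

    f0 is the density of the first passage through the *near* bound at
    relative distance ``w`` for a driftless standard Wiener process between
    bounds 0 and 1, at normalised time t* = t / a^2.  Returns log f0 and,
    optionally, d(log f0)/dt* (needed when the boundary separation is a free
    parameter).
    """
    tstar = np.asarray(tstar, dtype=float)
    out = np.full(tstar.shape, -np.inf)
    dout = np.zeros(tstar.shape) if want_dt else None
    valid = tstar > 0
    if not np.any(valid):
        return (out, dout) if want_dt else out
    t = tstar[valid]

    use_small = _use_small_mask(t, err)

    res = np.empty(t.shape)
    dres = np.empty(t.shape) if want_dt else None
    for mask, small in ((use_small, True), (~use_small, False)):
        if not np.any(mask):
            continue
        tm = t[mask]
        if small:
            K = int(np.ceil(_n_terms_small(tm, err) / 2.0)) + 1
            k = np.arange(-K, K + 1, dtype=float)
            c = w + 2.0 * k  # signed image weights
            logs = np.log(np.abs(c)) - c**2 / (2.0 * tm[:, None])
            lsum, sign = _logsumexp_signed(logs, np.sign(c)[None, :])
            logf = -0.5 * math.log(2.0 * math.pi) - 1.5 * np.log(tm) + lsum
            logf = np.where(sign > 0, logf, -np.inf)
            if want_dt:
                # d/dt* of the log of the image sum
                num_logs = logs + np.log(c**2 / 2.0)[None, :] - 2.0 * np.log(tm[:, None])
                lnum, nsign = _logsumexp_signed(num_logs, np.sign(c)[None, :])
                dres[mask] = -1.5 / tm + nsign * sign * np.exp(lnum - lsum)
        else:
            K = max(_n_terms_large(tm, err), 1)
            k = np.arange(1, K + 1, dtype=float)
            sk = np.sin(k * np.pi * w)
            with np.errstate(divide="ignore"):
                logs = np.log(k)[None, :] + np.log(np.abs(sk))[None, :] - k[None, :] ** 2 * np.pi**2 * tm[:, None] / 2.0
            lsum, sign = _logsumexp_signed(logs, np.sign(sk)[None, :])
            logf = math.log(math.pi) + lsum
            logf = np.where(sign > 0, logf, -np.inf)
            if want_dt:
                num_logs = logs + np.log(k**2 * np.pi**2 / 2.0)[None, :]
                lnum, nsign = _logsumexp_signed(num_logs, np.sign(sk)[None, :])
                dres[mask] = -nsign * sign * np.exp(lnum - lsum)
        res[mask] = logf

    out[valid] = res
    if want_dt:
        dout[valid] = dres
        return out, dout
    return out


def _use_small_mask(t: np.ndarray, err: float) -> np.ndarray:
    # per-element branch choice: prefer the series that needs fewer terms
    with np.errstate(divide="ignore", invalid="ignore"):
        ks_el = 2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(2.0 * err * np.sqrt(2.0 * np.pi * t)), 0.0))
        kl_el = np.sqrt(np.maximum(-2.0 * np.log(np.pi * t * err), 0.0) / (np.pi**2 * t))
    ks_el = np.where(2.0 * np.sqrt(2.0 * np.pi * t) * err < 1.0, np.maximum(ks_el, np.sqrt(t) + 1.0), 2.0)
    kl_el = np.where(np.pi * t * err < 1.0, np.maximum(kl_el, 1.0 / (np.pi * np.sqrt(t))), 1.0 / (np.pi * np.sqrt(t)))
    return ks_el <= kl_el


# ---------------------------------------------------------------------------
# drift factor (analytic Gaussian drift mixture) and its gradients
# ---------------------------------------------------------------------------


def _log_mix(t, v, sv, b, want_grads: bool = False):
    """log of the drift factor E_u[exp(u*b - u^2 t / 2)], u ~ N(v, sv^2).

    For sv = 0 this is v*b - v^2 t / 2.  Optionally returns the partial
    derivatives with respect to v, sv and b.
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(sv, dtype=float) ** 2
    den = 1.0 + s * t
    logm = -0.5 * np.log(den) + (s * b**2 + 2.0 * np.asarray(v) * b - np.asarray(v) ** 2 * t) / (2.0 * den)
    if not want_grads:
        return logm
    bvt = b - np.asarray(v) * t
    d_v = bvt / den
    d_s = -t / (2.0 * den) + bvt**2 / (2.0 * den**2)
    d_sv = 2.0 * np.asarray(sv) * d_s
    d_b = (s * b + np.asarray(v)) / den
    return logm, d_v, d_sv, d_b


def _upper_logdensity(t, v, sv, a, z, want_grads: bool = False, err: float = _SERIES_ERR, log_f0_cached=None):
    """log f_upper(t) for broadcastable arrays of t, v, sv (scalar a, z).

    ``log_f0_cached`` lets callers that evaluate the same observation times
    repeatedly (MCMC) skip recomputing the drift-free series.
    """
    t = np.asarray(t, dtype=float)
    w = 1.0 - z
    b = a * w
    if log_f0_cached is None:
        lf0 = _log_f0(t / a**2, w, err)
    else:
        lf0 = log_f0_cached
    if not want_grads:
        return _log_mix(t, v, sv, b) + lf0 - 2.0 * math.log(a)
    logm, d_v, d_sv, d_b = _log_mix(t, v, sv, b, want_grads=True)
    return logm + lf0 - 2.0 * math.log(a), d_v, d_sv


def _upper_logdensity_grad_a(t, v, sv, a, z, err: float = _SERIES_ERR):
    """(log f_upper, d/dv, d/dsv, d/da) with the boundary separation free."""
    t = np.asarray(t, dtype=float)
    w = 1.0 - z
    b = a * w
    lf0, dlf0_dt = _log_f0(t / a**2, w, err, want_dt=True)
    logm, d_v, d_sv, d_b = _log_mix(t, v, sv, b, want_grads=True)
    logf = logm + lf0 - 2.0 * math.log(a)
    d_a = d_b * w + dlf0_dt * (-2.0 * t / a**3) - 2.0 / a
    return logf, d_v, d_sv, d_a


# ---------------------------------------------------------------------------
# absorption probability
# ---------------------------------------------------------------------------


def _p_upper_fixed_drift(u, a, z):
    """P(hit upper bound eventually) for drift u; stable for |2ua| large."""
    u = np.asarray(u, dtype=float)
    x = 2.0 * u * a
    out = np.empty(np.broadcast(u, np.asarray(a)).shape or (1,))
    x = np.broadcast_to(x, out.shape).astype(float)
    small = np.abs(x) < 1e-6
    big_pos = x > 50.0
    big_neg = x < -50.0
    mid = ~(small | big_pos | big_neg)
    out[small] = z + x[small] * z * (1.0 - z) / 2.0
    out[big_pos] = 1.0 - np.exp(-x[big_pos] * z)
    out[big_neg] = np.exp(x[big_neg] * (1.0 - z))
    xm = x[mid]
    out[mid] = np.expm1(-xm * z) / np.expm1(-xm)
    if np.ndim(u) == 0 and np.ndim(a) == 0:
        return float(out[0]) if out.size == 1 else out
    return out


_gh_x, _gh_w = hermgauss(_GH_NODES)
_gh_w = _gh_w / math.sqrt(math.pi)


def prob_upper(params: DDMParams) -> float:
    """Probability that the accumulator is eventually absorbed at the leave bound."""
    if params.sv == 0:
        return float(_p_upper_fixed_drift(params.v, params.a, params.z))
    u = params.v + params.sv * math.sqrt(2.0) * _gh_x
    return float(np.sum(_gh_w * _p_upper_fixed_drift(u, params.a, params.z)))


# ---------------------------------------------------------------------------
# public density / survival / likelihood
# ---------------------------------------------------------------------------


def fpt_logdensity_upper(t, params: DDMParams):
    """log density (s^-1) of first passage through the leave bound at time t."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= params.t0):
        raise ValueError("density requested at t <= t0")
    out = _upper_logdensity(t - params.t0, params.v, params.sv, params.a, params.z)
    return out


def fpt_density_upper(t, params: DDMParams):
    """Density of the upper-boundary (chamber-leaving) passage time."""
    return np.exp(fpt_logdensity_upper(t, params))


def fpt_density_lower(t, params: DDMParams):
    """Density of the lower-boundary passage time (the modelled defect mass)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= params.t0):
        raise ValueError("density requested at t <= t0")
    # lower passage with drift v from start z == upper passage with drift -v from start 1-z
    return np.exp(_upper_logdensity(t - params.t0, -params.v, params.sv, params.a, 1.0 - params.z))


_SURV_NODES = 257  # composite-Simpson nodes (log-spaced) for the passage CDF
_SURV_LOGSPAN = 14.0


def _cdf_upper_grid(t_c: float, params: DDMParams):
    """Nodes and Simpson weights (including the dt = e^y dy factor) on (0, t_c)."""
    y = np.linspace(math.log(t_c) - _SURV_LOGSPAN, math.log(t_c), _SURV_NODES)
    h = y[1] - y[0]
    w = np.ones(_SURV_NODES)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= h / 3.0
    t = np.exp(y)
    return t, w * t  # quadrature in y with Jacobian e^y


def survival_upper(t, params: DDMParams):
    """P(no upper-boundary passage by time t): the censoring mass.

    The probability that the chamber has not been left by t, i.e.
    1 - F_upper(t).  This includes drift draws that never reach the leave
    bound (the animal "settles"), so S(t) -> 1 - P_upper as t -> inf.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t <= params.t0):
        raise ValueError("survival requested at t <= t0")
    out = np.empty(t.shape)
    for i, ti in enumerate(t.ravel()):
        nodes, wts = _cdf_upper_grid(ti - params.t0, params)
        f = np.exp(_upper_logdensity(nodes, params.v, params.sv, params.a, params.z))
        out.ravel()[i] = 1.0 - float(f @ wts)
    out = np.clip(out, 1e-300, None)
    return out if out.size > 1 else float(out[0])


def visit_loglik(visits, params: DDMParams) -> float:
    """Log-likelihood of a sequence of chamber visits under the DDM.

    Uncensored visits contribute the log upper-boundary passage density at
    their duration; visits truncated by the session end contribute the log of
    the upper-boundary survival mass beyond the censoring time.  An empty
    visit set has log-likelihood 0.
    """
    df = visits.to_frame() if hasattr(visits, "to_frame") and not hasattr(visits, "columns") else visits
    if hasattr(df, "columns"):
        dur = np.asarray(df["duration"], dtype=float)
        cens = np.asarray(df["censored"], dtype=bool)
    else:  # pragma: no cover - plain array fallback
        dur = np.asarray(df, dtype=float)
        cens = np.zeros(dur.shape, dtype=bool)
    if dur.size == 0:
        return 0.0
    bad = np.nonzero(dur <= params.t0)[0]
    if bad.size:
        raise ValueError(f"visit durations must exceed t0={params.t0}; offending visit indices: {bad.tolist()}")
    ll = 0.0
    if np.any(~cens):
        ll += float(np.sum(fpt_logdensity_upper(dur[~cens], params)))
    if np.any(cens):
        ll += float(np.sum(np.log(np.atleast_1d(survival_upper(dur[cens], params)))))
    return ll


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_fpt(
    params: DDMParams,
    n: int,
    dt: float = 1e-3,
    seed: int | None = None,
    max_time: float = 1e4,
    rng: np.random.Generator | None = None,
) -> FPTSamples:
    """Euler-Maruyama first-passage sampling with a Brownian-bridge crossing test.

    Each path draws its drift from Normal(v, sv^2) and evolves x <- x + u dt
    + sqrt(dt) N(0,1) from x0 = z*a between absorbing bounds 0 and a.  The
    per-step bridge test assigns the crossing probability
    exp(-2 d_prev d_next / dt) to excursions between grid points, removing the
    O(sqrt(dt)) first-passage bias of the plain scheme.  Paths that survive
    ``max_time`` are returned with ``absorbed=False`` and time = max_time.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    drift = params.v + params.sv * rng.standard_normal(n)
    time = np.full(n, float(max_time) + params.t0)
    upper = np.zeros(n, dtype=bool)
    absorbed = np.zeros(n, dtype=bool)
    n_resampled = 0

    alive = np.arange(n)
    x = np.full(n, params.z * params.a)
    a = params.a
    sdt = math.sqrt(dt)
    max_steps = int(math.ceil(max_time / dt))
    step = 0
    # a bridge excursion beyond a bound at distance > _far is less likely than 1e-12
    far = math.sqrt(0.5 * 55.0 * dt)
    cap = 1024  # grow chunks geometrically so short passages stay cheap
    while alive.size and step < max_steps:
        m = min(max(64, int(8_000_000 / max(alive.size, 1))), cap, max_steps - step)
        cap *= 4
        inc = drift[alive][:, None] * dt + sdt * rng.standard_normal((alive.size, m))
        path = np.cumsum(inc, axis=1)
        path += x[alive][:, None]
        prev = path - inc
        up_evt = path >= a
        lo_evt = path <= 0.0
        # bridge excursions only matter for rows that come near a bound;
        # double (up and low) excursions within one step are O(p_up * p_lo)
        rows_u = np.nonzero(path.max(axis=1) > a - far)[0]
        if rows_u.size:
            p_up = np.exp(np.maximum((a - prev[rows_u]) * (a - path[rows_u]), 0.0) * (-2.0 / dt))
            up_evt[rows_u] |= (rng.random(p_up.shape) < p_up) & ~lo_evt[rows_u]
        rows_l = np.nonzero(path.min(axis=1) < far)[0]
        if rows_l.size:
            p_lo = np.exp(np.maximum(prev[rows_l] * path[rows_l], 0.0) * (-2.0 / dt))
            lo_evt[rows_l] |= (rng.random(p_lo.shape) < p_lo) & ~up_evt[rows_l]
        event = up_evt | lo_evt
        any_event = event.any(axis=1)
        first = np.argmax(event, axis=1)
        rows = np.nonzero(any_event)[0]
        if rows.size:
            idx = alive[rows]
            j = first[rows]
            # the passage happened somewhere inside the step; attribute it
            # uniformly so returned times are not lattice-valued
            time[idx] = (step + j + rng.random(rows.size)) * dt + params.t0
            upper[idx] = up_evt[rows, j]
            absorbed[idx] = True
        # survivors advance to the end of the chunk
        surv = np.nonzero(~any_event)[0]
        xs = path[surv, -1]
        bad = ~np.isfinite(xs)
        if np.any(bad):  # pragma: no cover - defensive
            n_resampled += int(bad.sum())
            warnings.warn(f"restarted {int(bad.sum())} non-finite diffusion paths")
            xs[bad] = params.z * a
        x[alive[surv]] = xs
        alive = alive[surv]
        step += m
    return FPTSamples(time=time, upper=upper, absorbed=absorbed, drift=drift, n_resampled=n_resampled)
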