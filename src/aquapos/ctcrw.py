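"""Continuous-time correlated random walk (CTCRW) track model.

The model treats each horizontal axis independently as an integrated
Ornstein-Uhlenbeck process: velocity v decays toward zero with rate beta
(1/s) while being driven by Brownian noise of scale sigma, and position x
is the integral of v.  Over a gap of length D the exact discretization is

    v' = v e^(-bD) + eta_v
    x' = x + v (1 - e^(-bD)) / b + eta_x

with jointly Gaussian (eta_x, eta_v):

    Var eta_v  = s^2 (1 - e^(-2bD)) / (2b)
    Var eta_x  = s^2/b^2 (D - 2(1 - e^(-bD))/b + (1 - e^(-2bD))/(2b))
    Cov        = s^2 (1 - e^(-bD))^2 / (2b^2)

(b = beta, s = sigma).  Observed fixes are the position plus isotropic
Gaussian measurement error.  Because the model is linear-Gaussian, exact
filtering, fixed-interval (RTS) smoothing, likelihood evaluation and
interpolation to arbitrary times are available through the Kalman
recursions, and (beta, sigma) are estimated by maximizing the filter
likelihood with the measurement error held fixed — in field use the
error is pinned at the array's measured positioning accuracy (10 m)
rather than estimated from the track itself.

Irregular sampling (e.g. coded tags with uniform 30-90 s random delays)
is handled natively; prediction at a regular grid (every 60 s for coded
tags, every 3 s for a pinger) is smoothing with the grid times inserted
as unobserved states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

#: Diffuse prior variance (m^2) on the initial position, anchored at the
#: first observation.
POSITION_PRIOR_VAR = 1.0e6


class CtcrwDomainError(ValueError):
    pass


@dataclass(frozen=True)
class CTCRWParams:
    """beta: velocity decorrelation rate (1/s); sigma: velocity diffusion
    scale (m s^-3/2); measurement_error_sd: positioning error (m)."""

    beta: float
    sigma: float
    measurement_error_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.sigma <= 0:
            raise CtcrwDomainError("beta and sigma must be positive")
        if self.measurement_error_sd < 0:
            raise CtcrwDomainError("measurement error sd must be nonnegative")

    @property
    def stationary_velocity_var(self) -> float:
        return self.sigma**2 / (2.0 * self.beta)


def transition(params: CTCRWParams, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """State-transition matrix F and process covariance Q for one gap.

    State is (x, v) per axis.
    """
    if dt < 0:
        raise CtcrwDomainError("time gaps must be nonnegative")
    b, s2 = params.beta, params.sigma**2
    phi = math.exp(-b * dt)
    F = np.array([[1.0, (1.0 - phi) / b], [0.0, phi]])
    qv = s2 * (1.0 - phi**2) / (2.0 * b)
    qx = s2 / b**2 * (dt - 2.0 * (1.0 - phi) / b + (1.0 - phi**2) / (2.0 * b))
    qxv = s2 * (1.0 - phi) ** 2 / (2.0 * b**2)
    Q = np.array([[qx, qxv], [qxv, qv]])
    return F, Q


def ctcrw_simulate(
    params: CTCRWParams,
    times,
    start: tuple[float, float] = (0.0, 0.0),
    v0: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
    return_states: bool = False,
):
    """Draw one 2D track at the given (strictly increasing) times.

    Returns positions (n, 2); with ``return_states`` also the velocities
    (n, 2).  The state at times[0] is exactly (start, v0).
    """
    times = np.asarray(times, dtype=float)
    if len(times) and np.any(np.diff(times) <= 0):
        raise CtcrwDomainError("times must be strictly increasing")
    rng = rng or np.random.default_rng()
    n = len(times)
    pos = np.zeros((n, 2))
    vel = np.zeros((n, 2))
    pos[0] = start
    vel[0] = v0
    for i in range(1, n):
        F, Q = transition(params, times[i] - times[i - 1])
        L = np.linalg.cholesky(Q + 1e-30 * np.eye(2))
        for a in range(2):
            state = F @ np.array([pos[i - 1, a], vel[i - 1, a]]) + L @ rng.normal(
                size=2
            )
            pos[i, a], vel[i, a] = state
    if return_states:
        return pos, vel
    return pos


@dataclass
class CTCRWStates:
    """Filtered or smoothed state estimates on a common time base.

    mean columns are (x, vx, y, vy); cov[i, a] is the 2x2 position/
    velocity covariance of axis a at times[i].
    """

    times: np.ndarray
    mean: np.ndarray          # (n, 4)
    cov: np.ndarray           # (n, 2, 2, 2)
    log_likelihood: float
    observed: np.ndarray      # bool mask: which times carried a fix

    def position_var(self) -> np.ndarray:
        """Per-time (var_x, var_y)."""
        return self.cov[:, :, 0, 0]


def _axis_filter(times, y, obs_mask, params, prior_mean, prior_var):
    """Kalman forward pass for one axis; scalar inner loop for speed.

    Returns filtered means (n,2), covs (n,2,2), one-step predicted means/
    covs (needed by the smoother) and the log-likelihood.
    """
    n = len(times)
    b, s2 = params.beta, params.sigma**2
    r = params.measurement_error_sd**2
    dts = np.diff(times)
    phi = np.exp(-b * dts)
    f12 = (1.0 - phi) / b
    qv = s2 * (1.0 - phi**2) / (2.0 * b)
    qx = s2 / b**2 * (dts - 2.0 * (1.0 - phi) / b + (1.0 - phi**2) / (2.0 * b))
    qxv = s2 * (1.0 - phi) ** 2 / (2.0 * b**2)

    fm = np.empty((n, 2))
    fP = np.empty((n, 2, 2))
    pm = np.empty((n, 2))
    pP = np.empty((n, 2, 2))
    ll = 0.0
    mx, mv = prior_mean
    pxx, pxv, pvv = prior_var[0, 0], prior_var[0, 1], prior_var[1, 1]
    for i in range(n):
        if i > 0:
            a12 = f12[i - 1]
            ph = phi[i - 1]
            # F P F' + Q with F = [[1, a12], [0, ph]]
            nxx = pxx + a12 * (pxv + pxv) + a12 * a12 * pvv + qx[i - 1]
            nxv = ph * (pxv + a12 * pvv) + qxv[i - 1]
            nvv = ph * ph * pvv + qv[i - 1]
            mx = mx + a12 * mv
            mv = ph * mv
            pxx, pxv, pvv = nxx, nxv, nvv
        pm[i] = (mx, mv)
        pP[i] = ((pxx, pxv), (pxv, pvv))
        if obs_mask[i]:
            S = pxx + r
            innov = y[i] - mx
            ll += -0.5 * (math.log(2.0 * math.pi * S) + innov * innov / S)
            kx = pxx / S
            kv = pxv / S
            mx = mx + kx * innov
            mv = mv + kv * innov
            nxx = pxx - kx * pxx
            nxv = pxv - kx * pxv
            nvv = pvv - kv * pxv
            pxx, pxv, pvv = nxx, nxv, nvv
        fm[i] = (mx, mv)
        fP[i] = ((pxx, pxv), (pxv, pvv))
    return fm, fP, pm, pP, ll


def _axis_smooth(times, params, fm, fP, pm, pP):
    """RTS backward pass for one axis."""
    n = len(times)
    sm = fm.copy()
    sP = fP.copy()
    b = params.beta
    for i in range(n - 2, -1, -1):
        dt = times[i + 1] - times[i]
        ph = math.exp(-b * dt)
        a12 = (1.0 - ph) / b
        F = np.array([[1.0, a12], [0.0, ph]])
        Pp = pP[i + 1]
        try:
            G = fP[i] @ F.T @ np.linalg.inv(Pp)
        except np.linalg.LinAlgError:
            G = fP[i] @ F.T @ np.linalg.pinv(Pp)
        sm[i] = fm[i] + G @ (sm[i + 1] - pm[i + 1])
        sP[i] = fP[i] + G @ (sP[i + 1] - Pp) @ G.T
    return sm, sP


def _prepare(times, positions):
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise CtcrwDomainError("positions must be (n, 2)")
    if len(times) != len(positions):
        raise CtcrwDomainError("times and positions must align")
    if len(times) < 2:
        raise CtcrwDomainError("at least two fixes are required")
    if np.any(np.diff(times) <= 0):
        raise CtcrwDomainError("times must be strictly increasing")
    return times, positions


def _run(times, positions, params, obs_mask, smooth):
    n = len(times)
    vel_var = 10.0 * params.stationary_velocity_var
    first = int(np.flatnonzero(obs_mask)[0])
    mean = np.empty((n, 4))
    cov = np.empty((n, 2, 2, 2))
    ll = 0.0
    for a in range(2):
        prior_mean = (positions[first, a], 0.0)
        prior_var = np.diag([POSITION_PRIOR_VAR, vel_var])
        fm, fP, pm, pP, ll_a = _axis_filter(
            times, positions[:, a], obs_mask, params, prior_mean, prior_var
        )
        ll += ll_a
        if smooth:
            fm, fP = _axis_smooth(times, params, fm, fP, pm, pP)
        mean[:, 2 * a] = fm[:, 0]
        mean[:, 2 * a + 1] = fm[:, 1]
        cov[:, a] = fP
    return CTCRWStates(times, mean, cov, ll, obs_mask.copy())


def ctcrw_filter(times, positions, params: CTCRWParams) -> CTCRWStates:
    """Exact Kalman filtering of 2D fixes; returns states and the
    one-step predictive log-likelihood."""
    times, positions = _prepare(times, positions)
    mask = np.ones(len(times), dtype=bool)
    return _run(times, positions, params, mask, smooth=False)


def ctcrw_smooth(times, positions, params: CTCRWParams) -> CTCRWStates:
    """Fixed-interval (RTS) smoothing: marginal state estimates given the
    whole track.  Smoothed position variance never exceeds filtered."""
    times, positions = _prepare(times, positions)
    mask = np.ones(len(times), dtype=bool)
    return _run(times, positions, params, mask, smooth=True)


@dataclass(frozen=True)
class PredictionGrid:
    """Regular prediction times: every ``interval`` s from start to end."""

    interval: float
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise CtcrwDomainError("grid interval must be positive")
        if self.end < self.start:
            raise CtcrwDomainError("grid end precedes start")

    def times(self) -> np.ndarray:
        n = int(math.floor((self.end - self.start) / self.interval + 1e-9)) + 1
        return self.start + self.interval * np.arange(n)


def ctcrw_predict(
    times, positions, params: CTCRWParams, grid: PredictionGrid
) -> pd.DataFrame:
    """Smoothed positions at regular grid times.

    Grid times are merged with the observation times as unobserved
    states and the whole sequence is smoothed; returns a frame with
    columns time, x, y, se_x, se_y (posterior position SDs).
    """
    times, positions = _prepare(times, positions)
    gt = grid.times()
    if gt[-1] < times[0] or gt[0] > times[-1]:
        raise CtcrwDomainError("prediction grid lies entirely outside the track span")
    merged = np.union1d(times, gt)
    obs_mask = np.isin(merged, times)
    pos_full = np.zeros((len(merged), 2))
    pos_full[obs_mask] = positions[np.searchsorted(times, merged[obs_mask])]
    states = _run(merged, pos_full, params, obs_mask, smooth=True)
    sel = np.isin(merged, gt)
    var = states.position_var()[sel]
    return pd.DataFrame(
        {
            "time": merged[sel],
            "x": states.mean[sel, 0],
            "y": states.mean[sel, 2],
            "se_x": np.sqrt(np.maximum(var[:, 0], 0.0)),
            "se_y": np.sqrt(np.maximum(var[:, 1], 0.0)),
        }
    )


@dataclass(frozen=True)
class CTCRWFit:
    params: CTCRWParams
    log_likelihood: float
    converged: bool
    n_fixes: int


def _moment_start(times, positions, measurement_error_sd):
    """Method-of-moments starting values on the log scale."""
    dts = np.diff(times)
    dt_med = float(np.median(dts))
    v_emp = np.diff(positions, axis=0) / dts[:, None]
    var_obs = float(np.var(v_emp))
    var_meas = 2.0 * measurement_error_sd**2 / dt_med**2
    var_v = max(var_obs - var_meas, 0.1 * var_obs, 1e-8)
    rho = 0.5
    if len(v_emp) > 3:
        cs = [np.corrcoef(v_emp[1:, a], v_emp[:-1, a])[0, 1] for a in range(2)]
        cs = [c for c in cs if np.isfinite(c)]
        if cs:
            rho = float(np.mean(cs))
    beta0 = -math.log(min(max(rho, 0.05), 0.95)) / dt_med
    sigma0 = math.sqrt(2.0 * beta0 * var_v)
    return math.log(beta0), math.log(sigma0)


def ctcrw_fit(
    times,
    positions,
    measurement_error_sd: float = 10.0,
    n_starts: int = 3,
    seed: int | None = None,
) -> CTCRWFit:
    """Maximum-likelihood (beta, sigma) with the measurement error fixed.

    Optimizes the filter log-likelihood over (log beta, log sigma) by
    Nelder-Mead from a method-of-moments start plus random restarts.
    """
    times, positions = _prepare(times, positions)
    if len(times) < 20:
        raise CtcrwDomainError("fitting needs at least 20 fixes")
    mask = np.ones(len(times), dtype=bool)

    def nll(theta):
        lb, ls = theta
        if not (-30 < lb < 30 and -30 < ls < 30):
            return 1e12
        p = CTCRWParams(math.exp(lb), math.exp(ls), measurement_error_sd)
        try:
            return -_run(times, positions, p, mask, smooth=False).log_likelihood
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e12

    rng = np.random.default_rng(seed)
    x0 = np.array(_moment_start(times, positions, measurement_error_sd))
    starts = [x0] + [x0 + rng.normal(scale=1.0, size=2) for _ in range(n_starts - 1)]
    best = None
    for s in starts:
        res = minimize(nll, s, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    params = CTCRWParams(
        math.exp(best.x[0]), math.exp(best.x[1]), measurement_error_sd
    )
    return CTCRWFit(
        params=params,
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
        n_fixes=len(times),
    )
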