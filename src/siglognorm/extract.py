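"""Greedy decomposition of a speed profile into lognormal components.

The extractor repeatedly fits a single lognormal at the largest residual
speed peak, subtracts its planar velocity, and keeps adding components
until the reconstruction reaches the SNR stopping target (default 25 dB)
or a per-test component cap.  Periodic joint refinement polishes recently
added components against the observed velocity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import butter, filtfilt
from scipy.special import erf

from .model import LognormalComponent, superpose, wrap_angle
from .synth import Trajectory

__all__ = [
    "ExtractionConfig",
    "ReconstructionResult",
    "estimate_speed",
    "trajectory_speed",
    "compute_snr",
    "fit_single_lognormal",
    "decompose",
    "SNR_CAP_DB",
    "DEFAULT_NBLOG_CAPS",
]

SNR_CAP_DB = 120.0
_HALF_WIDTH = math.sqrt(2.0 * math.log(2.0))
DEFAULT_NBLOG_CAPS = {"simple": 6, "triangle": 15, "h_osc": 250, "v_osc": 250}


@dataclass
class ExtractionConfig:
    snr_target_db: float = 25.0
    max_components: int = 250
    min_gain_db: float = 0.05
    refine_every: int = 3
    joint_refine_max: int = 8      # at most this many trailing components refined jointly
    smoothing_cutoff_hz: float | None = None
    max_nfev: int = 120
    refine_max_nfev: int = 400
    refine_tol: float = 1e-10
    backfit_snr_db: float = 100.0   # stop polishing once this quality is reached


@dataclass
class ReconstructionResult:
    """Fitted component list plus global reconstruction quality."""

    components: list[LognormalComponent]
    snr_db: float
    residual_fraction: float
    low_quality: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def nblog(self) -> int:
        return len(self.components)

    @property
    def snr_per_nblog(self) -> float:
        return self.snr_db / self.nblog if self.nblog else float("nan")


def estimate_speed(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    cutoff_hz: float | None = 15.0,
    uniform_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Central-difference planar velocity, optionally low-pass filtered.

    Returns ``(vx, vy, speed)``.  Endpoints use one-sided differences.
    Raises ``ValueError`` when the time stamps deviate from a uniform grid
    by more than ``uniform_tol`` (relative to the median step) or when
    fewer than 5 samples are provided.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 samples to estimate velocity")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or np.any(np.abs(steps - dt) > uniform_tol * max(dt, 1.0)):
        raise ValueError("timestamps are not uniformly spaced")
    vx = np.gradient(x, dt)
    vy = np.gradient(y, dt)
    if cutoff_hz is not None:
        nyquist = 0.5 / dt
        if cutoff_hz < nyquist:
            b, a = butter(4, cutoff_hz / nyquist)
            vx = filtfilt(b, a, vx)
            vy = filtfilt(b, a, vy)
    return vx, vy, np.hypot(vx, vy)


def trajectory_speed(
    trajectory: Trajectory, cutoff_hz: float | None = 15.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """:func:`estimate_speed` applied to a :class:`Trajectory`."""
    return estimate_speed(trajectory.t, trajectory.x, trajectory.y, cutoff_hz)


def compute_snr(
    vx: np.ndarray, vy: np.ndarray, rx: np.ndarray, ry: np.ndarray
) -> float:
    """Reconstruction SNR in dB: signal energy over residual energy.

    Capped at 120 dB for a zero residual; a zero-energy original raises.
    """
    vx, vy, rx, ry = (np.asarray(a, dtype=float) for a in (vx, vy, rx, ry))
    if vx.shape != rx.shape:
        raise ValueError("original and reconstruction must share one grid")
    signal = float(np.sum(vx**2 + vy**2))
    if signal <= 0:
        raise ValueError("original velocity has zero energy")
    resid = float(np.sum((vx - rx) ** 2 + (vy - ry) ** 2))
    if resid == 0:
        return SNR_CAP_DB
    return min(SNR_CAP_DB, 10.0 * math.log10(signal / resid))


def observation_kernel(v: np.ndarray) -> np.ndarray:
    """Finite-difference observation operator applied to a model velocity.

    Central differencing of sampled positions returns the underlying
    velocity convolved with a short smoothing kernel ([1,2,1]/4 in the
    interior, a two-point average at the ends).  Applying the same operator
    to model velocities before comparing them with measured ones removes
    the systematic differentiation bias from the fit.
    """
    if v.size < 3:
        return v.copy()
    out = np.empty_like(v)
    out[1:-1] = 0.25 * (v[:-2] + 2.0 * v[1:-1] + v[2:])
    out[0] = 0.5 * (v[0] + v[1])
    out[-1] = 0.5 * (v[-2] + v[-1])
    return out


# ---------------------------------------------------------------------------
# Single-component fitting
# ---------------------------------------------------------------------------

def _expand_window(speed: np.ndarray, peak: int,
                   prominence: float = 0.05) -> tuple[int, int]:
    """Grow a window around ``peak`` until the residual dies or a valley.

    Expansion in each direction stops when the profile has fallen below 2%
    of the peak, or when it starts climbing again by more than
    ``prominence`` * peak above the running minimum (another component's
    territory); the cut is placed at the valley itself.
    """
    vp = speed[peak]

    def walk(step: int, limit: int) -> int:
        pos = peak
        vmin, argmin = vp, peak
        while pos != limit:
            nxt = speed[pos + step]
            if nxt < 0.02 * vp:
                pos += step
                break
            if nxt < vmin:
                vmin, argmin = nxt, pos + step
            elif nxt - vmin > prominence * vp:
                return argmin
            pos += step
        return pos

    lo = walk(-1, 0)
    hi = walk(+1, speed.size - 1)
    return lo, hi + 1


def _half_crossings(t: np.ndarray, v: np.ndarray, peak: int,
                    lo: int, hi: int) -> tuple[float | None, float | None]:
    vp = v[peak]
    t1 = t2 = None
    for j in range(peak, lo, -1):
        if v[j - 1] <= 0.5 * vp < v[j]:
            frac = (0.5 * vp - v[j - 1]) / (v[j] - v[j - 1])
            t1 = t[j - 1] + frac * (t[j] - t[j - 1])
            break
    for j in range(peak, hi - 1):
        if v[j + 1] <= 0.5 * vp < v[j]:
            frac = (v[j] - 0.5 * vp) / (v[j] - v[j + 1])
            t2 = t[j] + frac * (t[j + 1] - t[j])
            break
    return t1, t2


def _initial_guess(tp: float, vp: float, t1: float, t2: float,
                   t_lo: float) -> tuple[float, float, float, float]:
    """Closed-form (t0, mu, sigma, D) from peak time/height and half-width.

    Uses the identities: the speed is Gaussian in u = ln(t - t0) with SD
    sigma around mu - sigma^2, so ln(tp-t0) = mu - sigma^2 and the half
    height points sit at mu - sigma^2 -/+ sigma*sqrt(2 ln 2).
    """
    denom = 2.0 * tp - t1 - t2
    if abs(denom) > 1e-12:
        t0 = (tp * tp - t1 * t2) / denom
    else:
        t0 = t1 - 10.0 * (t2 - t1)
    if not (t0 < t1):
        t0 = t1 - 10.0 * (t2 - t1)
    t0 = max(t0, t_lo - 50.0 * (t2 - t1))
    sigma = math.log((t2 - t0) / (t1 - t0)) / (2.0 * _HALF_WIDTH)
    sigma = min(max(sigma, 5e-3), 1.0)
    mu = math.log(tp - t0) + sigma * sigma
    D = vp * sigma * math.sqrt(2.0 * math.pi) * math.exp(mu - sigma * sigma / 2.0)
    return t0, mu, sigma, D


def _angles_from_bearing(t: np.ndarray, rvx: np.ndarray, rvy: np.ndarray,
                         t0: float, mu: float, sigma: float) -> tuple[float, float]:
    """theta_s/theta_e from the residual bearing at the central-95% bounds."""
    z = 1.959963984540054
    ta = t0 + math.exp(mu - z * sigma)
    tb = t0 + math.exp(mu + z * sigma)
    ia = int(np.clip(np.searchsorted(t, ta), 0, t.size - 1))
    ib = int(np.clip(np.searchsorted(t, tb), 0, t.size - 1))
    phi1 = math.atan2(rvy[ia], rvx[ia])
    phi2 = math.atan2(rvy[ib], rvx[ib])
    # unwrap phi2 to the branch nearest phi1 before de-mixing the arc ends
    phi2 = phi1 + math.remainder(phi2 - phi1, 2.0 * math.pi)
    delta = (phi2 - phi1) / 0.95
    theta_s = phi1 - 0.025 * delta
    return theta_s, theta_s + delta


def _component_velocity(params: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    comp = LognormalComponent(t0=params[0], D=params[1], mu=params[2],
                              sigma=params[3], theta_s=params[4], theta_e=params[5])
    vx, vy, _ = superpose([comp], t)
    return vx, vy


_SQRT2PI = math.sqrt(2.0 * math.pi)


def _kernel_columns(arr: np.ndarray) -> np.ndarray:
    """Observation kernel applied to every column of a 2-D array."""
    if arr.shape[0] < 3:
        return arr
    out = np.empty_like(arr)
    out[1:-1] = 0.25 * (arr[:-2] + 2.0 * arr[1:-1] + arr[2:])
    out[0] = 0.5 * (arr[0] + arr[1])
    out[-1] = 0.5 * (arr[-2] + arr[-1])
    return out


def _model_and_jacobian(
    p: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Superposed velocity and its analytic Jacobian for stacked parameters.

    ``p`` holds 6 parameters (t0, D, mu, sigma, theta_s, theta_e) per
    component.  Returns ``(vx, vy, J)`` with the observation kernel already
    applied; ``J`` has shape (2N, 6K) with the vx rows stacked above vy.
    """
    n_comp = p.size // 6
    n = t.size
    vx = np.zeros(n)
    vy = np.zeros(n)
    jac = np.zeros((2 * n, 6 * n_comp))
    for k in range(n_comp):
        t0, D, mu, sg, ths, the = p[6 * k: 6 * k + 6]
        tau = t - t0
        m = tau > 0
        if not m.any():
            continue
        tau = tau[m]
        z = (np.log(tau) - mu) / sg
        lam = D / (sg * _SQRT2PI * tau) * np.exp(-0.5 * z * z)
        delta = wrap_angle(the - ths)
        erfw = erf(z / math.sqrt(2.0))
        theta = ths + 0.5 * delta * (1.0 + erfw)
        cth, sth = np.cos(theta), np.sin(theta)
        vx[m] += lam * cth
        vy[m] += lam * sth
        gauss = np.exp(-0.5 * z * z)
        coef = delta * gauss / (sg * _SQRT2PI)
        dlam = {
            0: lam * (1.0 + z / sg) / tau,          # d/dt0
            1: lam / D,                              # d/dD
            2: lam * z / sg,                         # d/dmu
            3: lam * (z * z - 1.0) / sg,             # d/dsigma
        }
        dtheta = {
            0: -coef / tau,
            2: -coef,
            3: -coef * z,
            4: 1.0 - 0.5 * (1.0 + erfw),
            5: 0.5 * (1.0 + erfw),
        }
        for col in range(6):
            dl = dlam.get(col, 0.0)
            dt_ = dtheta.get(col, 0.0)
            dvx = dl * cth - lam * sth * dt_
            dvy = dl * sth + lam * cth * dt_
            jac[:n][m, 6 * k + col] = dvx
            jac[n:][m, 6 * k + col] = dvy
    return (observation_kernel(vx), observation_kernel(vy),
            np.vstack([_kernel_columns(jac[:n]), _kernel_columns(jac[n:])]))


def fit_single_lognormal(
    t: np.ndarray,
    residual_vx: np.ndarray,
    residual_vy: np.ndarray,
    window: tuple[int, int] | None = None,
    max_nfev: int = 60,
    return_all: bool = False,
) -> LognormalComponent | list[LognormalComponent] | None:
    """Fit one lognormal to a residual velocity around its largest peak.

    Returns ``None`` (component rejection) when the window holds no usable
    local maximum or the bounded least-squares refinement fails.  With
    ``return_all`` every converged start basin is returned, best first.
    """
    t = np.asarray(t, dtype=float)
    speed = np.hypot(residual_vx, residual_vy)
    if window is None:
        peak = int(np.argmax(speed))
    else:
        lo0, hi0 = window
        if hi0 - lo0 < 5:
            return None
        peak = lo0 + int(np.argmax(speed[lo0:hi0]))
    if speed[peak] <= 0:
        return None
    # shape estimation uses the residual projected on the peak bearing and
    # rectified, which suppresses overlapping opposite-direction components
    ux, uy = residual_vx[peak] / speed[peak], residual_vy[peak] / speed[peak]
    proj = np.maximum(residual_vx * ux + residual_vy * uy, 0.0)
    lo, hi = _expand_window(proj, peak)
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    if hi - lo < 5:
        return None
    seg = proj[lo:hi]
    peak = lo + int(np.argmax(seg))
    vp = proj[peak]
    if vp <= 0 or peak in (lo, hi - 1):
        return None
    if np.ptp(seg) < 0.05 * vp:  # flat residual: no strict local maximum
        return None
    t1, t2 = _half_crossings(t, proj, peak, lo, hi)
    if t1 is None and t2 is None:
        return None
    if t1 is None:
        t1 = t[peak] - (t2 - t[peak])
    if t2 is None:
        t2 = t[peak] + (t[peak] - t1)
    if not (t1 < t[peak] < t2):
        return None
    try:
        t0, mu, sigma, D = _initial_guess(t[peak], vp, t1, t2, t[lo])
        theta_s, theta_e = _angles_from_bearing(t, residual_vx, residual_vy, t0, mu, sigma)
    except (ValueError, ZeroDivisionError):
        return None

    ts, tx, ty = t[lo:hi], residual_vx[lo:hi], residual_vy[lo:hi]
    dt = t[1] - t[0]
    # a single component cannot cover much more ground than the residual does
    d_max = max(4.0 * float(np.sum(np.hypot(residual_vx, residual_vy))) * dt, 2.0 * D)

    def resid(p: np.ndarray) -> np.ndarray:
        mvx, mvy, _ = _model_and_jacobian(p, ts)
        return np.concatenate([mvx - tx, mvy - ty])

    def jac(p: np.ndarray) -> np.ndarray:
        return _model_and_jacobian(p, ts)[2]

    width = max(t2 - t1, 4.0 * dt)
    tp = t[peak]
    starts = [(t0, mu, sigma, D)]
    # alternative asymmetry basins: place t0 a multiple of the measured
    # half-height width before the peak (small multiples = wide sigma) and
    # trust only the left half-crossing, which overlaps rarely contaminate
    for q in (0.7, 1.2, 2.0, 4.0):
        t0_q = tp - q * width
        if t0_q >= t1 - 1e-6:
            continue
        try:
            sg_q = min(max(math.log((tp - t0_q) / (t1 - t0_q)) / _HALF_WIDTH, 5e-3), 1.0)
            mu_q = math.log(tp - t0_q) + sg_q * sg_q
            D_q = vp * sg_q * _SQRT2PI * math.exp(mu_q - sg_q * sg_q / 2.0)
            starts.append((t0_q, mu_q, sg_q, D_q))
        except ValueError:
            continue
    # two angle initialisations: the de-mixed arc estimate, and the bearing
    # at the peak sample itself (robust when the arc estimate is
    # contaminated by a neighbouring component)
    phi_peak = math.atan2(residual_vy[peak], residual_vx[peak])
    angle_inits = [(theta_s, theta_e)]
    if abs(math.remainder(phi_peak - theta_s, 2.0 * math.pi)) > 0.5:
        angle_inits.append((phi_peak, phi_peak))
    solutions: list[tuple[float, LognormalComponent]] = []
    for t0_i, mu_i, sg_i, D_i in starts:
        for ths_i, the_i in angle_inits:
            p0 = np.array([t0_i, D_i, mu_i, sg_i, ths_i, the_i])
            lower = [t0_i - 5.0 * width, 0.05 * D_i, mu_i - 1.5, 5e-3,
                     ths_i - 1.5, the_i - 1.5]
            upper = [min(t0_i + 5.0 * width, tp - 1e-4), min(20.0 * D_i, d_max),
                     mu_i + 1.5, min(max(4.0 * sg_i, 0.3), 1.5),
                     ths_i + 1.5, the_i + 1.5]
            p0 = np.clip(p0, lower, upper)
            try:
                sol = least_squares(resid, p0, jac=jac, bounds=(lower, upper),
                                    max_nfev=max_nfev)
            except ValueError:
                continue
            if np.isfinite(sol.x).all() and sol.x[1] > 0 and sol.x[3] > 0:
                solutions.append((float(sol.cost), LognormalComponent(
                    t0=sol.x[0], D=sol.x[1], mu=sol.x[2], sigma=sol.x[3],
                    theta_s=sol.x[4], theta_e=sol.x[5])))
    if not solutions:
        return None
    solutions.sort(key=lambda sc: sc[0])
    if return_all:
        # refined solutions best-first, then the raw basin starts: when an
        # overlap distorts the window cost the right basin may only survive
        # as an unrefined start
        out = [c for _, c in solutions]
        for t0_i, mu_i, sg_i, D_i in starts:
            try:
                out.append(LognormalComponent(t0=t0_i, D=D_i, mu=mu_i, sigma=sg_i,
                                              theta_s=theta_s, theta_e=theta_e))
            except Exception:
                continue
        return out
    return solutions[0][1]


def _closed_form_candidate(
    t: np.ndarray, residual_vx: np.ndarray, residual_vy: np.ndarray
) -> LognormalComponent | None:
    """Unrefined closed-form seed at the largest residual peak."""
    speed = np.hypot(residual_vx, residual_vy)
    peak = int(np.argmax(speed))
    if speed[peak] <= 0:
        return None
    ux, uy = residual_vx[peak] / speed[peak], residual_vy[peak] / speed[peak]
    proj = np.maximum(residual_vx * ux + residual_vy * uy, 0.0)
    lo, hi = _expand_window(proj, peak)
    if hi - lo < 5 or peak in (lo, hi - 1):
        return None
    speed = proj
    t1, t2 = _half_crossings(t, speed, peak, lo, hi)
    if t1 is None and t2 is None:
        return None
    if t1 is None:
        t1 = t[peak] - (t2 - t[peak])
    if t2 is None:
        t2 = t[peak] + (t[peak] - t1)
    if not (t1 < t[peak] < t2):
        return None
    try:
        t0, mu, sigma, D = _initial_guess(t[peak], speed[peak], t1, t2, t[lo])
        theta_s, theta_e = _angles_from_bearing(t, residual_vx, residual_vy, t0, mu, sigma)
        return LognormalComponent(t0=t0, D=D, mu=mu, sigma=sigma,
                                  theta_s=theta_s, theta_e=theta_e)
    except (ValueError, ZeroDivisionError):
        return None


# ---------------------------------------------------------------------------
# Greedy decomposition
# ---------------------------------------------------------------------------

def _joint_refine(
    t: np.ndarray,
    vx: np.ndarray,
    vy: np.ndarray,
    fixed: list[LognormalComponent],
    free: list[LognormalComponent],
    max_nfev: int,
    tol: float = 1e-12,
    bound_scale: float = 1.0,
) -> list[LognormalComponent]:
    """Jointly re-refine ``free`` components against the observed velocity.

    The refinement is restricted to the time window spanned by the free
    components' supports, which keeps the cost flat for long trials.
    """
    if not free:
        return free
    d_max = 4.0 * float(np.sum(np.hypot(vx, vy))) * float(t[1] - t[0])
    t_lo = min(c.t0 + math.exp(c.mu - 4.0 * c.sigma) for c in free)
    t_hi = max(c.t0 + math.exp(c.mu + 4.0 * c.sigma) for c in free)
    lo = int(np.clip(np.searchsorted(t, t_lo) - 2, 0, t.size))
    hi = int(np.clip(np.searchsorted(t, t_hi) + 2, 0, t.size))
    if hi - lo < 10:
        lo, hi = 0, t.size
    t = t[lo:hi]
    vx, vy = vx[lo:hi], vy[lo:hi]
    fx = np.zeros_like(t)
    fy = np.zeros_like(t)
    if fixed:
        fx, fy, _ = superpose(fixed, t)
    tx, ty = vx - fx, vy - fy

    def unpack(p: np.ndarray) -> list[LognormalComponent]:
        comps = []
        for k in range(len(free)):
            q = p[6 * k: 6 * k + 6]
            comps.append(LognormalComponent(t0=q[0], D=q[1], mu=q[2], sigma=q[3],
                                            theta_s=q[4], theta_e=q[5]))
        return comps

    def resid(p: np.ndarray) -> np.ndarray:
        mvx, mvy, _ = _model_and_jacobian(np.asarray(p), t)
        return np.concatenate([mvx - tx, mvy - ty])

    def jac(p: np.ndarray) -> np.ndarray:
        return _model_and_jacobian(np.asarray(p), t)[2]

    p0, lower, upper = [], [], []
    for c in free:
        p0 += [c.t0, c.D, c.mu, c.sigma, c.theta_s, c.theta_e]
        bs = bound_scale
        lower += [c.t0 - 0.15 * bs, 0.2 / bs * min(c.D, d_max), c.mu - 0.8 * bs,
                  5e-3, c.theta_s - 1.0, c.theta_e - 1.0]
        upper += [c.t0 + 0.15 * bs, min(5.0 * bs * c.D, d_max), c.mu + 0.8 * bs,
                  1.5, c.theta_s + 1.0, c.theta_e + 1.0]
    try:
        sol = least_squares(resid, np.clip(p0, lower, upper), jac=jac,
                            bounds=(lower, upper), max_nfev=max_nfev,
                            xtol=tol, ftol=tol, gtol=tol)
    except ValueError:
        return free
    refined = unpack(sol.x)
    before = float(np.sum(resid(np.asarray(p0)) ** 2))
    after = float(np.sum(sol.fun ** 2))
    return refined if after <= before else free


def decompose(
    trajectory: Trajectory,
    config: ExtractionConfig | None = None,
    test_type: str | None = None,
) -> ReconstructionResult:
    """Greedy sigma-lognormal reconstruction of one trial.

    Components are extracted at residual speed peaks until the SNR target
    is met, a candidate stops improving the fit, or the component cap is
    hit (the result is then flagged low-quality, not raised).
    """
    config = config or ExtractionConfig()
    cap = config.max_components
    test = test_type or trajectory.test_type
    if test in DEFAULT_NBLOG_CAPS:
        cap = min(cap, DEFAULT_NBLOG_CAPS[test])
    t = trajectory.t
    vx, vy, _ = trajectory_speed(trajectory, config.smoothing_cutoff_hz)
    comps: list[LognormalComponent] = []
    rx = np.zeros_like(t)
    ry = np.zeros_like(t)
    snr = compute_snr(vx, vy, rx, ry)
    since_refine = 0
    if cap > 20:  # dense trains: seed every speed peak up front
        seeded = _train_seed(t, vx, vy, config, cap)
        if len(seeded) >= 2:
            s_rx, s_ry, _ = superpose(seeded, t)
            s_rx, s_ry = observation_kernel(s_rx), observation_kernel(s_ry)
            s_snr = compute_snr(vx, vy, s_rx, s_ry)
            if s_snr > snr:
                comps, rx, ry, snr = seeded, s_rx, s_ry, s_snr
    while len(comps) < cap and snr < config.snr_target_db:
        # dense component trains (oscillations) legitimately gain only a
        # fraction of a dB per component: scale the acceptance gate with
        # the remaining budget while never admitting an SNR decrease
        min_gain = min(config.min_gain_db, 4.343 / max(cap - len(comps), 1))
        res_vx, res_vy = vx - rx, vy - ry
        blocked = np.zeros(t.size, dtype=bool)
        accepted = False
        for _attempt in range(5):
            search_speed = np.hypot(res_vx, res_vy)
            search_speed[blocked] = 0.0
            if not search_speed.any():
                break
            peak = int(np.argmax(search_speed))
            win = _expand_window(search_speed, peak)
            cand = fit_single_lognormal(t, res_vx, res_vy, window=win,
                                        max_nfev=config.max_nfev)
            if cand is not None:
                cvx, cvy, _ = superpose([cand], t)
                cvx, cvy = observation_kernel(cvx), observation_kernel(cvy)
                new_snr = compute_snr(vx, vy, rx + cvx, ry + cvy)
                if new_snr - snr >= min_gain:
                    comps.append(cand)
                    rx, ry = rx + cvx, ry + cvy
                    snr = new_snr
                    accepted = True
                    since_refine += 1
                    if config.refine_every and since_refine >= config.refine_every:
                        comps, rx, ry, snr = _refine_tail(t, vx, vy, comps, config)
                        since_refine = 0
                    break
            # a plain candidate cannot improve the fit (typically overlap
            # cancellation): try absorbing it through joint tail refinement
            seeds = [c for c in (cand, _closed_form_candidate(t, res_vx, res_vy))
                     if c is not None]
            for seed in seeds:
                trial = comps + [seed]
                r_comps, r_rx, r_ry, r_snr = _refine_tail(t, vx, vy, trial, config)
                if r_snr - snr >= min_gain:
                    comps, rx, ry, snr = r_comps, r_rx, r_ry, r_snr
                    accepted = True
                    since_refine = 0
                    break
            if accepted:
                break
            blocked[win[0]:win[1]] = True
        if not accepted:
            break
    if comps and since_refine:
        comps, rx, ry, snr = _refine_tail(t, vx, vy, comps, config)
    if (comps and len(comps) <= config.joint_refine_max
            and snr < config.backfit_snr_db):
        comps, rx, ry, snr = _backfit(t, vx, vy, comps, config, snr)
    if comps and len(comps) <= 6 and snr < config.backfit_snr_db:
        seeds = _pair_reseed(t, vx, vy, config)
        if seeds:
            s_comps, s_rx, s_ry, s_snr = _refine_tail(t, vx, vy, seeds, config)
            if s_snr < config.backfit_snr_db:
                s_comps, s_rx, s_ry, s_snr = _backfit(t, vx, vy, s_comps, config, s_snr)
            if s_snr > snr:
                comps, rx, ry, snr = s_comps, s_rx, s_ry, s_snr
    if comps and len(comps) <= 6 and snr < config.backfit_snr_db:
        m_comps, m_rx, m_ry, m_snr = _opposed_multistart(t, vx, vy, comps, config, snr)
        if m_snr > snr:
            comps, rx, ry, snr = m_comps, m_rx, m_ry, m_snr
            if snr < config.backfit_snr_db:
                comps, rx, ry, snr = _backfit(t, vx, vy, comps, config, snr)
    if len(comps) >= 3 and len(comps) <= config.joint_refine_max:
        comps, rx, ry, snr = _prune_redundant(t, vx, vy, comps, config, snr)
    comps.sort(key=lambda c: c.t0)
    signal = float(np.sum(vx**2 + vy**2))
    resid = float(np.sum((vx - rx) ** 2 + (vy - ry) ** 2))
    return ReconstructionResult(
        components=comps,
        snr_db=snr,
        residual_fraction=resid / signal if signal > 0 else float("nan"),
        low_quality=snr < config.snr_target_db,
    )


def _backfit(
    t: np.ndarray,
    vx: np.ndarray,
    vy: np.ndarray,
    comps: list[LognormalComponent],
    config: ExtractionConfig,
    snr: float,
    max_passes: int = 3,
) -> tuple[list[LognormalComponent], np.ndarray, np.ndarray, float]:
    """Cyclic re-fit of each component against the others' residual.

    Greedy extraction can leave the component set in a local minimum; a
    few backfitting sweeps (drop one component, refit it on what the rest
    leave unexplained, jointly re-refine) reliably escape.  Components
    whose removal alone improves the fit are pruned.
    """
    rx, ry, _ = superpose(comps, t)
    rx, ry = observation_kernel(rx), observation_kernel(ry)
    for _ in range(max_passes):
        improved = False
        for i in sorted(range(len(comps)), key=lambda j: comps[j].D):
            others = comps[:i] + comps[i + 1:]
            if others:
                ox, oy, _ = superpose(others, t)
                ox, oy = observation_kernel(ox), observation_kernel(oy)
            else:
                ox = np.zeros_like(t)
                oy = np.zeros_like(t)
            if others:
                # parsimony: drop the component outright when the rest can
                # explain the signal essentially as well
                n_comps, n_rx, n_ry, n_snr = _refine_tail(t, vx, vy, list(others), config)
                if n_snr >= snr - 0.1:
                    comps, rx, ry, snr = n_comps, n_rx, n_ry, n_snr
                    improved = True
                    continue
            refit = fit_single_lognormal(t, vx - ox, vy - oy, max_nfev=config.max_nfev)
            if refit is not None:
                n_comps, n_rx, n_ry, n_snr = _refine_tail(t, vx, vy, others + [refit], config)
                if n_snr > snr + 1e-9:
                    comps, rx, ry, snr = n_comps, n_rx, n_ry, n_snr
                    improved = True
            if snr >= config.backfit_snr_db:
                return comps, rx, ry, snr
        if not improved:
            break
    return comps, rx, ry, snr


def _pair_reseed(
    t: np.ndarray,
    vx: np.ndarray,
    vy: np.ndarray,
    config: ExtractionConfig,
) -> list[LognormalComponent] | None:
    """Re-initialise as an opposed pair from the dominant-bearing projection.

    The net velocity of a pointing gesture is the agonist minus the
    antagonist contribution along the movement direction; fitting the
    rectified positive and negative lobes of that projection separately
    gives a far better starting point than peak-by-peak extraction when
    the two overlap heavily.
    """
    speed = np.hypot(vx, vy)
    peak = int(np.argmax(speed))
    if speed[peak] <= 0:
        return None
    ux, uy = vx[peak] / speed[peak], vy[peak] / speed[peak]
    s = vx * ux + vy * uy
    comps = []
    for lobe, bx, by in ((np.maximum(s, 0.0), ux, uy),
                         (np.maximum(-s, 0.0), -ux, -uy)):
        if lobe.max() <= 0.02 * speed[peak]:
            continue
        cand = fit_single_lognormal(t, lobe * bx, lobe * by, max_nfev=config.max_nfev)
        if cand is not None:
            comps.append(cand)
    return comps or None


def _prune_redundant(
    t: np.ndarray,
    vx: np.ndarray,
    vy: np.ndarray,
    comps: list[LognormalComponent],
    config: ExtractionConfig,
    snr: float,
) -> tuple[list[LognormalComponent], np.ndarray, np.ndarray, float]:
    """Drop components whose removal leaves the fit essentially as good.

    Implements the parsimony of the model: the smallest set of lognormals
    explaining the signal is preferred.  A removal is accepted when the
    remaining refined set stays within 0.1 dB of the current quality or
    above the polish target.
    """
    changed = True
    while changed and len(comps) > 1:
        changed = False
        for i in sorted(range(len(comps)), key=lambda j: comps[j].D):
            others = comps[:i] + comps[i + 1:]
            n_comps, n_rx, n_ry, n_snr = _refine_tail(t, vx, vy, list(others), config)
            if n_snr >= snr - 0.1 or n_snr >= config.backfit_snr_db:
                comps, snr = n_comps, n_snr
                rx, ry = n_rx, n_ry
                changed = True
                break
    rx, ry, _ = superpose(comps, t)
    rx, ry = observation_kernel(rx), observation_kernel(ry)
    return comps, rx, ry, compute_snr(vx, vy, rx, ry)


def _opposed_multistart(
    t: np.ndarray,
    vx: np.ndarray,
    vy: np.ndarray,
    comps: list[LognormalComponent],
    config: ExtractionConfig,
    snr: float,
) -> tuple[list[LognormalComponent], np.ndarray, np.ndarray, float]:
    """Search for a hidden opposed component paired with the dominant one.

    A small antagonist buried under the agonist's profile never produces
    its own residual peak; a coarse multistart over its command time and
    time scale, each start refined jointly with the dominant component,
    finds it reliably.
    """
    # anchor on fresh fits of the untouched signal: the current state may
    # already sit in a cancelling-pair minimum that would poison the probes
    all_anchors = fit_single_lognormal(t, vx, vy, max_nfev=config.max_nfev,
                                       return_all=True) or []
    if not all_anchors:
        all_anchors = [max(comps, key=lambda c: c.D)]
    cheap = ExtractionConfig(**{**config.__dict__,
                                "refine_max_nfev": 120, "refine_tol": 1e-8})

    def opposed_bearing(anchor: LognormalComponent) -> float:
        """Bearing of the residual where it opposes the anchor's motion."""
        ax, ay, _ = superpose([anchor], t)
        rvx = vx - observation_kernel(ax)
        rvy = vy - observation_kernel(ay)
        ux, uy = math.cos(anchor.theta_s), math.sin(anchor.theta_s)
        proj = rvx * ux + rvy * uy
        mask = proj < 0
        if not mask.any():
            return anchor.theta_s + math.pi
        w = -proj[mask]
        return math.atan2(float(np.sum(w * rvy[mask])),
                          float(np.sum(w * rvx[mask])))

    def search(anchors):
        best, best_snr = None, -math.inf
        for anchor in anchors:
            phi = opposed_bearing(anchor)
            for dt0 in (0.05, 0.12, 0.2, 0.3):
                for dmu in (-0.5, -0.25, 0.0):
                    for sfac in (1.0, 2.0):
                        probe = LognormalComponent(
                            t0=anchor.t0 + dt0, D=0.15 * anchor.D,
                            mu=anchor.mu + dmu,
                            sigma=min(sfac * anchor.sigma, 1.0),
                            theta_s=phi, theta_e=phi)
                        cand, _, _, cand_snr = _refine_tail(
                            t, vx, vy, [anchor, probe], cheap, bound_scale=2.5)
                        if cand_snr > best_snr:
                            best, best_snr = cand, cand_snr
        if best is None:
            return None
        return _refine_tail(t, vx, vy, best, config, bound_scale=2.5)

    # tier 1: the best refined anchors; tier 2: every remaining basin start
    for anchors in (all_anchors[:2], all_anchors[2:8]):
        if not anchors:
            continue
        result = search(anchors)
        if result is not None and result[3] > snr:
            comps, rx, ry, snr = result
            if snr >= config.backfit_snr_db:
                break
    else:
        rx, ry, _ = superpose(comps, t)
        rx, ry = observation_kernel(rx), observation_kernel(ry)
    return comps, rx, ry, snr


def _train_seed(
    t: np.ndarray,
    vx: np.ndarray,
    vy: np.ndarray,
    config: ExtractionConfig,
    cap: int,
) -> list[LognormalComponent]:
    """Seed one component per speed peak for dense component trains.

    Oscillation trials superpose so many alternating components that
    peak-by-peak greedy extraction cannot get a foothold; seeding the
    whole train at the observed speed peaks and refining in sliding
    windows converges instead.
    """
    from scipy.signal import find_peaks

    speed = np.hypot(vx, vy)
    vmax = float(speed.max())
    if vmax <= 0:
        return []
    dt = float(t[1] - t[0])
    peaks, props = find_peaks(speed, prominence=0.1 * vmax)
    if peaks.size < 2:
        return []
    widths = np.full(peaks.size, 4.0 * dt)
    from scipy.signal import peak_widths
    try:
        widths = np.maximum(peak_widths(speed, peaks, rel_height=0.5)[0] * dt, 3.0 * dt)
    except ValueError:
        pass
    comps = []
    for p, w in zip(peaks[:cap], widths[:cap]):
        tp, vp = float(t[p]), float(speed[p])
        t1, t2 = tp - 0.5 * w, tp + 0.5 * w
        try:
            t0, mu, sigma, D = _initial_guess(tp, vp, t1, t2, t1)
        except (ValueError, ZeroDivisionError):
            continue
        ang = math.atan2(vy[p], vx[p])
        try:
            comps.append(LognormalComponent(t0=t0, D=D, mu=mu, sigma=sigma,
                                            theta_s=ang, theta_e=ang))
        except Exception:
            continue
    comps.sort(key=lambda c: c.t0)
    # sliding-window joint refinement over the train
    m = config.joint_refine_max
    step = max(m // 2, 1)
    for start in range(0, len(comps), step):
        free = comps[start:start + m]
        fixed = comps[:start] + comps[start + m:]
        refined = _joint_refine(t, vx, vy, fixed, free, config.refine_max_nfev,
                                config.refine_tol)
        comps = comps[:start] + refined + comps[start + m:]
        if start + m >= len(comps):
            break
    return comps


def _refine_tail(t, vx, vy, comps, config, bound_scale=1.0):
    m = min(config.joint_refine_max, len(comps))
    # refine the components temporally closest to the newest one so the
    # refinement window stays narrow even on long component trains
    newest = comps[-1]
    order = sorted(range(len(comps)), key=lambda i: abs(comps[i].t0 - newest.t0))
    free_idx = set(order[:m])
    fixed = [c for i, c in enumerate(comps) if i not in free_idx]
    free = [c for i, c in enumerate(comps) if i in free_idx]
    # refinement bounds are centred on the current values, so a solution
    # parked against a bound can keep moving on the next round; long
    # component trains skip the extra rounds for speed
    rounds = 3 if len(comps) <= config.joint_refine_max else 1
    snr_prev = -math.inf
    for _ in range(rounds):
        free = _joint_refine(t, vx, vy, fixed, free, config.refine_max_nfev,
                             config.refine_tol, bound_scale)
        rx, ry, _ = superpose(fixed + free, t)
        rx, ry = observation_kernel(rx), observation_kernel(ry)
        snr_now = compute_snr(vx, vy, rx, ry)
        if snr_now - snr_prev < 0.05 or snr_now >= config.backfit_snr_db:
            break
        snr_prev = snr_now
    comps = fixed + free
    rx, ry, _ = superpose(comps, t)
    rx, ry = observation_kernel(rx), observation_kernel(ry)
    return comps, rx, ry, compute_snr(vx, vy, rx, ry)
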