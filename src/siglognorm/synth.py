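"""Seeded synthetic handwriting sessions.

Generates tablet-like planar pen trajectories for the four test types
(simple strokes, triangles, horizontal and vertical oscillations), with
participant-level lognormal parameter means drawn from configurable
population distributions and per-stroke jitter around them.  Ground-truth
components are embedded in every generated trajectory so the extractor can
be benchmarked on parameter recovery.

The default population settings emulate the published pre-fatigue group
summary statistics for each test type, with post-fatigue conditions applied
as additive mean shifts.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .model import LognormalComponent, superpose

__all__ = [
    "ParamSpec",
    "RoleConfig",
    "PopulationConfig",
    "Trajectory",
    "ParticipantParams",
    "default_population_config",
    "sample_population",
    "draw_stroke_parameters",
    "generate_trial",
    "generate_session",
    "add_noise",
    "measured_velocity_snr_db",
]

TEST_TYPES = ("simple", "triangle", "h_osc", "v_osc")
CONDITIONS = ("pre", "post")
FATIGUE_TYPES = ("ER", "IR")


@dataclass(frozen=True)
class ParamSpec:
    """Between-participant mean and SD of one lognormal parameter."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"SD must be >= 0, got {self.sd}")


@dataclass
class RoleConfig:
    """Population distributions for one component role within a test.

    ``t0`` is the absolute command time for discrete strokes and the
    successive-command interval (delta t0) for oscillation roles.
    """

    t0: ParamSpec
    D: ParamSpec
    mu: ParamSpec
    sigma: ParamSpec
    theta_s: ParamSpec
    theta_e: ParamSpec

    def params(self) -> dict[str, ParamSpec]:
        return {
            "t0": self.t0,
            "D": self.D,
            "mu": self.mu,
            "sigma": self.sigma,
            "theta_s": self.theta_s,
            "theta_e": self.theta_e,
        }


@dataclass
class PopulationConfig:
    """Full synthetic-population configuration.

    ``roles`` maps (test type, condition, role) -> RoleConfig, where
    condition is e.g. ``("ER", "pre")``.  ``within_sd_fraction`` scales the
    between-participant SDs down to per-stroke jitter around each
    participant's own mean.
    """

    roles: dict[tuple[str, str, str, str], RoleConfig] = field(default_factory=dict)
    n_participants: int = 20
    strokes_per_test: int = 30
    oscillation_duration_s: float = 10.0
    target_separation_mm: float = 50.0
    sample_rate_hz: float = 200.0
    within_sd_fraction: float = 0.5
    pre_post_correlation: float = 0.98
    noise_snr_db: float = float("inf")
    triangle_minor_components: int = 2

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    def role_config(self, test: str, fatigue: str, condition: str, role: str) -> RoleConfig:
        return self.roles[(test, fatigue, condition, role)]


@dataclass
class Trajectory:
    """Uniformly sampled planar pen path for one trial."""

    trial_id: str
    test_type: str
    participant: str
    fatigue_type: str
    condition: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    stimulus_time: float = 0.0
    ground_truth: list[LognormalComponent] | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have identical shapes")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if np.any(np.abs(steps - steps[0]) > 1e-9):
                raise ValueError("trajectory must be uniformly sampled")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("positions must be finite")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / self.dt


@dataclass
class ParticipantParams:
    """Per-participant parameter means: (test, fatigue, condition, role) -> values."""

    participant: str
    means: dict[tuple[str, str, str, str], dict[str, float]]


# ---------------------------------------------------------------------------
# Default population settings.
# Pre-fatigue means/SDs follow the published group tables for each test;
# post-fatigue applies the printed pre -> post mean shifts.
# ---------------------------------------------------------------------------

def _spec(mean: float, sd: float) -> ParamSpec:
    return ParamSpec(mean, sd)


_AGO_THETA_S = math.acos(0.81)   # |cos(theta_s)| = 0.81
_AGO_THETA_E = math.acos(0.96)
_ANT_THETA_S = math.pi - math.acos(0.95)
_ANT_THETA_E = math.pi - math.acos(0.91)

_SIMPLE_DEFAULTS: dict[tuple[str, str, str], dict[str, ParamSpec]] = {
    ("ER", "pre", "agonist"): {
        "t0": _spec(0.23, 0.08), "D": _spec(214.0, 19.8),
        "mu": _spec(-1.42, 0.18), "sigma": _spec(0.27, 0.06),
        "theta_s": _spec(_AGO_THETA_S, 0.05), "theta_e": _spec(_AGO_THETA_E, 0.03),
    },
    ("ER", "post", "agonist"): {
        "t0": _spec(0.25, 0.07), "D": _spec(217.0, 21.6),
        "mu": _spec(-1.41, 0.15), "sigma": _spec(0.30, 0.06),
        "theta_s": _spec(_AGO_THETA_S, 0.05), "theta_e": _spec(_AGO_THETA_E, 0.03),
    },
    ("ER", "pre", "antagonist"): {
        "t0": _spec(0.40, 0.12), "D": _spec(30.6, 6.94),
        "mu": _spec(-1.78, 0.18), "sigma": _spec(0.36, 0.11),
        "theta_s": _spec(_ANT_THETA_S, 0.05), "theta_e": _spec(_ANT_THETA_E, 0.03),
    },
    ("ER", "post", "antagonist"): {
        "t0": _spec(0.44, 0.12), "D": _spec(33.0, 8.33),
        "mu": _spec(-1.82, 0.20), "sigma": _spec(0.39, 0.12),
        "theta_s": _spec(_ANT_THETA_S, 0.05), "theta_e": _spec(_ANT_THETA_E, 0.03),
    },
    ("IR", "pre", "agonist"): {
        "t0": _spec(0.21, 0.08), "D": _spec(208.0, 25.0),
        "mu": _spec(-1.43, 0.18), "sigma": _spec(0.27, 0.05),
        "theta_s": _spec(_AGO_THETA_S, 0.05), "theta_e": _spec(_AGO_THETA_E, 0.03),
    },
    ("IR", "post", "agonist"): {
        "t0": _spec(0.24, 0.08), "D": _spec(208.0, 23.7),
        "mu": _spec(-1.46, 0.18), "sigma": _spec(0.29, 0.05),
        "theta_s": _spec(_AGO_THETA_S, 0.05), "theta_e": _spec(_AGO_THETA_E, 0.03),
    },
    ("IR", "pre", "antagonist"): {
        "t0": _spec(0.40, 0.11), "D": _spec(29.0, 6.66),
        "mu": _spec(-1.86, 0.22), "sigma": _spec(0.36, 0.08),
        "theta_s": _spec(_ANT_THETA_S, 0.05), "theta_e": _spec(_ANT_THETA_E, 0.03),
    },
    ("IR", "post", "antagonist"): {
        "t0": _spec(0.41, 0.11), "D": _spec(30.4, 7.53),
        "mu": _spec(-1.80, 0.16), "sigma": _spec(0.36, 0.10),
        "theta_s": _spec(_ANT_THETA_S, 0.05), "theta_e": _spec(_ANT_THETA_E, 0.03),
    },
}

# Triangles were only tabulated for the ER session; IR reuses the same
# pre-fatigue population with no shift applied.
_TRIANGLE_BASE = {
    "pre": {
        "t0": _spec(0.23, 0.08), "D": _spec(154.9, 9.29),
        "mu": _spec(-0.80, 0.21), "sigma": _spec(0.19, 0.03),
    },
    "post": {
        "t0": _spec(0.23, 0.06), "D": _spec(158.0, 10.2),
        "mu": _spec(-0.77, 0.18), "sigma": _spec(0.19, 0.03),
    },
}

_OSC_DEFAULTS = {
    ("h_osc", "ER", "pre"): {"t0": _spec(0.08, 0.01), "D": _spec(124.8, 23.7),
                             "mu": _spec(-0.81, 0.07), "sigma": _spec(0.06, 0.005)},
    ("h_osc", "ER", "post"): {"t0": _spec(0.09, 0.01), "D": _spec(126.2, 26.2),
                              "mu": _spec(-0.75, 0.10), "sigma": _spec(0.06, 0.005)},
    ("h_osc", "IR", "pre"): {"t0": _spec(0.09, 0.01), "D": _spec(124.2, 24.5),
                             "mu": _spec(-0.81, 0.11), "sigma": _spec(0.06, 0.005)},
    ("h_osc", "IR", "post"): {"t0": _spec(0.09, 0.01), "D": _spec(125.2, 28.8),
                              "mu": _spec(-0.75, 0.10), "sigma": _spec(0.06, 0.005)},
    ("v_osc", "ER", "pre"): {"t0": _spec(0.09, 0.01), "D": _spec(118.4, 19.2),
                             "mu": _spec(-0.73, 0.11), "sigma": _spec(0.06, 0.005)},
    ("v_osc", "ER", "post"): {"t0": _spec(0.09, 0.01), "D": _spec(123.9, 19.4),
                              "mu": _spec(-0.73, 0.14), "sigma": _spec(0.06, 0.005)},
    ("v_osc", "IR", "pre"): {"t0": _spec(0.09, 0.02), "D": _spec(119.4, 26.0),
                             "mu": _spec(-0.74, 0.17), "sigma": _spec(0.06, 0.005)},
    ("v_osc", "IR", "post"): {"t0": _spec(0.10, 0.01), "D": _spec(119.8, 21.6),
                              "mu": _spec(-0.69, 0.16), "sigma": _spec(0.06, 0.005)},
}

_TRIANGLE_BEARINGS = (0.0, -2.0 * math.pi / 3.0, 2.0 * math.pi / 3.0)  # clockwise


def default_population_config(**overrides) -> PopulationConfig:
    """Population config reproducing the published summary statistics.

    Keyword overrides are applied to the top-level scalar fields
    (``n_participants``, ``strokes_per_test``, ...).
    """
    roles: dict[tuple[str, str, str, str], RoleConfig] = {}
    for (fatigue, condition, role), params in _SIMPLE_DEFAULTS.items():
        roles[("simple", fatigue, condition, role)] = RoleConfig(**params)
    for fatigue in FATIGUE_TYPES:
        for condition in CONDITIONS:
            base = _TRIANGLE_BASE[condition if fatigue == "ER" else "pre"]
            for k, bearing in enumerate(_TRIANGLE_BEARINGS):
                roles[("triangle", fatigue, condition, f"stroke{k + 1}")] = RoleConfig(
                    t0=base["t0"], D=base["D"], mu=base["mu"], sigma=base["sigma"],
                    theta_s=_spec(bearing, 0.05), theta_e=_spec(bearing, 0.05),
                )
    for (test, fatigue, condition), params in _OSC_DEFAULTS.items():
        roles[(test, fatigue, condition, "oscillation")] = RoleConfig(
            t0=params["t0"], D=params["D"], mu=params["mu"], sigma=params["sigma"],
            theta_s=_spec(0.0, 0.04), theta_e=_spec(0.0, 0.04),
        )
    return PopulationConfig(roles=roles, **overrides)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

_POSITIVE_PARAMS = {"D", "sigma"}
# identifiability floors: components narrower than a few samples or smaller
# than a millimetre cannot be resolved by any extractor at tablet rates
_PARAM_FLOORS = {"sigma": 0.05, "D": 1.0}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      positive: bool, floor: float = 1e-6) -> float:
    if sd == 0:
        return mean if not positive else max(mean, floor)
    for _ in range(100):
        value = rng.normal(mean, sd)
        if not positive or value > floor:
            return float(value)
    return max(mean, floor)


def sample_population(config: PopulationConfig, seed: int | np.random.Generator) -> list[ParticipantParams]:
    """Draw per-participant parameter means for every test/condition/role.

    A participant's pre- and post-fatigue means for the same test/role
    share a common participant effect with correlation
    ``config.pre_post_correlation`` (each condition keeps its configured
    marginal mean and SD); ``D`` and ``sigma`` draws are floored to stay
    physically resolvable.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rho = config.pre_post_correlation
    mix = math.sqrt(max(1.0 - rho * rho, 0.0))
    param_names = ("t0", "D", "mu", "sigma", "theta_s", "theta_e")
    pair_keys = sorted({(test, fatigue, role)
                        for (test, fatigue, _cond, role) in config.roles})
    participants = []
    for p in range(config.n_participants):
        means: dict[tuple[str, str, str, str], dict[str, float]] = {}
        for test, fatigue, role in pair_keys:
            shared = {name: rng.standard_normal() for name in param_names}
            for condition in CONDITIONS:
                key = (test, fatigue, condition, role)
                if key not in config.roles:
                    continue
                role_cfg = config.roles[key].params()
                vals = {}
                for name in param_names:
                    spec = role_cfg[name]
                    z = rho * shared[name] + mix * rng.standard_normal()
                    value = spec.mean + spec.sd * z
                    if name in _POSITIVE_PARAMS:
                        value = max(value, _PARAM_FLOORS.get(name, 1e-6))
                    vals[name] = float(value)
                means[key] = vals
        participants.append(ParticipantParams(participant=f"P{p + 1:02d}", means=means))
    return participants


def _jitter(rng: np.random.Generator, mean: float, sd: float, fraction: float,
            positive: bool, floor: float = 1e-6) -> float:
    return _truncated_normal(rng, mean, sd * fraction, positive, floor)


def _draw_component(rng: np.random.Generator, means: Mapping[str, float],
                    sds: Mapping[str, ParamSpec], fraction: float,
                    t0_override: float | None = None) -> LognormalComponent:
    vals = {
        name: _jitter(rng, means[name], sds[name].sd, fraction,
                      name in _POSITIVE_PARAMS, _PARAM_FLOORS.get(name, 1e-6))
        for name in ("t0", "D", "mu", "sigma", "theta_s", "theta_e")
    }
    if t0_override is not None:
        vals["t0"] = t0_override
    vals["t0"] = max(vals["t0"], 1e-3)
    return LognormalComponent(**vals)


def _trial_components(test_type: str, participant: ParticipantParams,
                      fatigue: str, condition: str, config: PopulationConfig,
                      rng: np.random.Generator) -> list[LognormalComponent]:
    frac = config.within_sd_fraction
    comps: list[LognormalComponent] = []
    if test_type == "simple":
        ago_key = (test_type, fatigue, condition, "agonist")
        ant_key = (test_type, fatigue, condition, "antagonist")
        ago = _draw_component(rng, participant.means[ago_key],
                              config.role_config(*ago_key).params(), frac)
        # the antagonist command follows the agonist one: couple its t0 to
        # the agonist draw through a positive delay so the pair stays
        # temporally ordered (the marginal t0 distribution is preserved)
        delay_mean = max(
            participant.means[ant_key]["t0"] - participant.means[ago_key]["t0"], 0.10)
        delay_sd = config.role_config(*ant_key).t0.sd * frac
        delay = max(_truncated_normal(rng, delay_mean, delay_sd, positive=True), 0.06)
        ant = _draw_component(rng, participant.means[ant_key],
                              config.role_config(*ant_key).params(), frac,
                              t0_override=ago.t0 + delay)
        comps.extend([ago, ant])
    elif test_type == "triangle":
        t_next = None
        for k in range(3):
            key = (test_type, fatigue, condition, f"stroke{k + 1}")
            comp = _draw_component(rng, participant.means[key],
                                   config.role_config(*key).params(), frac,
                                   t0_override=t_next)
            comps.append(comp)
            # next corner command: after this stroke is mostly executed
            t_next = comp.t0 + math.exp(comp.mu) + 0.15 + rng.normal(0.0, 0.02)
        for _ in range(config.triangle_minor_components):
            base = comps[rng.integers(0, 3)]
            comps.append(LognormalComponent(
                t0=base.t0 + math.exp(base.mu) * (0.8 + 0.3 * rng.random()),
                D=float(rng.uniform(8.0, 20.0)),
                mu=base.mu - 0.9 + rng.normal(0.0, 0.1),
                sigma=max(0.12, base.sigma + rng.normal(0.0, 0.02)),
                theta_s=base.theta_e + rng.normal(0.0, 0.4),
                theta_e=base.theta_e + rng.normal(0.0, 0.4),
            ))
    elif test_type in ("h_osc", "v_osc"):
        key = (test_type, fatigue, condition, "oscillation")
        means = participant.means[key]
        sds = config.role_config(*key).params()
        base_angle = 0.0 if test_type == "h_osc" else math.pi / 2.0
        t0 = float(rng.uniform(0.25, 0.4))
        direction = 0
        while t0 < config.oscillation_duration_s + 0.3:
            comp = _draw_component(rng, means, sds, frac, t0_override=t0)
            angle = base_angle + (math.pi if direction % 2 else 0.0)
            comps.append(LognormalComponent(
                t0=comp.t0, D=comp.D, mu=comp.mu, sigma=comp.sigma,
                theta_s=angle + comp.theta_s, theta_e=angle + comp.theta_e,
            ))
            delta = _jitter(rng, means["t0"], sds["t0"].sd, frac, positive=True)
            t0 += max(delta, 0.02)
            direction += 1
    else:
        raise ValueError(f"unknown test type: {test_type!r}")
    return sorted(comps, key=lambda c: c.t0)


def draw_stroke_parameters(
    participant: ParticipantParams,
    key: tuple[str, str, str, str],
    config: PopulationConfig,
    rng: np.random.Generator,
    n_strokes: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-stroke lognormal parameter draws for one participant and role.

    Draws ``n_strokes`` values of every parameter around the participant's
    own means with the within-participant jitter; useful for
    parameter-level statistical studies that do not need full
    trajectories.
    """
    n = n_strokes if n_strokes is not None else config.strokes_per_test
    means = participant.means[key]
    sds = config.role_config(*key).params()
    out: dict[str, np.ndarray] = {}
    for name in ("t0", "D", "mu", "sigma", "theta_s", "theta_e"):
        out[name] = np.array([
            _jitter(rng, means[name], sds[name].sd, config.within_sd_fraction,
                    name in _POSITIVE_PARAMS, _PARAM_FLOORS.get(name, 1e-6))
            for _ in range(n)
        ])
    return out


def generate_trial(test_type: str, participant: ParticipantParams,
                   fatigue: str, condition: str, config: PopulationConfig,
                   rng: np.random.Generator, trial_index: int = 0) -> Trajectory:
    """Synthesize one trial trajectory with embedded ground truth.

    Positions are the cumulative trapezoid integral of the superposed
    component velocity, started at the origin.  Velocity noise (if the
    config requests a finite SNR) is added by :func:`add_noise`.
    """
    comps = _trial_components(test_type, participant, fatigue, condition, config, rng)
    t_end = max(c.t0 + math.exp(c.mu + 4.0 * c.sigma) for c in comps) + 0.1
    if test_type in ("h_osc", "v_osc"):
        t_end = max(t_end, config.oscillation_duration_s + 0.5)
    dt = 1.0 / config.sample_rate_hz
    t = np.arange(0.0, t_end + dt / 2.0, dt)
    vx, vy, _ = superpose(comps, t)
    x = np.concatenate([[0.0], cumulative_trapezoid(vx, t)])
    y = np.concatenate([[0.0], cumulative_trapezoid(vy, t)])
    traj = Trajectory(
        trial_id=f"{participant.participant}-{fatigue}-{condition}-{test_type}-{trial_index:03d}",
        test_type=test_type, participant=participant.participant,
        fatigue_type=fatigue, condition=condition,
        t=t, x=x, y=y, stimulus_time=0.0, ground_truth=comps,
    )
    if np.isfinite(config.noise_snr_db):
        traj = add_noise(traj, config.noise_snr_db, rng)
    return traj


def generate_session(config: PopulationConfig, seed: int,
                     tests: Iterable[str] = TEST_TYPES,
                     fatigue_types: Iterable[str] = FATIGUE_TYPES) -> dict:
    """Generate a full session: every participant x fatigue x condition x test.

    Oscillation tests produce a single trial; the other tests produce
    ``strokes_per_test`` trials.  Returns ``{"participants": [...],
    "trials": [Trajectory, ...]}`` and is a pure function of (config, seed).
    """
    rng = np.random.default_rng(seed)
    participants = sample_population(config, rng)
    trials: list[Trajectory] = []
    for participant in participants:
        for fatigue in fatigue_types:
            for condition in CONDITIONS:
                for test in tests:
                    n = 1 if test in ("h_osc", "v_osc") else config.strokes_per_test
                    for k in range(n):
                        trials.append(generate_trial(test, participant, fatigue,
                                                     condition, config, rng, k))
    return {"participants": participants, "trials": trials}


# ---------------------------------------------------------------------------
# Noise injection
# ---------------------------------------------------------------------------

def _central_diff(p: np.ndarray, dt: float) -> np.ndarray:
    v = np.empty_like(p)
    v[1:-1] = (p[2:] - p[:-2]) / (2.0 * dt)
    v[0] = (p[1] - p[0]) / dt
    v[-1] = (p[-1] - p[-2]) / dt
    return v


def measured_velocity_snr_db(clean: Trajectory, noisy: Trajectory) -> float:
    """Velocity-domain SNR between two equally sampled trajectories.

    Velocities are obtained by central differences of positions so the
    measurement matches what any downstream consumer of the positions sees.
    """
    dt = clean.dt
    vx, vy = _central_diff(clean.x, dt), _central_diff(clean.y, dt)
    nx, ny = _central_diff(noisy.x, dt), _central_diff(noisy.y, dt)
    signal = np.sum(vx**2 + vy**2)
    resid = np.sum((vx - nx) ** 2 + (vy - ny) ** 2)
    if resid == 0:
        return float("inf")
    return float(10.0 * np.log10(signal / resid))


def add_noise(trajectory: Trajectory, target_snr_db: float,
              rng: np.random.Generator) -> Trajectory:
    """Additive white velocity noise at an exact target SNR.

    Noise is drawn in the velocity domain, integrated into the positions,
    and scaled so that the SNR *as measured on central-difference
    velocities* equals the target.  Infinite target returns the input
    unchanged.
    """
    if math.isinf(target_snr_db):
        return trajectory
    if not (target_snr_db > 0 and math.isfinite(target_snr_db)):
        raise ValueError(f"target SNR must be positive and finite, got {target_snr_db}")
    dt = trajectory.dt
    unit_nx = rng.standard_normal(trajectory.t.size)
    unit_ny = rng.standard_normal(trajectory.t.size)
    px = np.concatenate([[0.0], cumulative_trapezoid(unit_nx, trajectory.t)])
    py = np.concatenate([[0.0], cumulative_trapezoid(unit_ny, trajectory.t)])
    vx, vy = _central_diff(trajectory.x, dt), _central_diff(trajectory.y, dt)
    signal_energy = np.sum(vx**2 + vy**2)
    noise_energy_unit = np.sum(_central_diff(px, dt) ** 2 + _central_diff(py, dt) ** 2)
    target_noise_energy = signal_energy / 10.0 ** (target_snr_db / 10.0)
    amp = math.sqrt(target_noise_energy / noise_energy_unit)
    noisy = copy.copy(trajectory)
    noisy.x = trajectory.x + amp * px
    noisy.y = trajectory.y + amp * py
    return noisy
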