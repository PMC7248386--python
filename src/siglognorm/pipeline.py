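"""End-to-end orchestration: simulate -> extract -> format -> analyze.

Stages exchange plain pandas DataFrames so that every intermediate artifact
can be written to (and re-read from) CSV.  The statistical stage follows
the battery's order: the multivariate Hotelling gate is evaluated before
any per-parameter group test.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import formatting, stats
from .extract import ExtractionConfig, decompose, estimate_speed
from .model import (
    LognormalComponent,
    UndefinedReactionTimeError,
    conduction_time,
    derived_parameters,
    reaction_time,
)
from .synth import (
    _TRIANGLE_BEARINGS,
    PopulationConfig,
    Trajectory,
    default_population_config,
    generate_session,
)

__all__ = [
    "extract_session",
    "format_components",
    "analyze_session",
    "run_pipeline",
    "COMPONENT_PARAMS",
    "individual_family",
    "group_family",
]

COMPONENT_PARAMS = [
    "t0", "D", "abs_cos_theta_s", "abs_cos_theta_e", "mu", "sigma",
    "mode", "median", "time_delay", "response_time", "asymmetry",
]
GLOBAL_PARAMS = ["nblog", "snr", "snr_per_nblog"]
OUTLIER_PARAMS = ["t0", "D", "mu", "sigma", "theta_s", "theta_e"]
_OSC_TESTS = ("h_osc", "v_osc")


def individual_family(test_type: str) -> list[str]:
    if test_type in _OSC_TESTS:
        return ["delta_t0", "D", "abs_cos_theta_s", "abs_cos_theta_e", "mu", "sigma",
                "mode", "median", "time_delay", "response_time", "asymmetry",
                "conduction"]
    return COMPONENT_PARAMS + GLOBAL_PARAMS + ["rt", "conduction"]


def group_family(test_type: str) -> list[str]:
    if test_type in _OSC_TESTS:
        return ["delta_t0", "D", "mu", "sigma", "mode", "median", "time_delay",
                "response_time", "asymmetry"] + GLOBAL_PARAMS
    return ["t0", "D", "abs_cos_theta_s", "abs_cos_theta_e", "mu", "sigma",
            "mode", "median", "time_delay", "response_time"] + GLOBAL_PARAMS


# ---------------------------------------------------------------------------
# Extraction stage
# ---------------------------------------------------------------------------

_TRIAL_KEYS = ("trial_id", "participant", "fatigue_type", "condition", "test_type")


def _trial_meta(trial: Trajectory) -> dict:
    return {
        "trial_id": trial.trial_id,
        "participant": trial.participant,
        "fatigue_type": trial.fatigue_type,
        "condition": trial.condition,
        "test_type": trial.test_type,
    }


def extract_session(
    trials: list[Trajectory],
    config: ExtractionConfig | None = None,
    use_ground_truth: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decompose every trial; returns (components table, trial-quality table).

    With ``use_ground_truth`` the embedded generator components stand in
    for the extractor output (useful for fast statistical studies); RT and
    SNR-style quality figures are still computed from the sampled signal.
    """
    config = config or ExtractionConfig()
    comp_rows, trial_rows = [], []
    for trial in trials:
        meta = _trial_meta(trial)
        vx, vy, speed = estimate_speed(trial.t, trial.x, trial.y, cutoff_hz=None)
        try:
            rt = reaction_time(speed, trial.t, trial.stimulus_time)
        except UndefinedReactionTimeError:
            rt = float("nan")
        if use_ground_truth:
            comps = list(trial.ground_truth or [])
            snr = 120.0
            low_quality = False
        else:
            result = decompose(trial, config)
            comps = result.components
            snr = result.snr_db
            low_quality = result.low_quality
        nblog = len(comps)
        bearing = math.atan2(trial.y[-1] - trial.y[0], trial.x[-1] - trial.x[0])
        trial_rows.append({
            **meta, "nblog": nblog, "snr": snr,
            "snr_per_nblog": snr / nblog if nblog else float("nan"),
            "rt": rt, "bearing": bearing, "low_quality": low_quality,
        })
        for k, c in enumerate(comps):
            comp_rows.append({
                **meta, "comp_index": k, "t0": c.t0, "D": c.D, "mu": c.mu,
                "sigma": c.sigma, "theta_s": c.theta_s, "theta_e": c.theta_e,
            })
    return pd.DataFrame(comp_rows), pd.DataFrame(trial_rows)


# ---------------------------------------------------------------------------
# Formatting stage
# ---------------------------------------------------------------------------

def _row_component(row: pd.Series) -> LognormalComponent:
    return LognormalComponent(t0=row["t0"], D=row["D"], mu=row["mu"],
                              sigma=row["sigma"], theta_s=row["theta_s"],
                              theta_e=row["theta_e"])


def _derived_columns(comp: LognormalComponent) -> dict:
    d = derived_parameters(comp)
    return {
        "abs_cos_theta_s": abs(math.cos(comp.theta_s)),
        "abs_cos_theta_e": abs(math.cos(comp.theta_e)),
        "mode": d.mode, "median": d.median, "time_delay": d.time_delay,
        "response_time": d.response_time, "asymmetry": d.asymmetry,
    }


def format_components(
    components: pd.DataFrame,
    trials: pd.DataFrame,
    triangle_bearings: tuple[float, float, float] = _TRIANGLE_BEARINGS,
    outlier_rejection: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Role-classify, phase-split, filter and derive per-component rows.

    Returns the classified component table and a retention summary.  Rows
    that are not selected for any role are kept with ``retained=False`` so
    the full provenance survives into the written artifacts.
    """
    trial_info = trials.set_index("trial_id")
    out_rows = []
    for trial_id, group in components.groupby("trial_id", sort=False):
        info = trial_info.loc[trial_id]
        test = info["test_type"]
        comps = [_row_component(r) for _, r in group.iterrows()]
        meta = {k: group.iloc[0][k] for k in _TRIAL_KEYS}
        rt = float(info["rt"])
        classified: list[tuple[int, formatting.ClassifiedComponent]] = []
        reason_all = None
        if test == "simple":
            ago, ant = formatting.classify_simple_stroke(comps, float(info["bearing"]))
            selected = {id(ago.component): ago}
            if ant is not None:
                selected[id(ant.component)] = ant
            for i, c in enumerate(comps):
                cc = selected.get(id(c))
                if cc is None:
                    cc = formatting.ClassifiedComponent(c, "unassigned", retained=False,
                                                        rejection_reason="unassigned")
                classified.append((i, cc))
        elif test == "triangle":
            try:
                assigned = formatting.assign_triangle_strokes(comps, triangle_bearings)
                selected = {id(cc.component): cc for cc in assigned}
                for i, c in enumerate(comps):
                    cc = selected.get(id(c))
                    if cc is None:
                        cc = formatting.ClassifiedComponent(c, "unassigned", retained=False,
                                                            rejection_reason="unassigned")
                    classified.append((i, cc))
            except formatting.TriangleRejection:
                reason_all = "invalid-reconstruction"
                for i, c in enumerate(comps):
                    classified.append((i, formatting.ClassifiedComponent(
                        c, "unassigned", retained=False,
                        rejection_reason=reason_all)))
        elif test in _OSC_TESTS:
            orientation = "horizontal" if test == "h_osc" else "vertical"
            ccs = formatting.split_oscillation_phases(comps, orientation)
            stable = sorted(
                (cc for cc in ccs if cc.retained and cc.phase == "stable"),
                key=lambda cc: cc.component.t0,
            )
            for prev, cur in zip(stable, stable[1:]):
                cur.delta_t0 = cur.component.t0 - prev.component.t0
            classified = list(enumerate(ccs))
        else:
            raise ValueError(f"unknown test type {test!r}")
        for i, cc in classified:
            comp = cc.component
            row = {
                **meta, "comp_index": i, "t0": comp.t0, "D": comp.D,
                "mu": comp.mu, "sigma": comp.sigma, "theta_s": comp.theta_s,
                "theta_e": comp.theta_e, "role": cc.role, "phase": cc.phase,
                "delta_t0": cc.delta_t0, "retained": cc.retained,
                "rejection_reason": cc.rejection_reason,
                **_derived_columns(comp),
                "rt": rt,
            }
            if test in _OSC_TESTS:
                row["conduction"] = (
                    abs(cc.delta_t0 - rt)
                    if cc.delta_t0 is not None and np.isfinite(rt) else float("nan")
                )
            else:
                row["conduction"] = (
                    conduction_time(comp.t0, rt)
                    if cc.retained and np.isfinite(rt) else float("nan")
                )
            out_rows.append(row)
    table = pd.DataFrame(out_rows)
    summary: dict = {"pre_outlier_retained_fraction": float(table["retained"].mean())}
    if outlier_rejection and len(table):
        candidates = table[table["retained"]]
        filtered, reject_summary = formatting.reject_outliers(
            candidates,
            group_cols=["participant", "fatigue_type", "condition", "test_type", "role"],
            param_cols=OUTLIER_PARAMS,
        )
        dropped = filtered.index[~filtered["retained"]]
        table.loc[dropped, "retained"] = False
        table.loc[dropped, "rejection_reason"] = "outlier"
        summary["outlier_pass"] = {k: v for k, v in reject_summary.items() if k != "small_groups"}
        summary["retained_fraction_by_test"] = {
            test: float(sub["retained"].mean())
            for test, sub in table.groupby("test_type")
        }
    return table, summary


# ---------------------------------------------------------------------------
# Analysis stage
# ---------------------------------------------------------------------------

def _series_for(
    classified: pd.DataFrame, trials: pd.DataFrame,
    participant: str, test: str, fatigue: str, condition: str,
    role: str | None, param: str,
) -> np.ndarray:
    """Observations of one parameter for one cell of the design."""
    if param in GLOBAL_PARAMS or param == "rt":
        sub = trials[(trials["participant"] == participant)
                     & (trials["test_type"] == test)
                     & (trials["fatigue_type"] == fatigue)
                     & (trials["condition"] == condition)]
        return sub[param].dropna().to_numpy()
    sub = classified[(classified["participant"] == participant)
                     & (classified["test_type"] == test)
                     & (classified["fatigue_type"] == fatigue)
                     & (classified["condition"] == condition)
                     & classified["retained"]]
    if role is not None:
        sub = sub[sub["role"] == role]
    if test in _OSC_TESTS:
        sub = sub[sub["phase"] == "stable"]
    return sub[param].dropna().to_numpy()


def _roles_for(test: str) -> list[str]:
    if test == "simple":
        return ["agonist", "antagonist"]
    if test == "triangle":
        return ["stroke1", "stroke2", "stroke3"]
    return ["osc_ER", "osc_IR"]


def individual_reports(
    classified: pd.DataFrame, trials: pd.DataFrame, alpha: float = 0.05
) -> list[stats.ComparisonReport]:
    """Per-participant pre/post rank tests, Bonferroni-corrected per family."""
    reports = []
    cells = classified[["participant", "test_type", "fatigue_type"]].drop_duplicates()
    for _, cell in cells.iterrows():
        participant, test, fatigue = cell
        family = individual_family(test)
        threshold = stats.bonferroni_threshold(alpha, len(family))
        for role in _roles_for(test):
            rep = stats.ComparisonReport(
                level="individual", test_type=test, fatigue_type=fatigue, role=role,
                alpha=alpha, family_size=len(family),
                metadata={"participant": participant},
            )
            for param in family:
                pre = _series_for(classified, trials, participant, test, fatigue,
                                  "pre", role, param)
                post = _series_for(classified, trials, participant, test, fatigue,
                                   "post", role, param)
                if pre.size < 2 or post.size < 2:
                    rep.parameters[param] = stats.ParameterResult(
                        param, float("nan"), False, n_pre=pre.size, n_post=post.size)
                    continue
                _, p = stats.mann_whitney(pre, post)
                rep.parameters[param] = stats.ParameterResult(
                    param, p, bool(p < threshold), n_pre=pre.size, n_post=post.size)
            reports.append(rep)
    return reports


def _participant_means(
    classified: pd.DataFrame, trials: pd.DataFrame,
    test: str, fatigue: str, condition: str, role: str | None, params: list[str],
) -> pd.DataFrame:
    participants = sorted(classified["participant"].unique())
    rows = {}
    for p in participants:
        rows[p] = {
            param: float(np.mean(vals)) if (vals := _series_for(
                classified, trials, p, test, fatigue, condition, role, param)).size
            else float("nan")
            for param in params
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def group_reports(
    classified: pd.DataFrame, trials: pd.DataFrame,
    alpha: float = 0.05, n_perm: int = 10_000, seed: int = 0,
) -> list[stats.ComparisonReport]:
    """Hotelling-gated group comparisons with effect sizes.

    The multivariate gate uses role-pooled participant means of the group
    parameter family; per-parameter signed-rank tests (run only when the
    gate opens) treat simple-stroke agonist and antagonist components
    separately, except for the whole-signal quality parameters.
    """
    reports = []
    cells = classified[["test_type", "fatigue_type"]].drop_duplicates()
    for _, (test, fatigue) in cells.iterrows():
        family = group_family(test)
        threshold = stats.bonferroni_threshold(alpha, len(family))
        pre_m = _participant_means(classified, trials, test, fatigue, "pre", None, family)
        post_m = _participant_means(classified, trials, test, fatigue, "post", None, family)
        try:
            t2, gate_p = stats.hotelling_t2_paired(
                pre_m.to_numpy(), post_m.to_numpy(), n_perm=n_perm, seed=seed)
        except ValueError:
            t2, gate_p = float("nan"), float("nan")
        gate_open = bool(gate_p < 0.05) if np.isfinite(gate_p) else False
        roles: list[str | None] = ["agonist", "antagonist"] if test == "simple" else [None]
        for role in roles:
            rep = stats.ComparisonReport(
                level="group", test_type=test, fatigue_type=fatigue, role=role,
                alpha=alpha, family_size=len(family), multivariate_p=gate_p,
                metadata={"hotelling_t2": t2, "gate_open": gate_open,
                          "n_perm": n_perm, "seed": seed},
            )
            if gate_open:
                for param in family:
                    # whole-signal quality parameters are not split by role
                    use_role = None if param in GLOBAL_PARAMS else role
                    pre = _participant_means(classified, trials, test, fatigue,
                                             "pre", use_role, [param])[param]
                    post = _participant_means(classified, trials, test, fatigue,
                                              "post", use_role, [param])[param]
                    paired = pd.DataFrame({"pre": pre, "post": post}).dropna()
                    if len(paired) < 6:
                        rep.parameters[param] = stats.ParameterResult(
                            param, float("nan"), False,
                            n_pre=len(paired), n_post=len(paired))
                        continue
                    p = stats.wilcoxon_group(paired["pre"], paired["post"])
                    try:
                        d, mag = stats.cohens_d(paired["pre"], paired["post"])
                    except ValueError:
                        d, mag = float("nan"), None
                    rep.parameters[param] = stats.ParameterResult(
                        param, p, bool(p < threshold), d=d, magnitude=mag,
                        n_pre=len(paired), n_post=len(paired))
            reports.append(rep)
    return reports


def analyze_session(
    classified: pd.DataFrame, trials: pd.DataFrame,
    alpha: float = 0.05, n_perm: int = 10_000, seed: int = 0,
) -> dict:
    individual = individual_reports(classified, trials, alpha)
    group = group_reports(classified, trials, alpha, n_perm, seed)
    population = stats.summarize_population(individual)
    return {"individual": individual, "group": group, "population": population}


def run_pipeline(
    config: PopulationConfig | None = None,
    seed: int = 0,
    extraction: ExtractionConfig | None = None,
    tests: tuple[str, ...] = ("simple", "triangle", "h_osc", "v_osc"),
    fatigue_types: tuple[str, ...] = ("ER", "IR"),
    use_ground_truth: bool = False,
    alpha: float = 0.05,
    n_perm: int = 10_000,
) -> dict:
    """Simulate a session and run extraction, formatting and statistics.

    Deterministic for fixed (config, seed).  Returns all intermediate
    tables plus the report set.
    """
    config = config or default_population_config()
    session = generate_session(config, seed, tests=tests, fatigue_types=fatigue_types)
    components, trials = extract_session(session["trials"], extraction,
                                         use_ground_truth=use_ground_truth)
    classified, retention = format_components(components, trials)
    reports = analyze_session(classified, trials, alpha=alpha, n_perm=n_perm, seed=seed)
    return {
        "session": session,
        "components": components,
        "trials": trials,
        "classified": classified,
        "retention": retention,
        **reports,
        "seed": seed,
    }
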