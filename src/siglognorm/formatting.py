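"""Post-extraction data formatting.

Assigns each extracted lognormal a functional role (agonist/antagonist for
simple strokes, stroke 1-3 for triangles, rotation direction and movement
phase for oscillations), filters artifacts and statistical outliers, and
computes the oscillation rhythm intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import DerivedParams, LognormalComponent, derived_parameters

__all__ = [
    "ClassifiedComponent",
    "TriangleRejection",
    "classify_simple_stroke",
    "assign_triangle_strokes",
    "split_oscillation_phases",
    "delta_t0",
    "reject_outliers",
    "ARTIFACT_AMPLITUDE_MM",
    "PHASE_BOUNDARIES_S",
]

ARTIFACT_AMPLITUDE_MM = 50.0
PHASE_BOUNDARIES_S = (2.0, 10.0)


@dataclass
class ClassifiedComponent:
    """A lognormal annotated with its functional role."""

    component: LognormalComponent
    role: str                      # agonist|antagonist|stroke1..3|osc_ER|osc_IR
    phase: str | None = None       # acceleration|stable|deceleration (oscillations)
    derived: DerivedParams | None = None
    delta_t0: float | None = None
    retained: bool = True
    rejection_reason: str | None = None

    def __post_init__(self) -> None:
        if self.derived is None:
            self.derived = derived_parameters(self.component)


class TriangleRejection(Exception):
    """A triangle trial whose reconstruction does not match the sides."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def _is_agonist(theta_s: float, bearing: float) -> bool:
    # strict inequality: a component exactly orthogonal counts as
    # antagonist (tolerance absorbs the rounding of pi/2 differences)
    return math.cos(theta_s - bearing) > 1e-12


def classify_simple_stroke(
    components: Sequence[LognormalComponent], bearing: float
) -> tuple[ClassifiedComponent, ClassifiedComponent | None]:
    """Pick the largest agonist and largest antagonist component.

    A component is agonist iff its starting angle points with the movement
    bearing (cos(theta_s - bearing) > 0).  Single-component strokes are
    classified as agonists regardless of angle.  Returns ``(agonist,
    antagonist_or_None)``; when several components share a side, the
    largest-amplitude one is selected.
    """
    if len(components) == 0:
        raise ValueError("classify_simple_stroke requires at least one component")
    if len(components) == 1:
        return ClassifiedComponent(components[0], "agonist"), None
    agonists = [c for c in components if _is_agonist(c.theta_s, bearing)]
    antagonists = [c for c in components if not _is_agonist(c.theta_s, bearing)]
    largest = max(components, key=lambda c: c.D)
    agonist = max(agonists, key=lambda c: c.D) if agonists else largest
    antagonist = max(antagonists, key=lambda c: c.D) if antagonists else None
    if antagonist is agonist:
        antagonist = None
    return ClassifiedComponent(agonist, "agonist"), (
        ClassifiedComponent(antagonist, "antagonist") if antagonist else None
    )


def assign_triangle_strokes(
    components: Sequence[LognormalComponent], stroke_bearings: Sequence[float]
) -> list[ClassifiedComponent]:
    """Map the three largest components, in t0 order, to strokes 1-3.

    Raises :class:`TriangleRejection` when fewer than three components are
    available or when any mapped component's starting angle does not point
    toward its side's bearing.
    """
    if len(stroke_bearings) != 3:
        raise ValueError("three stroke bearings are required")
    if len(components) < 3:
        raise TriangleRejection("fewer than three components")
    dominant = sorted(sorted(components, key=lambda c: -c.D)[:3], key=lambda c: c.t0)
    out = []
    for k, (comp, bearing) in enumerate(zip(dominant, stroke_bearings), start=1):
        if math.cos(comp.theta_s - bearing) <= 0.0:
            raise TriangleRejection(f"stroke {k} does not point toward its side")
        out.append(ClassifiedComponent(comp, f"stroke{k}"))
    return out


def _phase_of(t0: float) -> str:
    lo, hi = PHASE_BOUNDARIES_S
    if t0 < lo:
        return "acceleration"
    if t0 < hi:
        return "stable"
    return "deceleration"


def split_oscillation_phases(
    components: Sequence[LognormalComponent], orientation: str
) -> list[ClassifiedComponent]:
    """Phase-bin and direction-label oscillation components.

    Phase from t0 (left-closed bins at 2 s and 10 s).  Components with
    amplitude below 50 mm are flagged as artifacts.  Direction: positive
    cos(theta_s) (horizontal) or sin(theta_s) (vertical) -> external
    rotation (``osc_ER``), otherwise internal (``osc_IR``).
    """
    if orientation not in ("horizontal", "vertical"):
        raise ValueError(f"orientation must be horizontal|vertical, got {orientation!r}")
    out = []
    for comp in components:
        proj = math.cos(comp.theta_s) if orientation == "horizontal" else math.sin(comp.theta_s)
        role = "osc_ER" if proj > 0 else "osc_IR"
        cc = ClassifiedComponent(comp, role, phase=_phase_of(comp.t0))
        if comp.D < ARTIFACT_AMPLITUDE_MM:
            cc.retained = False
            cc.rejection_reason = "artifact"
        out.append(cc)
    return out


def delta_t0(components: Sequence[LognormalComponent]) -> list[float]:
    """Successive differences of ascending-sorted command times.

    Empty when fewer than two components are given.
    """
    t0s = sorted(c.t0 for c in components)
    return [b - a for a, b in zip(t0s, t0s[1:])]


def reject_outliers(
    table: pd.DataFrame,
    group_cols: Sequence[str],
    param_cols: Sequence[str],
    n_sd: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Single-pass mean +/- 3 SD outlier rejection within groups.

    A row is dropped iff ANY monitored parameter lies outside its group's
    mean +/- ``n_sd`` * SD, with bounds computed from the unfiltered group.
    Groups with fewer than two rows are kept unchanged and flagged.

    Returns the annotated table (``retained`` and ``rejection_reason``
    columns added) and a summary dict with per-group retention and the
    overall retained fraction.
    """
    out = table.copy()
    out["retained"] = True
    out["rejection_reason"] = None
    small_groups = []
    for key, idx in out.groupby(list(group_cols), sort=False, dropna=False).groups.items():
        sub = out.loc[idx, list(param_cols)]
        if len(idx) < 2:
            small_groups.append(key)
            continue
        mean = sub.mean()
        sd = sub.std(ddof=1)
        bad = ((sub - mean).abs() > n_sd * sd).any(axis=1)
        out.loc[idx[bad.to_numpy()], "retained"] = False
        out.loc[idx[bad.to_numpy()], "rejection_reason"] = "outlier"
    retained_fraction = float(out["retained"].mean()) if len(out) else float("nan")
    summary = {
        "retained_fraction": retained_fraction,
        "n_rows": int(len(out)),
        "n_rejected": int((~out["retained"]).sum()),
        "small_groups": small_groups,
    }
    return out, summary
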