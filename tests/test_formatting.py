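import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from siglognorm.formatting import (
    ARTIFACT_AMPLITUDE_MM,
    TriangleRejection,
    assign_triangle_strokes,
    classify_simple_stroke,
    delta_t0,
    reject_outliers,
    split_oscillation_phases,
)
from siglognorm.model import LognormalComponent


def comp(t0=0.2, D=100.0, mu=-1.4, sigma=0.3, theta_s=0.0, theta_e=None):
    return LognormalComponent(t0=t0, D=D, mu=mu, sigma=sigma, theta_s=theta_s,
                              theta_e=theta_s if theta_e is None else theta_e)


class TestClassifySimpleStroke:
    def test_single_component_is_agonist(self):
        ago, ant = classify_simple_stroke([comp(theta_s=0.0)], bearing=0.0)
        assert ago.role == "agonist" and ant is None

    def test_single_component_is_agonist_even_when_opposed(self):
        ago, ant = classify_simple_stroke([comp(theta_s=math.pi)], bearing=0.0)
        assert ago.role == "agonist" and ant is None

    def test_opposed_component_is_antagonist(self):
        components = [comp(theta_s=0.0, D=200.0), comp(theta_s=math.pi, D=30.0)]
        ago, ant = classify_simple_stroke(components, bearing=0.0)
        assert ago.component.D == 200.0
        assert ant is not None and ant.component.D == 30.0

    def test_largest_amplitude_wins_per_side(self):
        candidates = [comp(theta_s=0.1, D=d) for d in (50.0, 150.0, 90.0)]
        candidates += [comp(theta_s=math.pi, D=20.0)]
        ago, _ = classify_simple_stroke(candidates, bearing=0.0)
        # brute-force oracle over the agonist-side set
        best = max(candidates[:3], key=lambda c: c.D)
        assert ago.component is best

    def test_exactly_orthogonal_counts_as_antagonist(self):
        components = [comp(theta_s=0.0, D=100.0),
                      comp(theta_s=math.pi / 2.0, D=40.0)]
        _, ant = classify_simple_stroke(components, bearing=0.0)
        assert ant is not None and ant.component.D == 40.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_simple_stroke([], bearing=0.0)

    @given(rotation=st.floats(-math.pi, math.pi))
    @settings(max_examples=40, deadline=None)
    def test_rotation_invariance(self, rotation):
        components = [comp(theta_s=0.2, D=200.0), comp(theta_s=0.2 + math.pi, D=30.0)]
        rotated = [comp(t0=c.t0, D=c.D, mu=c.mu, sigma=c.sigma,
                        theta_s=c.theta_s + rotation) for c in components]
        ago_a, ant_a = classify_simple_stroke(components, bearing=0.2)
        ago_b, ant_b = classify_simple_stroke(rotated, bearing=0.2 + rotation)
        assert ago_a.component.D == ago_b.component.D
        assert (ant_a is None) == (ant_b is None)


BEARINGS = (0.0, -2.0 * math.pi / 3.0, 2.0 * math.pi / 3.0)


class TestAssignTriangleStrokes:
    def make_triangle(self):
        return [comp(t0=0.2, D=150.0, theta_s=BEARINGS[0]),
                comp(t0=0.8, D=140.0, theta_s=BEARINGS[1]),
                comp(t0=1.4, D=145.0, theta_s=BEARINGS[2])]

    def test_three_largest_in_t0_order(self):
        comps = self.make_triangle() + [comp(t0=0.5, D=10.0, theta_s=1.0),
                                        comp(t0=1.1, D=12.0, theta_s=-1.0)]
        assigned = assign_triangle_strokes(comps, BEARINGS)
        assert [cc.role for cc in assigned] == ["stroke1", "stroke2", "stroke3"]
        assert [cc.component.t0 for cc in assigned] == [0.2, 0.8, 1.4]

    def test_antialigned_dominant_rejected(self):
        comps = self.make_triangle()
        comps[1] = comp(t0=0.8, D=140.0, theta_s=BEARINGS[1] + math.pi)
        with pytest.raises(TriangleRejection):
            assign_triangle_strokes(comps, BEARINGS)

    def test_too_few_components_rejected(self):
        with pytest.raises(TriangleRejection):
            assign_triangle_strokes(self.make_triangle()[:2], BEARINGS)


class TestOscillationPhases:
    def test_phase_binning(self):
        comps = [comp(t0=1.5, D=120.0), comp(t0=5.0, D=120.0), comp(t0=11.0, D=120.0)]
        phases = [cc.phase for cc in split_oscillation_phases(comps, "horizontal")]
        assert phases == ["acceleration", "stable", "deceleration"]

    def test_boundaries_left_closed(self):
        comps = [comp(t0=2.0, D=120.0), comp(t0=10.0, D=120.0)]
        phases = [cc.phase for cc in split_oscillation_phases(comps, "horizontal")]
        assert phases == ["stable", "deceleration"]

    def test_small_amplitude_is_artifact(self):
        cc, = split_oscillation_phases([comp(t0=3.0, D=40.0)], "horizontal")
        assert not cc.retained and cc.rejection_reason == "artifact"
        assert ARTIFACT_AMPLITUDE_MM == 50.0

    def test_direction_rule_horizontal(self):
        cc, = split_oscillation_phases([comp(t0=3.0, D=120.0, theta_s=0.3)],
                                       "horizontal")
        assert cc.role == "osc_ER"
        cc, = split_oscillation_phases([comp(t0=3.0, D=120.0, theta_s=2.9)],
                                       "horizontal")
        assert cc.role == "osc_IR"

    def test_direction_rule_vertical_uses_sine(self):
        cc, = split_oscillation_phases([comp(t0=3.0, D=120.0, theta_s=1.2)],
                                       "vertical")
        assert cc.role == "osc_ER"
        cc, = split_oscillation_phases([comp(t0=3.0, D=120.0, theta_s=-1.2)],
                                       "vertical")
        assert cc.role == "osc_IR"

    def test_unknown_orientation_rejected(self):
        with pytest.raises(ValueError):
            split_oscillation_phases([], "diagonal")


class TestDeltaT0:
    def test_arithmetic_progression(self):
        comps = [comp(t0=2.1 + 0.09 * k, D=120.0) for k in range(5)]
        assert np.allclose(delta_t0(comps), 0.09)

    def test_single_component_empty(self):
        assert delta_t0([comp()]) == []

    def test_unsorted_matches_sort_then_diff(self, rng):
        t0s = rng.uniform(2.0, 9.0, size=12)
        comps = [comp(t0=v, D=120.0) for v in t0s]
        oracle = np.diff(np.sort(t0s)).tolist()
        assert np.allclose(delta_t0(comps), oracle)


class TestRejectOutliers:
    def make_table(self, mus):
        return pd.DataFrame({
            "participant": "P01", "test_type": "simple", "role": "agonist",
            "t0": 0.2, "D": 100.0, "mu": mus, "sigma": 0.3,
            "theta_s": 0.0, "theta_e": 0.0,
        })

    GROUPS = ["participant", "test_type", "role"]
    PARAMS = ["t0", "D", "mu", "sigma"]

    def test_identical_rows_all_kept(self):
        out, summary = reject_outliers(self.make_table([0.5] * 10),
                                       self.GROUPS, self.PARAMS)
        assert out["retained"].all()
        assert summary["retained_fraction"] == 1.0

    def test_planted_outlier_dropped(self, rng):
        mus = rng.normal(-1.4, 0.1, size=30)
        mean, sd = mus.mean(), mus.std(ddof=1)
        mus[7] = mean + 5.0 * sd
        table = self.make_table(mus)
        # brute-force oracle with bounds from the unfiltered data
        mean, sd = table["mu"].mean(), table["mu"].std(ddof=1)
        oracle = (table["mu"] - mean).abs() <= 3 * sd
        out, _ = reject_outliers(table, self.GROUPS, self.PARAMS)
        assert out["retained"].tolist() == oracle.tolist()
        assert not out.loc[7, "retained"]

    def test_any_single_parameter_out_drops_row(self, rng):
        table = self.make_table(list(rng.normal(-1.4, 0.1, size=30)))
        table.loc[3, "sigma"] = 5.0  # only sigma is extreme
        out, _ = reject_outliers(table, self.GROUPS, self.PARAMS)
        assert not out.loc[3, "retained"]
        assert out.loc[3, "rejection_reason"] == "outlier"

    def test_small_groups_kept_and_flagged(self):
        out, summary = reject_outliers(self.make_table([0.1]),
                                       self.GROUPS, self.PARAMS)
        assert out["retained"].all()
        assert len(summary["small_groups"]) == 1

    def test_single_pass_semantics(self, rng):
        # re-running on the filtered table must use recomputed bounds; the
        # first pass itself never iterates
        mus = list(rng.normal(0.0, 1.0, size=40)) + [8.0]
        table = self.make_table(mus)
        out, _ = reject_outliers(table, self.GROUPS, self.PARAMS)
        n_first = int((~out["retained"]).sum())
        assert n_first == 1
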