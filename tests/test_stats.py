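import itertools

import numpy as np
import pandas as pd
import pytest

from siglognorm.stats import (
    ComparisonReport,
    ParameterResult,
    bonferroni_threshold,
    cohens_d,
    effect_size_label,
    hotelling_t2_paired,
    mann_whitney,
    spearman_matrix,
    summarize_population,
    wilcoxon_group,
)


class TestBonferroni:
    def test_printed_oscillation_threshold(self):
        assert float(f"{bonferroni_threshold(0.05, 12):.2g}") == 0.0042

    def test_printed_group_threshold(self):
        assert float(f"{bonferroni_threshold(0.05, 13):.3g}") == 0.00385

    def test_single_comparison(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_family_size(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 4)


class TestMannWhitney:
    def test_u_matches_exhaustive_pair_count(self):
        pre, post = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        u, _ = mann_whitney(pre, post)
        wins = sum(a > b for a, b in itertools.product(pre, post))
        assert u == wins == 0

    def test_identical_samples_p_one(self):
        sample = [1.0, 2.0, 3.0, 4.0]
        _, p = mann_whitney(sample, sample)
        assert p == pytest.approx(1.0)

    def test_null_simulation_rarely_significant(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(500):
            pre = rng.normal(size=30)
            post = rng.normal(size=30)
            _, p = mann_whitney(pre, post)
            hits += p <= 0.0042
        assert hits <= 5  # >= 99% of repeats above the threshold

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [2.0, 3.0])


class TestHotelling:
    def test_identical_matrices(self):
        pre = np.random.default_rng(1).normal(size=(12, 4))
        t2, p = hotelling_t2_paired(pre, pre, n_perm=500, seed=0)
        assert t2 == 0.0 and p == 1.0

    def test_matches_classic_statistic(self):
        rng = np.random.default_rng(2)
        pre = rng.normal(size=(15, 4))
        post = pre + rng.normal(size=(15, 4))
        t2, _ = hotelling_t2_paired(pre, post, n_perm=100, seed=0)
        d = post - pre
        m = d.mean(axis=0)
        ref = 15 * m @ np.linalg.solve(np.cov(d, rowvar=False, ddof=1), m)
        assert t2 == pytest.approx(ref, rel=1e-9)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(size=(10, 3))
        post = pre + rng.normal(size=(10, 3))
        a = hotelling_t2_paired(pre, post, n_perm=2000, seed=11)
        b = hotelling_t2_paired(pre, post, n_perm=2000, seed=11)
        assert a == b

    def test_power_with_single_shifted_parameter(self):
        hits = 0
        for rep in range(200):
            rng = np.random.default_rng(500 + rep)
            pre = rng.normal(size=(20, 5))
            post = pre + rng.normal(size=(20, 5))
            post[:, 0] += 1.5
            _, p = hotelling_t2_paired(pre, post, n_perm=10_000, seed=rep)
            hits += p < 0.05
        assert hits >= 190  # >= 95% of 200 repeats

    def test_missing_rows_dropped(self):
        rng = np.random.default_rng(4)
        pre = rng.normal(size=(10, 3))
        post = pre + rng.normal(size=(10, 3))
        pre[0, 0] = np.nan
        t2, p = hotelling_t2_paired(pre, post, n_perm=200, seed=0)
        assert np.isfinite(t2) and 0 < p <= 1


class TestWilcoxonGroup:
    def test_constant_shift_minimal_p(self):
        pre = np.arange(20, dtype=float)
        post = pre + 1.0
        assert wilcoxon_group(pre, post) < 0.001

    def test_identical_returns_one(self):
        pre = np.arange(10, dtype=float)
        assert wilcoxon_group(pre, pre) == 1.0

    def test_minimum_pairs_enforced(self):
        with pytest.raises(ValueError):
            wilcoxon_group([1.0] * 5, [2.0] * 5)

    def test_exact_minimum_p_matches_enumeration(self):
        # all-positive differences, n=20: exact two-sided p = 2/2^20
        pre = np.zeros(20)
        post = np.arange(1.0, 21.0)
        assert wilcoxon_group(pre, post) == pytest.approx(2.0 / 2**20, rel=1e-9)


class TestCohensD:
    def test_equal_means(self):
        d, label = cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert d == 0.0 and label == "very small"

    @pytest.mark.parametrize("d,expected", [
        (0.66, "medium"), (0.93, "large"), (0.25, "small"),
        (1.3, "very large"), (2.4, "huge"), (0.005, "very small"),
        (-0.66, "medium"),
    ])
    def test_label_scale(self, d, expected):
        assert effect_size_label(d) == expected

    def test_hand_computed_value(self):
        # post - pre = 1.0; pooled SD = 0.5 by construction
        pre = [0.0, 0.5, -0.5]
        post = [1.0, 1.5, 0.5]
        d, label = cohens_d(pre, post)
        assert d == pytest.approx(1.0 / 0.5)
        assert label == "huge"

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestSpearman:
    def test_monotone_pairs(self):
        table = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 4, 6, 8, 10],
                              "c": [5, 4, 3, 2, 1]})
        rho, _ = spearman_matrix(table)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_six_point_table_matches_rank_formula(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        table = pd.DataFrame({"a": a, "b": b})
        rho, _ = spearman_matrix(table)
        ra = pd.Series(a).rank().to_numpy()
        rb = pd.Series(b).rank().to_numpy()
        d2 = np.sum((ra - rb) ** 2)
        oracle = 1.0 - 6.0 * d2 / (6 * 35)
        assert rho.loc["a", "b"] == pytest.approx(oracle)

    def test_constant_column_flagged_nan(self):
        table = pd.DataFrame({"a": [1, 2, 3, 4], "b": [7, 7, 7, 7]})
        rho, p = spearman_matrix(table)
        assert np.isnan(rho.loc["a", "b"]) and np.isnan(p.loc["a", "b"])


def _individual_report(participant, flags):
    rep = ComparisonReport(level="individual", test_type="simple",
                           fatigue_type="ER", role="agonist",
                           family_size=16, metadata={"participant": participant})
    for name, sig in flags.items():
        rep.parameters[name] = ParameterResult(name, 0.001 if sig else 0.5, sig)
    return rep


class TestSummarizePopulation:
    def test_no_flags_all_zero(self):
        reports = [_individual_report(f"P{k:02d}", {"t0": False, "mu": False})
                   for k in range(20)]
        out = summarize_population(reports, n_participants=20)
        assert (out[["central", "peripheral", "both"]] == 0.0).all().all()

    def test_crafted_central_percentage(self):
        reports = [_individual_report(f"P{k:02d}", {"t0": k < 7, "mu": False})
                   for k in range(20)]
        out = summarize_population(reports, n_participants=20)
        row = out[out["role"] == "agonist"].iloc[0]
        assert row["central"] == pytest.approx(35.0)

    def test_both_bounded_by_each_system(self, rng):
        reports = []
        for k in range(20):
            reports.append(_individual_report(
                f"P{k:02d}", {"t0": bool(rng.integers(2)),
                              "mu": bool(rng.integers(2)),
                              "sigma": bool(rng.integers(2))}))
        out = summarize_population(reports, n_participants=20)
        assert (out["both"] <= out["central"] + 1e-9).all()
        assert (out["both"] <= out["peripheral"] + 1e-9).all()

    def test_category_flags_and_threshold(self):
        rep = _individual_report("P01", {"t0": True, "mu": False})
        flags = rep.category_flags()
        assert flags["central"] and not flags["peripheral"] and not flags["both"]
        assert rep.threshold == pytest.approx(0.05 / 16)
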