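"""Scoring pipeline: outlier filter, collectives, medians, pass/fail."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ringtrial.evaluation import (
    DegenerateConsensusError,
    EmptyCollectiveError,
    EvaluationError,
    OTHER_CODE,
    certificate,
    certificates,
    consensus_median,
    evaluate_class_results,
    evaluate_concentrations,
    filter_outliers,
    form_collectives,
    pass_rate,
    score_participant,
)
from conftest import make_results


class TestFilterOutliers:
    def test_concentration_threshold_is_strict_20_percent(self, devices):
        res = make_results([
            ("P1", "F1", 120.0, None),    # exactly +20 %: kept
            ("P2", "F1", 120.01, None),   # more than +20 %: excluded
        ])
        included, excluded = filter_outliers(res, devices)
        assert list(included["participant_id"]) == ["P1"]
        assert list(excluded["participant_id"]) == ["P2"]
        assert "top calibration" in excluded["exclusion_reason"].iloc[0]

    def test_class_threshold_is_strict_half_class(self, devices):
        res = make_results([
            ("P1", "F1", None, 6.5),   # exactly ceiling + 0.5: kept
            ("P2", "F1", None, 6.6),   # beyond: excluded
        ])
        included, excluded = filter_outliers(res, devices)
        assert list(included["participant_id"]) == ["P1"]
        assert list(excluded["participant_id"]) == ["P2"]

    def test_empty_input_passes_through(self, devices):
        res = make_results([])
        included, excluded = filter_outliers(res, devices)
        assert included.empty and excluded.empty

    def test_missing_device_profile_names_the_code(self, devices):
        res = make_results([("P1", "F999", 10.0, 2)])
        with pytest.raises(KeyError, match="F999"):
            filter_outliers(res, devices)

    def test_row_order_never_changes_the_split(self, devices):
        rows = [(f"P{i}", "F1", v, None) for i, v in enumerate(
            [5.0, 130.0, 80.0, 121.0, 119.9, 200.0])]
        res = make_results(rows)
        base_inc, base_exc = filter_outliers(res, devices)
        shuffled = res.sample(frac=1.0, random_state=7)
        inc, exc = filter_outliers(shuffled, devices)
        assert set(inc["participant_id"]) == set(base_inc["participant_id"])
        assert set(exc["participant_id"]) == set(base_exc["participant_id"])


class TestFormCollectives:
    def brute_force_partition(self, res, min_size=4):
        """Independent oracle: dict of manufacturer -> size, pooling small ones."""
        sizes = res.groupby("manufacturer_code").size().to_dict()
        out = {}
        other = 0
        for code, n in sizes.items():
            if n >= min_size:
                out[code] = n
            else:
                other += n
        if other:
            out[OTHER_CODE] = other
        return out

    def test_small_groups_pool_into_other(self, results_factory):
        rows = (
            [(f"A{i}", "F1", 10.0, 2) for i in range(5)]
            + [(f"B{i}", "F2", 10.0, 2) for i in range(3)]
            + [(f"C{i}", "F3", 10.0, 2) for i in range(2)]
        )
        res = results_factory(rows)
        colls = {c.manufacturer_code: c.n for c in form_collectives(res)}
        assert colls == {"F1": 5, OTHER_CODE: 5}
        assert colls == self.brute_force_partition(res)

    def test_exactly_four_forms_own_collective(self, results_factory):
        res = results_factory([(f"A{i}", "F1", 10.0, 2) for i in range(4)])
        colls = {c.manufacturer_code: c.n for c in form_collectives(res)}
        assert colls == {"F1": 4}

    def test_all_singletons_form_single_other(self, results_factory):
        res = results_factory([(f"P{i}", f"F{200+i}", 10.0, 2) for i in range(6)])
        colls = form_collectives(res)
        assert len(colls) == 1
        assert colls[0].manufacturer_code == OTHER_CODE and colls[0].n == 6

    @given(st.lists(st.integers(min_value=1, max_value=8), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_partition_matches_brute_force_and_covers_everything(self, sizes):
        rows = []
        for g, n in enumerate(sizes):
            rows += [(f"G{g}P{i}", f"M{g}", 10.0, 2) for i in range(n)]
        res = make_results(rows)
        colls = form_collectives(res)
        assert {c.manufacturer_code: c.n for c in colls} == self.brute_force_partition(res)
        all_members = pd.concat([c.members for c in colls]) if colls else res.iloc[0:0]
        assert sorted(all_members["participant_id"]) == sorted(res["participant_id"])


class TestConsensusMedian:
    def test_odd_count(self):
        assert consensus_median([1, 2, 3]) == 2

    def test_even_count_uses_midpoint(self):
        # sort-and-midpoint oracle: sorted [1,2,3,10] -> (2+3)/2
        assert consensus_median([1, 2, 3, 10]) == 2.5

    def test_relevance_range_can_empty_the_collective(self):
        with pytest.raises(EmptyCollectiveError):
            consensus_median([5, 5, 5], relevance_range=(0, 4))

    def test_relevance_range_restricts_the_median(self):
        assert consensus_median([1, 2, 3, 100], relevance_range=(0, 50)) == 2

    @given(st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_sort_based_oracle(self, values):
        s = sorted(values)
        n = len(s)
        oracle = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
        assert consensus_median(values) == pytest.approx(oracle, rel=1e-12)


class TestScoreParticipant:
    @pytest.mark.parametrize(
        "value,median,dev,ok",
        [
            (12.5, 10.0, 25.0, True),    # exactly +25 % still passes
            (12.51, 10.0, 25.1, False),
            (7.5, 10.0, -25.0, True),    # symmetric band
            (10.0, 10.0, 0.0, True),
        ],
    )
    def test_band_boundary(self, value, median, dev, ok):
        deviation, passed = score_participant(value, median)
        assert deviation == pytest.approx(dev)
        assert passed is ok

    def test_degenerate_consensus_raises(self):
        with pytest.raises(DegenerateConsensusError):
            score_participant(5.0, 0.0)
        with pytest.raises(DegenerateConsensusError):
            score_participant(5.0, -1.0)

    def test_exhaustive_band_sweep(self):
        median = 40.0
        for v in np.arange(0.0, 80.0, 0.05):
            _, passed = score_participant(float(v), median)
            assert passed == (0.75 * median - 1e-9 <= v <= 1.25 * median + 1e-9), v


class TestEvaluateConcentrations:
    def test_all_at_median_pass_with_zero_deviation(self, results_factory):
        res = results_factory([(f"P{i}", "F1", 20.0, 4) for i in range(6)])
        out = evaluate_concentrations(res)
        assert out["passed"].all()
        assert (out["deviation_pct"] == 0).all()

    def test_participant_value_included_in_own_consensus(self, results_factory):
        # 4 members: median over all four, not leave-one-out
        res = results_factory([
            ("P1", "F1", 10.0, 2), ("P2", "F1", 10.0, 2),
            ("P3", "F1", 20.0, 3), ("P4", "F1", 30.0, 3),
        ])
        out = evaluate_concentrations(res)
        assert (out["consensus_median"] == 15.0).all()

    def test_excluded_outliers_never_influence_the_median(self, devices, results_factory):
        clean = results_factory([
            ("P1", "F1", 10.0, None), ("P2", "F1", 12.0, None),
            ("P3", "F1", 14.0, None), ("P4", "F1", 16.0, None),
        ])
        with_outlier = pd.concat(
            [clean, results_factory([("P9", "F1", 500.0, None)])],
            ignore_index=True,
        )
        inc, _ = filter_outliers(with_outlier, devices)
        assert evaluate_concentrations(inc)["consensus_median"].unique().tolist() == \
            evaluate_concentrations(clean)["consensus_median"].unique().tolist()


class TestEvaluateClassResults:
    def test_pooled_median_scores_the_deviant_lab(self, results_factory):
        # nine labs at class 3, one at 4: pooled median 3, +33 % deviation fails
        rows = [(f"P{i}", "F1", None, 3.0) for i in range(9)] + [("P9", "F1", None, 4.0)]
        out = evaluate_class_results(results_factory(rows))
        assert (out["consensus_median"] == 3.0).all()
        deviant = out[out["participant_id"] == "P9"].iloc[0]
        assert deviant["deviation_pct"] == pytest.approx(100 / 3, rel=1e-6)
        assert not deviant["passed"]
        assert out[out["participant_id"] != "P9"]["passed"].all()

    def test_divergent_collective_gets_its_own_median(self, results_factory):
        # F2 sits two full classes above everyone else, ranges disjoint
        rows = [(f"A{i}", "F1", None, 2.0) for i in range(20)] + [
            (f"B{i}", "F2", None, 4.0 + 0.5 * (i % 2)) for i in range(8)
        ]
        out = evaluate_class_results(results_factory(rows))
        f2 = out[out["manufacturer_code"] == "F2"]
        assert (f2["collective_code"] == "F2").all()
        assert f2["passed"].all()
        f1 = out[out["manufacturer_code"] == "F1"]
        assert (f1["collective_code"] == "pooled").all()
        assert (f1["consensus_median"] == 2.0).all()

    def test_single_collective_pooled_equals_collective_median(self, results_factory):
        rows = [(f"P{i}", "F1", None, float(c)) for i, c in enumerate([2, 2, 3, 3, 3])]
        out = evaluate_class_results(results_factory(rows))
        assert (out["collective_code"] == "pooled").all()
        assert (out["consensus_median"] == 3.0).all()

    def test_zero_pooled_median_is_unevaluable_not_fail(self, results_factory):
        rows = [(f"P{i}", "F1", None, 0.0) for i in range(5)]
        out = evaluate_class_results(results_factory(rows))
        assert (~out["evaluable"]).all()
        assert (~out["passed"]).all()


class TestCertificatesAndPassRate:
    def test_all_pass_gives_overall_pass(self, results_factory):
        res = results_factory([(f"P{i}", "F1", 20.0, 4) for i in range(5)])
        out = evaluate_concentrations(res)
        cert = certificate(out[out["participant_id"] == "P0"])
        assert cert["overall"] == "pass"

    def test_one_fail_among_three_fails_overall(self):
        out = pd.DataFrame({
            "survey_id": ["R"] * 3,
            "participant_id": ["P"] * 3,
            "analyte": ["a", "b", "c"],
            "evaluable": [True] * 3,
            "passed": [True, False, True],
        })
        assert certificate(out)["overall"] == "fail"

    def test_nothing_evaluable_is_unevaluable_not_fail(self):
        out = pd.DataFrame({
            "survey_id": ["R"], "participant_id": ["P"], "analyte": ["a"],
            "evaluable": [False], "passed": [False],
        })
        assert certificate(out)["overall"] == "unevaluable"

    def test_pass_rate_simple_counts(self):
        out = pd.DataFrame({"evaluable": [True] * 10, "passed": [True] * 9 + [False]})
        assert pass_rate(out) == pytest.approx(90.0)
        out_all = pd.DataFrame({"evaluable": [True] * 4, "passed": [True] * 4})
        assert pass_rate(out_all) == pytest.approx(100.0)

    def test_pass_rate_undefined_without_evaluable(self):
        with pytest.raises(EvaluationError):
            pass_rate(pd.DataFrame({"evaluable": [False], "passed": [False]}))

    def test_pass_rate_matches_per_lab_recount(self, results_factory):
        # 50 labs with spread values: recount pass/fail per lab by hand
        rng = np.random.default_rng(42)
        values = rng.lognormal(np.log(20), 0.3, size=50)
        res = results_factory(
            [(f"P{i}", "F1", float(v), None) for i, v in enumerate(values)]
        )
        out = evaluate_concentrations(res)
        med = float(np.median(values))
        manual = sum(1 for v in values if 0.75 * med <= v <= 1.25 * med)
        assert pass_rate(out) == pytest.approx(100.0 * manual / 50)
        assert out["passed"].sum() == manual

    def test_row_permutation_leaves_outcomes_unchanged(self, results_factory):
        rng = np.random.default_rng(3)
        rows = [(f"P{i}", code, float(v), None)
                for i, (code, v) in enumerate(
                    zip(["F1"] * 6 + ["F2"] * 5, rng.uniform(5, 40, 11)))]
        res = results_factory(rows)
        base = evaluate_concentrations(res).set_index("participant_id").sort_index()
        shuf = evaluate_concentrations(
            res.sample(frac=1.0, random_state=11)
        ).set_index("participant_id").sort_index()
        pd.testing.assert_frame_equal(base, shuf)
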