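"""Class composition, redistribution percentages and Kruskal-Wallis tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from casatrack import (KinematicsRecord, ValidationError, class_percentages,
                       compare_conditions_report, kruskal_wallis,
                       percent_variation, report_tables, significance_stars)


def rec(tid, cls, vsl=40.0, vcl=100.0, lin=40.0, condition=None, step=None):
    return KinematicsRecord(track_id=tid, n_points=200, vsl=vsl, vcl=vcl,
                            lin=lin, motility_class=cls, condition=condition,
                            time_step=step)


def tiefree_h(groups):
    """Textbook tie-free Kruskal-Wallis statistic, computed from ranks."""
    pooled = np.concatenate(groups)
    order = pooled.argsort()
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    n = len(pooled)
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


class TestClassPercentages:
    def test_reference_composition(self):
        # 15 slow, 19 medium, 15 rapid -> 30.6% / 38.8% / 30.6%
        recs = ([rec(i, "slow") for i in range(15)]
                + [rec(20 + i, "medium") for i in range(19)]
                + [rec(50 + i, "rapid") for i in range(15)])
        s = class_percentages(recs, "CTRL", "10min")
        assert s.total_motile == 49
        assert s.percentages["slow"] == pytest.approx(30.6, abs=0.05)
        assert s.percentages["medium"] == pytest.approx(38.8, abs=0.05)
        assert s.percentages["rapid"] == pytest.approx(30.6, abs=0.05)
        assert sum(s.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_class_is_hundred_percent(self):
        s = class_percentages([rec(0, "rapid", vcl=200.0)], "CTRL", "10min")
        assert s.percentages["rapid"] == 100.0

    def test_unclassified_excluded_from_denominator(self):
        recs = [rec(0, "slow"), rec(1, "unclassified", vsl=4.0, vcl=10.0)]
        s = class_percentages(recs, "CTRL", "10min")
        assert s.total_motile == 1 and s.percentages["slow"] == 100.0

    def test_zero_motile_warns_not_crashes(self):
        with pytest.warns(UserWarning):
            s = class_percentages([], "CTRL", "10min")
        assert s.total_motile == 0 and s.percentages == {}


class TestPercentVariation:
    @pytest.mark.parametrize("a,b,expected", [
        (20.0, 30.0, 50.0), (40.0, 10.0, -75.0), (33.0, 33.0, 0.0)])
    def test_arithmetic(self, a, b, expected):
        assert percent_variation(a, b) == pytest.approx(expected)

    def test_zero_start_undefined(self):
        with pytest.raises(ValidationError):
            percent_variation(0.0, 10.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0), st.floats(0.1, 100.0))
    def test_antisymmetric_sign(self, a, b):
        if a != b:
            assert (percent_variation(a, b) > 0) != (percent_variation(b, a) > 0)


class TestKruskalWallis:
    def test_identical_groups_no_effect(self):
        res = kruskal_wallis([[5.0, 5.0, 5.0], [5.0, 5.0]])
        assert res.h_statistic == 0.0 and res.p_value == 1.0

    def test_textbook_example(self):
        res = kruskal_wallis([[1.0, 2.0, 3.0], [10.0, 11.0, 12.0]])
        assert res.h_statistic == pytest.approx(3.857, abs=0.001)

    def test_matches_tiefree_formula_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            k = int(rng.integers(2, 4))
            groups = [rng.permutation(rng.uniform(0, 100, rng.integers(3, 9)))
                      for _ in range(k)]
            # continuous draws: ties have probability zero
            res = kruskal_wallis(groups)
            assert res.h_statistic == pytest.approx(tiefree_h(groups), abs=1e-9)

    def test_empty_group_is_error(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1.0, 2.0], []])

    def test_p_decreases_with_separation(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0, 1, 30)
        ps = [kruskal_wallis([base, base + shift]).p_value
              for shift in (0.0, 0.5, 1.0, 2.0)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_stars_follow_reporting_convention(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""


def _two_condition_records():
    rng = np.random.default_rng(10)
    recs = []
    tid = 0
    for cond in ("CTRL", "CYP"):
        for step in ("10min", "30min", "60min"):
            for cls, vcl0 in (("slow", 50.0), ("medium", 110.0),
                              ("rapid", 180.0)):
                for _ in range(8):
                    vcl = vcl0 + rng.uniform(-5, 5)
                    vsl = vcl * rng.uniform(0.3, 0.8)
                    recs.append(rec(tid, cls, vsl=vsl, vcl=vcl,
                                    lin=100 * vsl / vcl, condition=cond,
                                    step=step))
                    tid += 1
    return recs


class TestReport:
    def test_three_steps_give_three_pairwise_comparisons(self):
        report = compare_conditions_report(_two_condition_records())
        for cr in report.conditions.values():
            pairs = {t.step_pair for t in cr.kw_tests}
            assert pairs == {("30min", "10min"), ("60min", "30min"),
                             ("60min", "10min")}
            # 3 classes x 3 parameters x 3 step pairs
            assert len(cr.kw_tests) == 27
            # redistribution only between consecutive steps
            assert {(v.from_step, v.to_step) for v in cr.variations} == {
                ("10min", "30min"), ("30min", "60min")}

    def test_no_cross_condition_tests_ever(self):
        report = compare_conditions_report(_two_condition_records())
        tables = report_tables(report)
        kw = tables["kruskal_wallis"]
        assert set(kw["condition"]) == {"CTRL", "CYP"}
        # every comparison is a within-condition step pair
        assert kw["step_pair"].str.contains("min").all()
        assert "CTRL" not in " ".join(kw["step_pair"])
        assert report.note  # the cross-condition exclusion is documented

    def test_single_time_step_no_variations_no_error(self):
        recs = [rec(i, "slow", condition="CTRL", step="10min")
                for i in range(5)]
        report = compare_conditions_report(recs)
        cr = report.conditions["CTRL"]
        assert cr.variations == [] and cr.kw_tests == []

    def test_missing_labels_rejected(self):
        with pytest.raises(ValidationError):
            compare_conditions_report([rec(0, "slow")])

    def test_percentages_sum_to_hundred(self):
        report = compare_conditions_report(_two_condition_records())
        for cr in report.conditions.values():
            for s in cr.summaries.values():
                assert sum(s.percentages.values()) == pytest.approx(100.0,
                                                                    abs=1e-9)
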