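"""Trajectory comparison: gated tests and heterochrony classification."""

import numpy as np
import pytest

from ontotraj import (
    classify_heterochrony, common_slope_test, compare_pair, intercept_test,
    label_process, shift_test,
)
from ontotraj.comparison import (
    MIRROR_LABEL, PAEDOMORPH_LABELS, PERAMORPH_LABELS, compare_variable,
)
from ontotraj.synthetic import generate_pair, scenario_preset


def _two_groups(rng, n=80, slope_w=1.0, slope_d=1.0, offset_d=0.0,
                shift_d=0.0, sigma=0.05):
    """Bivariate samples with noise on both axes (true SMA slope as given)."""
    t1 = rng.uniform(-0.3, 0.3, n)
    t2 = rng.uniform(-0.3, 0.3, n) + shift_d
    xw = t1 + rng.normal(0, sigma, n)
    yw = slope_w * t1 + rng.normal(0, sigma, n)
    xd = t2 + rng.normal(0, sigma, n)
    yd = slope_d * t2 + offset_d + rng.normal(0, sigma, n)
    return xw, yw, xd, yd


class TestCommonSlopeTest:
    def test_identical_samples(self):
        x = np.linspace(0, 1, 30)
        y = 1.2 * x + np.sin(x)  # any fixed curve; identical in both groups
        res = common_slope_test(x, y, x.copy(), y.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.pvalue == pytest.approx(1.0)
        assert res.common_slope == pytest.approx(res.slopes[0])

    def test_common_slope_between_group_slopes(self):
        rng = np.random.default_rng(1)
        xw, yw, xd, yd = _two_groups(rng, slope_w=0.9, slope_d=1.2)
        res = common_slope_test(xw, yw, xd, yd)
        lo, hi = sorted(res.slopes)
        assert lo <= res.common_slope <= hi

    def test_power_at_large_slope_difference(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(50):
            xw, yw, xd, yd = _two_groups(rng, slope_w=0.8, slope_d=1.3)
            if common_slope_test(xw, yw, xd, yd).pvalue < 0.0036:
                hits += 1
        assert hits >= 48

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(3)
        rej = sum(common_slope_test(*_two_groups(rng)).pvalue < 0.05
                  for _ in range(400))
        assert 0.02 <= rej / 400 <= 0.09


class TestInterceptTest:
    def test_identical_samples(self):
        x = np.linspace(0, 1, 30)
        y = x + 0.3
        res = intercept_test(x, y, x.copy(), y.copy(), 1.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_power_at_offset(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(50):
            xw, yw, xd, yd = _two_groups(rng, offset_d=0.2)
            b = common_slope_test(xw, yw, xd, yd).common_slope
            res = intercept_test(xw, yw, xd, yd, b)
            if res.pvalue < 0.0036 and res.higher_form == "domestic":
                hits += 1
        assert hits >= 48

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(5)
        rej = 0
        for _ in range(400):
            xw, yw, xd, yd = _two_groups(rng)
            b = common_slope_test(xw, yw, xd, yd).common_slope
            rej += intercept_test(xw, yw, xd, yd, b).pvalue < 0.05
        assert 0.02 <= rej / 400 <= 0.10


class TestShiftTest:
    def test_identical_samples(self):
        x = np.linspace(0, 1, 30)
        y = x
        res = shift_test(x, y, x.copy(), y.copy(), 1.0)
        assert res.direction == "none"

    def test_domestic_extension_detected(self):
        rng = np.random.default_rng(6)
        xw, yw, xd, yd = _two_groups(rng, shift_d=0.4)
        yd = yd + 0.4  # stay on the same line y = x
        b = common_slope_test(xw, yw, xd, yd).common_slope
        res = shift_test(xw, yw, xd, yd, b, alpha=0.0036)
        assert res.direction == "domestic_extends"

    def test_wild_extension_mirror(self):
        rng = np.random.default_rng(6)
        xw, yw, xd, yd = _two_groups(rng, shift_d=0.4)
        yd = yd + 0.4
        b = common_slope_test(xd, yd, xw, yw).common_slope
        res = shift_test(xd, yd, xw, yw, b, alpha=0.0036)
        assert res.direction == "wild_extends"


class TestClassification:
    def test_label_process_partition(self):
        """The six heterochrony labels partition exactly into the two
        process triplets."""
        assert PERAMORPH_LABELS == {"acceleration", "hypermorphosis",
                                    "pre_displacement"}
        assert PAEDOMORPH_LABELS == {"deceleration", "hypomorphosis",
                                     "post_displacement"}
        for label in PERAMORPH_LABELS:
            assert label_process(label) == "peramorphosis"
        for label in PAEDOMORPH_LABELS:
            assert label_process(label) == "paedomorphosis"
        assert label_process("no_change") == "none"

    @pytest.mark.parametrize("kwargs,expected", [
        (dict(slope_significant=True, wild_slope=1.0, domestic_slope=1.3),
         ("acceleration", "peramorphosis")),
        (dict(slope_significant=True, wild_slope=1.0, domestic_slope=0.7),
         ("deceleration", "paedomorphosis")),
        (dict(slope_significant=False, wild_slope=1, domestic_slope=1,
              intercept_significant=True, domestic_intercept_higher=True),
         ("pre_displacement", "peramorphosis")),
        (dict(slope_significant=False, wild_slope=1, domestic_slope=1,
              intercept_significant=True, domestic_intercept_higher=False),
         ("post_displacement", "paedomorphosis")),
        (dict(slope_significant=False, wild_slope=1, domestic_slope=1,
              shift_direction="domestic_extends"),
         ("hypermorphosis", "peramorphosis")),
        (dict(slope_significant=False, wild_slope=1, domestic_slope=1,
              shift_direction="wild_extends"),
         ("hypomorphosis", "paedomorphosis")),
        (dict(slope_significant=False, wild_slope=1, domestic_slope=1),
         ("no_change", "none")),
    ])
    def test_decision_tree(self, kwargs, expected):
        assert classify_heterochrony(**kwargs) == expected

    def test_slope_takes_precedence(self):
        label, _ = classify_heterochrony(
            slope_significant=True, wild_slope=1.0, domestic_slope=1.3,
            intercept_significant=True, domestic_intercept_higher=False,
            shift_direction="wild_extends")
        assert label == "acceleration"


class TestComparePair:
    def test_identical_data_all_no_change(self):
        wild, _, _ = generate_pair("no_change", seed=17)
        twin = wild.subset(wild.variable_names)
        twin.form = "domestic"
        result = compare_pair(wild, twin)
        assert all(c.label == "no_change" for c in result.comparisons)
        assert result.summary.n_heterochronic_events == 0

    def test_gating_suppresses_later_tests(self):
        wild, dom, _ = generate_pair("acceleration", seed=18)
        c = compare_pair(wild, dom, variables=["LN"]).comparisons[0]
        assert c.slope_significant
        assert c.intercept_test is None and c.shift_test is None

    def test_form_swap_mirrors_labels(self):
        for name in ("acceleration", "pre_displacement", "hypermorphosis",
                     "no_change"):
            wild, dom, truth = generate_pair(name, seed=19)
            fwd = compare_pair(wild, dom, variables=["LN"]).comparisons[0]
            # relabel the two series so the domestic plays the wild role
            wild2 = dom.subset(dom.variable_names)
            wild2.form = "wild"
            dom2 = wild.subset(wild.variable_names)
            dom2.form = "domestic"
            rev = compare_pair(wild2, dom2, variables=["LN"]).comparisons[0]
            assert rev.label == MIRROR_LABEL[fwd.label]

    def test_intercept_dominated_scenario(self):
        """Shared slopes with several offset intercepts concentrate the
        tallies in the displacement categories."""
        preset = scenario_preset("pre_displacement", seed=20)
        intercepts = preset.domestic.intercept_vector.copy()
        intercepts[3] -= 0.2  # UPR down, LN already up
        preset.domestic = preset.domestic.with_changes(intercepts=intercepts)
        wild, dom, _ = generate_pair(preset)
        summary = compare_pair(wild, dom).summary
        assert summary.n_different_intercepts >= 2
        assert summary.n_different_slopes == 0
        assert summary.label_tallies["pre_displacement"] >= 1
        assert summary.label_tallies["post_displacement"] >= 1

    def test_summary_tallies_sum_to_variables(self):
        wild, dom, _ = generate_pair("acceleration", seed=21)
        summary = compare_pair(wild, dom).summary
        assert sum(summary.label_tallies.values()) == summary.n_variables
        assert (summary.n_different_slopes + summary.n_different_intercepts
                + summary.n_shifts + summary.n_no_change) == summary.n_variables

    def test_null_false_label_rate_bounded(self):
        """Under identical generating processes the share of variables
        labelled other than no_change stays near twice the corrected
        alpha (slope + intercept gates)."""
        total = bad = 0
        for seed in range(60):
            wild, dom, _ = generate_pair("isometric_null", seed=seed)
            for c in compare_pair(wild, dom).comparisons:
                total += 1
                bad += c.label != "no_change"
        alpha_corr = 0.05 / 14
        rate = bad / total
        bound = 2 * alpha_corr + 3 * np.sqrt(2 * alpha_corr / total) + 0.005
        assert rate <= bound
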