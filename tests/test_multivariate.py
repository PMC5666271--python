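"""Multivariate allometry: eigenvector, jackknife, trimming, classification."""

import numpy as np
import pytest

from ontotraj import (
    CANONICAL_VARIABLES, MultivarConfig, classify_signs, first_eigenvector,
    isometry_value, jackknife_ci, jackknife_pseudovalues, run_multivar,
    trim_pseudovalues,
)
from ontotraj.multivariate import AllometryCoefficient, PseudovalueMatrix
from ontotraj.synthetic import SyntheticSpec, generate_pair, generate_series


def naive_pseudovalues(series):
    """Independent brute-force oracle: fresh covariance + eigendecomposition
    per leave-one-out round, no shared code with the pipeline."""
    X = np.log10(series.measurements)
    n = X.shape[0]

    def axis(Z):
        w, V = np.linalg.eigh(np.cov(Z, rowvar=False, ddof=1))
        v = V[:, -1]
        return v if v.sum() > 0 else -v

    v_full = axis(X)
    out = np.empty_like(X)
    for i in range(n):
        v_i = axis(np.delete(X, i, axis=0))
        if v_i @ v_full < 0:
            v_i = -v_i
        out[i] = n * v_full - (n - 1) * v_i
    return out


class TestFirstEigenvector:
    def test_exact_isometry(self, isometric_series):
        v = first_eigenvector(isometric_series)
        assert np.allclose(v, 1 / np.sqrt(14), atol=1e-10)

    def test_unit_norm(self, doglike_series):
        v = first_eigenvector(doglike_series)
        assert abs(np.linalg.norm(v) - 1.0) < 1e-12

    def test_recovers_generating_direction(self, doglike_exponents):
        spec = SyntheticSpec(form="wild", n=200, exponents=doglike_exponents,
                             noise_sd=0.01, seed=21)
        v = first_eigenvector(generate_series(spec))
        target = doglike_exponents / np.linalg.norm(doglike_exponents)
        assert np.max(np.abs(v - target)) < 0.02

    def test_isometry_value_constant(self):
        assert round(isometry_value(14), 3) == 0.267
        assert isometry_value(4) == 0.5

    def test_too_few_specimens_rejected(self, isometric_series):
        tiny = isometric_series
        tiny = tiny.subset(tiny.variable_names)
        tiny.measurements = tiny.measurements[:2]
        tiny.specimen_ids = tiny.specimen_ids[:2]
        with pytest.raises(ValueError):
            first_eigenvector(tiny)

    def test_tied_leading_eigenvalues_rejected(self):
        from ontotraj.series import GrowthSeries

        # a log-covariance that is exactly spherical: the first principal
        # axis is not identified and the analysis must refuse
        z = 0.1 * np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        series = GrowthSeries("deg", "wild", "p", ["A", "B"],
                              10.0 ** (1.0 + z), ["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="tied|degenerate"):
            first_eigenvector(series)


class TestPseudovalues:
    def test_noiseless_isometry_constant_pseudovalues(self, isometric_series):
        pv = jackknife_pseudovalues(isometric_series)
        assert np.allclose(pv.values, 1 / np.sqrt(14), atol=1e-10)
        assert np.allclose(pv.values.std(axis=0), 0.0, atol=1e-10)

    def test_matches_bruteforce_oracle(self, small_series):
        pv = jackknife_pseudovalues(small_series)
        np.testing.assert_allclose(pv.values, naive_pseudovalues(small_series),
                                   atol=1e-10)

    def test_column_means_feed_downstream(self, small_series):
        pv = jackknife_pseudovalues(small_series)
        coeffs = jackknife_ci(pv, 0.95)
        np.testing.assert_allclose(pv.values.mean(axis=0),
                                   [c.jackknife_mean for c in coeffs], atol=1e-14)


class TestTrimming:
    def _pv(self, values):
        values = np.asarray(values, float)
        return PseudovalueMatrix(values, [f"v{k}" for k in range(values.shape[1])],
                                 values.mean(axis=0))

    def test_m0_is_identity(self):
        pv = self._pv(np.arange(10.0).reshape(5, 2))
        out = trim_pseudovalues(pv, 0)
        np.testing.assert_array_equal(out.values, pv.values)

    def test_removes_extremes_per_column(self):
        pv = self._pv(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]))
        out = trim_pseudovalues(pv, 1)
        np.testing.assert_array_equal(out.values.ravel(), [2.0, 3.0, 4.0])

    def test_constant_column_stays_constant(self):
        pv = self._pv(np.full((6, 1), 7.0))
        out = trim_pseudovalues(pv, 1)
        assert out.values.shape == (4, 1)
        assert np.all(out.values == 7.0)

    def test_overtrimming_rejected(self):
        pv = self._pv(np.arange(6.0).reshape(6, 1))
        with pytest.raises(ValueError):
            trim_pseudovalues(pv, 2)

    def test_trimming_does_not_raise_sd(self, doglike_series):
        pv = jackknife_pseudovalues(doglike_series)
        trimmed = trim_pseudovalues(pv, 1)
        sd_full = pv.values.std(axis=0, ddof=1)
        sd_trim = trimmed.values.std(axis=0, ddof=1)
        assert np.all(sd_trim <= sd_full + 1e-15)


class TestJackknifeCI:
    def _single_column(self, values):
        values = np.asarray(values, float).reshape(-1, 1)
        return PseudovalueMatrix(values, ["v"], np.array([0.0]))

    def test_hand_computed_interval(self):
        # mean 3, sd 1.5811, t_{4, 0.975} = 2.7764 -> 3 +/- 1.9632
        pv = self._single_column([1, 2, 3, 4, 5])
        (c,) = jackknife_ci(pv, 0.95, np.array([2.5]))
        assert c.jackknife_mean == pytest.approx(3.0)
        assert c.jackknife_sd == pytest.approx(1.5811, abs=1e-4)
        assert c.ci_low == pytest.approx(1.0368, abs=1e-4)
        assert c.ci_high == pytest.approx(4.9632, abs=1e-4)
        assert c.bias == pytest.approx(0.5)

    def test_constant_column(self):
        pv = self._single_column([0.4, 0.4, 0.4, 0.4])
        (c,) = jackknife_ci(pv, 0.95, np.array([0.35]))
        assert (c.ci_low, c.ci_high) == (0.4, 0.4)
        assert c.jackknife_sd == 0.0
        assert c.bias == pytest.approx(0.05)

    def test_two_sd_multiplier_variant(self):
        pv = self._single_column([1, 2, 3, 4, 5])
        (c,) = jackknife_ci(pv, 0.95, np.array([3.0]), multiplier="two_sd")
        half = 2 * np.std([1, 2, 3, 4, 5], ddof=1) / np.sqrt(5)
        assert c.ci_high - c.jackknife_mean == pytest.approx(half)


class TestClassification:
    def _coef(self, lo, hi):
        mid = 0.5 * (lo + hi)
        return AllometryCoefficient("v", mid, mid, 0.0, 0.0, lo, hi)

    @pytest.mark.parametrize("lo,hi,expected", [
        (0.30, 0.40, "P"), (0.20, 0.30, "I"), (0.10, 0.20, "N"),
        (0.267, 0.267, "I"),
    ])
    def test_interval_position(self, lo, hi, expected):
        coef = self._coef(lo, hi)
        classify_signs([coef], 0.267)
        assert coef.sign == expected

    def test_ci_ordering_invariant(self, doglike_series):
        result = run_multivar(doglike_series)
        for c in result.coefficients:
            assert c.ci_low <= c.jackknife_mean <= c.ci_high
            assert c.bias == pytest.approx(c.jackknife_mean - c.estimate_full)


class TestRunMultivar:
    def test_isometric_fixture_all_I_mode_U(self, isometric_series):
        result = run_multivar(isometric_series)
        assert result.mode_used == "U"  # sd tie (both zero) -> untrimmed
        assert all(c.sign == "I" for c in result.coefficients)
        assert result.isometry_value == pytest.approx(1 / np.sqrt(14))
        assert result.p == 14

    def test_gross_outlier_selects_trimmed(self):
        _, domestic, _ = generate_pair("outlier_injection", seed=3)
        result = run_multivar(domestic)
        assert result.mean_sd_trimmed < result.mean_sd_untrimmed
        assert result.mode_used == "T"

    def test_forced_modes(self, doglike_series):
        u = run_multivar(doglike_series, MultivarConfig(mode="untrimmed"))
        t = run_multivar(doglike_series, MultivarConfig(mode="trimmed"))
        assert u.mode_used == "U" and t.mode_used == "T"
        assert all(c.trimmed for c in t.coefficients)

    def test_variable_order_preserved(self, doglike_series):
        result = run_multivar(doglike_series)
        assert result.variable_names == list(CANONICAL_VARIABLES)

    def test_reduced_variable_set_changes_isometry_value(self, doglike_series):
        ten = [v for v in CANONICAL_VARIABLES
               if v not in ("LD", "HD", "HC", "LPR")]
        result = run_multivar(doglike_series, variables=ten)
        assert result.p == 10
        assert result.isometry_value == pytest.approx(1 / np.sqrt(10))

    def test_tiny_series_rejected(self, doglike_exponents):
        spec = SyntheticSpec(form="wild", n=4, exponents=doglike_exponents,
                             noise_sd=0.02, seed=9)
        with pytest.raises(ValueError):
            run_multivar(generate_series(spec))

    def test_small_series_warns(self, doglike_exponents):
        import warnings

        spec = SyntheticSpec(form="wild", n=8, exponents=doglike_exponents,
                             noise_sd=0.02, seed=9)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            run_multivar(generate_series(spec))
        assert any("unreliable" in str(w.message) for w in caught)
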