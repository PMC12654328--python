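"""MAD/MADn, dispersion permutation tests, and the BCa bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import bootstrap as scipy_bootstrap
from scipy.stats import median_abs_deviation

from flychoice.dispersion import (
    bca_ci,
    global_dispersion_test,
    mad,
    madn,
    pairwise_dispersion_tests,
)
from flychoice.resampling import make_rng


class TestMad:
    @pytest.mark.parametrize(
        "values,expected",
        [((1, 2, 3, 4, 5), 1.0),
         ((7, 7, 7, 7), 0.0),
         ((0.1, 0.4, 0.5, 0.6, 0.9, 1.0), 0.25)],  # median 0.55, midpoint rule
    )
    def test_hand_examples(self, values, expected):
        assert mad(np.array(values, dtype=float)) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad(np.array([]))

    def test_matches_scipy(self, rng):
        x = rng.normal(size=101)
        assert mad(x) == pytest.approx(median_abs_deviation(x))
        assert madn(x) == pytest.approx(median_abs_deviation(x, scale=1 / 1.4826))

    def test_madn_constant_factor(self):
        assert madn(np.array([1.0, 2, 3, 4, 5])) == pytest.approx(1.4826)

    def test_normal_consistency(self):
        # MADn estimates the SD of a normal: 50k draws within ±0.02 of 1
        x = np.random.default_rng(7).normal(size=50_000)
        assert abs(madn(x) - 1.0) < 0.02

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=30),
        st.floats(-5, 5), st.floats(-10, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_equivariance(self, values, c, d):
        x = np.asarray(values)
        assert madn(c * x + d) == pytest.approx(abs(c) * madn(x), abs=1e-9)


class TestGlobalDispersionTest:
    def test_identical_groups_give_p_one(self, rng):
        g = {"a": [1.0, 2, 3, 4, 5], "b": [1.0, 2, 3, 4, 5]}
        res = global_dispersion_test(g, 200, rng)
        assert res.observed_stat == 0.0
        assert res.p_value == 1.0

    def test_observed_range_hand_value(self, rng):
        g = {"a": [1.0, 2, 3, 4, 5], "b": [10.0, 20, 30, 40, 50]}
        res = global_dispersion_test(g, 50, rng)
        assert res.observed_stat == pytest.approx(1.4826 * 9)

    def test_tiny_group_rejected(self, rng):
        with pytest.raises(ValueError):
            global_dispersion_test({"a": [1.0], "b": [1.0, 2.0]}, 10, rng)

    def test_index_scale_is_twice_lcp_scale(self, rng):
        lcps = {"a": np.array([0.3, 0.5, 0.6, 0.9, 0.2]),
                "b": np.array([0.4, 0.45, 0.5, 0.55, 0.6])}
        indices = {g: 2 * v - 1 for g, v in lcps.items()}
        r_idx = global_dispersion_test(indices, 50, make_rng(1, "s"))
        r_lcp = global_dispersion_test(lcps, 50, make_rng(1, "s"))
        assert r_idx.observed_stat == pytest.approx(2 * r_lcp.observed_stat)


class TestPairwiseDispersion:
    def test_effects_and_holm_family(self, rng):
        g = {"a": [1.0, 2, 3, 4, 5], "b": [10.0, 20, 30, 40, 50],
             "c": [1.0, 2, 3, 4, 5]}
        results = pairwise_dispersion_tests(g, 100, rng)
        assert len(results) == 3
        by_pair = {r.pair: r for r in results}
        assert by_pair[("a", "b")].effect == pytest.approx(1.4826 * 9)
        assert by_pair[("a", "c")].effect == 0.0
        assert by_pair[("a", "c")].p_raw == 1.0
        for r in results:
            assert r.p_holm >= r.p_raw
            assert r.p_holm <= 1.0

    def test_holm_hand_example_six_pairs(self):
        from flychoice.resampling import holm_adjust

        adj = holm_adjust([0.001, 0.001, 0.2, 0.3, 0.9, 0.9])
        assert adj == pytest.approx([0.006, 0.006, 0.8, 0.9, 1.0, 1.0])


class TestBcaCI:
    def test_constant_data_degenerate(self, rng):
        ci = bca_ci(np.full(20, 0.5), madn, n_boot=200, rng=rng)
        assert ci.degenerate
        assert ci.point == ci.lower == ci.upper == 0.0

    def test_reduces_to_percentile_when_z0_and_accel_vanish(self, rng, monkeypatch):
        # force z0 = 0 and a = 0: the transformed quantile levels are
        # exactly alpha/2 and 1 - alpha/2
        x = np.random.default_rng(11).normal(size=60)
        ci = bca_ci(x, statistic=np.mean, n_boot=2000, rng=make_rng(5, "b"))
        boot = []
        r2 = make_rng(5, "b")
        done = 0
        while done < 2000:
            k = min(2048, 2000 - done)
            idx = r2.integers(0, x.size, size=(k, x.size))
            boot.append(x[idx].mean(axis=1))
            done += k
        boot = np.concatenate(boot)
        from scipy.special import ndtr

        lo_level = ndtr(ci.z0 + (ci.z0 + (-1.959963984540054)) /
                        (1 - ci.accel * (ci.z0 - 1.959963984540054)))
        assert ci.lower == pytest.approx(np.quantile(boot, lo_level))
        if ci.z0 == 0.0 and ci.accel == 0.0:
            assert ci.lower == pytest.approx(np.quantile(boot, 0.025))

    def test_interval_brackets_point_for_mean(self, rng):
        x = np.random.default_rng(3).normal(size=40)
        ci = bca_ci(x, statistic=np.mean, n_boot=2000, rng=rng)
        assert ci.lower <= ci.point <= ci.upper

    def test_agrees_with_scipy_bca_for_the_mean(self):
        # independent reference implementation of BCa on a smooth,
        # tie-free statistic
        x = np.random.default_rng(42).normal(size=50)
        ours = bca_ci(x, statistic=np.mean, n_boot=9999, rng=make_rng(0, "ref"))
        ref = scipy_bootstrap((x,), np.mean, n_resamples=9999, method="BCa",
                              confidence_level=0.95,
                              random_state=np.random.default_rng(1))
        assert ours.lower == pytest.approx(ref.confidence_interval.low, abs=0.02)
        assert ours.upper == pytest.approx(ref.confidence_interval.high, abs=0.02)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            bca_ci(np.array([1.0]), madn, n_boot=10, rng=rng)
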