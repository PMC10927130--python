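"""Unit and property tests for the RPT keypress-metric extraction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rptfusion.features import (
    assemble_profile,
    category_stats,
    fit_limit_function,
    fit_value_function,
    profiles_from_responses,
    shannon_entropy,
    tradeoff_features,
)
from rptfusion.labels import METRICS

from conftest import make_responses


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5] * 20, math.log2(20)),          # uniform over 20 pictures
            ([1] + [0] * 19, 0.0),              # point mass
            ([4, 4, 2], 1.521928094887362),     # -0.4log2(.4)*2 - .2log2(.2)
            ([7, 7], 1.0),                      # two equal pictures = 1 bit
        ],
    )
    def test_known_values(self, counts, expected):
        assert shannon_entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_is_undefined_not_zero(self):
        assert math.isnan(shannon_entropy([0, 0, 0]))
        assert math.isnan(shannon_entropy([]))

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=30)
        .filter(lambda ks: sum(ks) > 0)
    )
    @settings(deadline=None)
    def test_bounds(self, counts):
        h = shannon_entropy(counts)
        assert 0.0 <= h <= math.log2(len(counts)) + 1e-12


class TestCategoryStats:
    def test_uniform_counts(self):
        resp = make_responses({"cat1": [5] * 20}, valence="inc")
        (empty_dec, s) = sorted(category_stats(resp), key=lambda r: r.valence)
        assert s.valence == "inc"
        assert s.K == 5 and s.sigma == 0
        assert s.H == pytest.approx(math.log2(20))
        assert empty_dec.n_active == 0 and math.isnan(empty_dec.K)

    def test_single_active_picture(self):
        resp = make_responses({"cat1": [3] + [0] * 19})
        s = [r for r in category_stats(resp) if r.valence == "dec"][0]
        assert s.H == 0.0 and s.sigma == 0.0 and s.K == 3 and s.n_active == 1

    def test_zeros_excluded_from_mean(self):
        resp = make_responses({"cat1": [4, 4, 2, 0, 0]})
        s = [r for r in category_stats(resp) if r.valence == "dec"][0]
        assert s.K == pytest.approx(10 / 3)
        assert s.H == pytest.approx(1.521928094887362)
        assert s.n_active == 3

    def test_zero_inclusive_variant(self):
        resp = make_responses({"cat1": [4, 4, 2, 0, 0]})
        s = [
            r for r in category_stats(resp, include_zeros=True)
            if r.valence == "dec"
        ][0]
        assert s.K == pytest.approx(2.0)

    @given(st.integers(min_value=2, max_value=9), st.data())
    @settings(deadline=None, max_examples=30)
    def test_count_scaling_property(self, m, data):
        """Scaling all counts by m leaves H fixed, scales K and sigma by m."""
        counts = data.draw(
            st.lists(st.integers(min_value=0, max_value=9), min_size=4, max_size=12)
            .filter(lambda ks: sum(k > 0 for k in ks) >= 2)
        )
        s1 = [r for r in category_stats(make_responses({"c": counts}))
              if r.valence == "dec"][0]
        s2 = [r for r in category_stats(make_responses({"c": [m * k for k in counts]}))
              if r.valence == "dec"][0]
        assert s2.H == pytest.approx(s1.H, abs=1e-9)
        assert s2.K == pytest.approx(m * s1.K, rel=1e-9)
        assert s2.sigma == pytest.approx(m * s1.sigma, rel=1e-9)


class TestValueFunction:
    def test_exact_log_recovery(self):
        K = np.array([2.0, 3.0, 5.0, 9.0])
        fit = fit_value_function(np.column_stack([K, 2 * np.log(K - 1)]))
        assert fit["fit_ok"]
        assert fit["offset"] == pytest.approx(1.0, abs=1e-6)
        assert fit["curvature"] == pytest.approx(2.0, abs=1e-6)

    def test_underdetermined(self):
        assert not fit_value_function([(1, 1), (2, 2)])["fit_ok"]
        assert not fit_value_function([(2, 1), (2, 2), (2, 3)])["fit_ok"]

    def test_noisy_recovery_monte_carlo(self):
        """Median recovered (offset, curvature) over 100 noisy 4-point
        designs stays within +/-0.5 of the truth."""
        rng = np.random.default_rng(42)
        x0, b = 0.5, 1.5
        K = np.array([1.5, 3.0, 5.0, 8.0])
        offs, curvs = [], []
        for _ in range(100):
            H = b * np.log(K - x0) + rng.normal(0, 0.05, K.size)
            fit = fit_value_function(np.column_stack([K, H]))
            assert fit["fit_ok"]
            offs.append(fit["offset"])
            curvs.append(fit["curvature"])
        assert abs(np.median(offs) - x0) < 0.5
        assert abs(np.median(curvs) - b) < 0.5

    def test_power_law_fallback(self):
        K = np.array([1.0, 2.0, 4.0, 8.0])
        fit = fit_value_function(np.column_stack([K, 3 * K**0.5]), form="power")
        assert fit["fit_ok"]
        assert fit["curvature"] == pytest.approx(0.5, abs=1e-9)


class TestLimitFunction:
    def test_closed_form_parabola(self):
        K = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = fit_limit_function(np.column_stack([K, -((K - 2) ** 2) + 4]))
        assert fit["fit_ok"]
        assert fit["turning_point"] == pytest.approx(2.0, abs=1e-9)
        assert fit["apex"] == pytest.approx(4.0, abs=1e-9)
        assert fit["quad_area"] == pytest.approx(32 / 3, abs=1e-9)

    def test_upward_parabola_has_no_area(self):
        K = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_limit_function(np.column_stack([K, (K - 1) ** 2 + 1]))
        assert not fit["fit_ok"]
        assert math.isnan(fit["quad_area"])

    def test_coefficients_equal_normal_equations(self):
        """Fitted quadratic equals the closed-form least-squares solution."""
        rng = np.random.default_rng(3)
        K = np.array([0.5, 1.5, 3.0, 4.5])
        s = rng.uniform(0, 5, 4)
        fit = fit_limit_function(np.column_stack([K, s]))
        V = np.vander(K, 3)
        coef = np.linalg.solve(V.T @ V, V.T @ s)
        assert np.allclose(fit["coeffs"], coef, atol=1e-9)

    def test_vertex_matches_coefficient_formulas(self):
        """Vertex/area features equal the closed forms of the fitted
        coefficients on random concave designs."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            K = np.sort(rng.uniform(0, 8, 5))
            s = rng.uniform(0.5, 4, 5)
            fit = fit_limit_function(np.column_stack([K, s]))
            if fit["coeffs"] is None:
                continue
            a, b, c = fit["coeffs"]
            if abs(a) < 1e-8:
                continue
            assert fit["turning_point"] == pytest.approx(-b / (2 * a), abs=1e-9)
            assert fit["apex"] == pytest.approx(c - b**2 / (4 * a), abs=1e-9)
            if fit["fit_ok"]:
                disc = b**2 - 4 * a * c
                assert fit["quad_area"] == pytest.approx(
                    disc**1.5 / (6 * a**2), abs=1e-9
                )


class TestTradeoff:
    def test_three_four_five(self):
        t = tradeoff_features([(3.0, 4.0)])
        assert t["r"] == pytest.approx(5.0)
        assert t["theta"] == pytest.approx(53.13010235415598)
        assert t["sigma_theta"] == 0.0 and t["sigma_r"] == 0.0

    def test_axis_symmetry(self):
        t = tradeoff_features([(1.0, 0.0), (0.0, 1.0)])
        assert t["theta"] == pytest.approx(45.0)
        assert t["r"] == pytest.approx(1.0)
        assert t["sigma_r"] == pytest.approx(0.0)

    def test_matches_hand_arithmetic(self):
        pts = [(1.0, 2.0), (2.0, 1.0), (3.0, 3.0), (0.5, 4.0)]
        r = [math.hypot(a, b) for a, b in pts]
        th = [math.degrees(math.atan2(b, a)) for a, b in pts]
        t = tradeoff_features(pts)
        assert t["r"] == pytest.approx(np.mean(r))
        assert t["theta"] == pytest.approx(np.mean(th))
        assert t["sigma_r"] == pytest.approx(np.std(r, ddof=1))
        assert t["sigma_theta"] == pytest.approx(np.std(th, ddof=1))

    def test_per_category_identity(self):
        """r^2 = H+^2 + H-^2 holds per category by construction."""
        pts = [(0.3, 2.2), (1.7, 0.9)]
        for hp, hm in pts:
            t = tradeoff_features([(hp, hm)])
            assert t["r"] ** 2 == pytest.approx(hp**2 + hm**2)

    def test_no_usable_category(self):
        t = tradeoff_features([(0.0, 0.0)])
        assert not t["fit_ok"] and math.isnan(t["r"])


class TestAssembleProfile:
    def test_profile_exposes_fifteen_metrics(self, small_cohort):
        ds, _ = small_cohort
        prof = profiles_from_responses(ds.responses)
        assert [c for c in prof.columns if c in METRICS] == list(METRICS)
        assert len(METRICS) == 15

    def test_all_zero_avoidance_is_excluded(self):
        frames = [make_responses({f"cat{i}": [3, 4, 5, 6]}, valence="inc")
                  for i in range(1, 5)]
        resp = pd.concat(frames, ignore_index=True)
        prof = assemble_profile(resp)
        assert not prof.valid
        assert prof.exclusion_reason != ""

    def test_k_plus_is_category_mean(self):
        frames = []
        for i, k in enumerate((2, 4, 6, 8), start=1):
            frames.append(make_responses({f"cat{i}": [k] * 10}, valence="inc"))
            frames.append(make_responses({f"cat{i}": [1, 2, 3, 4, 5]}))
        prof = assemble_profile(pd.concat(frames, ignore_index=True))
        assert prof.mean_k_inc == pytest.approx(5.0)
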