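import numpy as np
import pytest

from thermoniche.mechanistic import (
    BriereParams,
    QuadraticParams,
    TraitPosterior,
    abundance_curve,
    briere,
    curve_extrema,
    posterior_summary,
    quadratic,
)
from thermoniche.synthetic import default_trait_truth


class TestBriere:
    def test_zero_at_and_outside_thermal_limits(self):
        p = BriereParams(c=1e-4, T0=10, Tm=38)
        assert briere(10.0, p) == 0.0
        assert briere(38.0, p) == 0.0
        assert briere(5.0, p) == 0.0
        assert briere(40.0, p) == 0.0

    def test_direct_formula_evaluation(self):
        p = BriereParams(c=1e-4, T0=10, Tm=38)
        expected = 1e-4 * 25 * 15 * np.sqrt(13)
        assert briere(25.0, p) == pytest.approx(expected, rel=1e-12)
        assert briere(25.0, p) == pytest.approx(0.135208, abs=1e-6)

    def test_positive_inside_and_continuous_at_limits(self):
        p = BriereParams(c=1e-4, T0=10, Tm=38)
        grid = np.linspace(10.01, 37.99, 500)
        assert np.all(briere(grid, p) > 0)
        # approaches 0 at both thermal limits (no jump discontinuity)
        assert briere(10 + 1e-9, p) < 1e-10
        assert briere(38 - 1e-9, p) < 1e-3

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BriereParams(c=-1, T0=10, Tm=38)
        with pytest.raises(ValueError):
            BriereParams(c=1, T0=38, Tm=10)


class TestQuadratic:
    def test_concave_down_vertex_and_zeros(self):
        p = QuadraticParams(q=0.01, T0=5, Tm=35)
        mid = (5 + 35) / 2
        assert quadratic(mid, p) == pytest.approx(0.01 * 15**2)
        assert quadratic(20.0, p) == pytest.approx(2.25)
        assert quadratic(5.0, p) == 0.0
        assert quadratic(35.0, p) == 0.0
        assert quadratic(2.0, p) == 0.0  # truncated below

    def test_concave_up_minimum_at_midpoint(self):
        p = QuadraticParams(q=0.01, T0=5, Tm=35, orientation="concave_up")
        grid = np.linspace(0, 40, 401)
        v = quadratic(grid, p)
        assert grid[np.argmin(v)] == pytest.approx(20.0)
        assert quadratic(0.0, p) > quadratic(10.0, p)
        assert quadratic(40.0, p) > quadratic(30.0, p)


class TestAbundanceCurve:
    def test_hand_arithmetic_at_one_temperature(self):
        traits = {
            "EFD": QuadraticParams(q=0.04, T0=12, Tm=36),
            "pEA": QuadraticParams(q=0.006, T0=12, Tm=36),
            "MDR": BriereParams(c=7e-5, T0=12, Tm=36),
            "mu": QuadraticParams(q=1e-4, T0=50, Tm=90, orientation="concave_up"),
        }
        T = 25.0
        curve = abundance_curve(TraitPosterior.from_point(traits), np.array([T]))
        efd = 0.04 * 13 * 11
        pea = 0.006 * 13 * 11
        mdr = 7e-5 * 25 * 13 * np.sqrt(11)
        mu = 1e-4 * (25 - 50) * (25 - 90)
        assert curve.values[0, 0] == pytest.approx(efd * pea * mdr / mu**2, rel=1e-12)

    def test_zero_numerator_trait_zeroes_abundance(self):
        traits = default_trait_truth(12, 36)
        curve = abundance_curve(TraitPosterior.from_point(traits))
        outside = (curve.grid <= 12) | (curve.grid >= 36)
        assert np.all(curve.values[0, outside] == 0)

    def test_identical_draws_zero_width_band(self):
        traits = default_trait_truth()
        curve = abundance_curve(TraitPosterior.from_point(traits, n_draws=20))
        np.testing.assert_array_equal(curve.lower, curve.upper)
        np.testing.assert_array_equal(curve.median, curve.lower)

    def test_band_contains_median(self):
        from thermoniche.synthetic import generate_trait_posteriors

        post = generate_trait_posteriors(default_trait_truth(), n_draws=100, dispersion=0.05, seed=0)
        curve = abundance_curve(post)
        assert np.all(curve.lower <= curve.median + 1e-12)
        assert np.all(curve.median <= curve.upper + 1e-12)

    def test_empty_or_descending_grid_rejected(self):
        traits = TraitPosterior.from_point(default_trait_truth())
        with pytest.raises(ValueError):
            abundance_curve(traits, np.array([]))
        with pytest.raises(ValueError):
            abundance_curve(traits, np.array([3.0, 2.0, 1.0]))


class TestCurveExtrema:
    def test_support_limits_match_trait_zeros(self):
        # Tmin = max numerator T0, Tmax = min numerator Tm, within one grid step
        traits = {
            "EFD": QuadraticParams(q=0.04, T0=10, Tm=38),
            "pEA": QuadraticParams(q=0.006, T0=9, Tm=37),
            "MDR": BriereParams(c=7e-5, T0=13, Tm=35),
            "mu": QuadraticParams(q=1e-4, T0=49, Tm=89, orientation="concave_up"),
        }
        curve = abundance_curve(TraitPosterior.from_point(traits))
        tmin, topt, tmax = curve_extrema(curve.values[0], curve.grid)
        assert 13.0 <= tmin <= 13.1 + 1e-9
        assert 34.9 - 1e-9 <= tmax <= 35.0
        assert tmin < topt < tmax

    def test_optimum_matches_dense_brute_force(self):
        traits = default_trait_truth(12, 36)
        coarse = abundance_curve(TraitPosterior.from_point(traits))  # 0.1 degC grid
        _, topt, _ = curve_extrema(coarse.values[0], coarse.grid)
        fine_grid = np.arange(10.0, 38.0, 0.001)
        fine = abundance_curve(TraitPosterior.from_point(traits), fine_grid)
        topt_fine = fine_grid[np.argmax(fine.values[0])]
        assert abs(topt - topt_fine) <= 0.1

    def test_all_zero_curve_gives_absent_extrema(self):
        grid = np.arange(0.0, 10.0, 1.0)
        assert curve_extrema(np.zeros(10), grid) == (None, None, None)

    def test_scale_invariance_of_extrema(self):
        traits = default_trait_truth()
        scaled = dict(traits)
        scaled["EFD"] = QuadraticParams(q=traits["EFD"].q * 7.0, T0=traits["EFD"].T0, Tm=traits["EFD"].Tm)
        a = abundance_curve(TraitPosterior.from_point(traits))
        b = abundance_curve(TraitPosterior.from_point(scaled))
        np.testing.assert_allclose(b.values, 7.0 * a.values, rtol=1e-12)
        assert curve_extrema(a.values[0], a.grid) == curve_extrema(b.values[0], b.grid)

    def test_grid_refinement_moves_extrema_at_most_one_coarse_step(self):
        traits = TraitPosterior.from_point(default_trait_truth())
        coarse_grid = np.arange(0.0, 45.0, 0.2)
        fine_grid = np.arange(0.0, 45.0, 0.1)
        a = curve_extrema(abundance_curve(traits, coarse_grid).values[0], coarse_grid)
        b = curve_extrema(abundance_curve(traits, fine_grid).values[0], fine_grid)
        for x, y in zip(a, b):
            assert abs(x - y) <= 0.2 + 1e-9


class TestPosteriorSummary:
    def test_identical_draws_zero_width_ci(self):
        curve = abundance_curve(TraitPosterior.from_point(default_trait_truth(), n_draws=5))
        s = posterior_summary(curve)
        for q in ("Tmin", "Topt", "Tmax"):
            assert s.summary[q]["lower"] == s.summary[q]["upper"] == s.summary[q]["median"]
        assert s.n_undefined == 0

    def test_quantiles_match_analytic_distribution(self):
        # MDR's lower zero is the binding constraint: Tmin ~ Normal(13, 0.5)
        rng = np.random.default_rng(42)
        n = 5000
        sigma = 0.5
        t0s = rng.normal(13.0, sigma, n)
        draws = {
            "EFD": [QuadraticParams(0.04, 9.0, 37.0)] * n,
            "pEA": [QuadraticParams(0.006, 9.0, 37.0)] * n,
            "MDR": [BriereParams(7e-5, t, 36.0) for t in t0s],
            "mu": [QuadraticParams(1e-4, 50.0, 90.0, "concave_up")] * n,
        }
        step = 0.01
        grid = np.arange(5.0, 40.0, step)
        curve = abundance_curve(TraitPosterior(draws), grid)
        s = posterior_summary(curve)
        # Monte-Carlo SE of the quantiles plus one grid-step discretization
        se_med = 1.2533 * sigma / np.sqrt(n)
        z = 1.959963984540054
        from scipy.stats import norm

        for q, target in (("median", 13.0), ("lower", 13.0 - z * sigma), ("upper", 13.0 + z * sigma)):
            p = {"median": 0.5, "lower": 0.025, "upper": 0.975}[q]
            dens = norm.pdf(norm.ppf(p), scale=sigma)
            se = np.sqrt(p * (1 - p) / n) / dens
            assert abs(s.summary["Tmin"][q] - target) <= 3 * se + step

    def test_no_defined_draws_rejected(self):
        draws = TraitPosterior.from_point(default_trait_truth(12, 36), n_draws=2)
        grid = np.array([1.0, 2.0, 3.0])  # entirely outside the support
        curve = abundance_curve(draws, grid)
        with pytest.raises(ValueError):
            posterior_summary(curve)
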