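import numpy as np
import pytest

import vanthoff as vh
from vanthoff.fitting import transform_scale, chi_squared, bic
from vanthoff.spline import KnotSet, build_natural_spline

from conftest import random_knotset


def series(T, y, sigma):
    return vh.VantHoffSeries(np.asarray(T, float), np.asarray(y, float), np.asarray(sigma, float))


class TestTransformScale:
    def test_linear_is_identity(self):
        s = series([300, 310], [0, 1], [0.1, 0.1])
        d = transform_scale(s, "linear")
        np.testing.assert_allclose(d.x, [300, 310])
        np.testing.assert_allclose(d.y, [0, 1])

    def test_reciprocal_reverses_order(self):
        s = series([300, 310], [0, 1], [0.1, 0.2])
        d = transform_scale(s, "reciprocal")
        np.testing.assert_allclose(d.x, [1 / 310, 1 / 300])
        np.testing.assert_allclose(d.y, [1, 0])  # 310 K comes first in x
        np.testing.assert_allclose(d.sigma, [0.2, 0.1])

    def test_unknown_scale_raises(self):
        s = series([300, 310], [0, 1], [0.1, 0.1])
        with pytest.raises(ValueError):
            transform_scale(s, "log")


class TestChiSquared:
    def test_data_on_spline_gives_zero(self):
        sp = build_natural_spline(KnotSet(np.array([0.0, 1.0]), np.array([0.0, 2.0])))
        s = series([0.25, 0.5], [0.5, 1.0], [0.3, 0.3])
        d = transform_scale(s, "linear")
        assert chi_squared(d, sp) == pytest.approx(0.0, abs=1e-24)

    def test_standardized_residuals_sum(self):
        # residuals of +1 and -2 standard errors give chi^2 = 5
        sp = build_natural_spline(KnotSet(np.array([0.0, 1.0]), np.array([0.0, 0.0])))
        s = series([0.2, 0.8], [0.5, -1.0], [0.5, 0.5])
        d = transform_scale(s, "linear")
        assert chi_squared(d, sp) == pytest.approx(5.0, rel=1e-12)

    def test_random_data_against_direct_summation(self):
        rng = np.random.default_rng(21)
        ks = random_knotset(rng, 3, lo=280.0, hi=320.0)
        sp = build_natural_spline(ks)
        T = np.linspace(281, 319, 9)
        y = rng.normal(size=9)
        sig = rng.uniform(0.1, 0.5, size=9)
        d = transform_scale(series(T, y, sig), "linear")
        expected = sum(
            ((yi - float(sp(xi))) / si) ** 2 for xi, yi, si in zip(d.x, d.y, d.sigma)
        )
        assert chi_squared(d, sp) == pytest.approx(expected, rel=1e-12)

    def test_point_outside_domain_raises(self):
        sp = build_natural_spline(KnotSet(np.array([0.0, 1.0]), np.array([0.0, 0.0])))
        d = transform_scale(series([0.5, 2.0], [0, 0], [1, 1]), "linear")
        with pytest.raises(ValueError):
            chi_squared(d, sp)


class TestBic:
    def test_direct_arithmetic(self):
        assert bic(10.0, 2, 11) == pytest.approx(10 + 4 * np.log(11), rel=1e-12)
        assert bic(10.0, 2, 11) == pytest.approx(19.5916, abs=5e-4)

    def test_penalty_monotone_in_n(self):
        values = [bic(3.0, n, 30) for n in range(1, 8)]
        assert all(b2 > b1 for b1, b2 in zip(values, values[1:]))

    def test_no_degrees_of_freedom_raises(self):
        with pytest.raises(ValueError):
            bic(1.0, 2, 4)


class TestFreeKnotFit:
    def test_n1_matches_weighted_least_squares(self, study_grid):
        # straight-line model: compare against the closed-form WLS solution
        # of the normal equations, an independent oracle
        rng = np.random.default_rng(22)
        y = -12000 / study_grid + 40 + rng.normal(0, 0.1, study_grid.size)
        sig = rng.uniform(0.05, 0.3, study_grid.size)
        s = series(study_grid, y, sig)
        for scale in ("linear", "reciprocal"):
            fit = vh.fit_free_knot_spline(s, 1, scale)
            d = transform_scale(s, scale)
            W = 1.0 / sig**2
            Wd = 1.0 / d.sigma**2
            X = np.vstack([np.ones_like(d.x), d.x]).T
            beta = np.linalg.solve(X.T @ (Wd[:, None] * X), X.T @ (Wd * d.y))
            sp = fit.spline()
            lo, hi = sp.domain
            assert float(sp(lo)) == pytest.approx(beta[0] + beta[1] * lo, abs=1e-8)
            assert float(sp(hi)) == pytest.approx(beta[0] + beta[1] * hi, abs=1e-8)

    def test_exact_recovery_of_a_spline_truth(self):
        # data generated exactly on a 4-knot natural spline is refit to
        # machine-level chi^2 with the same interval count
        ks = KnotSet(np.array([0.0, 0.3, 0.7, 1.0]) * 40 + 283,
                     np.array([-2.0, 0.5, 1.0, -0.5]))
        sp = build_natural_spline(ks)
        T = np.linspace(283, 323, 21)
        s = series(T, np.asarray(sp(T)), np.full(21, 0.1))
        fit = vh.fit_free_knot_spline(s, 3, "linear", vh.FitConfig(seed=3, multistart=10))
        assert fit.chi2_min <= 1e-8

    def test_row_order_invariance(self, study_grid):
        rng = np.random.default_rng(23)
        y = rng.normal(size=study_grid.size)
        sig = rng.uniform(0.1, 0.2, study_grid.size)
        s1 = series(study_grid, y, sig)
        perm = rng.permutation(study_grid.size)
        # the series sorts its rows on construction, so permuted input must
        # give a bit-identical fit
        s2 = series(study_grid[perm], y[perm], sig[perm])
        cfg = vh.FitConfig(seed=5, multistart=4)
        f1 = vh.fit_free_knot_spline(s1, 2, "reciprocal", cfg)
        f2 = vh.fit_free_knot_spline(s2, 2, "reciprocal", cfg)
        assert f1.chi2_min == f2.chi2_min
        np.testing.assert_array_equal(f1.knots.positions, f2.knots.positions)

    def test_too_few_points_raises(self):
        s = series([300, 310, 320], [0, 1, 2], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError, match="points"):
            vh.fit_free_knot_spline(s, 2, "linear")

    def test_edge_knots_pinned_to_data_extremes(self, study_grid, constant_dh_spec):
        s = vh.simulate_lnkeq_series(constant_dh_spec, study_grid, seed=2)
        fit = vh.fit_free_knot_spline(s, 2, "reciprocal", vh.FitConfig(seed=2, multistart=3))
        assert fit.knots.positions[0] == pytest.approx(1 / study_grid[-1], rel=1e-14)
        assert fit.knots.positions[-1] == pytest.approx(1 / study_grid[0], rel=1e-14)


class TestModelSelection:
    def test_wide_span_distinguishes_reciprocal_truth(self):
        # over four decades in T the reciprocal line cannot be mimicked by
        # a linear-scale line, so the scan must pick reciprocal N=1
        T = np.geomspace(30, 300000, 21)
        y = 5.0 - 2000.0 / T
        s = series(T, y, np.full(21, 0.05))
        rep = vh.select_model(s, vh.FitConfig(seed=1, n_max=2, multistart=3))
        assert rep.selected.scale == "reciprocal"
        assert rep.selected.n_intervals == 1

    def test_three_points_only_n1(self):
        s = series([290, 300, 310], [0.0, 0.5, 1.0], [0.1, 0.1, 0.1])
        rep = vh.select_model(s, vh.FitConfig(seed=0))
        assert len(rep.results) == 2
        assert {r.scale for r in rep.results} == {"linear", "reciprocal"}
        assert all(r.n_intervals == 1 for r in rep.results)

    def test_fewer_than_three_points_raises(self):
        s = series([290, 300], [0.0, 0.5], [0.1, 0.1])
        with pytest.raises(ValueError, match="3"):
            vh.select_model(s)

    def test_identical_seed_gives_identical_report(self, study_grid, constant_dh_spec):
        s = vh.simulate_lnkeq_series(constant_dh_spec, study_grid, seed=9)
        cfg = vh.FitConfig(seed=9, n_max=3, multistart=4)
        r1 = vh.select_model(s, cfg)
        r2 = vh.select_model(s, cfg)
        assert r1.to_dict() == r2.to_dict()

    def test_chi2_nesting_in_n(self, study_grid, strong_dcp_spec):
        s = vh.simulate_lnkeq_series(strong_dcp_spec, study_grid, seed=4)
        rep = vh.select_model(s, vh.FitConfig(seed=4, n_max=5, multistart=4))
        for scale in ("linear", "reciprocal"):
            chis = [r.chi2_min for r in rep.results if r.scale == scale]
            assert all(c2 <= c1 + 1e-6 for c1, c2 in zip(chis, chis[1:]))

    def test_selected_attains_minimum_bic(self, study_grid, constant_dh_spec):
        s = vh.simulate_lnkeq_series(constant_dh_spec, study_grid, seed=6)
        rep = vh.select_model(s, vh.FitConfig(seed=6, n_max=3, multistart=3))
        assert rep.selected.bic <= min(r.bic for r in rep.results) + rep.config.bic_tie_tol

    def test_report_serializes_full_candidate_table(self, tmp_path, study_grid, constant_dh_spec):
        import json

        s = vh.simulate_lnkeq_series(constant_dh_spec, study_grid, seed=7)
        rep = vh.select_model(s, vh.FitConfig(seed=7, n_max=2, multistart=3))
        p = tmp_path / "report.json"
        rep.to_json(p)
        loaded = json.loads(p.read_text())
        assert len(loaded["candidates"]) == 4
        assert loaded["config"]["seed"] == 7
        assert loaded["bic_comparison"] == "absolute"
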