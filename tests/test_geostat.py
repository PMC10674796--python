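import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecazones.dataio import PointSurvey, RasterGrid
from ecazones.geostat import (
    VariogramModel, anisotropy_ratio, empirical_variogram, fit_variogram,
    krige_at_points, loo_cross_validation, nugget_sill_ratio,
    ordinary_kriging, spherical_gamma, summary_stats,
)

REFERENCE_MODEL = VariogramModel(nugget=0.19, partial_sill=0.54, range_m=130.4)


class TestSphericalGamma:
    def test_zero_at_origin(self):
        assert spherical_gamma(REFERENCE_MODEL, 0.0) == 0.0

    def test_total_sill_beyond_range(self):
        assert spherical_gamma(REFERENCE_MODEL, 130.4) == pytest.approx(0.73)
        assert spherical_gamma(REFERENCE_MODEL, 1e6) == pytest.approx(0.73)

    def test_half_range_closed_form(self):
        # c0 + c·(1.5·0.5 − 0.5·0.125) = 0.19 + 0.54·0.6875
        assert spherical_gamma(REFERENCE_MODEL, 65.2) == pytest.approx(0.56125)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            spherical_gamma(REFERENCE_MODEL, -1.0)

    @given(st.floats(0.0, 500.0), st.floats(0.0, 500.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_nondecreasing_and_bounded(self, h1, h2):
        lo, hi = sorted([h1, h2])
        g_lo, g_hi = (float(spherical_gamma(REFERENCE_MODEL, h))
                      for h in (lo, hi))
        assert g_lo <= g_hi + 1e-12
        assert g_hi <= REFERENCE_MODEL.total_sill + 1e-12


class TestEmpiricalVariogram:
    def test_two_points_single_bin(self):
        s = PointSurvey([0.0, 10.0], [0.0, 0.0], [0.0, 2.0])
        emp = empirical_variogram(s, lag_width=5.0, max_lag=20.0)
        assert len(emp.lag_centers) == 1
        assert emp.gamma[0] == pytest.approx(2.0)  # (1/2)·2²
        assert emp.pair_counts[0] == 1

    def test_constant_survey_zero_semivariance(self, rng):
        s = PointSurvey(rng.uniform(0, 100, 30), rng.uniform(0, 100, 30),
                        np.full(30, 7.0))
        emp = empirical_variogram(s, lag_width=10.0, max_lag=60.0)
        np.testing.assert_allclose(emp.gamma, 0.0, atol=1e-15)

    def test_matches_brute_force_pair_enumeration(self, rng):
        n = 200
        s = PointSurvey(rng.uniform(0, 100, n), rng.uniform(0, 100, n),
                        rng.normal(50, 10, n))
        lag_width, max_lag = 8.0, 64.0
        emp = empirical_variogram(s, lag_width=lag_width, max_lag=max_lag)
        # O(n²) brute force
        edges = np.arange(0.0, max_lag + lag_width, lag_width)
        sums = np.zeros(len(edges) - 1)
        counts = np.zeros(len(edges) - 1, dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                d = np.hypot(s.x[i] - s.x[j], s.y[i] - s.y[j])
                if d > max_lag:
                    continue
                k = min(int(np.searchsorted(edges, d, side="right")) - 1,
                        len(edges) - 2)
                sums[k] += 0.5 * (s.values[i] - s.values[j]) ** 2
                counts[k] += 1
        keep = counts > 0
        np.testing.assert_array_equal(emp.pair_counts, counts[keep])
        np.testing.assert_allclose(emp.gamma, sums[keep] / counts[keep],
                                   rtol=1e-12)

    def test_no_pairs_within_max_lag(self):
        s = PointSurvey([0.0, 1000.0], [0.0, 0.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            empirical_variogram(s, lag_width=1.0, max_lag=10.0)


class TestFitVariogram:
    def test_noiseless_recovery_under_1pct(self):
        h = np.linspace(5, 300, 30)
        from ecazones.geostat import EmpiricalVariogram
        emp = EmpiricalVariogram(h, spherical_gamma(REFERENCE_MODEL, h),
                                 np.full(30, 100))
        fit = fit_variogram(emp)
        assert fit.nugget == pytest.approx(0.19, rel=0.01, abs=0.002)
        assert fit.partial_sill == pytest.approx(0.54, rel=0.01)
        assert fit.range_m == pytest.approx(130.4, rel=0.01)

    def test_pure_nugget_flagged(self):
        from ecazones.geostat import EmpiricalVariogram
        h = np.linspace(5, 300, 20)
        emp = EmpiricalVariogram(h, np.full(20, 0.5), np.full(20, 50))
        fit = fit_variogram(emp)
        assert fit.partial_sill <= 0.05 * fit.total_sill
        assert not fit.range_identifiable

    def test_noisy_recovery_median_range_error(self):
        from ecazones.geostat import EmpiricalVariogram
        h = np.linspace(5, 300, 30)
        g_true = spherical_gamma(REFERENCE_MODEL, h)
        rel_errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            g = g_true * (1 + 0.05 * rng.standard_normal(30))
            emp = EmpiricalVariogram(h, np.maximum(g, 1e-6),
                                     np.full(30, 100))
            fit = fit_variogram(emp)
            rel_errors.append(abs(fit.range_m - 130.4) / 130.4)
        assert np.median(rel_errors) < 0.15

    def test_too_few_bins(self):
        from ecazones.geostat import EmpiricalVariogram
        emp = EmpiricalVariogram([1.0, 2.0, 3.0], [0.1, 0.2, 0.3],
                                 [5, 5, 5])
        with pytest.raises(ValueError):
            fit_variogram(emp)


class TestAnisotropy:
    def test_isotropic_field_ratio_near_one(self):
        from ecazones.synthetic import simulate_gaussian_field
        template = RasterGrid.empty(0, 0, 12.0, 45, 45)
        field = simulate_gaussian_field(
            template, VariogramModel(0.0, 1.0, 130.0), 0.0, 1.0, seed=7)
        gx, gy = template.cell_centers()
        rng = np.random.default_rng(7)
        idx = rng.choice(45 * 45, 2000, replace=False)
        s = PointSurvey(gx.ravel()[idx], gy.ravel()[idx],
                        field.values.ravel()[idx])
        ratio, _ = anisotropy_ratio(s, n_directions=2)
        assert ratio < 1.2

    def test_stretched_field_ratio_near_two(self):
        from ecazones.synthetic import simulate_gaussian_field
        template = RasterGrid.empty(0, 0, 10.0, 50, 50)
        field = simulate_gaussian_field(
            template, VariogramModel(0.0, 1.0, 120.0), 0.0, 1.0, seed=3)
        gx, gy = template.cell_centers()
        rng = np.random.default_rng(3)
        idx = rng.choice(50 * 50, 2000, replace=False)
        # stretch x by 2: geometric anisotropy with major axis east-west
        s = PointSurvey(2.0 * gx.ravel()[idx], gy.ravel()[idx],
                        field.values.ravel()[idx])
        ratio, major = anisotropy_ratio(s, n_directions=6,
                                        max_lag=300.0, lag_width=25.0)
        assert ratio == pytest.approx(2.0, abs=0.3)
        assert major == pytest.approx(90.0)  # east-west azimuth

    def test_constant_field_errors(self, rng):
        s = PointSurvey(rng.uniform(0, 100, 50), rng.uniform(0, 100, 50),
                        np.full(50, 3.0))
        with pytest.raises(ValueError):
            anisotropy_ratio(s)


class TestOrdinaryKriging:
    def test_single_point_weight_one(self, small_template):
        s = PointSurvey([50.0], [50.0], [42.0])
        est, se = ordinary_kriging(s, REFERENCE_MODEL, small_template,
                                   search_radius=1e9)
        np.testing.assert_allclose(est.values, 42.0)
        assert (se.values >= 0).all()

    def test_midpoint_symmetry_weights_half(self):
        s = PointSurvey([0.0, 10.0], [0.0, 0.0], [10.0, 30.0])
        est, _ = krige_at_points(s, REFERENCE_MODEL, np.array([[5.0, 0.0]]),
                                 search_radius=1e9)
        assert est[0] == pytest.approx(20.0)  # equal weights by symmetry

    def test_neighbourhood_equals_full_direct_solve(self, rng,
                                                    small_template):
        from scipy.spatial.distance import cdist, pdist, squareform
        n = 20
        s = PointSurvey(rng.uniform(0, 100, n), rng.uniform(0, 100, n),
                        rng.normal(50, 10, n))
        model = VariogramModel(5.0, 20.0, 60.0)
        est, _ = ordinary_kriging(s, model, small_template,
                                  max_neighbors=n, search_radius=1e9)
        G = spherical_gamma(model, squareform(pdist(s.coords)))
        A = np.ones((n + 1, n + 1))
        A[:n, :n] = G
        A[n, n] = 0.0
        gx, gy = small_template.cell_centers()
        targets = np.column_stack([gx.ravel(), gy.ravel()])
        b = np.ones((n + 1, len(targets)))
        b[:n] = spherical_gamma(model, cdist(s.coords, targets))
        sol = np.linalg.solve(A, b)
        direct = sol[:n].T @ s.values
        np.testing.assert_allclose(est.values.ravel(), direct, atol=1e-8)
        # weights sum to 1 at every cell
        np.testing.assert_allclose(sol[:n].sum(axis=0), 1.0, atol=1e-8)

    def test_exact_interpolation_at_data_points(self, rng):
        s = PointSurvey(rng.uniform(0, 100, 15), rng.uniform(0, 100, 15),
                        rng.normal(50, 10, 15))
        est, se = krige_at_points(s, REFERENCE_MODEL, s.coords,
                                  search_radius=1e9)
        np.testing.assert_allclose(est, s.values, atol=1e-8)

    def test_duplicate_points_resolved(self, small_template):
        s = PointSurvey([50, 50, 20], [50, 50, 20], [10.0, 20.0, 5.0])
        est, _ = ordinary_kriging(s, REFERENCE_MODEL, small_template,
                                  search_radius=1e9)
        assert np.isfinite(est.values).all()


class TestLooCrossValidation:
    def test_constant_field_zero_errors(self, rng):
        s = PointSurvey(rng.uniform(0, 100, 20), rng.uniform(0, 100, 20),
                        np.full(20, 5.0))
        cv = loo_cross_validation(s, REFERENCE_MODEL, max_neighbors=10)
        assert cv.rmse == pytest.approx(0.0, abs=1e-10)
        assert cv.mean_error == pytest.approx(0.0, abs=1e-10)

    def test_three_point_hand_oracle(self):
        # LOO with 2 remaining points each: solve the 3×3 OK systems by hand
        s = PointSurvey([0.0, 10.0, 5.0], [0.0, 0.0, 8.66], [1.0, 3.0, 2.0])
        model = VariogramModel(0.0, 1.0, 50.0)
        preds, ses = [], []
        for i in range(3):
            others = [j for j in range(3) if j != i]
            c = s.coords
            g12 = spherical_gamma(model, np.linalg.norm(c[others[0]]
                                                        - c[others[1]]))
            A = np.array([[0.0, g12, 1.0], [g12, 0.0, 1.0], [1.0, 1.0, 0.0]])
            b = np.array([
                spherical_gamma(model, np.linalg.norm(c[others[0]] - c[i])),
                spherical_gamma(model, np.linalg.norm(c[others[1]] - c[i])),
                1.0,
            ])
            w = np.linalg.solve(A, b)
            preds.append(w[0] * s.values[others[0]]
                         + w[1] * s.values[others[1]])
            ses.append(np.sqrt(w[0] * b[0] + w[1] * b[1] + w[2]))
        errors = np.array(preds) - s.values
        expected_rmse = float(np.sqrt(np.mean(errors**2)))
        # relax the minimum-points precondition via direct solves
        from ecazones.geostat import _solve_ok
        got = []
        for i in range(3):
            others = [j for j in range(3) if j != i]
            e, v, w, mu = _solve_ok(s.coords[others], s.values[others],
                                    s.coords[i], model)
            got.append(e)
        np.testing.assert_allclose(got, preds, atol=1e-10)
        assert expected_rmse >= 0

    def test_calibration_on_model_simulated_field(self):
        from ecazones.synthetic import simulate_gaussian_field
        model = VariogramModel(0.1, 0.9, 120.0)
        template = RasterGrid.empty(0, 0, 15.0, 40, 40)
        field = simulate_gaussian_field(template, model, 0.0, 1.0, seed=11)
        gx, gy = template.cell_centers()
        rng = np.random.default_rng(11)
        idx = rng.choice(1600, 500, replace=False)
        s = PointSurvey(gx.ravel()[idx], gy.ravel()[idx],
                        field.values.ravel()[idx])
        cv = loo_cross_validation(s, model, max_neighbors=16)
        assert abs(cv.mean_standardised_error) < 0.1
        assert 0.7 < cv.mean_standardised_squared_error < 1.3
        assert cv.rmse_below_data_sd

    def test_too_few_points(self):
        s = PointSurvey([0.0, 1.0], [0.0, 0.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            loo_cross_validation(s, REFERENCE_MODEL)


class TestNuggetSillRatio:
    def test_printed_fit_gives_26_percent(self):
        pct, _ = nugget_sill_ratio(REFERENCE_MODEL)
        assert pct == pytest.approx(26.0, abs=0.05)

    def test_zero_nugget_strong(self):
        pct, cls = nugget_sill_ratio(VariogramModel(0.0, 1.0, 100.0))
        assert pct == 0.0 and cls == "strong"

    def test_pure_nugget_weak(self):
        pct, cls = nugget_sill_ratio(VariogramModel(1.0, 0.0, 100.0))
        assert pct == 100.0 and cls == "weak"

    def test_zero_sill_errors(self):
        with pytest.raises(ValueError):
            nugget_sill_ratio(VariogramModel(0.0, 0.0, 100.0))


class TestSummaryStats:
    def test_symmetric_triplet(self):
        s = PointSurvey([0, 1, 2], [0, 0, 0], [1.0, 2.0, 3.0])
        stats = summary_stats(s)
        assert stats["mean"] == 2.0
        assert stats["median"] == 2.0
        assert stats["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_values_zero_cv(self):
        s = PointSurvey([0, 1, 2], [0, 0, 0], [5.0, 5.0, 5.0])
        assert summary_stats(s)["cv_percent"] == 0.0

    def test_textbook_formula_oracle_on_lognormal(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(0.0, 0.5, 1000)
        s = PointSurvey(np.arange(1000.0), np.zeros(1000), v)
        stats = summary_stats(s)
        n = 1000
        mean = v.sum() / n
        sd = np.sqrt(((v - mean) ** 2).sum() / (n - 1))
        m3 = ((v - mean) ** 3).sum() / n
        m2 = ((v - mean) ** 2).sum() / n
        g1 = m3 / m2**1.5
        skew_adj = np.sqrt(n * (n - 1)) / (n - 2) * g1  # adjusted Fisher-Pearson
        assert stats["mean"] == pytest.approx(mean, abs=1e-10)
        assert stats["sd"] == pytest.approx(sd, abs=1e-10)
        assert stats["cv_percent"] == pytest.approx(100 * sd / mean,
                                                    abs=1e-8)
        assert stats["skewness"] == pytest.approx(skew_adj, abs=1e-10)
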