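import numpy as np
import pytest

from microkrige.synthdata import simulate_grf_points
from microkrige.variogram import (
    Coregionalization,
    EmpiricalVariogram,
    VariogramModel,
    empirical_semivariogram,
    fit_coregionalization,
    fit_variogram,
    major_range,
    model_gamma,
    select_model,
)


def brute_force_semivariogram(points, values, bin_width, max_lag):
    """All-pairs oracle for the method-of-moments estimator."""
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    nbins = int(np.ceil(max_lag / bin_width))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, int)
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d = np.hypot(*(points[i] - points[j]))
            b = int(d // bin_width)
            if b < nbins:
                sums[b] += (values[i] - values[j]) ** 2
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        gamma = np.where(counts > 0, sums / (2 * np.maximum(counts, 1)), np.nan)
    return gamma, counts


class TestEmpirical:
    def test_worked_example(self):
        emp = empirical_semivariogram(
            np.array([[0.0, 0], [1, 0], [2, 0]]), [0.0, 1.0, 2.0],
            bin_width=1.0, max_lag=3.0)
        assert emp.gamma[1] == pytest.approx(0.5)
        assert emp.pair_counts[1] == 2
        assert emp.gamma[2] == pytest.approx(2.0)
        assert emp.pair_counts[2] == 1

    def test_constant_values(self, rng):
        pts = rng.uniform(0, 50, (30, 2))
        emp = empirical_semivariogram(pts, np.full(30, 7.0))
        assert np.nanmax(emp.gamma) == 0.0

    def test_duplicated_points(self, rng):
        pts = rng.uniform(0, 50, (15, 2))
        vals = rng.normal(0, 1, 15)
        emp1 = empirical_semivariogram(pts, vals, bin_width=5.0, max_lag=40.0)
        pts2 = np.vstack([pts, pts])
        vals2 = np.concatenate([vals, vals])
        emp2 = empirical_semivariogram(pts2, vals2, bin_width=5.0, max_lag=40.0)
        # bin 0 additionally picks up the 15 zero-distance duplicate pairs
        nz = emp1.pair_counts > 0
        nz[0] = False
        assert emp2.gamma[nz] == pytest.approx(emp1.gamma[nz])
        assert np.array_equal(emp2.pair_counts[nz], emp1.pair_counts[nz] * 4)
        assert emp2.pair_counts[0] == emp1.pair_counts[0] * 4 + 15

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 80, (50, 2))
        vals = rng.normal(20, 4, 50)
        emp = empirical_semivariogram(pts, vals, bin_width=7.0, max_lag=56.0)
        gamma_bf, counts_bf = brute_force_semivariogram(pts, vals, 7.0, 56.0)
        nz = counts_bf > 0
        assert np.allclose(emp.gamma[nz], gamma_bf[nz], atol=1e-12)
        assert np.array_equal(emp.pair_counts, counts_bf)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            empirical_semivariogram(np.array([[0.0, 0]]), [1.0])


class TestModelGamma:
    @pytest.mark.parametrize("kind,shape", [("stable", 0.7), ("spherical", 1.0),
                                            ("exponential", 1.0), ("gaussian", 2.0)])
    def test_zero_at_origin(self, kind, shape):
        m = VariogramModel(kind, 0.5, 2.0, 30.0, shape=shape)
        assert model_gamma(m, 0.0) == 0.0

    def test_exponential_closed_form(self):
        m = VariogramModel("exponential", 0.0, 1.0, 30.0)
        assert model_gamma(m, 30.0) == pytest.approx(1 - np.exp(-3), abs=1e-12)

    def test_spherical_plateau(self):
        m = VariogramModel("spherical", 0.3, 1.7, 40.0)
        assert model_gamma(m, 40.0) == pytest.approx(2.0)
        assert model_gamma(m, 400.0) == pytest.approx(2.0)

    def test_negative_distance(self):
        m = VariogramModel("exponential", 0, 1, 30)
        with pytest.raises(ValueError):
            model_gamma(m, -1.0)

    def test_nondecreasing_in_distance(self):
        for kind in ("stable", "spherical", "exponential", "gaussian"):
            m = VariogramModel(kind, 0.2, 3.0, 25.0, shape=1.3)
            g = model_gamma(m, np.linspace(0.01, 200, 500))
            assert np.all(np.diff(g) >= -1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            VariogramModel("stable", -1, 1, 10)
        with pytest.raises(ValueError):
            VariogramModel("stable", 0, 1, 10, shape=3.0)
        with pytest.raises(ValueError):
            VariogramModel("cubic", 0, 1, 10)


def exact_emp(model, lags, counts=200):
    return EmpiricalVariogram(lag_centers=lags, gamma=model_gamma(model, lags),
                              pair_counts=np.full(len(lags), counts),
                              max_lag=float(lags[-1] + 1), bin_width=float(lags[1] - lags[0]))


class TestFit:
    def test_exact_spherical_recovery(self):
        true = VariogramModel("spherical", 0.4, 2.1, 33.0)
        emp = exact_emp(true, (np.arange(12) + 0.5) * 5.0)
        fit = fit_variogram(emp, "spherical")
        assert fit.nugget == pytest.approx(true.nugget, rel=0.01, abs=0.01)
        assert fit.partial_sill == pytest.approx(true.partial_sill, rel=0.01)
        assert fit.range_param == pytest.approx(true.range_param, rel=0.01)

    def test_grf_recovery_median(self, rng):
        true = VariogramModel("exponential", 0.0, 4.0, 30.0)
        errs = []
        for seed in range(10):
            pts = np.random.default_rng(seed).uniform(0, 200, (400, 2))
            z = simulate_grf_points(pts, true, seed=seed)
            fit = fit_variogram(empirical_semivariogram(pts, z), "exponential")
            errs.append(fit.range_param)
        assert abs(np.median(errs) - 30.0) / 30.0 < 0.30

    def test_too_few_bins(self):
        emp = exact_emp(VariogramModel("exponential", 0, 1, 10), np.array([1.0, 2, 3]))
        with pytest.raises(ValueError):
            fit_variogram(emp, "exponential")

    def test_nonnegative_params_always(self, rng):
        pts = rng.uniform(0, 60, (40, 2))
        vals = rng.normal(0, 1, 40)
        for kind in ("stable", "spherical", "exponential", "gaussian"):
            fit = fit_variogram(empirical_semivariogram(pts, vals), kind)
            assert fit.nugget >= 0 and fit.partial_sill >= 0 and fit.range_param > 0


class TestSelect:
    def test_spherical_truth_selected(self):
        true = VariogramModel("spherical", 0.2, 2.0, 35.0)
        emp = exact_emp(true, (np.arange(14) + 0.5) * 4.0)
        best, table = select_model(emp)
        assert best.kind in ("spherical", "stable")
        assert len(table) == 4

    def test_single_candidate(self):
        emp = exact_emp(VariogramModel("exponential", 0.1, 1.0, 20.0),
                        (np.arange(10) + 0.5) * 4.0)
        best, table = select_model(emp, candidate_kinds=("gaussian",))
        assert best.kind == "gaussian"
        assert len(table) == 1


class TestMajorRange:
    def test_exponential(self):
        m = VariogramModel("exponential", 0.0, 1.0, 30.0)
        assert major_range(m) == pytest.approx(30.0, rel=0.01)

    def test_spherical_definition(self):
        assert major_range(VariogramModel("spherical", 0.0, 1.0, 58.0)) == 58.0

    def test_degenerate(self):
        m = VariogramModel("exponential", 1.0, 0.0, 30.0)
        with pytest.warns(UserWarning):
            assert major_range(m) == 0.0


class TestCoregionalization:
    def test_psd_enforced(self):
        with pytest.raises(ValueError):
            Coregionalization(("pm", "c"), VariogramModel("exponential", 0, 1, 30),
                              np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_identical_covariate_hits_bound(self, rng):
        pts = rng.uniform(0, 100, (120, 2))
        z = simulate_grf_points(pts, VariogramModel("exponential", 0.0, 4.0, 30.0), seed=3)
        coreg = fit_coregionalization(pts, z, {"svf50": z.copy()}, kind="exponential")
        b01 = coreg.sills[0, 1]
        bound = np.sqrt(coreg.sills[0, 0] * coreg.sills[1, 1])
        assert b01 == pytest.approx(bound, rel=0.05)

    def test_independent_covariate_small_cross(self):
        ratios = []
        for seed in range(10):
            srng = np.random.default_rng(seed)
            pts = srng.uniform(0, 150, (200, 2))
            z = simulate_grf_points(pts, VariogramModel("exponential", 0.0, 4.0, 30.0),
                                    seed=seed)
            c = simulate_grf_points(pts, VariogramModel("exponential", 0.0, 4.0, 30.0),
                                    seed=seed + 1000)
            coreg = fit_coregionalization(pts, z, {"svf50": c})
            ratios.append(abs(coreg.sills[0, 1])
                          / np.sqrt(coreg.sills[0, 0] * coreg.sills[1, 1]))
        assert np.median(ratios) < 0.2

    def test_degenerate_covariate_dropped(self, rng):
        pts = rng.uniform(0, 100, (60, 2))
        z = rng.normal(0, 1, 60)
        coreg = fit_coregionalization(pts, z, {"svf50": np.full(60, 0.5)})
        assert coreg.names == ("pm",)

    def test_all_structures_psd(self, demo):
        frame = demo["clean_frame"]
        pts = demo["points"]
        from microkrige.covariates import extract_covariates
        cov = extract_covariates(demo["scene"], pts[:150], warn_inside=False)
        coreg = fit_coregionalization(pts[:150], frame["pm25"].to_numpy()[:150],
                                      {n: cov[n].to_numpy() for n in cov.columns})
        eig = np.linalg.eigvalsh(coreg.sills)
        assert eig.min() >= -1e-10
        for u in range(len(coreg.names)):
            for v in range(u + 1, len(coreg.names)):
                assert (coreg.sills[u, v] ** 2
                        <= coreg.sills[u, u] * coreg.sills[v, v] + 1e-10)
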