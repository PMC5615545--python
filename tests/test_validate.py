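import numpy as np
import pandas as pd
import pytest

from microkrige.interpolate import KernelSpec, MethodConfig, table1_configs
from microkrige.synthdata import simulate_grf_points
from microkrige.validate import (
    compare_kernels,
    compare_methods,
    evaluate_methods,
    kfold_r2,
    loocv,
)
from microkrige.variogram import Coregionalization, VariogramModel

from conftest import bare_scene

EXP = VariogramModel("exponential", 0.5, 4.0, 30.0)


def brute_force_loocv(points, values, model):
    """Refit-per-fold OK oracle."""
    from microkrige.interpolate import ok_predict_points
    n = len(points)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        preds[i] = ok_predict_points(points[keep], values[keep], model,
                                     points[i:i + 1])[0]
    return preds


class TestLOOCV:
    def test_rmse_hand_value(self):
        # predictions {1, 2} vs observations {0, 4}: sqrt((1 + 4)/2)
        preds = np.array([1.0, 2.0])
        obs = np.array([0.0, 4.0])
        rmse = float(np.sqrt(np.mean((preds - obs) ** 2)))
        assert rmse == pytest.approx(1.5811, abs=1e-4)

    def test_constant_field_ok(self, rng):
        pts = rng.uniform(0, 100, (12, 2))
        vals = np.full(12, 8.0)
        cfg = MethodConfig(name="OK", algorithm="OK", variogram=EXP)
        preds, rmse, n_excl = loocv(pts, vals, cfg)
        assert preds == pytest.approx(8.0, abs=1e-8)
        assert rmse == pytest.approx(0.0, abs=1e-8)
        assert n_excl == 0

    def test_ok_matches_brute_force(self, rng):
        pts = rng.uniform(0, 80, (15, 2))
        vals = rng.uniform(10, 40, 15)
        cfg = MethodConfig(name="OK", algorithm="OK", variogram=EXP)
        preds, _, _ = loocv(pts, vals, cfg)
        assert preds == pytest.approx(brute_force_loocv(pts, vals, EXP), abs=1e-8)

    def test_ock_matches_brute_force(self, rng):
        from microkrige.interpolate import ock_predict_points
        pts = rng.uniform(0, 80, (15, 2))
        vals = rng.uniform(10, 40, 15)
        cov = pd.DataFrame({"svf50": rng.uniform(0, 1, 15)})
        coreg = Coregionalization(("pm", "svf50"),
                                  VariogramModel("exponential", 0.0, 1.0, 30.0),
                                  np.array([0.3, 0.05]),
                                  np.array([[4.0, 1.2], [1.2, 1.0]]))
        cfg = MethodConfig(name="OCK_SVF", algorithm="OCK", covariate_set=("svf50",),
                           coreg=coreg)
        preds, _, _ = loocv(pts, vals, cfg, covariate_table=cov)
        want = np.empty(15)
        for i in range(15):
            keep = np.arange(15) != i
            want[i] = ock_predict_points(pts[keep], vals[keep],
                                         {"svf50": cov["svf50"].to_numpy()[keep]},
                                         coreg, pts[i:i + 1])[0]
        assert preds == pytest.approx(want, abs=1e-8)

    def test_lpi_kib_loocv_run(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        vals = rng.uniform(5, 25, 20)
        scene = bare_scene((100.0, 100.0))
        for alg in ("LPI", "KIB"):
            cfg = MethodConfig(name=alg, algorithm=alg,
                               kernel=KernelSpec("exponential", 40.0))
            preds, rmse, _ = loocv(pts, vals, cfg, scene=scene)
            assert np.all(np.isfinite(preds))
            assert rmse >= 0

    def test_needs_three_points(self):
        cfg = MethodConfig(name="OK", algorithm="OK", variogram=EXP)
        with pytest.raises(ValueError):
            loocv(np.array([[0.0, 0], [1, 1]]), np.array([1.0, 2.0]), cfg)

    def test_ok_beats_mean_predictor(self):
        wins = 0
        true = VariogramModel("exponential", 0.2, 4.0, 30.0)
        for seed in range(20):
            pts = np.random.default_rng(seed).uniform(0, 150, (80, 2))
            z = simulate_grf_points(pts, true, seed=seed, mean=30.0)
            cfg = MethodConfig(name="OK", algorithm="OK", variogram=true)
            _, rmse, _ = loocv(pts, z, cfg)
            mean_rmse = float(np.sqrt(np.mean((z - z.mean()) ** 2)))
            wins += rmse < mean_rmse
        assert wins >= 19

    def test_permutation_invariant(self, rng):
        pts = rng.uniform(0, 80, (18, 2))
        vals = rng.uniform(10, 30, 18)
        cfg = MethodConfig(name="OK", algorithm="OK", variogram=EXP)
        _, rmse1, _ = loocv(pts, vals, cfg)
        perm = rng.permutation(18)
        _, rmse2, _ = loocv(pts[perm], vals[perm], cfg)
        assert rmse1 == pytest.approx(rmse2, abs=1e-10)


class TestKFold:
    def test_perfect_predictions(self, rng):
        # an exact interpolator on a deterministic smooth field scores ~1
        pts = rng.uniform(0, 100, (40, 2))
        vals = 20 + 0.1 * pts[:, 0] + 0.05 * pts[:, 1]
        cfg = MethodConfig(name="LPI", algorithm="LPI",
                           kernel=KernelSpec("gaussian", 80.0))
        r2 = kfold_r2(pts, vals, cfg, k=2, seed=0)
        assert r2 == pytest.approx(1.0, abs=1e-6)

    def test_null_r2_small(self):
        # white noise + pure-nugget kriging: out-of-fold predictions carry no
        # information, so the squared correlation stays near zero
        nug = VariogramModel("exponential", 1.0, 1e-12, 1e3)
        r2s = []
        for seed in range(20):
            srng = np.random.default_rng(seed)
            pts = srng.uniform(0, 200, (200, 2))
            vals = srng.normal(0, 1, 200)
            cfg = MethodConfig(name="OK", algorithm="OK", variogram=nug)
            r2s.append(kfold_r2(pts, vals, cfg, k=2, seed=seed))
        assert np.median(r2s) < 0.05

    def test_seed_determinism(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        vals = rng.uniform(10, 30, 30)
        cfg = MethodConfig(name="OK", algorithm="OK", variogram=EXP)
        assert kfold_r2(pts, vals, cfg, seed=5) == kfold_r2(pts, vals, cfg, seed=5)

    def test_zero_variance_warns(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        cfg = MethodConfig(name="OK", algorithm="OK", variogram=EXP)
        with pytest.warns(UserWarning):
            r2 = kfold_r2(pts, np.full(20, 3.0), cfg, seed=0)
        assert np.isnan(r2)


class TestCompare:
    def test_kernel_report_shape(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        values = {"pm25": rng.uniform(10, 30, 30), "pm10": rng.uniform(20, 50, 30)}
        report = compare_kernels(pts, values, bandwidth=50.0, seed=1)
        assert len(report.table) == 12          # 6 kernels x 2 variables
        assert report.table.groupby("variable")["winner"].sum().tolist() == [1, 1]

    def test_identical_kernel_identical_rows(self, rng):
        pts = rng.uniform(0, 100, (25, 2))
        values = {"pm25": rng.uniform(10, 30, 25)}
        report = compare_kernels(pts, values, bandwidth=40.0, seed=2,
                                 kernel_kinds=("gaussian", "gaussian"))
        a, b = report.table.iloc[0], report.table.iloc[1]
        assert a.rmse == b.rmse and a.r2_kfold == b.r2_kfold

    def test_groupings_structure_and_averaging(self, rng):
        pts = rng.uniform(0, 100, (25, 2))
        vals = rng.uniform(15, 45, 25)
        cov = pd.DataFrame({"svf50": rng.uniform(0.3, 1, 25),
                            "fai50": rng.uniform(0, 0.4, 25),
                            "rda50": rng.uniform(0, 0.6, 25)})
        coregs = {}
        for cs in (("svf50",), ("fai50",), ("rda50",), ("fai50", "rda50", "svf50")):
            p1 = len(cs) + 1
            coregs[cs] = Coregionalization(
                ("pm",) + cs, VariogramModel("exponential", 0.0, 1.0, 30.0),
                np.full(p1, 0.2), np.diag([4.0] + [1.0] * len(cs)))
        cfgs = table1_configs(kernel=KernelSpec("exponential", 50.0),
                              variogram=EXP, coregs=coregs)
        scene = bare_scene((100.0, 100.0))
        report, by_alg, by_cov = compare_methods(
            pts, {"pm25": vals}, cfgs, covariate_table=cov, scene=scene, seed=3)
        assert len(report.table) == 13
        assert sorted(by_alg.algorithm) == ["KIB", "LPI", "OCK", "OK"]
        assert sorted(by_cov.covariate) == ["fai50", "none", "rda50", "svf50"]
        # group means equal hand-averaged member rows
        t = report.table
        lpi_mean = t[t.algorithm == "LPI"].rmse.mean()
        assert by_alg.loc[by_alg.algorithm == "LPI", "rmse"].iloc[0] == pytest.approx(lpi_mean)
        none_mean = t[(t.covariate == "none")].rmse.mean()
        assert by_cov.loc[by_cov.covariate == "none", "rmse"].iloc[0] == pytest.approx(none_mean)

    def test_report_csv_roundtrip(self, rng, tmp_path):
        pts = rng.uniform(0, 100, (20, 2))
        report = compare_kernels(pts, {"pm25": rng.uniform(10, 30, 20)}, seed=4)
        path = tmp_path / "report.csv"
        report.to_csv(path)
        back = pd.read_csv(path)
        assert len(back) == len(report.table)
        assert {"n", "k", "seed", "rmse", "r2_kfold"} <= set(back.columns)
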