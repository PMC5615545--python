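"""End-to-end pipeline: simulate/load -> preprocess -> covariates ->
variogram -> 13 interpolations -> cross-validation -> mapping."""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .covariates import COVARIATE_NAMES, extract_covariates
from .grids import GridSpec
from .interpolate import KernelSpec, run_method, table1_configs
from .io import (
    read_scene_geojson,
    read_transect_csv,
    write_ascii_grid,
    write_clean_csv,
    write_scene_geojson,
    write_surface,
    write_transect_csv,
)
from .preprocess import clean_points_frame, preprocess_records
from .synthdata import (
    DEFAULT_TRUE_VARIOGRAM,
    default_route,
    make_street_grid,
    roadside_hotspots,
    simulate_pm_field,
    simulate_walk,
)
from .validate import compare_all_13
from .variogram import (
    empirical_semivariogram,
    fit_coregionalization,
    major_range,
    select_model,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    outdir: str = "run_out"
    seed: int = 1
    # inputs: either simulate=True or provide paths
    simulate: bool = True
    transect_csv: str | None = None
    scene_geojson: str | None = None
    # simulation knobs
    layout: str = "orthogonal"
    extent: tuple[float, float] = (500.0, 500.0)
    block_size: float = 80.0
    road_width: float = 20.0
    mean_level: float = 30.0          # placeholder background; no reported value
    n_hotspots: int = 8
    # analysis knobs
    merge_radius: float = 2.0
    thin_step: int = 1                # keep every k-th clean point
    bandwidth: float = 50.0
    kernel: str = "exponential"
    lpi_order: int = 1
    variogram_kinds: tuple[str, ...] = ("stable", "spherical", "exponential", "gaussian")
    grid_divisor: float = 330.0       # cellsize = short side / divisor
    cell_size: float | None = None
    k: int = 2
    barrier_resolution: float | None = None
    variables: tuple[str, ...] = ("pm25", "pm10")
    crs: str = "local-meters"

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded)."""
        data = _plain(asdict(self))
        data.pop("outdir", None)
        blob = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=True))

    def validate_paths(self) -> None:
        if not self.simulate:
            for p in (self.transect_csv, self.scene_geojson):
                if p is None:
                    raise ValueError("non-simulated runs need transect_csv and scene_geojson")
                if not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def simulate_inputs(config: RunConfig, outdir: Path):
    """Generate scene, truth field and transect; write them under outdir."""
    scene = make_street_grid(config.layout, extent=tuple(config.extent),
                             block_size=config.block_size,
                             road_width=config.road_width, seed=config.seed)
    hotspots = roadside_hotspots(scene, n=config.n_hotspots,
                                 amplitude_range=(30.0, 45.0),
                                 decay_range=(14.0, 20.0), seed=config.seed + 1)
    truth = simulate_pm_field(scene, DEFAULT_TRUE_VARIOGRAM, hotspots,
                              covariate_betas={"svf50": -1.0, "fai50": 2.0, "rda50": 1.5},
                              mean_level=config.mean_level, seed=config.seed + 2,
                              cell_size=500.0 / 60.0 if config.extent[0] >= 450 else None)
    route = default_route(scene)
    records = simulate_walk(route, truth, seed=config.seed + 3)
    write_scene_geojson(scene, outdir / "scene.geojson")
    write_transect_csv(records, outdir / "transect.csv")
    write_ascii_grid(truth.grid, truth.pm25, outdir / "truth_pm25.asc")
    write_ascii_grid(truth.grid, truth.pm10, outdir / "truth_pm10.asc")
    (outdir / "truth_meta.yaml").write_text(yaml.safe_dump(_plain({
        "true_variogram": asdict(truth.true_variogram),
        "hotspots": [asdict(h) for h in truth.hotspots],
        "covariate_betas": truth.covariate_betas,
        "mean_level": truth.mean_level,
    }), sort_keys=True))
    return scene, records


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Stage order: (simulate) -> preprocess -> covariates -> variogram ->
    interpolate (13 surfaces per variable) -> validate -> map. A manifest
    records the package version, seed, config hash and outputs. Deterministic
    stages are byte-identical across reruns of the same config.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(outdir / "config.yaml")
    manifest: dict = {"config_hash": chash, "seed": config.seed,
                      "version": __version__, "stages": {}, "surfaces": {}}
    t_all = time.time()

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"][name] = {"t_start": round(time.time() - t_all, 2)}

    try:
        if config.simulate:
            stage("simulate")
            scene, records = simulate_inputs(config, outdir)
        else:
            scene = read_scene_geojson(config.scene_geojson)
            records = read_transect_csv(config.transect_csv)

        stage("preprocess")
        clean = preprocess_records(records, merge_radius=config.merge_radius)
        clean = clean[:: max(1, int(config.thin_step))]
        write_clean_csv(clean, outdir / "clean.csv")
        frame = clean_points_frame(clean)
        pts = frame[["x", "y"]].to_numpy()

        stage("covariates")
        cov_table = extract_covariates(scene, pts)
        cov_table.to_csv(outdir / "covariates.csv", index=False, float_format="%.10g")

        stage("variogram")
        models = {}
        vario_rows = []
        for var in config.variables:
            emp = empirical_semivariogram(pts, frame[var].to_numpy())
            model, scores = select_model(emp, config.variogram_kinds)
            models[var] = model
            vario_rows.append({"variable": var, "kind": model.kind,
                               "nugget": model.nugget, "partial_sill": model.partial_sill,
                               "range_param": model.range_param, "shape": model.shape,
                               "major_range": major_range(model)})
            _plot_variogram(emp, model, outdir / f"variogram_{var}.png")
        import pandas as pd
        pd.DataFrame(vario_rows).to_csv(outdir / "variogram_fits.csv", index=False,
                                        float_format="%.10g")

        stage("interpolate")
        short = min(config.extent) if config.simulate else min(scene.extent)
        cell = config.cell_size or short / config.grid_divisor
        grid = GridSpec.from_extent(scene.extent[0], scene.extent[1], cellsize=cell)
        kernel = KernelSpec(kind=config.kernel, bandwidth=config.bandwidth)
        cov_values = {nm: cov_table[nm].to_numpy() for nm in COVARIATE_NAMES}
        for var in config.variables:
            vals = frame[var].to_numpy()
            coregs = {}
            for cs in (("svf50",), ("fai50",), ("rda50",), tuple(sorted(COVARIATE_NAMES))):
                coregs[cs] = fit_coregionalization(
                    pts, vals, {nm: cov_values[nm] for nm in cs},
                    kind=models[var].kind)
            configs = table1_configs(kernel=kernel, variogram=models[var],
                                     coregs=coregs, order=config.lpi_order)
            for cfg in configs:
                surf = run_method(cfg, pts, vals, covariate_table=cov_table,
                                  scene=scene, grid=grid)
                fname = f"surface_{var}_{cfg.name}.asc"
                write_surface(surf, outdir / fname, format="asc")
                manifest["surfaces"].setdefault(var, []).append(fname)

        stage("validate")
        values_by_var = {var: frame[var].to_numpy() for var in config.variables}
        # rebuild per-variable configs for validation (coregs fitted above per var)
        cv_tables = []
        grouped_a, grouped_c = [], []
        for var in config.variables:
            vals = values_by_var[var]
            coregs = {}
            for cs in (("svf50",), ("fai50",), ("rda50",), tuple(sorted(COVARIATE_NAMES))):
                coregs[cs] = fit_coregionalization(
                    pts, vals, {nm: cov_values[nm] for nm in cs}, kind=models[var].kind)
            report, by_alg, by_cov = compare_all_13(
                pts, {var: vals}, kernel, models[var], coregs, cov_table,
                scene=scene, k=config.k, seed=config.seed, order=config.lpi_order,
                barrier_resolution=config.barrier_resolution)
            cv_tables.append(report.table)
            grouped_a.append(by_alg)
            grouped_c.append(by_cov)
        cv = pd.concat(cv_tables, ignore_index=True)
        cv.insert(0, "n", len(pts))
        cv.insert(1, "k", config.k)
        cv.insert(2, "seed", config.seed)
        cv.insert(3, "config_hash", chash)
        cv.to_csv(outdir / "cv_report.csv", index=False, float_format="%.10g")
        pd.concat(grouped_a, ignore_index=True).to_csv(
            outdir / "cv_by_algorithm.csv", index=False, float_format="%.10g")
        pd.concat(grouped_c, ignore_index=True).to_csv(
            outdir / "cv_by_covariate.csv", index=False, float_format="%.10g")

        stage("map")
        # best method per variable by LOOCV RMSE -> copy of its surface name
        best = (cv.sort_values(["variable", "rmse"]).groupby("variable").head(1)
                [["variable", "method", "rmse", "r2_kfold"]])
        best.to_csv(outdir / "best_methods.csv", index=False, float_format="%.10g")
    except Exception as exc:
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") from exc

    manifest["grid_cellsize"] = float(cell)
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(_plain(manifest), sort_keys=True))
    return outdir


def _plot_variogram(emp, model, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .variogram import model_gamma

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ok = emp.pair_counts > 0
    ax.plot(emp.lag_centers[ok], emp.gamma[ok], "o", ms=4, label="empirical")
    d = np.linspace(0, emp.max_lag, 200)
    ax.plot(d, model_gamma(model, d), "-", label=f"{model.kind} fit")
    ax.set_xlabel("lag (m)")
    ax.set_ylabel("semivariance")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
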