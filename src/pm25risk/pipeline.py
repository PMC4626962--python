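"""End-to-end analysis pipeline.

Stages, in order (each writes its artifacts under the run's output
directory and registers them in ``manifest.json``):

1. ``data``      -- generate a synthetic station network (or load a CSV);
2. ``monthly``   -- aggregate daily records to station-month means;
3. ``screen``    -- correlation matrix and PCA/varimax loadings;
4. ``train``     -- fit the network on pooled station-months (features:
   temp, precip, wind, SO2, NO2, GDP, population density), chronological
   80/20 train/validation split per station;
5. ``evaluate``  -- per-station validation statistics (r, IA, MBE, RMSE);
6. ``forecast``  -- project covariates to each horizon and predict PM2.5
   with the frozen network (fit-then-forecast);
7. ``grid``      -- IDW concentration rasters per horizon and month;
8. ``risk``      -- population-density rasters, population-risk surfaces
   and natural-breaks class maps.

The manifest records the configuration, seeds, per-stage artifact content
hashes and warnings; it contains no timestamps, so two runs with the same
configuration and seed produce byte-identical manifests.  Wall-clock
timings go to ``run.log``, which is not part of the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ann, evaluation, screening, synthetic
from .exposure import ExposureParams, population_risk
from .spatial import GridSpec, RasterField, grid_from_points, idw_interpolate

__all__ = [
    "FEATURES",
    "RunConfig",
    "PipelineUserError",
    "StageFailure",
    "run_pipeline",
    "STAGES",
    "run_stage",
]

#: model features, in training order (station coordinates excluded)
FEATURES = ["temp", "precip", "wind", "so2", "no2", "gdp", "pop_density"]


class PipelineUserError(Exception):
    """Bad configuration or missing upstream artifact (user error)."""


class StageFailure(Exception):
    """A stage failed while executing."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/out"
    data_csv: str | None = None          # load instead of generating
    synthetic: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    horizons: list[int] = field(default_factory=lambda: [7, 12])
    projection: str = "linear"           # linear | geometric | constant
    scenario: dict = field(default_factory=dict)  # per-variable annual factor
    spatial: dict = field(default_factory=dict)
    exposure: dict = field(default_factory=dict)
    months: list[int] | None = None      # months to rasterize (default: all)

    def validate(self) -> None:
        if any(h <= 0 for h in self.horizons):
            raise PipelineUserError("horizons must be positive (years)")
        if self.projection not in ("linear", "geometric", "constant"):
            raise PipelineUserError(
                f"unknown projection method {self.projection!r}"
            )
        if self.data_csv is not None and not Path(self.data_csv).exists():
            raise PipelineUserError(f"data_csv not found: {self.data_csv}")
        unknown = set(self.scenario) - set(FEATURES)
        if unknown:
            raise PipelineUserError(
                f"scenario names unknown covariates: {sorted(unknown)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineUserError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# manifest plumbing


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_manifest(out: Path) -> dict:
    mpath = out / "manifest.json"
    if mpath.exists():
        return json.loads(mpath.read_text())
    return {"config": None, "seed": None, "stages": {}}


def _record_stage(
    out: Path, cfg: RunConfig, stage: str, artifacts: list[Path],
    caught: list[warnings.WarningMessage],
) -> None:
    manifest = _load_manifest(out)
    cfg_dict = cfg.to_dict()
    cfg_dict.pop("output_dir")  # where a run lives is not part of its content
    manifest["config"] = cfg_dict
    manifest["seed"] = cfg.seed
    manifest["stages"][stage] = {
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(artifacts)
        },
        "warnings": sorted(str(w.message) for w in caught),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def _log(out: Path, stage: str, seconds: float) -> None:
    with open(out / "run.log", "a") as fh:
        fh.write(f"stage={stage} wall_time_s={seconds:.3f}\n")


def _require(out: Path, relpath: str, producer: str) -> Path:
    p = out / relpath
    if not p.exists():
        raise PipelineUserError(
            f"missing artifact {relpath!r}; run the {producer!r} sub-command first"
        )
    return p


# ---------------------------------------------------------------------------
# stages


def stage_data(cfg: RunConfig, out: Path) -> list[Path]:
    if cfg.data_csv is not None:
        df = synthetic.read_csv(cfg.data_csv)
    else:
        spec_kwargs = dict(cfg.synthetic)
        spec_kwargs.setdefault("seed", cfg.seed)
        spec = synthetic.SyntheticSpec.from_dict(spec_kwargs)
        df = synthetic.generate_stations(spec)
    synthetic.write_csv(df, out / "data.csv")
    return [out / "data.csv"]


def _read_data(out: Path) -> pd.DataFrame:
    return synthetic.read_csv(_require(out, "data.csv", "simulate"))


def monthly_means(df: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of daily values per station-month."""
    d = df.copy()
    d["year"] = d["date"].dt.year
    d["month"] = d["date"].dt.month
    cols = ["pm25"] + FEATURES
    g = (
        d.groupby(["station_id", "year", "month"], sort=True)
        .agg({**{c: "mean" for c in cols}, "x": "first", "y": "first"})
        .reset_index()
    )
    return g[["station_id", "x", "y", "year", "month"] + cols]


def stage_monthly(cfg: RunConfig, out: Path) -> list[Path]:
    monthly = monthly_means(_read_data(out))
    monthly.to_csv(out / "monthly.csv", index=False)
    return [out / "monthly.csv"]


def stage_screen(cfg: RunConfig, out: Path) -> list[Path]:
    df = _read_data(out)
    corr = screening.correlation_matrix(df)
    corr.write_csv(out / "correlations.csv")
    pca = screening.pca_varimax(df)
    pca.write_csv(out / "pca_loadings.csv")
    return [out / "correlations.csv", out / "pca_loadings.csv"]


def _read_monthly(out: Path) -> pd.DataFrame:
    return pd.read_csv(_require(out, "monthly.csv", "simulate"))


def _chronological_split(monthly: pd.DataFrame, frac: float = 0.8):
    periods = sorted(
        monthly[["year", "month"]].drop_duplicates().itertuples(index=False)
    )
    n_train = max(1, min(len(periods) - 1, int(round(frac * len(periods)))))
    train_set = {(p.year, p.month) for p in periods[:n_train]}
    key = list(zip(monthly["year"], monthly["month"]))
    is_train = np.array([k in train_set for k in key])
    return monthly[is_train], monthly[~is_train]


def stage_train(cfg: RunConfig, out: Path) -> list[Path]:
    monthly = _read_monthly(out)
    train_df, _ = _chronological_split(monthly)
    opts = dict(cfg.train)
    algo = opts.pop("algo", "trainlm")
    tc = ann.TrainConfig(
        eta=opts.pop("eta", 0.1),
        max_epochs=opts.pop("max_epochs", 200),
        tol=opts.pop("tol", 0.0),
        seed=opts.pop("seed", cfg.seed + 1),
        n_hidden=opts.pop("n_hidden", None),
        optimizer_options=opts.pop("optimizer_options", {}),
    )
    if opts:
        raise PipelineUserError(f"unknown train config keys: {sorted(opts)}")
    fitres = ann.fit(
        train_df[FEATURES].to_numpy(),
        train_df["pm25"].to_numpy(),
        tc,
        optimizer=algo,
    )
    _save_model(fitres, algo, out / "model.json")
    pd.DataFrame({"epoch": range(1, len(fitres.trace) + 1),
                  "sse": fitres.trace}).to_csv(out / "train_trace.csv",
                                               index=False)
    return [out / "model.json", out / "train_trace.csv"]


def _save_model(fitres: ann.FitResult, algo: str, path: Path) -> None:
    x, y = fitres.x_norm, fitres.y_norm
    payload = {
        "features": FEATURES,
        "optimizer": algo,
        "converged": fitres.converged,
        "params": {
            "w_in": fitres.params.w_in.tolist(),
            "w_out": fitres.params.w_out.tolist(),
            "theta_hidden": fitres.params.theta_hidden.tolist(),
            "theta_out": fitres.params.theta_out.tolist(),
        },
        "x_norm": {"lo": x.lo, "hi": x.hi, "mins": x.mins.tolist(),
                   "maxs": x.maxs.tolist(), "keep": x.keep.tolist()},
        "y_norm": {"lo": y.lo, "hi": y.hi, "mins": y.mins.tolist(),
                   "maxs": y.maxs.tolist(), "keep": y.keep.tolist()},
        "clip_nonneg": fitres.config.clip_nonneg,
        "clip_inputs": fitres.config.clip_inputs,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _load_model(out: Path) -> ann.FitResult:
    raw = json.loads(_require(out, "model.json", "train").read_text())

    def norm(d):
        nz = ann.Normalizer(lo=d["lo"], hi=d["hi"])
        nz.mins = np.asarray(d["mins"], dtype=float)
        nz.maxs = np.asarray(d["maxs"], dtype=float)
        nz.keep = np.asarray(d["keep"], dtype=bool)
        nz.dropped = list(np.nonzero(~nz.keep)[0])
        return nz

    params = ann.NetworkParams(
        raw["params"]["w_in"], raw["params"]["w_out"],
        raw["params"]["theta_hidden"], raw["params"]["theta_out"],
    )
    cfg = ann.TrainConfig(clip_nonneg=raw["clip_nonneg"],
                          clip_inputs=raw.get("clip_inputs", True))
    return ann.FitResult(
        params, norm(raw["x_norm"]), norm(raw["y_norm"]), [], cfg,
        raw["optimizer"], raw["converged"],
    )


def stage_evaluate(cfg: RunConfig, out: Path) -> list[Path]:
    monthly = _read_monthly(out)
    fitres = _load_model(out)
    _, val_df = _chronological_split(monthly)
    reports = []
    for sid, g in val_df.groupby("station_id", sort=True):
        pred = ann.predict(fitres, g[FEATURES].to_numpy())
        reports.append(evaluation.evaluate_station(pred, g["pm25"], sid))
    evaluation.write_report_csv(reports, out / "eval_report.csv")
    return [out / "eval_report.csv"]


def _project(df: pd.DataFrame, horizon: int, method: str) -> pd.DataFrame:
    """Per-station, per-calendar-month covariates at the horizon year."""
    if method == "constant":
        d = df.copy()
        d["year"] = d["date"].dt.year
        d["month"] = d["date"].dt.month
        base_year = int(d["year"].max())
        g = (
            d.groupby(["station_id", "month"], sort=True)
            .agg({**{c: "mean" for c in synthetic.COVARIATES},
                  "x": "first", "y": "first"})
            .reset_index()
        )
        g["year"] = base_year + horizon
        return g
    return synthetic.project_covariates(df, horizon, method=method)


def _apply_scenario(proj: pd.DataFrame, scenario: dict, horizon: int):
    for var, factor in scenario.items():
        proj[var] = proj[var] * factor ** horizon
    return proj


def forecast_table(
    cfg: RunConfig, data: pd.DataFrame, fitres: ann.FitResult, horizon: int
) -> pd.DataFrame:
    """Predicted station-month PM2.5 at the horizon (0 = fitted base year)."""
    if horizon == 0:
        monthly = monthly_means(data)
        base_year = int(monthly["year"].max())
        proj = monthly[monthly["year"] == base_year].copy()
        proj = proj[["station_id", "x", "y", "year", "month"] + FEATURES]
    else:
        proj = _project(data, horizon, cfg.projection)
        proj = _apply_scenario(proj, cfg.scenario, horizon)
    proj = proj.sort_values(["station_id", "month"]).reset_index(drop=True)
    proj["pm25_pred"] = ann.predict_ptpt(fitres, proj[FEATURES].to_numpy())
    return proj


def stage_forecast(cfg: RunConfig, out: Path) -> list[Path]:
    data = _read_data(out)
    fitres = _load_model(out)
    paths = []
    for h in [0] + list(cfg.horizons):
        table = forecast_table(cfg, data, fitres, h)
        p = out / f"forecast_h{h}.csv"
        table.to_csv(p, index=False)
        paths.append(p)
    return paths


def _grid_spec(cfg: RunConfig, data: pd.DataFrame) -> GridSpec:
    sp = cfg.spatial
    coords = data.groupby("station_id", sort=True)[["x", "y"]].first()
    return grid_from_points(
        coords["x"].to_numpy(), coords["y"].to_numpy(),
        n_cols=sp.get("n_cols", 200), n_rows=sp.get("n_rows", 200),
        pad=sp.get("pad", 0.1),
    )


def _forecast_files(cfg: RunConfig, out: Path) -> list[tuple[int, Path]]:
    return [
        (h, _require(out, f"forecast_h{h}.csv", "forecast"))
        for h in [0] + list(cfg.horizons)
    ]


def _rasterize(table, grid, months, value_col, power):
    out = {}
    for month, g in table.groupby("month", sort=True):
        if months is not None and month not in months:
            continue
        out[int(month)] = idw_interpolate(
            g["x"].to_numpy(), g["y"].to_numpy(),
            g[value_col].to_numpy(), grid, power=power,
        )
    return out


def stage_grid(cfg: RunConfig, out: Path) -> list[Path]:
    data = _read_data(out)
    grid = _grid_spec(cfg, data)
    power = cfg.spatial.get("power", 2.0)
    paths = []
    for h, fpath in _forecast_files(cfg, out):
        table = pd.read_csv(fpath)
        year = int(table["year"].iloc[0])
        for month, fld in _rasterize(
            table, grid, cfg.months, "pm25_pred", power
        ).items():
            p = out / f"conc_{year}_{month:02d}.asc"
            fld.to_ascii(p)
            paths.append(p)
    return paths


def stage_risk(cfg: RunConfig, out: Path) -> list[Path]:
    data = _read_data(out)
    grid = _grid_spec(cfg, data)
    power = cfg.spatial.get("power", 2.0)
    params = ExposureParams(**cfg.exposure)
    paths = []
    for h, fpath in _forecast_files(cfg, out):
        table = pd.read_csv(fpath)
        year = int(table["year"].iloc[0])
        pop_fields = _rasterize(table, grid, cfg.months, "pop_density", power)
        for month, pop_fld in pop_fields.items():
            conc_name = f"conc_{year}_{month:02d}.asc"
            conc_fld = RasterField.from_ascii(_require(out, conc_name, "grid"))
            surface = population_risk(
                conc_fld, pop_fld, params, classify_k=3, source_id=conc_name,
            )
            base = f"{year}_{month:02d}"
            surface.population.to_ascii(out / f"risk_{base}.asc")
            surface.classes.to_ascii(out / f"riskclass_{base}.asc")
            surface.write_sidecar(out / f"risk_{base}.json")
            paths += [out / f"risk_{base}.asc", out / f"riskclass_{base}.asc",
                      out / f"risk_{base}.json"]
    return paths


STAGES = {
    "data": stage_data,
    "monthly": stage_monthly,
    "screen": stage_screen,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "forecast": stage_forecast,
    "grid": stage_grid,
    "risk": stage_risk,
}


def run_stage(cfg: RunConfig, stage: str) -> list[Path]:
    """Run one stage, record its artifacts and warnings in the manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            artifacts = STAGES[stage](cfg, out)
        except PipelineUserError:
            raise
        except Exception as exc:
            _record_stage(out, cfg, stage + ":failed", [], [])
            raise StageFailure(stage, exc) from exc
    _record_stage(out, cfg, stage, artifacts, caught)
    _log(out, stage, time.perf_counter() - t0)
    return artifacts


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all stages in order; returns the output directory."""
    cfg.validate()
    for stage in STAGES:
        run_stage(cfg, stage)
    return Path(cfg.output_dir)
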