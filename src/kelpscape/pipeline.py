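"""End-to-end orchestration: simulate -> qc -> transect-sim -> correlogram
-> sdm -> validate -> learning-curve, with a run manifest.

Every stage reads its inputs from, and writes its outputs to, a single run
directory; a stage whose outputs already exist is skipped unless forced, so
deleting one stage's files and re-running regenerates only that stage and
its dependents.  One master seed spawns per-stage streams; tabular outputs
use fixed 9-significant-digit formatting so re-runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from kelpscape import __version__, correlogram as cg, io as kio, sdm as ksdm
from kelpscape import synth, transects, validation
from kelpscape._seeds import stage_seed_int
from kelpscape.errors import ConfigError, SiteTooSmallError
from kelpscape.raster import EnvironmentRasters

FLOAT_FMT = "%.9g"


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults; only ``seed`` has none."""

    seed: int | None = None
    out_dir: str = "run"
    preset: str | None = "paperlike"
    input_path: str | None = None  # pre-existing quadrat table instead of simulating
    site_config_path: str | None = None  # plain-text per-site generative config
    # qc
    min_alt: float = kio.DEFAULT_MIN_ALTITUDE
    max_alt: float = kio.DEFAULT_MAX_ALTITUDE
    max_gap: float = kio.DEFAULT_MAX_GAP
    # transect simulation
    transect_length: float = 50.0
    transect_repeats: int = 5
    n_max: int = 25
    t_threshold: float = 2.0
    # correlogram
    bin_width: float = 5.0
    max_dist: float = 100.0
    min_pairs: int = 30
    null_reps: int = 199
    null_mode: str = "permute"
    # sdm
    covariates: tuple[str, ...] = ksdm.DEFAULT_COVARIATES
    coords_mode: str = "meters"
    # validation
    loocv_max_n: int = 500
    kfold_k: int = 10
    # learning curve
    lc_grid_start: int = 10
    lc_grid_stop: int = 450
    lc_grid_step: int = 40
    lc_repeats: int = 5
    lc_loocv_cap: int | None = None
    lc_full_cap: int = 1000
    lc_eps: float = 0.005

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a master seed is mandatory (stochastic stages)")
        if self.preset is None and self.input_path is None and self.site_config_path is None:
            raise ConfigError("one of preset, input_path or site_config_path is required")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()

    @property
    def lc_grid(self) -> range:
        return range(self.lc_grid_start, self.lc_grid_stop + 1, self.lc_grid_step)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        import configparser

        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)
        kwargs: dict = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for section in parser.sections():
            for key, val in parser[section].items():
                if key not in fields:
                    raise ConfigError(f"unknown config key {key!r} in [{section}]")
                if key == "covariates":
                    kwargs[key] = tuple(v.strip() for v in val.split(","))
                elif key in ("preset", "input_path", "site_config_path", "out_dir",
                             "null_mode", "coords_mode"):
                    kwargs[key] = val
                elif key == "lc_loocv_cap":
                    kwargs[key] = None if val.lower() in ("none", "0") else int(val)
                elif key in ("seed", "transect_repeats", "n_max", "min_pairs", "null_reps",
                             "loocv_max_n", "kfold_k", "lc_grid_start", "lc_grid_stop",
                             "lc_grid_step", "lc_repeats", "lc_full_cap"):
                    kwargs[key] = int(val)
                else:
                    kwargs[key] = float(val)
        kwargs.update(overrides)
        return cls(**kwargs)


def _usable_covariates(records: pd.DataFrame, config: RunConfig) -> tuple[str, ...]:
    """Drop covariates that are constant over the survey (e.g. a reef flag
    when every quadrat sits on mapped reef) — they carry no information and
    would make the design rank-deficient."""
    import kelpscape.sdm as _sdm

    X = _sdm.design_matrix(records, config.covariates, config.coords_mode)
    keep = tuple(
        c for j, c in enumerate(config.covariates) if X[:, j].std() > 0
    )
    dropped = set(config.covariates) - set(keep)
    if dropped:
        warnings.warn(
            f"dropping constant covariate(s) from the SDM: {', '.join(sorted(dropped))}",
            stacklevel=2,
        )
    return keep


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def _done(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


STAGES = ("simulate", "qc", "transect_sim", "correlogram", "sdm", "validate", "learning_curve")


def run_pipeline(config: RunConfig, force: bool = False, stages=STAGES) -> dict:
    """Execute the pipeline; returns the run manifest (also written to disk).

    Stage outputs already present are reused unless ``force``; a failing
    stage halts the run with its name while earlier outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.hash(),
        "config": dataclasses.asdict(config),
        "stage_seeds": {s: stage_seed_int(seed, s) for s in STAGES},
        "stages_run": [],
    }

    current = None
    try:
        # -- simulate ------------------------------------------------------
        current = "simulate"
        raw_path = out / "quadrats_raw.csv"
        if "simulate" in stages:
            if config.input_path is not None:
                records = kio.read_quadrats(config.input_path)
                if "x" not in records.columns:
                    records = kio.project_coordinates(records)
                records.to_csv(raw_path, index=False, float_format=FLOAT_FMT)
            elif not _done([raw_path]) or force:
                if config.site_config_path:
                    configs = synth.configs_from_file(config.site_config_path)
                elif config.preset in synth.PRESETS:
                    configs = synth.PRESETS[config.preset]()
                else:
                    raise ConfigError(f"unknown preset {config.preset!r}")
                records, env, truth = synth.generate_study(
                    configs, seed=stage_seed_int(seed, "simulate")
                )
                records.to_csv(raw_path, index=False, float_format=FLOAT_FMT)
                env.write(out)
                truth.write(out)
                manifest["stages_run"].append("simulate")

        # -- qc ------------------------------------------------------------
        current = "qc"
        qc_path = out / "quadrats.csv"
        qc_report_path = out / "qc_report.json"
        if "qc" in stages and (force or not _done([qc_path, qc_report_path])):
            records = pd.read_csv(raw_path)
            records, report = kio.apply_altitude_filter(
                records, config.min_alt, config.max_alt
            )
            records.to_csv(qc_path, index=False, float_format=FLOAT_FMT)
            _write_json(qc_report_path, report.to_dict())
            manifest["stages_run"].append("qc")

        # -- transect simulation --------------------------------------------
        current = "transect_sim"
        ts_path = out / "transect_sim.csv"
        if "transect_sim" in stages and (force or not _done([ts_path])):
            records = pd.read_csv(qc_path)
            frames = []
            for sid, grp in records.groupby("site_id", sort=True):
                track = kio.build_track(grp, max_gap=config.max_gap)
                try:
                    cap = transects.max_feasible_transects(track, config.transect_length)
                    n_hi = min(config.n_max, cap)
                    if n_hi < 1:
                        raise SiteTooSmallError(f"site {sid} too small")
                    frames.append(
                        transects.run_design_sweep(
                            track,
                            n_range=range(1, n_hi + 1),
                            repeats=config.transect_repeats,
                            length=config.transect_length,
                            seed=stage_seed_int(seed, "transect_sim"),
                        )
                    )
                except SiteTooSmallError as err:
                    warnings.warn(f"transect sim skipped for {sid}: {err}", stacklevel=2)
            pd.concat(frames, ignore_index=True).to_csv(
                ts_path, index=False, float_format=FLOAT_FMT
            )
            manifest["stages_run"].append("transect_sim")

        # -- correlograms ---------------------------------------------------
        current = "correlogram"
        corr_path = out / "correlogram.csv"
        if "correlogram" in stages and (force or not _done([corr_path])):
            records = pd.read_csv(qc_path)
            results = cg.site_correlograms(
                records,
                bin_width=config.bin_width,
                max_dist=config.max_dist,
                min_pairs=config.min_pairs,
                n_reps=config.null_reps,
                null_mode=config.null_mode,
                seed=stage_seed_int(seed, "correlogram"),
            )
            pd.concat([r.to_frame() for r in results], ignore_index=True).to_csv(
                corr_path, index=False, float_format=FLOAT_FMT
            )
            manifest["stages_run"].append("correlogram")

        # -- sdm -------------------------------------------------------------
        current = "sdm"
        model_path = out / "sdm_model.json"
        pred_path = out / "prediction.asc"
        if "sdm" in stages and (force or not _done([model_path, pred_path])):
            records = pd.read_csv(qc_path)
            covs = _usable_covariates(records, config)
            model = ksdm.fit_binomial_glm(
                records, covs, coords_mode=config.coords_mode
            )
            model.to_json(model_path)
            if (out / "bathymetry.asc").exists() and config.coords_mode == "meters":
                env = EnvironmentRasters.read(out)
                surface = ksdm.predict_surface(model, env)
                surface.write(out)
            manifest["stages_run"].append("sdm")

        # -- validation -------------------------------------------------------
        current = "validate"
        cv_summary_path = out / "cv_summary.json"
        cv_folds_path = out / "cv_folds.csv"
        if "validate" in stages and (force or not _done([cv_summary_path, cv_folds_path])):
            records = pd.read_csv(qc_path)
            covs = _usable_covariates(records, config)
            loo = validation.loocv(
                records,
                covs,
                max_n=config.loocv_max_n,
                seed=stage_seed_int(seed, "validate-loocv"),
                coords_mode=config.coords_mode,
            )
            kf = validation.kfold_cv(
                records,
                covs,
                k=config.kfold_k,
                seed=stage_seed_int(seed, "validate-kfold"),
                coords_mode=config.coords_mode,
            )
            folds = pd.DataFrame(
                {
                    "strategy": ["loocv"] + ["kfold"] * len(kf.fold_auc),
                    "fold": [-1] + list(range(len(kf.fold_auc))),
                    "auc": [loo.mean_auc] + kf.fold_auc,
                }
            )
            folds.to_csv(cv_folds_path, index=False, float_format=FLOAT_FMT)
            _write_json(
                cv_summary_path, {"loocv": loo.summary(), "kfold": kf.summary()}
            )
            manifest["stages_run"].append("validate")

        # -- learning curve ---------------------------------------------------
        current = "learning_curve"
        lc_path = out / "learning_curve.csv"
        lc_summary_path = out / "learning_curve_summary.json"
        if "learning_curve" in stages and (force or not _done([lc_path, lc_summary_path])):
            records = pd.read_csv(qc_path)
            covs = _usable_covariates(records, config)
            lc = validation.learning_curve(
                records,
                covs,
                n_grid=config.lc_grid,
                repeats=config.lc_repeats,
                seed=stage_seed_int(seed, "learning_curve"),
                loocv_cap=config.lc_loocv_cap,
                full_cap=config.lc_full_cap,
                eps=config.lc_eps,
                coords_mode=config.coords_mode,
            )
            lc.table.to_csv(lc_path, index=False, float_format=FLOAT_FMT)
            _write_json(
                lc_summary_path,
                {
                    "full_error": lc.full_error,
                    "asymptote_n": lc.asymptote_n,
                    "eps": lc.eps,
                },
            )
            manifest["stages_run"].append("learning_curve")

        # -- per-site summary --------------------------------------------------
        current = "summary"
        summary_path = out / "site_summary.csv"
        if (out / "quadrats.csv").exists() and (force or not summary_path.exists()):
            _write_site_summary(out, config)
    except ConfigError:
        raise
    except Exception as err:
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err

    _write_json(out / "manifest.json", manifest)
    return manifest


def _write_site_summary(out: Path, config: RunConfig) -> None:
    records = pd.read_csv(out / "quadrats.csv")
    rows = []
    ts = pd.read_csv(out / "transect_sim.csv") if (out / "transect_sim.csv").exists() else None
    corr = pd.read_csv(out / "correlogram.csv") if (out / "correlogram.csv").exists() else None
    for sid, grp in records.groupby("site_id", sort=True):
        row = {
            "site_id": sid,
            "n_quadrats": len(grp),
            "mean_cover": float((grp["k"] / grp["m"]).mean()),
        }
        if corr is not None and sid in set(corr["site_id"]):
            sub = corr[corr["site_id"] == sid]
            row["x_intercept"] = float(sub["x_intercept"].iloc[0])
            row["I_first_band"] = float(sub.sort_values("midpoint")["I"].iloc[0])
        if ts is not None and sid in set(ts["site_id"]):
            req = transects.required_transects(
                ts[ts["site_id"] == sid], t_threshold=config.t_threshold
            )
            row["required_transects"] = req if req is not None else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "site_summary.csv", index=False, float_format=FLOAT_FMT)
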