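"""End-to-end analysis pipeline with file artifacts and a manifest.

Stages: cohort (simulated or read from CSV) -> follow-up intervals ->
correlation report -> GEE fits of the selected models -> in-sample and
cross-validated performance with a bootstrap CI -> quartile stratification ->
variable ledger -> power curve.  Every artifact records the seed and options
that produced it, and warnings are collected rather than silenced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as vio
from .cohort import SimConfig, simulate_cohort
from .descriptives import correlation_report, ledger_frame, variable_ledger
from .design import MODEL1, MODEL2, MODEL3, ModelSpec, encode_model_matrix
from .errors import ConfigError
from .evaluation import bootstrap_cv_ci, cross_validate, evaluate
from .gee import ExchangeableGEE
from .intervals import WindowPolicy, build_intervals, intervals_to_frame
from .power import PowerConfig, sample_size_curve
from .strata import assign_quartiles, box_summary, stratum_summaries

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

BUILTIN_MODELS = {"model1": MODEL1, "model2": MODEL2, "model3": MODEL3}


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` (a visits.csv) or ``sim`` (a simulation
    block) must be given.  The bootstrap defaults use a reduced profile
    (200 draws x 25 inner splits) so a full run stays at interactive scale;
    the published full profile is 1000 x 200.
    """

    outdir: str = "dmdwalk_out"
    seed: int = 0
    input_path: str | None = None
    sim: SimConfig | None = None
    window: WindowPolicy = field(default_factory=WindowPolicy)
    models: tuple[str, ...] = ("model1", "model2", "model3")
    cv_model: str = "model2"
    n_splits: int = 200
    train_fraction: float = 0.8
    n_boot: int = 200
    n_splits_inner: int = 25
    power: PowerConfig = field(default_factory=PowerConfig)
    #: extra model specs by name, each a list of term names (see ModelSpec)
    custom_models: dict = field(default_factory=dict)

    def model_map(self) -> dict[str, ModelSpec]:
        models = dict(BUILTIN_MODELS)
        for name, terms in self.custom_models.items():
            models[name] = ModelSpec(name, tuple(terms))
        return models

    def validate(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ConfigError("exactly one of input_path or sim must be provided")
        known = self.model_map()
        for name in self.models + (self.cv_model,):
            if name not in known:
                raise ConfigError(f"unknown model {name!r}; choose from {sorted(known)}")
        if self.cv_model not in self.models:
            raise ConfigError("cv_model must be among the selected models")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "sim" in raw and isinstance(raw["sim"], dict):
            raw["sim"] = SimConfig(**raw["sim"])
        if "window" in raw and isinstance(raw["window"], dict):
            win = dict(raw["window"])
            if "required_baseline_fields" in win:
                win["required_baseline_fields"] = tuple(win["required_baseline_fields"])
            raw["window"] = WindowPolicy(**win)
        if "power" in raw and isinstance(raw["power"], dict):
            pw = dict(raw["power"])
            if "sigma_range" in pw:
                pw["sigma_range"] = tuple(pw["sigma_range"])
            raw["power"] = PowerConfig(**pw)
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _dump(payload, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the artifact bundle; returns the manifest."""
    config.validate()
    model_map = config.model_map()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "options": {
            "models": list(config.models),
            "cv_model": config.cv_model,
            "n_splits": config.n_splits,
            "train_fraction": config.train_fraction,
            "n_boot": config.n_boot,
            "n_splits_inner": config.n_splits_inner,
            "window": dataclasses.asdict(config.window),
        },
        "stages": {},
        "warnings": [],
        "artifacts": [],
    }

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                self_inner.catcher = warnings.catch_warnings(record=True)
                self_inner.log = self_inner.catcher.__enter__()
                warnings.simplefilter("always")
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                for w in self_inner.log:
                    manifest["warnings"].append(f"{name}: {w.message}")
                self_inner.catcher.__exit__(exc_type, exc, tb)
                manifest["stages"].setdefault(name, {}).update(
                    seconds=round(time.perf_counter() - self_inner.t0, 3),
                    ok=exc_type is None,
                )
                if exc_type is not None:
                    manifest["stages"][name]["error"] = str(exc)
                    _dump(manifest, outdir / "manifest.json")
                return False

        return _Stage()

    def emit(name: str):
        manifest["artifacts"].append(name)

    # ---- cohort ----------------------------------------------------------
    with stage("cohort"):
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            visits, truth = simulate_cohort(sim)
            vio.write_truth(truth, outdir / "truth.json")
            emit("truth.json")
        else:
            visits = vio.read_visits(config.input_path)
        vio.write_visits(visits, outdir / "visits.csv")
        emit("visits.csv")
        n_patients = len({v.patient_id for v in visits})
        manifest["stages"]["cohort"] = {
            "n_visits": len(visits),
            "n_patients": n_patients,
        }
        logger.info("cohort: %d visits from %d patients", len(visits), n_patients)

    # ---- intervals -------------------------------------------------------
    with stage("intervals"):
        intervals = build_intervals(visits, config.window)
        intervals_to_frame(intervals).to_csv(outdir / "intervals.csv", index=False)
        emit("intervals.csv")
        contributing = {iv.patient_id for iv in intervals}
        manifest["stages"].setdefault("intervals", {}).update(
            {
                "n_intervals": len(intervals),
                "n_contributing_patients": len(contributing),
                "n_excluded_patients": n_patients - len(contributing),
                "n_loss_of_ambulation": sum(iv.lost_ambulation for iv in intervals),
            }
        )
        logger.info(
            "intervals: %d intervals from %d of %d patients",
            len(intervals),
            len(contributing),
            n_patients,
        )

    # ---- correlations ----------------------------------------------------
    with stage("correlations"):
        corr = correlation_report(intervals)
        corr.r.to_csv(outdir / "correlations_r.csv")
        corr.p.to_csv(outdir / "correlations_p.csv")
        emit("correlations_r.csv")
        emit("correlations_p.csv")
        for note in corr.notices:
            manifest["warnings"].append(f"correlations: {note}")

    # ---- model fits ------------------------------------------------------
    fits = {}
    with stage("fit"):
        for name in config.models:
            spec = model_map[name]
            res = ExchangeableGEE.from_intervals(intervals, spec).fit()
            fits[name] = res
            res.to_json(outdir / f"fit_{name}.json")
            emit(f"fit_{name}.json")
            if res.model.design.dropped_columns:
                manifest["warnings"].append(
                    f"fit {name}: dropped constant columns {res.model.design.dropped_columns}"
                )
        skipped_models = sorted(set(BUILTIN_MODELS) - set(config.models))
        if skipped_models:
            manifest["stages"].setdefault("fit", {})["skipped_models"] = {
                m: "not selected in config.models" for m in skipped_models
            }

    # ---- evaluation ------------------------------------------------------
    with stage("evaluate"):
        report = {"in_sample": {}, "seed": config.seed}
        for name, res in fits.items():
            ev = evaluate(res.model.endog, res.predict())
            report["in_sample"][name] = dataclasses.asdict(ev)
        cv = cross_validate(
            intervals,
            model_map[config.cv_model],
            n_splits=config.n_splits,
            train_fraction=config.train_fraction,
            seed=config.seed,
        )
        report["cross_validation"] = {
            "model": config.cv_model,
            "mean_rmse": cv.mean_rmse,
            "derived_r2": cv.derived_r2,
            "n_splits": cv.n_splits,
            "n_skipped": cv.n_skipped,
            "train_fraction": cv.train_fraction,
            "no_leakage_certificate": True,  # asserted on every split
        }
        boot = bootstrap_cv_ci(
            intervals,
            model_map[config.cv_model],
            n_boot=config.n_boot,
            n_splits_inner=config.n_splits_inner,
            train_fraction=config.train_fraction,
            seed=config.seed,
        )
        report["bootstrap_ci"] = dataclasses.asdict(boot)
        _dump(report, outdir / "evaluation.json")
        emit("evaluation.json")

    # ---- stratification --------------------------------------------------
    with stage("stratify"):
        cv_fit = fits[config.cv_model]
        preds = cv_fit.predict()
        strata = assign_quartiles(preds)
        stratum_summaries(intervals, strata).to_csv(outdir / "strata.csv")
        _dump(
            {
                "thresholds_m_per_year": list(strata.thresholds),
                "counts": strata.counts,
                "box": box_summary(intervals, strata),
                "model": config.cv_model,
            },
            outdir / "strata_box.json",
        )
        emit("strata.csv")
        emit("strata_box.json")

    # ---- ledger ----------------------------------------------------------
    with stage("ledger"):
        rows = variable_ledger(intervals)
        ledger_frame(rows).to_csv(outdir / "ledger.csv", index=False)
        emit("ledger.csv")

    # ---- power -----------------------------------------------------------
    with stage("power"):
        curve = sample_size_curve(config.power)
        curve.table.to_csv(outdir / "power.csv", index=False)
        emit("power.csv")

    manifest["complete"] = all(s.get("ok", True) for s in manifest["stages"].values())
    _dump(manifest, outdir / "manifest.json")
    return manifest
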