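"""Pipeline orchestration: run enabled stages in dependency order, collect a report.

The run report is a JSON-serialisable record of every stage's outputs plus
provenance (input file hashes, the config snapshot, the seed and the package
version) and a list of warnings, each tagged with its originating stage.
Stages form two independent branches — screen -> flux -> mechanics -> model,
and dissolution / stability — so a failure in one branch does not abort the
others; the run as a whole fails iff any enabled stage failed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import datasets, io
from .diffusion import FilamentGeometry, fit_steady_state_flux, permeability
from .dissolution import ReleaseKinetics
from .hsp import ScreenThresholds, screen_combinations
from .mechanics import average_roughness, bending_modulus, max_height, toughness
from .multivariate import assemble_feature_table, fit_flux_model, run_pca
from .stability import fit_arrhenius, fit_degradation, predict_shelf_life

__all__ = ["RunReport", "run_pipeline"]

#: Execution order; model depends on screen + flux (+ mechanics data).
STAGE_ORDER = ("screen", "flux", "mechanics", "model", "dissolution", "stability")


@dataclass
class RunReport:
    """Serialisable record of one pipeline run."""

    stages: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "stages": self.stages,
                "provenance": self.provenance,
                "warnings": self.warnings,
                "errors": self.errors,
            },
            indent=indent,
            sort_keys=True,
            default=_jsonify,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        doc = json.loads(text)
        return cls(
            stages=doc["stages"],
            provenance=doc["provenance"],
            warnings=doc["warnings"],
            errors=doc["errors"],
        )


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _hash_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _quantity(value: float, unit: str) -> dict:
    return {"value": float(value), "unit": unit}


def run_pipeline(config: dict) -> RunReport:
    """Execute the stages enabled in ``config`` and return the run report.

    ``config`` maps stage names to their stage configs (see the CLI docs for
    the per-stage keys); a global ``seed`` feeds any stochastic stage.
    Unknown stage names raise before anything executes.
    """
    unknown = set(config) - set(STAGE_ORDER) - {"seed"}
    if unknown:
        raise ValueError(f"unknown pipeline stage(s): {sorted(unknown)}")

    report = RunReport()
    report.provenance = {
        "package_version": __version__,
        "seed": config.get("seed"),
        "config": {k: v for k, v in config.items()},
        "input_hashes": {},
    }
    for stage in STAGE_ORDER:
        if stage not in config:
            continue
        runner = _STAGES[stage]
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            try:
                report.stages[stage] = runner(config[stage], report)
            except Exception as exc:  # noqa: BLE001 - branch isolation is the contract
                report.errors[stage] = f"{type(exc).__name__}: {exc}"
        for w in caught:
            report.warnings.append({"stage": stage, "message": str(w.message)})
    return report


def _stage_screen(cfg: dict, report: RunReport) -> dict:
    if cfg.get("materials", "bundled") == "bundled":
        materials = datasets.load_reference_materials()
    else:
        materials = io.read_materials(cfg["materials"])
        report.provenance["input_hashes"][str(cfg["materials"])] = _hash_file(
            cfg["materials"]
        )
    drug = next(m for m in materials.values() if m.role == "drug")
    solvents = [m for m in materials.values() if m.role == "solvent"]
    filaments = [m for m in materials.values() if m.role == "filament"]
    thresholds = ScreenThresholds(**cfg.get("thresholds", {}))
    results = screen_combinations(drug, solvents, filaments, thresholds)
    return {
        "n_combinations": len(results),
        "thresholds": dataclasses.asdict(thresholds),
        "results": [
            {
                **dataclasses.asdict(r),
                "ra_unit": "MPa^1/2",
            }
            for r in results
        ],
    }


def _stage_flux(cfg: dict, report: RunReport) -> dict:
    out = []
    for exp in cfg["inputs"]:
        geometry = FilamentGeometry(
            length=exp.get("length_cm", 1.0), diameter=exp.get("diameter_cm", 0.175)
        )
        tc = io.read_timecourse(
            exp["input"],
            geometry=geometry,
            solvent=exp.get("solvent", ""),
            filament=exp.get("filament", ""),
        )
        report.provenance["input_hashes"][str(exp["input"])] = _hash_file(exp["input"])
        window = tuple(exp["window"]) if "window" in exp else None
        res = fit_steady_state_flux(tc, window)
        record = {
            "solvent": res.solvent,
            "filament": res.filament,
            "jss": _quantity(res.jss, "mg/cm^2/h"),
            "intercept": _quantity(res.intercept, "mg/cm^2"),
            "r_squared": _quantity(res.r_squared, "dimensionless"),
            "window_h": list(res.window),
            "n_points_used": res.n_points_used,
        }
        if "csat" in exp:
            record["permeability"] = _quantity(
                permeability(res.jss, exp["csat"]), "cm/h"
            )
        out.append(record)
    return {"n_experiments": len(out), "results": out}


def _stage_mechanics(cfg: dict, report: RunReport) -> dict:
    out: dict = {}
    if "roughness" in cfg:
        profile = io.read_roughness(cfg["roughness"])
        report.provenance["input_hashes"][str(cfg["roughness"])] = _hash_file(
            cfg["roughness"]
        )
        out["roughness"] = {
            "rav": _quantity(average_roughness(profile), "um"),
            "rz": _quantity(max_height(profile), "um"),
            "n_points": int(profile.heights.size),
        }
    if "force" in cfg:
        curve = io.read_force_curve(cfg["force"])
        report.provenance["input_hashes"][str(cfg["force"])] = _hash_file(cfg["force"])
        out["force"] = {
            "bending_modulus": _quantity(
                bending_modulus(
                    curve,
                    linear_fraction=cfg.get("linear_fraction", 0.15),
                    r2_threshold=cfg.get("r2_threshold", 0.99),
                ),
                "N/mm",
            ),
            "toughness": _quantity(toughness(curve), "N mm"),
            "n_points": int(curve.force.size),
        }
    if not out:
        raise ValueError("mechanics stage needs 'roughness' and/or 'force' inputs")
    return out


def _stage_model(cfg: dict, report: RunReport) -> dict:
    if cfg.get("features", "bundled") == "bundled":
        materials = datasets.load_reference_materials()
        drug = next(m for m in materials.values() if m.role == "drug")
        screen = screen_combinations(
            drug,
            [m for m in materials.values() if m.role == "solvent"],
            [m for m in materials.values() if m.role == "filament"],
        )
        table = assemble_feature_table(
            screen,
            datasets.reference_mechanics_table(),
            datasets.reference_flux_table(),
            datasets.SATURATION_SOLUBILITY,
        )
    else:
        df = io.read_table(cfg["features"], "features")
        report.provenance["input_hashes"][str(cfg["features"])] = _hash_file(
            cfg["features"]
        )
        table = df.set_index(["solvent", "filament"]).sort_index()

    out: dict = {"n_rows": int(len(table))}
    pca = run_pca(table)
    out["pca"] = {
        "explained_variance_fraction": pca.explained_variance.tolist(),
        "correlation_loadings": {
            col: pca.correlation_loadings[col].to_dict()
            for col in pca.correlation_loadings.columns
        },
    }
    method = cfg.get("method", "svm_rbf")
    res = fit_flux_model(table, method=method)
    out["regression"] = {
        "method": res.method,
        "hyperparameters": res.hyperparameters,
        "training_r_squared": _quantity(res.r_squared, "dimensionless"),
        "training_rmse": _quantity(res.rmse, "mg/cm^2/h"),
        "r_squared_is_training_fit": True,
        "predictions": {
            "/".join(k): _quantity(v, "mg/cm^2/h")
            for k, v in res.predictions.items()
        },
    }
    if res.loo_r_squared is not None:
        out["regression"]["loo_r_squared"] = _quantity(
            res.loo_r_squared, "dimensionless"
        )
    return out


def _stage_dissolution(cfg: dict, report: RunReport) -> dict:
    profile = io.read_dissolution(
        cfg["input"],
        q_inf=cfg.get("q_inf"),
        geometry_class=cfg.get("geometry_class", "cylinder"),
        medium_switch_time=cfg.get("medium_switch_time"),
    )
    report.provenance["input_hashes"][str(cfg["input"])] = _hash_file(cfg["input"])
    results = ReleaseKinetics(
        profile, kp_fraction_cap=cfg.get("kp_fraction_cap", 0.6)
    ).fit()
    best = results.best
    return {
        "fits": [
            {
                "model": f.model,
                "params": f.params,
                "r_squared": f.r_squared,
                "mechanism": f.mechanism,
                "error": f.error,
            }
            for f in results.fits
        ],
        "best_model": best.model,
        "mechanism": best.mechanism,
    }


def _stage_stability(cfg: dict, report: RunReport) -> dict:
    study = io.read_stability(cfg["input"])
    report.provenance["input_hashes"][str(cfg["input"])] = _hash_file(cfg["input"])
    per_condition = []
    pairs = []
    for cond in study:
        fits = fit_degradation(cond)
        best = fits[0]
        per_condition.append(
            {
                "temperature_K": cond.temperature,
                "rh_pct": cond.rh,
                "best_model": best.model,
                "k": _quantity(best.k, best.unit),
                "r_squared": best.r_squared,
            }
        )
        pairs.append((cond, best.k))
    # Arrhenius surface needs a single kinetic law across conditions: use the
    # law that wins most conditions, refit each condition under it.
    from collections import Counter

    common = Counter(c["best_model"] for c in per_condition).most_common(1)[0][0]
    pairs = [
        (cond, fit_degradation(cond, models=(common,))[0].k) for cond in study
    ]
    af = fit_arrhenius(pairs)
    storage_c, storage_rh = cfg.get("storage", (25.0, 60.0))
    pred = predict_shelf_life(
        af,
        common,
        storage_temperature=storage_c + 273.15,
        storage_rh=storage_rh,
        limit=cfg.get("limit", 10.0),
    )
    return {
        "per_condition": per_condition,
        "kinetic_model": common,
        "arrhenius": {
            "ln_A": af.ln_a,
            "Ea": _quantity(af.ea, "kcal/mol"),
            "B": _quantity(af.b, "per %RH"),
            "r_squared": af.r_squared,
        },
        "shelf_life": {
            "storage_temperature_C": storage_c,
            "storage_rh_pct": storage_rh,
            "k_extrapolated": pred.k_extrapolated,
            "specification_limit_pct": pred.specification_limit,
            "days": _quantity(pred.shelf_life_days, "days"),
            "years": _quantity(pred.shelf_life_years, "years"),
        },
    }


_STAGES = {
    "screen": _stage_screen,
    "flux": _stage_flux,
    "mechanics": _stage_mechanics,
    "model": _stage_model,
    "dissolution": _stage_dissolution,
    "stability": _stage_stability,
}
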