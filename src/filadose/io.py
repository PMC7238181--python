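"""CSV and config readers/writers for the pipeline's file dialects.

All tables are comma-separated UTF-8 with a mandatory header and ``.``
decimals.  Each reader validates against a named schema; unknown extra
columns are accepted with a warning, missing required columns or unparseable
cells raise :class:`TableError` with row/column coordinates.  Units are fixed
at the I/O boundary: hours, mg, cm for diffusion; days / percent for
stability; mm / um / N for mechanics.
"""

from __future__ import annotations

import warnings

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diffusion import DiffusionTimeCourse, FilamentGeometry
from .dissolution import DissolutionProfile
from .hsp import HansenParameters, Material, estimate_hsp_from_groups
from .mechanics import ForceCurve, RoughnessProfile
from .stability import StabilityCondition, StabilityStudy

__all__ = [
    "TableError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_materials",
    "read_timecourse",
    "read_dissolution",
    "read_stability",
    "read_roughness",
    "read_force_curve",
    "read_config",
]


class TableError(ValueError):
    """A CSV failed schema validation; message carries row/column coordinates."""


#: schema name -> required numeric columns (string columns listed separately).
SCHEMAS: dict[str, dict] = {
    "timecourse": {"numeric": ("time_h", "replicate", "cumulative_mg"), "string": ()},
    "dissolution": {"numeric": ("time_h", "released_pct"), "string": ()},
    "dissolution_mg": {"numeric": ("time_h", "released_mg"), "string": ()},
    "stability": {
        "numeric": ("temp_C", "rh_pct", "day", "percent_remaining"),
        "string": (),
    },
    "roughness": {"numeric": ("position_mm", "height_um"), "string": ()},
    "force": {"numeric": ("travel_mm", "force_N"), "string": ()},
    "features": {
        "numeric": (
            "ra_solvent_filament",
            "roughness_rav",
            "bending_modulus",
            "toughness",
            "jss",
            "permeability",
        ),
        "string": ("solvent", "filament"),
    },
    "flux_summary": {"numeric": ("jss",), "string": ("solvent", "filament")},
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Returns a DataFrame with the schema columns coerced to their types; row
    numbers in error messages are 1-based data rows (header excluded).
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    spec = SCHEMAS[schema]
    required = (*spec["numeric"], *spec["string"])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring extra column(s) {extra}", stacklevel=2)
    out = df[list(required)].copy()
    for col in spec["numeric"]:
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() & out[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise TableError(
                f"{path}: unparseable value {out[col][bad.idxmax()]!r} "
                f"at row {row}, column {col!r}"
            )
        if parsed.isna().any():
            row = int(parsed.isna().idxmax()) + 1
            raise TableError(f"{path}: empty cell at row {row}, column {col!r}")
        out[col] = parsed
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table in the package CSV dialect (comma, UTF-8, header)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


def read_config(path: str | Path) -> dict:
    """Read a YAML run/experiment config into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise TableError(f"{path}: config must be a mapping")
    return doc


def read_materials(path: str | Path) -> dict[str, Material]:
    """Read a materials YAML: per-material HSP triple or group counts.

    Each entry needs ``name``, ``role`` and either ``delta_d/delta_p/delta_h``
    (tabulated) or ``groups`` (a group -> count mapping for the van Krevelen
    estimate); optional ``saturation_solubility`` map and ``density``.
    """
    doc = read_config(path)
    materials: dict[str, Material] = {}
    for i, entry in enumerate(doc.get("materials", [])):
        name = entry.get("name")
        if not name:
            raise TableError(f"{path}: material #{i + 1} has no name")
        if "delta_d" in entry:
            hsp = HansenParameters(
                entry["delta_d"], entry["delta_p"], entry["delta_h"]
            )
        elif "groups" in entry:
            hsp = estimate_hsp_from_groups(
                list(entry["groups"].items()),
                molar_volume_override=entry.get("molar_volume"),
            )
        else:
            raise TableError(
                f"{path}: material {name!r} needs delta_d/p/h or groups"
            )
        materials[name] = Material(
            name=name,
            role=entry["role"],
            hsp=hsp,
            saturation_solubility=entry.get("saturation_solubility"),
            density=entry.get("density"),
        )
    if not materials:
        raise TableError(f"{path}: no materials defined")
    return materials


def read_timecourse(
    path: str | Path,
    geometry: FilamentGeometry | None = None,
    solvent: str = "",
    filament: str = "",
) -> DiffusionTimeCourse:
    """Read a loading time-course CSV (``time_h, replicate, cumulative_mg``)."""
    df = read_table(path, "timecourse")
    times = np.array(sorted(df["time_h"].unique()), dtype=float)
    replicates = sorted(df["replicate"].unique())
    mass = np.empty((len(replicates), times.size))
    for r, rep in enumerate(replicates):
        sub = df[df["replicate"] == rep].set_index("time_h")["cumulative_mg"]
        if set(sub.index) != set(times):
            raise TableError(
                f"{path}: replicate {rep:g} does not cover every time point"
            )
        mass[r] = sub.loc[times].to_numpy()
    return DiffusionTimeCourse(
        times=times,
        cumulative_mass=mass,
        geometry=geometry or FilamentGeometry(),
        solvent=solvent,
        filament=filament,
    )


def read_dissolution(
    path: str | Path,
    q_inf: float | None = None,
    geometry_class: str = "cylinder",
    medium_switch_time: float | None = None,
) -> DissolutionProfile:
    """Read a dissolution CSV; percent dialect by default, mg with ``q_inf``."""
    if q_inf is None:
        df = read_table(path, "dissolution")
        released, q = df["released_pct"].to_numpy(), 100.0
    else:
        df = read_table(path, "dissolution_mg")
        released, q = df["released_mg"].to_numpy(), q_inf
    return DissolutionProfile(
        times=df["time_h"].to_numpy(),
        released=released,
        q_inf=q,
        geometry_class=geometry_class,
        medium_switch_time=medium_switch_time,
    )


def read_stability(path: str | Path) -> StabilityStudy:
    """Read a stability CSV (``temp_C, rh_pct, day, percent_remaining``)."""
    df = read_table(path, "stability")
    conditions = []
    for (temp_c, rh), grp in df.groupby(["temp_C", "rh_pct"], sort=True):
        grp = grp.sort_values("day")
        conditions.append(
            StabilityCondition(
                temperature=float(temp_c) + 273.15,
                rh=float(rh),
                observations=list(
                    zip(grp["day"].astype(float), grp["percent_remaining"].astype(float))
                ),
                convention="percent_remaining",
            )
        )
    return StabilityStudy(conditions=conditions)


def read_roughness(path: str | Path) -> RoughnessProfile:
    df = read_table(path, "roughness")
    return RoughnessProfile(
        positions=df["position_mm"].to_numpy(), heights=df["height_um"].to_numpy()
    )


def read_force_curve(path: str | Path) -> ForceCurve:
    df = read_table(path, "force")
    return ForceCurve(
        travel=df["travel_mm"].to_numpy(), force=df["force_N"].to_numpy()
    )
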