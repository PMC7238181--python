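"""Bundled reference data for the nifedipine passive-loading case study.

The package ships the published summary tables of the study it re-implements:
tabulated Hansen parameters and saturation solubilities, the measured
steady-state fluxes per (solvent, filament) combination, the blank-filament
mechanics (roughness, bending modulus, toughness), and the accelerated
stability study design.  These are *inputs* to the pipeline — raw instrument
traces are not published and are emulated by :mod:`filadose.simulate`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .hsp import HansenParameters, Material
from .stability import StabilityCondition

__all__ = [
    "load_reference_materials",
    "reference_flux_table",
    "reference_mechanics_table",
    "reference_stability_design",
    "SATURATION_SOLUBILITY",
]

#: Nifedipine saturation solubility Csat (mg/cm^3) in each loading solvent.
SATURATION_SOLUBILITY = {"ethanol": 31.6, "ethyl_acetate": 71.2}


def load_reference_materials() -> dict[str, Material]:
    """Load the bundled nifedipine / solvent / filament material set."""
    with resources.files("filadose.data").joinpath("materials_nifedipine.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        doc = yaml.safe_load(fh)
    materials = {}
    for entry in doc["materials"]:
        materials[entry["name"]] = Material(
            name=entry["name"],
            role=entry["role"],
            hsp=HansenParameters(
                entry["delta_d"], entry["delta_p"], entry["delta_h"]
            ),
            saturation_solubility=entry.get("saturation_solubility"),
            density=entry.get("density"),
        )
    return materials


def reference_flux_table() -> pd.DataFrame:
    """Measured steady-state flux over the 0-4 h loading window.

    Columns: solvent, filament, jss (mg/cm^2/h).  One row per
    (solvent, filament) combination of the study.
    """
    rows = [
        ("ethanol", "PVA", 0.278),
        ("ethanol", "PLA", 0.064),
        ("ethanol", "TPU", 0.203),
        ("ethanol", "HS", 0.276),
        ("ethyl_acetate", "PVA", 0.115),
        ("ethyl_acetate", "PLA", 0.126),
        ("ethyl_acetate", "TPU", 0.126),
        ("ethyl_acetate", "HS", 0.046),
    ]
    return pd.DataFrame(rows, columns=["solvent", "filament", "jss"])


def reference_mechanics_table() -> pd.DataFrame:
    """Blank-filament surface roughness and three-point-bend summary values.

    Columns: filament, rav_um, rz_um, bending_modulus_nmm, toughness_nmm.
    """
    rows = [
        ("HS", 2.99, 15.2, 7.86, 141.80),
        ("PVA", 1.84, 13.05, 7.11, 130.82),
        ("PLA", 2.79, 15.39, 6.84, 157.50),
        ("TPU", 2.24, 14.58, 0.72, 12.26),
    ]
    return pd.DataFrame(
        rows,
        columns=["filament", "rav_um", "rz_um", "bending_modulus_nmm", "toughness_nmm"],
    )


def reference_stability_design(
    observations: list[tuple[float, float]] | None = None,
) -> list[StabilityCondition]:
    """The six accelerated-stability chamber conditions (T in K, RH in %).

    Sampling days are 14, 28 and 48 at every condition.  ``observations`` may
    pre-populate each condition (mainly useful for tests); by default the
    conditions are returned without data, ready for the synthetic generator.
    """
    conditions = [
        (80.0, 75.0),
        (80.0, 10.0),
        (70.0, 50.0),
        (70.0, 10.0),
        (60.0, 75.0),
        (50.0, 50.0),
    ]
    obs = observations if observations is not None else []
    return [
        StabilityCondition(temperature=t_c + 273.15, rh=rh, observations=list(obs))
        for t_c, rh in conditions
    ]
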