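"""Hansen solubility parameters, HSP distances and drug/solvent/filament screening.

The Hansen framework partitions a material's cohesive energy density into
dispersion (``delta_d``), polar (``delta_p``) and hydrogen-bonding (``delta_h``)
components, each in MPa^1/2.  Two materials are predicted to be the more
miscible the smaller the scaled Euclidean distance

    Ra = sqrt(4 (dd1-dd2)^2 + (dp1-dp2)^2 + (dh1-dh2)^2)

between their parameter triples (the factor 4 on the dispersion term is part of
the standard Hansen metric).  For passive loading of a drug into a polymer
filament from solution the useful regime is a *large* drug-solvent distance
(the solvent holds the drug weakly, so it partitions out) combined with an
*intermediate* solvent-filament distance (the solvent swells the filament
enough to carry drug in, without dissolving it).  ``screen_combinations``
encodes that rule.

Parameters can be supplied from tabulated literature values or estimated with
the Hoftyzer-van Krevelen group-contribution method from functional-group
counts (``estimate_hsp_from_groups``); a small group table is bundled with the
package.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "HansenParameters",
    "Material",
    "GroupContributionTable",
    "ScreenResult",
    "ScreenThresholds",
    "total_hsp",
    "ra_distance",
    "estimate_hsp_from_groups",
    "screen_combinations",
    "load_group_table",
]


def total_hsp(delta_d: float, delta_p: float, delta_h: float) -> float:
    """Total solubility parameter: Euclidean norm of the component triple (MPa^1/2)."""
    for name, v in (("delta_d", delta_d), ("delta_p", delta_p), ("delta_h", delta_h)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v!r}")
    return math.sqrt(delta_d**2 + delta_p**2 + delta_h**2)


@dataclass(frozen=True)
class HansenParameters:
    """A (delta_d, delta_p, delta_h) triple in MPa^1/2 with the derived total.

    ``source`` records whether the values are tabulated literature values or a
    group-contribution estimate.
    """

    delta_d: float
    delta_p: float
    delta_h: float
    source: str = "tabulated"

    def __post_init__(self) -> None:
        if self.source not in ("tabulated", "group_contribution"):
            raise ValueError(f"unknown HSP source {self.source!r}")
        # validates non-negativity/finiteness as a side effect
        total_hsp(self.delta_d, self.delta_p, self.delta_h)

    @property
    def delta_t(self) -> float:
        """Total solubility parameter (MPa^1/2)."""
        return total_hsp(self.delta_d, self.delta_p, self.delta_h)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.delta_d, self.delta_p, self.delta_h)


def ra_distance(hsp_1: HansenParameters, hsp_2: HansenParameters) -> float:
    """Hansen distance Ra between two parameter triples (MPa^1/2).

    Symmetric in its arguments; zero iff the triples are identical.
    """
    return math.sqrt(
        4.0 * (hsp_1.delta_d - hsp_2.delta_d) ** 2
        + (hsp_1.delta_p - hsp_2.delta_p) ** 2
        + (hsp_1.delta_h - hsp_2.delta_h) ** 2
    )


@dataclass(frozen=True)
class Material:
    """A drug, solvent or filament with its Hansen parameters.

    ``saturation_solubility`` maps solvent name -> Csat (mg/cm^3) and is only
    meaningful for drugs; ``density`` (g/cm^3) only for filaments.  ``ro`` is an
    optional Hansen interaction radius carried as an annotation (no sphere fit
    is performed by this package).
    """

    name: str
    role: str
    hsp: HansenParameters
    saturation_solubility: Mapping[str, float] | None = None
    density: float | None = None
    ro: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("drug", "solvent", "filament"):
            raise ValueError(f"unknown material role {self.role!r}")
        if self.saturation_solubility is not None:
            for solvent, csat in self.saturation_solubility.items():
                if csat <= 0:
                    raise ValueError(
                        f"saturation solubility in {solvent!r} must be > 0, got {csat}"
                    )
        if self.density is not None and self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")


@dataclass(frozen=True)
class GroupContributionTable:
    """Hoftyzer-van Krevelen group increments.

    ``entries`` maps group name -> (F_d, F_p, E_h, V):
    F_d, F_p molar attraction constants (MPa^1/2 cm^3/mol), E_h hydrogen-bond
    cohesive energy (J/mol), V molar volume increment (cm^3/mol, > 0).
    """

    entries: Mapping[str, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        for group, (_fd, _fp, _eh, v) in self.entries.items():
            if v <= 0:
                raise ValueError(f"molar volume increment for {group!r} must be > 0")

    def __contains__(self, group: str) -> bool:
        return group in self.entries

    def __getitem__(self, group: str) -> tuple[float, float, float, float]:
        return self.entries[group]


def load_group_table() -> GroupContributionTable:
    """Load the bundled Hoftyzer-van Krevelen group-contribution table."""
    entries: dict[str, tuple[float, float, float, float]] = {}
    with resources.files("filadose.data").joinpath("group_contributions.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        for row in csv.DictReader(
            line for line in fh if not line.startswith("#")
        ):
            entries[row["group"]] = (
                float(row["F_d"]),
                float(row["F_p"]),
                float(row["E_h"]),
                float(row["V"]),
            )
    return GroupContributionTable(entries)


def estimate_hsp_from_groups(
    groups: Sequence[tuple[str, int]],
    table: GroupContributionTable | None = None,
    molar_volume_override: float | None = None,
) -> HansenParameters:
    """Estimate Hansen parameters from functional-group counts.

    Hoftyzer-van Krevelen forms::

        delta_d = sum(n F_d) / V
        delta_p = sqrt(sum(n F_p^2)) / V
        delta_h = sqrt(sum(n E_h) / V)

    with molar volume ``V = sum(n V_increment)`` unless overridden.

    Parameters
    ----------
    groups
        ``(group_name, count)`` pairs; counts >= 1, at least one group.
    table
        Group-contribution table; the bundled table is used when omitted.
    molar_volume_override
        Molar volume in cm^3/mol to use instead of the additive estimate
        (useful when a measured density/molar mass is available, or when the
        molecule contains groups with non-positive volume increments).
    """
    if not groups or sum(n for _, n in groups) < 1:
        raise ValueError("at least one group with count >= 1 is required")
    if table is None:
        table = load_group_table()
    unknown = sorted({g for g, _ in groups if g not in table})
    if unknown:
        raise KeyError(f"unknown group(s) in contribution table: {', '.join(unknown)}")

    sum_fd = sum(n * table[g][0] for g, n in groups)
    sum_fp2 = sum(n * table[g][1] ** 2 for g, n in groups)
    sum_eh = sum(n * table[g][2] for g, n in groups)
    volume = (
        molar_volume_override
        if molar_volume_override is not None
        else sum(n * table[g][3] for g, n in groups)
    )
    if volume <= 0:
        raise ValueError(f"molar volume must be > 0, got {volume}")

    return HansenParameters(
        delta_d=sum_fd / volume,
        delta_p=math.sqrt(sum_fp2) / volume,
        delta_h=math.sqrt(sum_eh / volume),
        source="group_contribution",
    )


@dataclass(frozen=True)
class ScreenThresholds:
    """Thresholds for the passive-loading screening rule.

    A combination is *favoured* when the drug-solvent distance exceeds
    ``t_high`` (weak drug-solvent affinity) and the solvent-filament distance
    lies within ``width`` of ``t_mid`` (solvent swells but does not dissolve
    the filament); *borderline* when exactly one of the two holds.
    """

    t_high: float = 10.0
    t_mid: float = 10.0
    width: float = 3.0


@dataclass(frozen=True)
class ScreenResult:
    drug: str
    solvent: str
    filament: str
    ra_drug_solvent: float
    ra_solvent_filament: float
    ra_drug_filament: float
    rank_score: float
    verdict: str


def _verdict(ra_ds: float, ra_sf: float, thresholds: ScreenThresholds) -> str:
    high_enough = ra_ds > thresholds.t_high
    intermediate = abs(ra_sf - thresholds.t_mid) <= thresholds.width
    if high_enough and intermediate:
        return "favoured"
    if high_enough or intermediate:
        return "borderline"
    return "rejected"


def screen_combinations(
    drug: Material,
    solvents: Iterable[Material],
    filaments: Iterable[Material],
    thresholds: ScreenThresholds | None = None,
) -> list[ScreenResult]:
    """Rank every (solvent, filament) pair for passive loading of ``drug``.

    ``rank_score = ra_drug_solvent - |ra_solvent_filament - t_mid|`` (higher is
    better; a package-defined convenience score — the raw Ra values are always
    reported alongside).  Output is sorted by score descending, ties broken
    lexicographically by (solvent, filament).
    """
    thresholds = thresholds or ScreenThresholds()
    solvents = list(solvents)
    filaments = list(filaments)
    if not solvents or not filaments:
        raise ValueError("need at least one solvent and one filament to screen")

    results = []
    for solvent in solvents:
        ra_ds = ra_distance(drug.hsp, solvent.hsp)
        for filament in filaments:
            ra_sf = ra_distance(solvent.hsp, filament.hsp)
            results.append(
                ScreenResult(
                    drug=drug.name,
                    solvent=solvent.name,
                    filament=filament.name,
                    ra_drug_solvent=ra_ds,
                    ra_solvent_filament=ra_sf,
                    ra_drug_filament=ra_distance(drug.hsp, filament.hsp),
                    rank_score=ra_ds - abs(ra_sf - thresholds.t_mid),
                    verdict=_verdict(ra_ds, ra_sf, thresholds),
                )
            )
    results.sort(key=lambda r: (-r.rank_score, r.solvent, r.filament))
    return results
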