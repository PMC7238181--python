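"""Steady-state flux, permeability and tablet dose geometry.

A filament section immersed in a saturated drug solution takes up drug by
passive diffusion.  Plotting cumulative drug mass per unit filament surface
area against immersion time gives an initially linear uptake whose slope is
the steady-state flux Jss (mg/cm^2/h):

    Jss = dM / (S dt)

with S the closed-cylinder surface area of the section.  The permeability
coefficient follows as P = Jss / Csat with Csat the drug's saturation
solubility in the loading solvent (mg/cm^3), and the enhancement ratio
compares fluxes between solvents for the same filament.

Flux estimation is exposed statsmodels-style: build a
:class:`SteadyStateFlux` model from a :class:`DiffusionTimeCourse`, call
``fit()`` and read the estimates off the returned :class:`FluxResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FilamentGeometry",
    "DiffusionTimeCourse",
    "SteadyStateFlux",
    "FluxResults",
    "TabletDesign",
    "filament_surface_area",
    "fit_steady_state_flux",
    "permeability",
    "enhancement_ratio",
    "design_tablet",
]


def filament_surface_area(length: float, diameter: float) -> float:
    """Closed-cylinder surface area 2*pi*r^2 + 2*pi*r*h (cm^2); inputs in cm."""
    if length <= 0 or diameter <= 0:
        raise ValueError("length and diameter must be > 0")
    r = diameter / 2.0
    return 2.0 * math.pi * r**2 + 2.0 * math.pi * r * length


@dataclass(frozen=True)
class FilamentGeometry:
    """Filament section geometry (cm); the nominal section is 1.0 x 0.175 cm."""

    length: float = 1.0
    diameter: float = 0.175

    @property
    def surface_area(self) -> float:
        """Closed-cylinder surface area (cm^2)."""
        return filament_surface_area(self.length, self.diameter)


@dataclass
class DiffusionTimeCourse:
    """Cumulative drug uptake observations for one (solvent, filament) pair.

    ``cumulative_mass`` holds one series per replicate, each aligned with
    ``times`` (hours); masses are mg of drug extracted per filament section.
    """

    times: np.ndarray
    cumulative_mass: np.ndarray  # shape (n_replicates, n_times)
    geometry: FilamentGeometry = field(default_factory=FilamentGeometry)
    solvent: str = ""
    filament: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_mass = np.atleast_2d(
            np.asarray(self.cumulative_mass, dtype=float)
        )
        if self.times.ndim != 1 or self.times.size < 3:
            raise ValueError("need at least 3 time points")
        if np.any(np.diff(self.times) <= 0) or np.any(self.times < 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if self.cumulative_mass.shape[1] != self.times.size:
            raise ValueError("each replicate series must align with times")
        if np.any(self.cumulative_mass < 0):
            raise ValueError("cumulative masses must be >= 0")

    @property
    def mean_mass(self) -> np.ndarray:
        """Replicate-averaged cumulative mass (mg) per time point."""
        return self.cumulative_mass.mean(axis=0)


@dataclass(frozen=True)
class FluxResults:
    """Estimates from the linear-window flux regression."""

    jss: float  # mg/cm^2/h
    intercept: float  # mg/cm^2
    r_squared: float
    window: tuple[float, float]  # hours
    n_points_used: int
    solvent: str = ""
    filament: str = ""

    def permeability(self, csat: float) -> float:
        """Permeability coefficient P = Jss/Csat (cm/h)."""
        return permeability(self.jss, csat)

    def summary(self) -> str:
        lines = [
            "Steady-state flux regression",
            "=" * 34,
            f"combination     {self.solvent or '-'} / {self.filament or '-'}",
            f"window          {self.window[0]:g}-{self.window[1]:g} h"
            f"  ({self.n_points_used} points)",
            f"Jss             {self.jss:.4g} mg/cm^2/h",
            f"intercept       {self.intercept:.4g} mg/cm^2",
            f"R^2             {self.r_squared:.4f}",
        ]
        return "\n".join(lines)


class SteadyStateFlux:
    """OLS model for the linear portion of a drug-uptake time course.

    Replicates are averaged per time point, normalised by the section surface
    area, and regressed on time (free intercept) over ``window`` — by default
    the 0-4 h loading window.
    """

    def __init__(
        self,
        timecourse: DiffusionTimeCourse,
        window: tuple[float, float] | None = None,
    ) -> None:
        self.timecourse = timecourse
        self.window = (0.0, 4.0) if window is None else (float(window[0]), float(window[1]))
        t0, t1 = self.window
        if t1 <= t0:
            raise ValueError("window end must exceed window start")

    def fit(self) -> FluxResults:
        tc = self.timecourse
        t0, t1 = self.window
        mask = (tc.times >= t0) & (tc.times <= t1)
        t = tc.times[mask]
        if t.size < 2:
            raise ValueError(
                f"need >= 2 time points inside window {self.window}, got {t.size}"
            )
        if np.ptp(t) == 0:
            raise ValueError("zero time variance inside the window")
        per_area = tc.mean_mass[mask] / tc.geometry.surface_area
        res = stats.linregress(t, per_area)
        # constant response: slope 0, define R^2 = 0 rather than NaN
        r2 = 0.0 if np.ptp(per_area) == 0 else float(res.rvalue**2)
        return FluxResults(
            jss=float(res.slope),
            intercept=float(res.intercept),
            r_squared=r2,
            window=self.window,
            n_points_used=int(t.size),
            solvent=tc.solvent,
            filament=tc.filament,
        )


def fit_steady_state_flux(
    tc: DiffusionTimeCourse, window: tuple[float, float] | None = None
) -> FluxResults:
    """Convenience wrapper: ``SteadyStateFlux(tc, window).fit()``."""
    return SteadyStateFlux(tc, window).fit()


def permeability(jss: float, csat: float) -> float:
    """Permeability coefficient P = Jss / Csat (cm/h); Csat in mg/cm^3 must be > 0."""
    if csat <= 0:
        raise ValueError(f"Csat must be > 0, got {csat}")
    return jss / csat


def enhancement_ratio(jss_ethanol: float, jss_other: float) -> float:
    """Ratio of steady-state fluxes between two solvents for the same filament."""
    if jss_other <= 0:
        raise ValueError("denominator flux must be > 0")
    return jss_ethanol / jss_other


@dataclass(frozen=True)
class TabletDesign:
    """Cylindrical tablet sized to carry a target dose at a given loading."""

    dose: float  # mg
    loading_fraction: float  # w/w
    density: float  # g/cm^3
    diameter: float  # mm
    tablet_mass: float  # mg
    volume: float  # cm^3
    height: float  # mm


def design_tablet(
    dose: float, loading_fraction: float, density: float, diameter: float
) -> TabletDesign:
    """Size a flat cylindrical tablet for ``dose`` mg of drug.

    ``loading_fraction`` is the drug mass fraction in the printed matrix
    (w/w, in (0, 1)); ``density`` g/cm^3; ``diameter`` mm.  Mass follows as
    dose/loading, volume as mass/density, height from the cylinder volume.
    """
    if not 0 < loading_fraction <= 1:
        raise ValueError("loading_fraction must be in (0, 1]")
    if dose <= 0 or density <= 0 or diameter <= 0:
        raise ValueError("dose, density and diameter must be > 0")
    mass_mg = dose / loading_fraction
    volume_cm3 = (mass_mg / 1000.0) / density
    radius_cm = diameter / 20.0
    height_mm = volume_cm3 / (math.pi * radius_cm**2) * 10.0
    return TabletDesign(
        dose=dose,
        loading_fraction=loading_fraction,
        density=density,
        diameter=diameter,
        tablet_mass=mass_mg,
        volume=volume_cm3,
        height=height_mm,
    )


def cylinder_volume(diameter_mm: float, height_mm: float) -> float:
    """Volume of a cylindrical tablet (cm^3) from its mm dimensions."""
    if diameter_mm <= 0 or height_mm <= 0:
        raise ValueError("dimensions must be > 0")
    r_cm = diameter_mm / 20.0
    return math.pi * r_cm**2 * (height_mm / 10.0)


__all__.append("cylinder_volume")
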