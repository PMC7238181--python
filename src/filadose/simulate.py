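"""Synthetic raw-data generators with known ground truth.

The study's raw instrument outputs (uptake time courses, dissolution
profiles, stability assay series, profilometry traces, force-travel curves)
are not published; these generators emulate each of them from explicit truth
parameters so that every estimator in the package can be exercised
end-to-end.  Every generator is a pure function of its arguments and a
:class:`GeneratorSpec` (seed + noise model): identical inputs give
bit-identical output.  At ``noise_model="none"`` each generator is the exact
inverse of its estimator.

Default truth values mirror the magnitudes of the reference study (fluxes
around 0.05-0.3 mg/cm^2/h, bending moduli of a few N/mm, activation energies
of 10-25 kcal/mol) so that fixtures resemble realistic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffusion import DiffusionTimeCourse, FilamentGeometry
from .dissolution import DissolutionProfile
from .mechanics import ForceCurve, RoughnessProfile
from .stability import (
    GAS_CONSTANT_KCAL,
    StabilityCondition,
    StabilityStudy,
    degradation_curve,
)

__all__ = [
    "GeneratorSpec",
    "gen_diffusion_timecourse",
    "gen_dissolution_profile",
    "gen_stability_study",
    "gen_roughness_profile",
    "gen_force_curve",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Randomness contract for a generator: seed, noise family and scale."""

    seed: int = 0
    noise_model: str = "none"  # none | additive_gaussian | multiplicative_lognormal
    noise_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_model not in (
            "none",
            "additive_gaussian",
            "multiplicative_lognormal",
        ):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(
        self, values: np.ndarray, rng: np.random.Generator, ref_scale: float | None = None
    ) -> np.ndarray:
        """Apply the declared noise family to ``values``.

        ``ref_scale`` sets the additive-Gaussian sigma (defaults to the mean
        magnitude of the values); multiplicative noise is lognormal with
        sigma = noise_scale on the log scale.
        """
        if self.noise_model == "none" or self.noise_scale == 0:
            return values
        if self.noise_model == "additive_gaussian":
            scale = (
                ref_scale
                if ref_scale is not None
                else float(np.mean(np.abs(values))) or 1.0
            )
            return values + rng.normal(0.0, self.noise_scale * scale, values.shape)
        return values * rng.lognormal(0.0, self.noise_scale, values.shape)


def gen_diffusion_timecourse(
    jss_true: float,
    geometry: FilamentGeometry | None = None,
    t_points: np.ndarray | None = None,
    plateau_time: float | None = 4.0,
    spec: GeneratorSpec | None = None,
    n_replicates: int = 3,
    plateau_tau: float = 2.0,
    solvent: str = "",
    filament: str = "",
) -> DiffusionTimeCourse:
    """Linear-then-plateau cumulative uptake, one noisy series per replicate.

    Uptake is exactly linear (slope jss_true * S) up to ``plateau_time``, then
    approaches its asymptote exponentially with time constant ``plateau_tau``
    (hours), emulating the sharp-rise-then-gradual-saturation shape of
    measured loading curves.  ``plateau_time=None`` keeps the uptake linear
    throughout.
    """
    if jss_true < 0:
        raise ValueError("jss_true must be >= 0")
    geometry = geometry or FilamentGeometry()
    spec = spec or GeneratorSpec()
    t = np.asarray(
        t_points if t_points is not None else [0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0],
        dtype=float,
    )
    s = geometry.surface_area
    if plateau_time is None:
        mean = jss_true * s * t
    else:
        post = np.clip(t - plateau_time, 0.0, None)
        effective_t = np.minimum(t, plateau_time) + plateau_tau * (
            1.0 - np.exp(-post / plateau_tau)
        )
        mean = jss_true * s * effective_t
    rng = spec.rng()
    reps = np.vstack([spec.apply(mean, rng) for _ in range(n_replicates)])
    return DiffusionTimeCourse(
        times=t,
        cumulative_mass=np.clip(reps, 0.0, None),
        geometry=geometry,
        solvent=solvent,
        filament=filament,
    )


def _release_mean(model: str, params: dict, q_inf: float, t: np.ndarray) -> np.ndarray:
    if model == "zero_order":
        return params["K0"] * t
    if model == "first_order":
        return params.get("Q0", 1.0) * np.exp(params["K1"] * t)
    if model == "hixson_crowell":
        root = np.clip(q_inf ** (1 / 3) - params["Ks"] * t, 0.0, None)
        return q_inf - root**3
    if model == "korsmeyer_peppas":
        return q_inf * params["K_KP"] * np.power(t, params["n"])
    raise ValueError(f"unknown release model {model!r}")


def gen_dissolution_profile(
    model: str,
    params: dict,
    q_inf: float,
    t_points: np.ndarray | None = None,
    spec: GeneratorSpec | None = None,
    geometry_class: str = "cylinder",
) -> DissolutionProfile:
    """Forward-evaluate a release law, clip to [0, q_inf], apply noise.

    Parameter maps mirror the fitted laws: ``{"K0": ...}``, ``{"K1", "Q0"}``,
    ``{"Ks"}``, ``{"K_KP", "n"}``.
    """
    spec = spec or GeneratorSpec()
    t = np.asarray(
        t_points
        if t_points is not None
        else [0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0],
        dtype=float,
    )
    mean = np.clip(_release_mean(model, params, q_inf, t), 0.0, q_inf)
    noisy = spec.apply(mean, spec.rng())
    released = np.clip(np.maximum.accumulate(noisy), 0.0, q_inf)
    return DissolutionProfile(
        times=t, released=released, q_inf=q_inf, geometry_class=geometry_class
    )


def gen_stability_study(
    ln_a: float,
    ea: float,
    b: float,
    kinetic_model: str = "zero",
    conditions: list[tuple[float, float, list[float]]] | None = None,
    spec: GeneratorSpec | None = None,
    d_inf: float = 100.0,
) -> StabilityStudy:
    """Forward-simulate an accelerated stability study.

    Per condition ``(T_kelvin, rh, sampling_days)`` the rate constant follows
    the humidity-corrected Arrhenius surface ``ln k = ln_a - ea/(R T) + b*RH``
    and the percent-degraded curve follows ``kinetic_model``; noise is applied
    to the degraded percentages.  The default design is the six-chamber,
    three-timepoint layout of the reference study.
    """
    spec = spec or GeneratorSpec()
    if conditions is None:
        days = [14.0, 28.0, 48.0]
        conditions = [
            (353.15, 75.0, days),
            (353.15, 10.0, days),
            (343.15, 50.0, days),
            (343.15, 10.0, days),
            (333.15, 75.0, days),
            (323.15, 50.0, days),
        ]
    rng = spec.rng()
    out = []
    for temp, rh, sampling in conditions:
        k = np.exp(ln_a - ea / (GAS_CONSTANT_KCAL * temp) + b * rh)
        t = np.asarray(sampling, dtype=float)
        degraded = degradation_curve(kinetic_model, k, t, d_inf)
        degraded = np.clip(spec.apply(degraded, rng), 0.0, 100.0)
        out.append(
            StabilityCondition(
                temperature=temp,
                rh=rh,
                observations=[(float(tt), float(d)) for tt, d in zip(t, degraded)],
                convention="percent_degraded",
            )
        )
    return StabilityStudy(conditions=out)


def gen_roughness_profile(
    rav_target: float,
    n_points: int = 200,
    length_mm: float = 8.0,
    spec: GeneratorSpec | None = None,
) -> RoughnessProfile:
    """Random zero-mean trace rescaled so its realised Rav equals the target exactly."""
    if rav_target <= 0:
        raise ValueError("rav_target must be > 0")
    if n_points < 10:
        raise ValueError("need at least 10 points")
    spec = spec or GeneratorSpec()
    rng = spec.rng()
    z = rng.standard_normal(n_points)
    z -= z.mean()
    mad = np.mean(np.abs(z))
    z *= rav_target / mad
    return RoughnessProfile(
        positions=np.linspace(0.0, length_mm, n_points), heights=z
    )


def gen_force_curve(
    modulus: float,
    yield_travel: float = 1.0,
    peak_force: float | None = None,
    travel_end: float = 4.0,
    n_points: int = 200,
    decline_fraction: float = 0.3,
    spec: GeneratorSpec | None = None,
) -> ForceCurve:
    """Elastic-then-yield three-point-bend curve.

    Force rises linearly with slope ``modulus`` (N/mm) up to ``yield_travel``
    (mm), then plateaus at the yield force (capped at ``peak_force`` when
    given) and declines linearly by ``decline_fraction`` of the plateau over
    the remaining travel.  Noise, if requested, is applied to the post-yield
    section only so the elastic gradient stays exactly recoverable at zero
    noise.
    """
    if modulus <= 0 or yield_travel <= 0 or travel_end <= yield_travel:
        raise ValueError("need modulus > 0 and 0 < yield_travel < travel_end")
    spec = spec or GeneratorSpec()
    x = np.linspace(0.0, travel_end, n_points)
    f_yield = modulus * yield_travel
    plateau = min(f_yield, peak_force) if peak_force is not None else f_yield
    force = np.where(x <= yield_travel, modulus * x, 0.0)
    post = x > yield_travel
    frac = (x[post] - yield_travel) / (travel_end - yield_travel)
    force[post] = plateau * (1.0 - decline_fraction * frac)
    rng = spec.rng()
    force[post] = np.clip(spec.apply(force[post], rng), 0.0, None)
    return ForceCurve(travel=x, force=force)
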