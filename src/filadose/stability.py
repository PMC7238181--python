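"""Accelerated-stability kinetics and humidity-corrected Arrhenius shelf life.

A solid dosage form is stored at several elevated temperature / relative
humidity conditions and assayed over time.  Per condition, the percent of drug
degraded d(t) is fitted to one of five kinetic laws (d_inf defaults to 100%):

* zero order:  d = k t
* first order: d = d_inf (1 - exp(-k t))
* second order:d = d_inf^2 k t / (1 + d_inf k t)
* diffusion:   d = k sqrt(t)
* Avrami:      d = d_inf (1 - exp(-k t^2))   (canonical form, exponent 2)

The per-condition rate constants are then regressed on the humidity-corrected
Arrhenius surface

    ln k = ln A - Ea / (R T) + B * RH

with R = 0.00198 kcal/(K mol), giving the activation energy Ea (kcal/mol) and
the humidity sensitivity B (per %RH).  Extrapolating k to storage conditions
(25 degC / 60% RH by default) and inverting the kinetic law at the
specification limit (10% degraded) yields the predicted shelf life.

The assay convention is explicit: observations may arrive as percent
*remaining* (the usual assay output) or percent *degraded*; fitting always
happens on the degraded scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "GAS_CONSTANT_KCAL",
    "StabilityCondition",
    "StabilityStudy",
    "DegradationFit",
    "ArrheniusModel",
    "ArrheniusResults",
    "ShelfLifePrediction",
    "fit_degradation",
    "fit_arrhenius",
    "predict_shelf_life",
    "degradation_curve",
    "invert_degradation",
    "DEGRADATION_MODELS",
]

#: Gas constant in kcal/(K mol), the unit convention of pharmaceutical
#: accelerated-stability work.
GAS_CONSTANT_KCAL = 0.00198

DEGRADATION_MODELS = ("zero", "first", "second", "diffusion", "avrami")


@dataclass
class StabilityCondition:
    """One chamber condition: temperature (K), RH (%), and assay observations.

    ``observations`` is a list of ``(day, percent)`` pairs whose meaning is set
    by ``convention``: ``percent_remaining`` (default, the assay output) or
    ``percent_degraded``.
    """

    temperature: float
    rh: float
    observations: list[tuple[float, float]] = field(default_factory=list)
    convention: str = "percent_remaining"

    def __post_init__(self) -> None:
        if self.temperature <= 273:
            raise ValueError("temperature must be in Kelvin and above 273 K")
        if not 0 <= self.rh <= 100:
            raise ValueError("RH must be in [0, 100] %")
        if self.convention not in ("percent_remaining", "percent_degraded"):
            raise ValueError(f"unknown convention {self.convention!r}")
        days = [d for d, _ in self.observations]
        if any(d < 0 for d in days) or any(
            b <= a for a, b in zip(days, days[1:])
        ):
            raise ValueError("days must be non-negative and increasing")

    def percent_degraded(self) -> tuple[np.ndarray, np.ndarray]:
        """(days, percent degraded) regardless of the ingest convention."""
        days = np.array([d for d, _ in self.observations], dtype=float)
        pct = np.array([p for _, p in self.observations], dtype=float)
        if self.convention == "percent_remaining":
            pct = 100.0 - pct
        return days, pct


@dataclass
class StabilityStudy:
    """A set of chamber conditions forming one accelerated-stability study."""

    conditions: list[StabilityCondition]

    def __iter__(self):
        return iter(self.conditions)


def degradation_curve(
    model: str, k: float, t: np.ndarray, d_inf: float = 100.0, as_printed: bool = False
) -> np.ndarray:
    """Percent degraded at times ``t`` (days) under the given kinetic law.

    ``as_printed=True`` selects, for the Avrami law only, the literal
    remaining-percent form ``remaining = d_inf - exp(-k t^2)`` (degraded =
    100 - remaining); the default is the canonical fraction form.
    """
    t = np.asarray(t, dtype=float)
    if model == "zero":
        return k * t
    if model == "first":
        return d_inf * (1.0 - np.exp(-k * t))
    if model == "second":
        return d_inf**2 * k * t / (1.0 + d_inf * k * t)
    if model == "diffusion":
        return k * np.sqrt(t)
    if model == "avrami":
        if as_printed:
            return 100.0 - (d_inf - np.exp(-k * t**2))
        return d_inf * (1.0 - np.exp(-k * t**2))
    raise ValueError(f"unknown degradation model {model!r}")


def invert_degradation(model: str, k: float, limit: float, d_inf: float = 100.0) -> float:
    """Days until ``limit`` percent degraded under the given law (closed form)."""
    if k <= 0:
        raise ValueError("rate constant must be > 0 to invert")
    if not 0 < limit < 100:
        raise ValueError("limit must be in (0, 100) percent")
    if model == "zero":
        return limit / k
    if model == "diffusion":
        return (limit / k) ** 2
    if model == "first":
        if limit >= d_inf:
            raise ValueError("limit unreachable: at or above the first-order plateau")
        return -math.log(1.0 - limit / d_inf) / k
    if model == "second":
        if limit >= d_inf:
            raise ValueError("limit unreachable: at or above the second-order plateau")
        return limit / (d_inf * k * (d_inf - limit))
    if model == "avrami":
        if limit >= d_inf:
            raise ValueError("limit unreachable: at or above the Avrami plateau")
        return math.sqrt(-math.log(1.0 - limit / d_inf) / k)
    raise ValueError(f"unknown degradation model {model!r}")


@dataclass(frozen=True)
class DegradationFit:
    """One kinetic-law fit on the percent-degraded scale."""

    model: str
    k: float
    r_squared: float
    convention: str = "percent_degraded"
    d_inf: float = 100.0
    unit: str = ""
    flat: bool = False  # degenerate all-equal data

    def time_to(self, limit: float) -> float:
        return invert_degradation(self.model, self.k, limit, self.d_inf)


_K_UNITS = {
    "zero": "%/day",
    "first": "1/day",
    "second": "1/(%*day)",
    "diffusion": "%/day^(1/2)",
    "avrami": "1/day^2",
}


def _fit_one_model(model: str, t: np.ndarray, d: np.ndarray, d_inf: float) -> DegradationFit:
    def r2(pred):
        ss_tot = float(np.sum((d - d.mean()) ** 2))
        if ss_tot == 0:
            return 1.0
        return max(0.0, 1.0 - float(np.sum((d - pred) ** 2)) / ss_tot)

    if model == "zero":
        k = float(np.dot(t, d) / np.dot(t, t))
    elif model == "diffusion":
        s = np.sqrt(t)
        k = float(np.dot(s, d) / np.dot(s, s))
    else:
        # one-parameter nonlinear laws; crude rate-scale start value
        d_pos = np.clip(d, 0.0, 0.999 * d_inf)
        with np.errstate(divide="ignore", invalid="ignore"):
            if model == "first":
                y = -np.log(1.0 - d_pos / d_inf)
                k0 = float(np.dot(t, y) / np.dot(t, t))
            elif model == "avrami":
                y = -np.log(1.0 - d_pos / d_inf)
                k0 = float(np.dot(t**2, y) / np.dot(t**2, t**2))
            else:  # second
                y = d_pos / (d_inf * (d_inf - d_pos))
                k0 = float(np.dot(t, y) / np.dot(t, t))
        k0 = max(k0, 1e-12)
        try:
            popt, _ = optimize.curve_fit(
                lambda tt, kk: degradation_curve(model, kk, tt, d_inf),
                t,
                d,
                p0=[k0],
                bounds=(0.0, np.inf),
                maxfev=10000,
            )
            k = float(popt[0])
        except RuntimeError:
            k = k0
    k = max(k, 0.0)
    return DegradationFit(
        model=model,
        k=k,
        r_squared=r2(degradation_curve(model, k, t, d_inf)),
        d_inf=d_inf,
        unit=_K_UNITS[model],
    )


def fit_degradation(
    condition: StabilityCondition,
    models: tuple[str, ...] | None = None,
    d_inf: float = 100.0,
) -> list[DegradationFit]:
    """Fit the requested kinetic laws to one condition, best R^2 first."""
    models = DEGRADATION_MODELS if models is None else tuple(models)
    unknown = set(models) - set(DEGRADATION_MODELS)
    if unknown:
        raise ValueError(f"unknown degradation model(s): {sorted(unknown)}")
    t, d = condition.percent_degraded()
    if t.size < 3:
        raise ValueError("need at least 3 observations per condition")
    if np.ptp(d) == 0:
        # flat data: every model collapses to k = 0
        return [
            DegradationFit(m, 0.0, 1.0, d_inf=d_inf, unit=_K_UNITS[m], flat=True)
            for m in models
        ]
    fits = [_fit_one_model(m, t, d, d_inf) for m in models]
    fits.sort(key=lambda f: (-f.r_squared, DEGRADATION_MODELS.index(f.model)))
    return fits


class ArrheniusModel:
    """OLS regression of ln k on 1/T and RH across chamber conditions.

    Built from ``(condition, k)`` pairs; requires at least three conditions
    spanning two distinct temperatures and two distinct RH values, all with
    k > 0 (the log is taken).
    """

    def __init__(self, fits: list[tuple[StabilityCondition, float]]) -> None:
        if len(fits) < 3:
            raise ValueError("need at least 3 (condition, k) pairs")
        temps = np.array([c.temperature for c, _ in fits])
        rhs = np.array([c.rh for c, _ in fits])
        ks = np.array([k for _, k in fits], dtype=float)
        if np.any(ks <= 0):
            raise ValueError("all rate constants must be > 0 (log scale)")
        if np.unique(temps).size < 2:
            raise ValueError("rank-deficient design: only one distinct temperature")
        if np.unique(rhs).size < 2:
            raise ValueError("rank-deficient design: only one distinct RH")
        self.temperatures = temps
        self.rh = rhs
        self.k = ks

    def fit(self) -> "ArrheniusResults":
        y = np.log(self.k)
        x = np.column_stack(
            [np.ones_like(y), 1.0 / self.temperatures, self.rh]
        )
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        pred = x @ beta
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
        return ArrheniusResults(
            ln_a=float(beta[0]),
            ea=-float(beta[1]) * GAS_CONSTANT_KCAL,
            b=float(beta[2]),
            r_squared=r2,
            residuals=y - pred,
            model=self,
        )


@dataclass(frozen=True)
class ArrheniusResults:
    """Humidity-corrected Arrhenius surface: ln k = ln_a - ea/(R T) + b RH."""

    ln_a: float
    ea: float  # kcal/mol
    b: float  # per %RH
    r_squared: float
    residuals: np.ndarray
    model: ArrheniusModel | None = None

    def ln_k(self, temperature: float, rh: float) -> float:
        return self.ln_a - self.ea / (GAS_CONSTANT_KCAL * temperature) + self.b * rh

    def k(self, temperature: float, rh: float) -> float:
        """Extrapolated rate constant at a storage condition (T in K, RH in %)."""
        return math.exp(self.ln_k(temperature, rh))

    def summary(self) -> str:
        return "\n".join(
            [
                "Humidity-corrected Arrhenius fit",
                "=" * 34,
                f"ln A            {self.ln_a:.4g}",
                f"Ea              {self.ea:.4g} kcal/mol",
                f"B (humidity)    {self.b:.4g} per %RH",
                f"R^2             {self.r_squared:.4f}",
            ]
        )


def fit_arrhenius(fits: list[tuple[StabilityCondition, float]]) -> ArrheniusResults:
    """Convenience wrapper: ``ArrheniusModel(fits).fit()``."""
    return ArrheniusModel(fits).fit()


@dataclass(frozen=True)
class ShelfLifePrediction:
    storage_temperature: float  # K
    storage_rh: float  # %
    k_extrapolated: float
    kinetic_model: str
    specification_limit: float  # % degraded
    shelf_life_days: float

    @property
    def shelf_life_years(self) -> float:
        return self.shelf_life_days / 365.25

    def summary(self) -> str:
        return "\n".join(
            [
                "Shelf-life prediction",
                "=" * 34,
                f"storage         {self.storage_temperature - 273.15:.1f} degC / "
                f"{self.storage_rh:.0f}% RH",
                f"kinetic model   {self.kinetic_model}",
                f"k (storage)     {self.k_extrapolated:.4g}",
                f"limit           {self.specification_limit:g}% degraded",
                f"shelf life      {self.shelf_life_days:.0f} days "
                f"({self.shelf_life_years:.2f} years)",
            ]
        )


def predict_shelf_life(
    af: ArrheniusResults,
    model: str,
    storage_temperature: float = 298.15,
    storage_rh: float = 60.0,
    limit: float = 10.0,
    d_inf: float = 100.0,
) -> ShelfLifePrediction:
    """Extrapolate k to storage conditions and invert the kinetic law at the limit."""
    if not 0 < limit < 100:
        raise ValueError("specification limit must be in (0, 100) percent")
    k_storage = af.k(storage_temperature, storage_rh)
    days = invert_degradation(model, k_storage, limit, d_inf)
    return ShelfLifePrediction(
        storage_temperature=storage_temperature,
        storage_rh=storage_rh,
        k_extrapolated=k_storage,
        kinetic_model=model,
        specification_limit=limit,
        shelf_life_days=days,
    )
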