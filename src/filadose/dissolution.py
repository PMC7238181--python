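"""Release-kinetics modelling of tablet dissolution profiles.

Four classical release laws are fitted to a cumulative dissolution profile
(Q_t = drug dissolved at time t, Q_inf = total drug in the dosage form):

* zero order:        Q_t = K0 t
* first order:       ln Q_t = ln Q0 + K1 t
* Hixson-Crowell:    Q_inf^(1/3) - (Q_inf - Q_t)^(1/3) = Ks t
* Korsmeyer-Peppas:  Q_t / Q_inf = K_KP t^n   (fitted up to a fractional-release cap)

Each model is fitted by least squares on its stated (possibly transformed)
scale, which matches the linearised convention of the dissolution literature;
R^2 on that same scale ranks the models.  The Korsmeyer-Peppas exponent n
classifies the transport mechanism with geometry-dependent Fickian thresholds
(0.50 thin film, 0.45 cylinder, 0.43 sphere); n >= 1 indicates zero-order
(relaxation/erosion controlled) transport.

Usage is statsmodels-style::

    res = ReleaseKinetics(profile).fit()
    res.best.model, res.best.params, res.best.r_squared
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DissolutionProfile",
    "ReleaseKineticFit",
    "ReleaseKinetics",
    "ReleaseKineticsResults",
    "fit_release_models",
    "select_best_model",
    "classify_mechanism",
    "withdrawal_correction",
    "MODEL_ORDER",
]

#: Fixed model ordering used for tie-breaking and default requests.
MODEL_ORDER = ("zero_order", "first_order", "hixson_crowell", "korsmeyer_peppas")

#: Number of fitted parameters per model (tie-break: fewer is preferred).
_N_PARAMS = {
    "zero_order": 1,
    "first_order": 2,
    "hixson_crowell": 1,
    "korsmeyer_peppas": 2,
}

_FICKIAN_THRESHOLD = {"thin_film": 0.50, "cylinder": 0.45, "sphere": 0.43}


@dataclass
class DissolutionProfile:
    """A cumulative dissolution profile.

    ``released`` is cumulative drug dissolved, in the same units as ``q_inf``
    (mg, or percent with q_inf = 100).  Small assay-noise decrements are
    tolerated up to ``epsilon`` (fraction of q_inf) and clipped to the running
    maximum before fitting.
    """

    times: np.ndarray
    released: np.ndarray
    q_inf: float
    geometry_class: str = "cylinder"
    medium_switch_time: float | None = None
    epsilon: float = 0.005

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.released = np.asarray(self.released, dtype=float)
        if self.times.shape != self.released.shape or self.times.ndim != 1:
            raise ValueError("times and released must be equal-length 1-D arrays")
        if self.q_inf <= 0:
            raise ValueError("q_inf must be > 0")
        if self.geometry_class not in _FICKIAN_THRESHOLD:
            raise ValueError(f"unknown geometry class {self.geometry_class!r}")
        decrements = np.diff(self.released)
        if np.any(decrements < -self.epsilon * self.q_inf):
            raise ValueError(
                "released must be non-decreasing (beyond the assay-noise epsilon)"
            )
        if np.any(self.released > 1.1 * self.q_inf):
            raise ValueError("released exceeds 110% of q_inf")

    def monotone_released(self) -> np.ndarray:
        """Released amounts with noise decrements clipped to the running maximum."""
        return np.maximum.accumulate(self.released)

    @property
    def fraction_released(self) -> np.ndarray:
        return self.monotone_released() / self.q_inf


@dataclass(frozen=True)
class ReleaseKineticFit:
    """One fitted release law: parameters, R^2 on the fitted scale, mechanism."""

    model: str
    params: dict[str, float]
    r_squared: float
    fit_range: tuple[int, ...]
    mechanism: str | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def classify_mechanism(n: float, geometry_class: str = "cylinder") -> str:
    """Classify transport from the Korsmeyer-Peppas exponent.

    Fickian diffusion below the geometry threshold, anomalous (coupled
    diffusion/relaxation) between it and 1, zero-order transport at n >= 1.
    """
    if n <= 0:
        raise ValueError(f"release exponent must be > 0, got {n}")
    try:
        threshold = _FICKIAN_THRESHOLD[geometry_class]
    except KeyError:
        raise ValueError(f"unknown geometry class {geometry_class!r}") from None
    if n >= 1.0:
        return "zero_order_transport"
    if n <= threshold:
        return "fickian"
    return "anomalous"


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def _fit_through_origin(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope for y = k t and R^2 of that constrained fit."""
    k = float(np.dot(t, y) / np.dot(t, t))
    return k, _r_squared(y, k * t)


def _fit_zero_order(profile, t, q, idx):
    k, r2 = _fit_through_origin(t, q)
    return ReleaseKineticFit("zero_order", {"K0": k}, r2, idx)


def _fit_first_order(profile, t, q, idx):
    pos = q > 0
    if pos.sum() < 3:
        return ReleaseKineticFit(
            "first_order", {}, 0.0, idx, error="fewer than 3 positive release values"
        )
    res = stats.linregress(t[pos], np.log(q[pos]))
    r2 = float(res.rvalue**2)
    return ReleaseKineticFit(
        "first_order",
        {"K1": float(res.slope), "Q0": float(np.exp(res.intercept))},
        r2,
        tuple(np.asarray(idx)[pos]),
    )


def _fit_hixson_crowell(profile, t, q, idx):
    remaining = np.clip(profile.q_inf - q, 0.0, None)
    y = profile.q_inf ** (1 / 3) - remaining ** (1 / 3)
    k, r2 = _fit_through_origin(t, y)
    return ReleaseKineticFit("hixson_crowell", {"Ks": k}, r2, idx)


def _fit_korsmeyer_peppas(profile, t, q, idx, fraction_cap):
    frac = q / profile.q_inf
    mask = (frac <= fraction_cap) & (t > 0)
    if mask.sum() < 3:
        return ReleaseKineticFit(
            "korsmeyer_peppas",
            {},
            0.0,
            idx,
            error=f"fewer than 3 points below the {fraction_cap:.0%} fractional cap",
        )
    tm, fm = t[mask], frac[mask]

    def model(tt, k, n):
        return k * np.power(tt, n)

    # log-log start values keep the nonlinear fit well-conditioned
    pos = fm > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(np.log(tm[pos]), np.log(fm[pos]), 1)
        p0 = (float(np.exp(intercept)), float(np.clip(slope, 0.05, 2.0)))
    else:
        p0 = (0.1, 0.5)
    try:
        popt, _ = optimize.curve_fit(
            model, tm, fm, p0=p0, bounds=([1e-12, 1e-3], [np.inf, 5.0]), maxfev=10000
        )
    except RuntimeError as exc:
        return ReleaseKineticFit("korsmeyer_peppas", {}, 0.0, idx, error=str(exc))
    k_kp, n = float(popt[0]), float(popt[1])
    r2 = _r_squared(fm, model(tm, k_kp, n))
    return ReleaseKineticFit(
        "korsmeyer_peppas",
        {"K_KP": k_kp, "n": n},
        r2,
        tuple(np.asarray(idx)[mask]),
        mechanism=classify_mechanism(n, profile.geometry_class),
    )


class ReleaseKinetics:
    """Fit a set of release laws to one dissolution profile.

    Parameters
    ----------
    profile
        The cumulative dissolution profile.
    models
        Subset of :data:`MODEL_ORDER` to fit (default: all four).
    kp_fraction_cap
        Korsmeyer-Peppas fits only use points with fractional release at or
        below this cap (default 0.6, the customary validity range of the
        power law; set to 1.0 to use the full profile).
    """

    def __init__(
        self,
        profile: DissolutionProfile,
        models: tuple[str, ...] | None = None,
        kp_fraction_cap: float = 0.6,
    ) -> None:
        requested = MODEL_ORDER if models is None else tuple(models)
        unknown = set(requested) - set(MODEL_ORDER)
        if unknown:
            raise ValueError(f"unknown release model(s): {sorted(unknown)}")
        # canonical order: results must not depend on request order
        self.models = tuple(m for m in MODEL_ORDER if m in requested)
        self.profile = profile
        self.kp_fraction_cap = kp_fraction_cap
        if profile.times.size < 4:
            raise ValueError("need at least 4 usable points")

    def fit(self) -> "ReleaseKineticsResults":
        profile = self.profile
        q = profile.monotone_released()
        t = profile.times
        idx = tuple(range(t.size))
        fits = []
        for model in self.models:
            if model == "zero_order":
                fits.append(_fit_zero_order(profile, t, q, idx))
            elif model == "first_order":
                fits.append(_fit_first_order(profile, t, q, idx))
            elif model == "hixson_crowell":
                fits.append(_fit_hixson_crowell(profile, t, q, idx))
            else:
                fits.append(
                    _fit_korsmeyer_peppas(profile, t, q, idx, self.kp_fraction_cap)
                )
        ranked = sorted(fits, key=lambda f: (-f.r_squared, _N_PARAMS[f.model]))
        return ReleaseKineticsResults(fits=ranked, profile=profile)


@dataclass(frozen=True)
class ReleaseKineticsResults:
    """All requested fits, best first (by R^2, then parsimony, then fixed order)."""

    fits: list[ReleaseKineticFit]
    profile: DissolutionProfile

    @property
    def best(self) -> ReleaseKineticFit:
        return select_best_model(self.fits)

    def summary(self) -> str:
        lines = ["Release kinetics", "=" * 52]
        lines.append(f"{'model':<20}{'R^2':>8}  parameters")
        for f in self.fits:
            if not f.ok:
                lines.append(f"{f.model:<20}{'--':>8}  failed: {f.error}")
                continue
            params = ", ".join(f"{k}={v:.4g}" for k, v in f.params.items())
            mech = f"  [{f.mechanism}]" if f.mechanism else ""
            lines.append(f"{f.model:<20}{f.r_squared:>8.4f}  {params}{mech}")
        lines.append(f"best: {self.best.model}")
        return "\n".join(lines)


def fit_release_models(
    profile: DissolutionProfile,
    models: tuple[str, ...] | None = None,
    kp_fraction_cap: float = 0.6,
) -> list[ReleaseKineticFit]:
    """Convenience wrapper: ``ReleaseKinetics(...).fit().fits``."""
    return ReleaseKinetics(profile, models, kp_fraction_cap).fit().fits


def select_best_model(fits: list[ReleaseKineticFit]) -> ReleaseKineticFit:
    """Highest R^2; ties go to fewer parameters, then the fixed model order."""
    ok = [f for f in fits if f.ok]
    if not ok:
        raise ValueError("all release-model fits failed")
    return min(
        ok, key=lambda f: (-f.r_squared, _N_PARAMS[f.model], MODEL_ORDER.index(f.model))
    )


def withdrawal_correction(
    times: np.ndarray,
    concentrations: np.ndarray,
    sample_volume: float,
    medium_volume: float | np.ndarray,
) -> np.ndarray:
    """Cumulative-amount correction for repeated sampling without replacement.

    Returns the cumulative dissolved amount at each sampling time, adding back
    the drug removed with each earlier aliquot:
    ``M_i = C_i V_i + sum_{j<i} C_j v`` with aliquot volume ``v`` and medium
    volume ``V_i`` (a scalar or per-sample array, so a mid-run medium addition
    can be represented).  Off by default in the pipeline.
    """
    c = np.asarray(concentrations, dtype=float)
    v_medium = np.broadcast_to(np.asarray(medium_volume, dtype=float), c.shape)
    removed = np.concatenate([[0.0], np.cumsum(c[:-1] * sample_volume)])
    return c * v_medium + removed
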