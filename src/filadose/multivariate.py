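"""Multivariate analysis of the loading experiments: PCA and flux regression.

The feature table holds one row per (solvent, filament) combination with six
variables: the solvent-filament Hansen distance Ra, the blank-filament
surface roughness Rav, bending modulus, toughness (the "stiffness" of the
loading experiments), the measured steady-state flux Jss and the derived
permeability.  PCA on the standardised columns (with correlation loadings)
exposes the covariance structure; regression models — multiple linear
regression, partial least squares and an RBF-kernel support vector machine —
predict Jss from the four material descriptors.

With only a handful of rows no honest generalisation claim is possible; the
SVM hyperparameters are chosen by an exhaustive grid search scored by
leave-one-out R^2, the model is refitted on all rows, and the reported R^2 is
a training-set fit (stated explicitly in the results metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR

__all__ = [
    "FEATURE_COLUMNS",
    "DESCRIPTOR_COLUMNS",
    "assemble_feature_table",
    "run_pca",
    "PcaResult",
    "FluxRegression",
    "RegressionResults",
    "fit_flux_model",
    "DEFAULT_SVM_GRID",
]

#: The six analysed variables, in fixed column order.
FEATURE_COLUMNS = (
    "ra_solvent_filament",
    "roughness_rav",
    "bending_modulus",
    "toughness",
    "jss",
    "permeability",
)

#: Material descriptors used as regression inputs (the target is jss).
DESCRIPTOR_COLUMNS = (
    "ra_solvent_filament",
    "roughness_rav",
    "bending_modulus",
    "toughness",
)

DEFAULT_SVM_GRID = {
    "C": (0.1, 1.0, 10.0, 100.0),
    "gamma": (0.01, 0.1, 0.5, 1.0, 2.0),
    "epsilon": (0.001, 0.01, 0.05),
}


def assemble_feature_table(
    screen_results,
    mechanics_table: pd.DataFrame,
    flux_table: pd.DataFrame,
    csat: dict[str, float],
) -> pd.DataFrame:
    """Join screening, mechanics and flux outputs into the modelling table.

    Parameters
    ----------
    screen_results
        Iterable of :class:`~filadose.hsp.ScreenResult` covering every
        (solvent, filament) combination present in ``flux_table``.
    mechanics_table
        One row per filament: columns ``filament, rav_um,
        bending_modulus_nmm, toughness_nmm`` (blank-filament values, used for
        both solvents).
    flux_table
        One row per combination: columns ``solvent, filament, jss``.
    csat
        Solvent name -> saturation solubility (mg/cm^3), for the permeability
        column.

    Returns a DataFrame indexed by (solvent, filament) with the six
    :data:`FEATURE_COLUMNS`, sorted by index for determinism.
    """
    ra = {(r.solvent, r.filament): r.ra_solvent_filament for r in screen_results}
    mech = mechanics_table.set_index("filament")
    rows = []
    for _, rec in flux_table.iterrows():
        key = (rec["solvent"], rec["filament"])
        if key not in ra:
            raise KeyError(f"no screening result for combination {key}")
        if rec["filament"] not in mech.index:
            raise KeyError(f"no mechanics data for filament {rec['filament']!r}")
        if rec["solvent"] not in csat:
            raise KeyError(f"no saturation solubility for solvent {rec['solvent']!r}")
        m = mech.loc[rec["filament"]]
        rows.append(
            {
                "solvent": rec["solvent"],
                "filament": rec["filament"],
                "ra_solvent_filament": ra[key],
                "roughness_rav": m["rav_um"],
                "bending_modulus": m["bending_modulus_nmm"],
                "toughness": m["toughness_nmm"],
                "jss": rec["jss"],
                "permeability": rec["jss"] / csat[rec["solvent"]],
            }
        )
    table = pd.DataFrame(rows).set_index(["solvent", "filament"]).sort_index()
    return table[list(FEATURE_COLUMNS)]


@dataclass(frozen=True)
class PcaResult:
    """PCA of the standardised feature table.

    ``loadings`` has one column per component (orthonormal eigenvectors);
    ``correlation_loadings`` are the Pearson correlations of each original
    variable with each score vector, the quantity plotted in correlation
    loading plots.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    correlation_loadings: pd.DataFrame
    explained_variance: np.ndarray


def run_pca(table: pd.DataFrame, standardise: bool = True) -> PcaResult:
    """Principal component analysis of the feature table."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows for PCA")
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    zero_var = [c for c, s in zip(table.columns, sd) if s == 0]
    if zero_var:
        raise ValueError(f"zero-variance column(s): {zero_var}")
    if standardise:
        x = (x - x.mean(axis=0)) / sd
    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(x)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    corr = np.empty((x.shape[1], n_comp))
    for j in range(n_comp):
        s = scores[:, j]
        s_sd = s.std(ddof=1)
        for i in range(x.shape[1]):
            corr[i, j] = (
                0.0
                if s_sd == 0
                else float(np.corrcoef(table.iloc[:, i], s)[0, 1])
            )
    return PcaResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=table.columns, columns=comp_names
        ),
        correlation_loadings=pd.DataFrame(
            corr, index=table.columns, columns=comp_names
        ),
        explained_variance=pca.explained_variance_ratio_,
    )


def _r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if np.allclose(pred, y) else 0.0
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


class FluxRegression:
    """Regression of Jss on the material descriptors.

    Parameters
    ----------
    table
        Feature table from :func:`assemble_feature_table`.
    method
        ``"mlr"``, ``"pls"`` or ``"svm_rbf"``.
    features
        Descriptor columns (default :data:`DESCRIPTOR_COLUMNS`; a config
        switch in the pipeline allows swapping toughness for the bending
        modulus as the "stiffness" input).
    svm_grid / svm_tune / pls_components
        Tuning: the SVM grid is searched exhaustively in fixed order
        (ascending C, then gamma, then epsilon), each candidate scored by
        training-set R^2 (``svm_tune="training"``, the default — the reported
        fit statistic is a training fit, so selection is aligned with it) or
        by leave-one-out R^2 (``svm_tune="loo"``); ties keep the first
        (least-C) candidate.  The leave-one-out score of the selected
        hyperparameters is always reported as a diagnostic.  PLS uses
        ``pls_components`` latent variables (default 2).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        method: str = "svm_rbf",
        features: tuple[str, ...] = DESCRIPTOR_COLUMNS,
        target: str = "jss",
        svm_grid: dict | None = None,
        svm_tune: str = "training",
        pls_components: int = 2,
    ) -> None:
        if svm_tune not in ("training", "loo"):
            raise ValueError(f"unknown svm_tune {svm_tune!r}")
        if method not in ("mlr", "pls", "svm_rbf"):
            raise ValueError(f"unknown regression method {method!r}")
        if len(table) < 3:
            raise ValueError("need at least 3 rows to fit")
        missing = [c for c in (*features, target) if c not in table.columns]
        if missing:
            raise KeyError(f"missing column(s): {missing}")
        if method == "pls" and pls_components > len(table) - 1:
            raise ValueError("PLS components cannot exceed rows - 1")
        self.table = table
        self.method = method
        self.features = tuple(features)
        self.target = target
        self.svm_grid = DEFAULT_SVM_GRID if svm_grid is None else svm_grid
        self.svm_tune = svm_tune
        self.pls_components = pls_components

    # -- internals ---------------------------------------------------------
    def _standardise(self, x: np.ndarray, y: np.ndarray):
        x_mean, x_sd = x.mean(axis=0), x.std(axis=0, ddof=0)
        x_sd = np.where(x_sd == 0, 1.0, x_sd)
        y_mean, y_sd = y.mean(), y.std(ddof=0)
        y_sd = y_sd if y_sd > 0 else 1.0
        return (x - x_mean) / x_sd, (y - y_mean) / y_sd, (x_mean, x_sd, y_mean, y_sd)

    def _make_estimator(self, hyper: dict):
        if self.method == "mlr":
            return LinearRegression()
        if self.method == "pls":
            return PLSRegression(n_components=self.pls_components, scale=False)
        return SVR(kernel="rbf", **hyper)

    def _loo_r2(self, xs: np.ndarray, ys: np.ndarray, hyper: dict) -> float:
        preds = np.empty_like(ys)
        for i in range(len(ys)):
            mask = np.ones(len(ys), dtype=bool)
            mask[i] = False
            est = self._make_estimator(hyper)
            est.fit(xs[mask], ys[mask])
            preds[i] = np.ravel(est.predict(xs[i : i + 1]))[0]
        return _r_squared(ys, preds)

    def fit(self) -> "RegressionResults":
        x = self.table[list(self.features)].to_numpy(dtype=float)
        y = self.table[self.target].to_numpy(dtype=float)
        xs, ys, scaling = self._standardise(x, y)

        hyper: dict = {}
        loo_r2 = None
        if self.method == "svm_rbf":
            best = None
            for c in self.svm_grid["C"]:
                for gamma in self.svm_grid["gamma"]:
                    for epsilon in self.svm_grid["epsilon"]:
                        cand = {"C": c, "gamma": gamma, "epsilon": epsilon}
                        if self.svm_tune == "loo":
                            score = self._loo_r2(xs, ys, cand)
                        else:
                            est = self._make_estimator(cand)
                            est.fit(xs, ys)
                            score = _r_squared(ys, np.ravel(est.predict(xs)))
                        if best is None or score > best[0]:
                            best = (score, cand)
            _, hyper = best
            loo_r2 = self._loo_r2(xs, ys, hyper)
        elif self.method == "pls":
            hyper = {"n_components": self.pls_components}

        est = self._make_estimator(hyper)
        est.fit(xs, ys)
        pred_s = np.ravel(est.predict(xs))
        x_mean, x_sd, y_mean, y_sd = scaling
        pred = pred_s * y_sd + y_mean
        rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
        return RegressionResults(
            method=self.method,
            hyperparameters=dict(hyper),
            r_squared=_r_squared(y, pred),
            rmse=rmse,
            loo_r_squared=loo_r2,
            predictions=pd.Series(pred, index=self.table.index, name="jss_pred"),
            features=self.features,
            target=self.target,
            _estimator=est,
            _scaling=scaling,
        )


@dataclass
class RegressionResults:
    """Fitted flux-regression model.

    ``r_squared`` and ``rmse`` are training-set statistics (the study design
    has too few rows for a held-out estimate); for the SVM,
    ``loo_r_squared`` is the leave-one-out score of the selected
    hyperparameters.
    """

    method: str
    hyperparameters: dict
    r_squared: float
    rmse: float
    loo_r_squared: float | None
    predictions: pd.Series
    features: tuple[str, ...]
    target: str
    _estimator: object = field(repr=False, default=None)
    _scaling: tuple = field(repr=False, default=None)

    def predict(self, descriptors: pd.DataFrame | dict) -> np.ndarray:
        """Predict Jss (original scale) for new descriptor rows."""
        if isinstance(descriptors, dict):
            descriptors = pd.DataFrame([descriptors])
        missing = [c for c in self.features if c not in descriptors.columns]
        if missing:
            raise KeyError(f"missing descriptor(s): {missing}")
        extra = [c for c in descriptors.columns if c not in self.features]
        if extra:
            descriptors = descriptors[list(self.features)]
        x = descriptors[list(self.features)].to_numpy(dtype=float)
        x_mean, x_sd, y_mean, y_sd = self._scaling
        pred_s = np.ravel(self._estimator.predict((x - x_mean) / x_sd))
        return pred_s * y_sd + y_mean

    def summary(self) -> str:
        lines = [
            f"Flux regression ({self.method})",
            "=" * 34,
            f"features        {', '.join(self.features)}",
            f"target          {self.target}",
            f"training R^2    {self.r_squared:.4f}",
            f"training RMSE   {self.rmse:.4g}",
        ]
        if self.loo_r_squared is not None:
            lines.append(f"LOO R^2         {self.loo_r_squared:.4f}")
        if self.hyperparameters:
            hp = ", ".join(f"{k}={v}" for k, v in self.hyperparameters.items())
            lines.append(f"hyperparameters {hp}")
        return "\n".join(lines)


def fit_flux_model(
    table: pd.DataFrame, method: str = "svm_rbf", **tuning
) -> RegressionResults:
    """Convenience wrapper: ``FluxRegression(table, method, **tuning).fit()``."""
    return FluxRegression(table, method, **tuning).fit()
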