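"""PLS1 calibration of oxidation markers from NIR spectra.

Latent variables are covariance-maximising linear combinations of the
spectral channels; prediction is affine in the input spectrum.  Validation
uses leave-one-material-group-out cross-validation: each packaging material
in turn is held out, the model is refit (with fold-local centering) on the
remaining materials, and the held-out rows are predicted.  Reported figures
of merit follow standard chemometric practice: RMSEC, RMSECV, R2 (calibration
and CV), bias (mean signed CV error) and RPD = sd(y)/RMSECV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "PlsModel",
    "CalMetrics",
    "fit_pls",
    "crossval_material",
    "select_lv",
    "rpd",
]


@dataclass
class PlsModel:
    """Fitted single-response PLS model (NIPALS, deterministic)."""

    n_lv: int
    x_weights: np.ndarray       # (p, k)
    x_loadings: np.ndarray      # (p, k)
    y_loadings: np.ndarray      # (k,)
    regression_vector: np.ndarray  # (p,)
    x_mean: np.ndarray
    y_mean: float

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        return (X - self.x_mean) @ self.regression_vector + self.y_mean


@dataclass
class CalMetrics:
    """Calibration and cross-validation figures of merit at the chosen LV count."""

    n_lv: int
    rmsec: float
    rmsecv: float
    r2_cal: float
    r2_cv: float
    bias: float                  # mean signed cross-validation error
    rpd: float                   # sd(y) / rmsecv
    per_lv_curves: pd.DataFrame  # columns: n_lv, rmsec, rmsecv


def rpd(sd_y: float, rmsecv: float) -> float:
    """Ratio of performance to deviation: reference sd over RMSECV."""
    if rmsecv <= 0:
        raise ValueError("rmsecv must be > 0")
    return sd_y / rmsecv


def fit_pls(X, y, n_lv: int) -> PlsModel:
    """Fit a single-response PLS model with ``n_lv`` latent variables.

    X and y are column-centered internally; successive score vectors are
    mutually orthogonal by construction of the NIPALS deflation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    max_lv = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_lv <= max_lv:
        raise ValueError(f"n_lv must be in [1, {max_lv}], got {n_lv}")
    m = PLSRegression(n_components=n_lv, scale=False).fit(X, y)
    return PlsModel(
        n_lv=n_lv,
        x_weights=m.x_weights_,
        x_loadings=m.x_loadings_,
        y_loadings=m.y_loadings_.ravel(),
        regression_vector=m.coef_.ravel(),
        x_mean=m._x_mean,
        y_mean=float(np.mean(y)),
    )


def _rmse(err: np.ndarray) -> float:
    return float(np.sqrt(np.mean(err**2)))


def crossval_material(X, y, design: pd.DataFrame, n_lv: int) -> CalMetrics:
    """Leave-one-material-group-out cross-validation at 1..n_lv latent variables.

    For each material level the model is trained on the other levels —
    re-centering on the training fold so no information leaks from the held-out
    group — and the held-out rows are predicted.  RMSECV pools all held-out
    squared errors; the reported metrics are taken at the RMSECV-minimising
    LV count (ties -> fewer LVs).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    materials = design["material"].to_numpy()
    levels = pd.unique(materials)
    if len(levels) < 3:
        raise ValueError("need >= 3 material groups so every fold trains on >= 2")

    lvs = np.arange(1, n_lv + 1)
    sq_err = np.zeros((len(lvs), len(y)))   # CV squared errors, per LV
    cv_err = np.zeros((len(lvs), len(y)))   # signed, for bias
    for level in levels:
        test = materials == level
        train = ~test
        for i, k in enumerate(lvs):
            model = fit_pls(X[train], y[train], int(k))
            err = model.predict(X[test]) - y[test]
            cv_err[i, test] = err
            sq_err[i, test] = err**2

    rmsecv_curve = np.sqrt(sq_err.mean(axis=1))
    rmsec_curve = np.array(
        [_rmse(fit_pls(X, y, int(k)).predict(X) - y) for k in lvs]
    )
    curves = pd.DataFrame({"n_lv": lvs, "rmsec": rmsec_curve, "rmsecv": rmsecv_curve})

    best = select_lv(curves)
    i = int(np.flatnonzero(lvs == best)[0])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    sd_y = float(np.std(y, ddof=1))
    return CalMetrics(
        n_lv=best,
        rmsec=float(rmsec_curve[i]),
        rmsecv=float(rmsecv_curve[i]),
        r2_cal=1.0 - float(np.sum((fit_pls(X, y, best).predict(X) - y) ** 2)) / ss_tot,
        r2_cv=1.0 - float(sq_err[i].sum()) / ss_tot,
        bias=float(cv_err[i].mean()),
        rpd=rpd(sd_y, float(rmsecv_curve[i])),
        per_lv_curves=curves,
    )


def select_lv(per_lv_curves: pd.DataFrame) -> int:
    """LV count minimising RMSECV; ties break to the smaller count."""
    if len(per_lv_curves) == 0:
        raise ValueError("empty per-LV curve")
    curves = per_lv_curves.sort_values("n_lv")
    i = int(np.argmin(curves["rmsecv"].to_numpy()))  # argmin takes first minimum
    return int(curves["n_lv"].to_numpy()[i])
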