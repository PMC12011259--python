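"""Per-tree biomass estimators and fit metrics.

Two estimator families: the classical power-law allometry M = a * D^b
(optionally with a height factor H^c), fitted by ordinary least squares in
log space, and a small feed-forward network on (DBH, height, age, one-hot
region). A root-shoot ratio converts aboveground to belowground biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

__all__ = [
    "AllometricModel",
    "MlpEstimator",
    "FitMetrics",
    "fit_allometric",
    "predict_biomass",
    "belowground_from_aboveground",
    "evaluate_model",
]

N_REGIONS = 6  # region codes 0..5


@dataclass(frozen=True)
class AllometricModel:
    """Power-law biomass model M = a * D^b [* H^c], kg out, cm/m in.

    ``log_sigma`` is the residual SD of the log-space fit; when
    ``bias_correct`` is set, predictions carry the lognormal
    back-transform factor exp(sigma^2 / 2).
    """

    a: float
    b: float
    c: float | None = None
    log_sigma: float = 0.0
    bias_correct: bool = False

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("scale coefficient a must be > 0")

    def predict(self, dbh, height=None):
        """Predict biomass (kg) from DBH (cm) and optionally height (m)."""
        dbh = np.asarray(dbh, dtype=float)
        if np.any(dbh < 0):
            raise ValueError("DBH must be >= 0")
        out = self.a * dbh**self.b
        if self.c is not None:
            if height is None:
                raise ValueError("model was fitted with height; height missing")
            height = np.asarray(height, dtype=float)
            out = out * height**self.c
        if self.bias_correct:
            out = out * math.exp(self.log_sigma**2 / 2.0)
        return out if out.ndim else float(out)


def fit_allometric(
    dbh: Sequence[float],
    mass: Sequence[float],
    heights: Sequence[float] | None = None,
    bias_correct: bool = False,
) -> AllometricModel:
    """Fit M = a*D^b (or a*D^b*H^c) by least squares on log-log data.

    Requires at least 3 strictly positive (D, M) pairs; recovers the
    generating parameters exactly on noiseless power-law data.
    """
    d = np.asarray(dbh, dtype=float)
    m = np.asarray(mass, dtype=float)
    if d.shape != m.shape or d.ndim != 1:
        raise ValueError("dbh and mass must be 1-D and equal length")
    if d.size < 3:
        raise ValueError(f"need >= 3 pairs to fit, got {d.size}")
    if np.any(d <= 0) or np.any(m <= 0):
        raise ValueError("DBH and mass must be strictly positive")
    cols = [np.ones_like(d), np.log(d)]
    if heights is not None:
        h = np.asarray(heights, dtype=float)
        if h.shape != d.shape:
            raise ValueError("heights must match dbh length")
        if np.any(h <= 0):
            raise ValueError("heights must be strictly positive")
        cols.append(np.log(h))
    X = np.column_stack(cols)
    y = np.log(m)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(d.size - X.shape[1], 1)
    sigma = float(np.sqrt(resid @ resid / dof))
    return AllometricModel(
        a=float(np.exp(coef[0])),
        b=float(coef[1]),
        c=float(coef[2]) if heights is not None else None,
        log_sigma=sigma,
        bias_correct=bias_correct,
    )


@dataclass
class MlpEstimator:
    """Feed-forward biomass regressor on (DBH, height, age, region one-hot).

    Deterministic for a fixed seed; predictions are clamped at zero. The
    ``sigmoid`` activation maps to scikit-learn's logistic unit. Setting
    ``loss="binary_crossentropy"`` trains on min-max-scaled targets in
    (0, 1) — a documented variant, off by default.
    """

    hidden_layer_sizes: tuple[int, ...] = (16,)
    activation: str = "sigmoid"  # "sigmoid" | "relu"
    loss: str = "mse"  # "mse" | "binary_crossentropy"
    seed: int = 0
    max_iter: int = 2000
    _net: MLPRegressor | None = field(default=None, repr=False)
    _scaler: StandardScaler | None = field(default=None, repr=False)
    _y_range: tuple[float, float] | None = field(default=None, repr=False)

    _ACTIVATIONS = {"sigmoid": "logistic", "relu": "relu"}

    def __post_init__(self) -> None:
        if self.activation not in self._ACTIVATIONS:
            raise ValueError(
                f"activation must be one of {sorted(self._ACTIVATIONS)}"
            )
        if self.loss not in {"mse", "binary_crossentropy"}:
            raise ValueError("loss must be 'mse' or 'binary_crossentropy'")
        if any(h <= 0 for h in self.hidden_layer_sizes):
            raise ValueError("hidden layer sizes must be positive")

    @staticmethod
    def design_matrix(dbh, height, age, region) -> np.ndarray:
        """Stack features: dbh, height, age and a 6-wide region one-hot."""
        dbh = np.asarray(dbh, dtype=float)
        height = np.asarray(height, dtype=float)
        age = np.asarray(age, dtype=float)
        region = np.asarray(region, dtype=int)
        for name, arr in (("dbh", dbh), ("height", height), ("age", age)):
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"feature {name!r} contains non-finite values")
        if np.any((region < 0) | (region >= N_REGIONS)):
            raise ValueError(f"region codes must be in 0..{N_REGIONS - 1}")
        onehot = np.eye(N_REGIONS)[region]
        return np.column_stack([dbh, height, age, onehot])

    def fit(self, dbh, height, age, region, mass) -> "MlpEstimator":
        X = self.design_matrix(dbh, height, age, region)
        y = np.asarray(mass, dtype=float)
        if y.shape[0] != X.shape[0]:
            raise ValueError("mass length must match features")
        self._scaler = StandardScaler().fit(X)
        Xs = self._scaler.transform(X)
        if self.loss == "binary_crossentropy":
            lo, hi = float(y.min()), float(y.max())
            if hi <= lo:
                raise ValueError("constant target; cannot min-max scale")
            self._y_range = (lo, hi)
            # squash strictly inside (0,1) so the BCE-style target is valid
            y_fit = 0.02 + 0.96 * (y - lo) / (hi - lo)
        else:
            self._y_range = None
            y_fit = y
        self._net = MLPRegressor(
            hidden_layer_sizes=self.hidden_layer_sizes,
            activation=self._ACTIVATIONS[self.activation],
            solver="lbfgs",
            max_iter=self.max_iter,
            random_state=self.seed,
        ).fit(Xs, y_fit)
        return self

    def predict(self, dbh, height, age, region) -> np.ndarray:
        if self._net is None or self._scaler is None:
            raise RuntimeError("estimator is not fitted")
        X = self._scaler.transform(self.design_matrix(dbh, height, age, region))
        y = self._net.predict(X)
        if self._y_range is not None:
            lo, hi = self._y_range
            y = lo + (y - 0.02) / 0.96 * (hi - lo)
        return np.clip(y, 0.0, None)


def predict_biomass(model, tree) -> float:
    """Predict one tree's biomass (kg) with either estimator family.

    ``tree`` is any object exposing ``dbh`` and, as the model requires,
    ``height``, ``age`` and ``region_code`` attributes.
    """
    dbh = getattr(tree, "dbh", None)
    if dbh is None:
        raise ValueError("tree record is missing feature 'dbh'")
    if isinstance(model, AllometricModel):
        height = getattr(tree, "height", None)
        if model.c is not None and height is None:
            raise ValueError("tree record is missing feature 'height'")
        return float(model.predict(dbh, height))
    for feat in ("height", "age", "region_code"):
        if getattr(tree, feat, None) is None:
            raise ValueError(f"tree record is missing feature {feat!r}")
    return float(
        model.predict(
            [dbh], [tree.height], [tree.age], [tree.region_code]
        )[0]
    )


def belowground_from_aboveground(
    b_aa: float, root_shoot_ratio: float = 0.25
) -> float:
    """Belowground biomass from aboveground via a root-shoot ratio."""
    if b_aa < 0:
        raise ValueError("aboveground biomass must be >= 0")
    if not (0.0 < root_shoot_ratio <= 1.0):
        raise ValueError("root_shoot_ratio must be in (0, 1]")
    return b_aa * root_shoot_ratio


@dataclass(frozen=True)
class FitMetrics:
    """Standard regression metrics; r2 is None when SST is zero."""

    r2: float | None
    mae: float
    rmse: float
    mse: float

    def as_dict(self) -> dict:
        return {"r2": self.r2, "mae": self.mae, "rmse": self.rmse, "mse": self.mse}


def evaluate_model(predicted, observed) -> FitMetrics:
    """R^2 = 1 - SSE/SST plus MAE, RMSE and MSE of predicted vs observed."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("predicted and observed must be equal-length, non-empty")
    err = p - o
    mse = float(np.mean(err**2))
    sst = float(np.sum((o - o.mean()) ** 2))
    r2 = None if sst == 0.0 else 1.0 - float(np.sum(err**2)) / sst
    return FitMetrics(
        r2=r2,
        mae=float(np.mean(np.abs(err))),
        rmse=math.sqrt(mse),
        mse=mse,
    )
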