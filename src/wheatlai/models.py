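"""The six-regressor suite, accuracy metrics, and the wheat-pixel mask stage.

Regressors and their default settings:

* RF — random forest, 500 trees, minimum 8 samples per leaf.
* XGBOOST — gradient-boosted stumps: learning rate 0.5, max depth 1,
  gamma 0.01, alpha 0.02, lambda 0.1, subsample 0.3, colsample_bytree 0.5.
* SVM — RBF kernel, C and gamma tuned on a log-2 grid 2^-8 ... 2^8 by
  5-fold cross-validation on the calibration set, features standardized.
* BPNN — one hidden layer with one node (configurable), standardized inputs.
* CNN1D / LSTM — the compact numpy networks of :mod:`wheatlai.nn`.

Accuracy is reported as R^2 (squared Pearson correlation of measured vs
predicted), RMSE (root mean squared residual, LAI units) and
RPD = SD(measured)/RMSE, the ratio of performance to deviation; RPD > 2
marks a highly reliable model, RPD < 1.4 an unreliable one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import GridSearchCV
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .indices import BandSet, MASK_VI_NAMES, compute_vi
from .nn import CNN1DRegressor, LSTMRegressor
from .raster import Raster

ALGORITHMS: tuple[str, ...] = ("RF", "XGBOOST", "SVM", "BPNN", "CNN1D", "LSTM")

#: Algorithms whose fit is bit-reproducible for a fixed seed.
DETERMINISTIC_ALGORITHMS: tuple[str, ...] = ("RF", "XGBOOST", "SVM")


@dataclass
class ModelSpec:
    """An algorithm name, hyperparameter overrides, and a seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class FitResult:
    """A trained model plus the feature names it expects, in order."""

    spec: ModelSpec
    model: object
    feature_names: list[str]

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        return np.asarray(self.model.predict(np.asarray(X, dtype=float))).ravel()


def _build_model(spec: ModelSpec, n_features: int):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.algorithm == "RF":
        return RandomForestRegressor(
            n_estimators=hp.pop("n_estimators", 500),
            min_samples_leaf=hp.pop("min_samples_leaf", 8),
            random_state=seed, n_jobs=1, **hp)
    if spec.algorithm == "XGBOOST":
        return XGBRegressor(
            n_estimators=hp.pop("n_estimators", 200),
            learning_rate=hp.pop("learning_rate", 0.5),
            max_depth=hp.pop("max_depth", 1),
            gamma=hp.pop("gamma", 0.01),
            reg_alpha=hp.pop("reg_alpha", 0.02),
            reg_lambda=hp.pop("reg_lambda", 0.1),
            subsample=hp.pop("subsample", 0.3),
            colsample_bytree=hp.pop("colsample_bytree", 0.5),
            random_state=seed, n_jobs=1, tree_method="hist", **hp)
    if spec.algorithm == "SVM":
        grid = hp.pop("grid", [2.0**e for e in range(-8, 9)])
        cv = hp.pop("cv", 5)
        pipe = Pipeline([("scale", StandardScaler()),
                         ("svr", SVR(kernel="rbf", **hp))])
        return GridSearchCV(pipe, {"svr__C": grid, "svr__gamma": grid},
                            cv=cv, scoring="neg_mean_squared_error", n_jobs=1)
    if spec.algorithm == "BPNN":
        return Pipeline([
            ("scale", StandardScaler()),
            ("mlp", MLPRegressor(
                hidden_layer_sizes=hp.pop("hidden_layer_sizes", (1,)),
                solver=hp.pop("solver", "lbfgs"),
                max_iter=hp.pop("max_iter", 2000),
                random_state=seed, **hp))])
    if spec.algorithm == "CNN1D":
        return CNN1DRegressor(seed=seed, **hp)
    if spec.algorithm == "LSTM":
        return LSTMRegressor(seed=seed, **hp)
    raise AssertionError(spec.algorithm)


def fit_model(spec: ModelSpec, X_cal, y_cal,
              feature_names: Sequence[str] | None = None) -> FitResult:
    """Train one algorithm on the calibration set.

    ``X_cal`` may be a DataFrame (column names become the fit's feature
    names) or an array.  NaN anywhere in the inputs is an error naming the
    offending feature and sample.
    """
    if isinstance(X_cal, pd.DataFrame):
        names = list(X_cal.columns)
        X = X_cal.to_numpy(dtype=float)
        index = list(X_cal.index)
    else:
        X = np.asarray(X_cal, dtype=float)
        names = list(feature_names) if feature_names else [
            f"x{i}" for i in range(X.shape[1])]
        index = list(range(X.shape[0]))
    y = np.asarray(y_cal, dtype=float).ravel()
    if X.shape[0] < 5:
        raise ValueError("need at least 5 calibration samples")
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-finite value in feature {names[c]!r} at sample {index[r]!r}")
    if not np.isfinite(y).all():
        raise ValueError("non-finite target values")
    model = _build_model(spec, X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return FitResult(spec, model, names)


# ---------------------------------------------------------------------------
# Accuracy metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """R^2, RMSE and RPD of predictions against measured values."""

    r2: float
    rmse: float
    rpd: float
    n: int
    label: str
    r2_sse: float = np.nan  # 1 - SSE/SST variant, for reference

    def as_dict(self) -> dict:
        return {"label": self.label, "n": self.n, "R2": self.r2,
                "RMSE": self.rmse, "RPD": self.rpd}


def evaluate(measured, predicted, label: str = "calibration") -> EvalReport:
    """Accuracy report for one evaluation set.

    R^2 is the squared Pearson correlation of measured and predicted values;
    RMSE the root mean squared residual; RPD the population SD of the
    measured values over the RMSE (+inf for perfect predictions).
    """
    x = np.asarray(measured, dtype=float).ravel()
    y = np.asarray(predicted, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("measured and predicted must share length >= 2")
    sd = x.std()
    if sd == 0:
        raise ValueError("measured values have zero variance")
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    if y.std() == 0:
        warnings.warn("zero-variance predictions; reporting R2 = 0", stacklevel=2)
        r2 = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
        r2 = r * r
    rpd = float(sd / rmse) if rmse > 0 else float("inf")
    sst = float(((x - x.mean()) ** 2).sum())
    r2_sse = 1.0 - float(((y - x) ** 2).sum()) / sst
    return EvalReport(r2, rmse, rpd, int(x.size), label, r2_sse)


# ---------------------------------------------------------------------------
# Wheat-pixel mask
# ---------------------------------------------------------------------------

@dataclass
class MaskReport:
    """Overall accuracy and Cohen's kappa of a binary wheat/soil mask."""

    oa: float
    kappa: float
    confusion: np.ndarray  # rows: truth (soil, wheat); cols: predicted


def evaluate_mask(predicted, truth) -> MaskReport:
    """OA and kappa from the 2x2 confusion matrix; single-class truth => kappa NaN."""
    p = (predicted.values if isinstance(predicted, Raster) else
         np.asarray(predicted)).astype(bool).ravel()
    t = (truth.values if isinstance(truth, Raster) else
         np.asarray(truth)).astype(bool).ravel()
    if p.shape != t.shape:
        raise ValueError("masks must share shape")
    conf = np.zeros((2, 2), dtype=np.int64)
    for ti in (0, 1):
        for pi in (0, 1):
            conf[ti, pi] = int(np.sum((t == ti) & (p == pi)))
    total = conf.sum()
    po = conf.trace() / total
    pe = float((conf.sum(axis=1) * conf.sum(axis=0)).sum()) / total**2
    kappa = (po - pe) / (1 - pe) if pe < 1 else np.nan
    return MaskReport(float(po), float(kappa), conf)


def _mask_features(bands: BandSet) -> np.ndarray:
    """Per-pixel feature matrix: 4 bands + NDVI, EVI2, REOSAVI, OSAVI."""
    layers = list(bands.arrays())
    layers += [compute_vi(bands, name).values for name in MASK_VI_NAMES]
    return np.stack([a.ravel() for a in layers], axis=1)


@dataclass
class MaskModel:
    """A trained wheat/soil pixel classifier."""

    classifier: RandomForestClassifier

    def predict_raster(self, bands: BandSet) -> Raster:
        feats = _mask_features(bands)
        valid = np.isfinite(feats).all(axis=1)
        out = np.zeros(feats.shape[0])
        if valid.any():
            out[valid] = self.classifier.predict(feats[valid])
        out[~valid] = np.nan
        return bands.grid.like(out.reshape(bands.grid.shape))


def train_wheat_mask(bands: BandSet, labels: Raster, seed: int = 42,
                     max_pixels: int = 20000) -> MaskModel:
    """Random-forest wheat-pixel classifier (library-default hyperparameters).

    Trains on the 8 per-pixel features (4 band reflectances plus NDVI, EVI2,
    REOSAVI and OSAVI) against the 0/1 label raster, subsampling at most
    ``max_pixels`` pixels reproducibly.
    """
    feats = _mask_features(bands)
    y = labels.values.ravel()
    valid = np.isfinite(feats).all(axis=1) & np.isfinite(y)
    feats, y = feats[valid], (y[valid] > 0.5).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    if feats.shape[0] > max_pixels:
        rng = np.random.default_rng(seed)
        sel = rng.choice(feats.shape[0], max_pixels, replace=False)
        feats, y = feats[sel], y[sel]
    clf = RandomForestClassifier(random_state=seed, n_jobs=1)
    clf.fit(feats, y)
    return MaskModel(clf)
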