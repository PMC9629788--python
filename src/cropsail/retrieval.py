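"""Inverse predictors: k-best look-up table, random forest, neural network.

All three map a normalized reflectance feature vector (optionally with the
two solar angles appended) to the four target traits jointly. Features are
standardized with training statistics; the LUT stores normalized features
with raw traits (the mean of k traits is taken in physical units), while RF
and the network are trained on standardized targets and predictions are
mapped back to physical units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from .datasets import (
    Normalization,
    apply_normalization,
    fit_normalization,
    invert_normalization,
)
from .errors import FitError, SchemaError

__all__ = ["PredictorSpec", "FitArtifact", "lut_cost", "lut_predict", "fit", "predict"]


@dataclass(frozen=True)
class PredictorSpec:
    """Hyperparameters of the three retrieval methods (fixed defaults).

    LUT: mean of the ``k`` lowest-cost table entries. RF: 200 trees, leaf
    size 1, floor(log2(n_features)) features per split. Network: three
    hidden layers of 256 rectified-linear units, adaptive-moment optimizer
    at learning rate 0.001, squared-error loss, up to 1000 epochs with
    early stopping (10% validation slice, patience 20).
    """

    method: str = "LUT"  # LUT | RF | FFNN
    k: int = 10
    rf_trees: int = 200
    rf_min_leaf: int = 1
    nn_hidden_layers: int = 3
    nn_units: int = 256
    nn_learning_rate: float = 0.001
    nn_max_epochs: int = 1000
    nn_validation_fraction: float = 0.1
    nn_patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("LUT", "RF", "FFNN"):
            raise FitError(f"unknown method {self.method!r}")
        if self.k < 1:
            raise FitError(f"k must be >= 1, got {self.k}")
        for name in ("rf_trees", "rf_min_leaf", "nn_hidden_layers", "nn_units",
                     "nn_max_epochs", "nn_patience"):
            if getattr(self, name) < 1:
                raise FitError(f"{name} must be positive")


@dataclass
class FitArtifact:
    """A fitted inverse mapping plus the schemas it expects."""

    spec: PredictorSpec
    feature_norm: Normalization
    target_norm: Normalization | None
    n_features: int
    n_targets: int
    lut_features: np.ndarray | None = None  # normalized, (n, m)
    lut_traits: np.ndarray | None = None    # raw physical units, (n, 4)
    model: object | None = None             # fitted sklearn estimator


def lut_cost(query: np.ndarray, record: np.ndarray) -> float:
    """RMSE cost between two feature vectors: sqrt(mean((V - V_lut)^2))."""
    q = np.asarray(query, dtype=float)
    r = np.asarray(record, dtype=float)
    if q.shape != r.shape or q.ndim != 1 or q.size == 0:
        raise SchemaError(f"feature vectors must share a 1-D shape, got {q.shape} vs {r.shape}")
    return float(np.sqrt(np.mean((q - r) ** 2)))


def _lut_costs(table: np.ndarray, query: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean((table - query[None, :]) ** 2, axis=1))


def lut_predict(artifact: FitArtifact, query: np.ndarray, k: int | None = None) -> np.ndarray:
    """Mean traits of the k lowest-cost table records (stable tie-break).

    ``query`` is a raw (unnormalized) feature vector; the cost is evaluated
    in normalized feature space. Returns the 4 traits in physical units.
    """
    if artifact.lut_features is None:
        raise FitError("artifact holds no look-up table")
    k = artifact.spec.k if k is None else k
    n = artifact.lut_features.shape[0]
    if not 1 <= k <= n:
        raise FitError(f"k={k} outside [1, table size={n}]")
    q = apply_normalization(artifact.feature_norm, np.asarray(query, float))
    if q.shape != (artifact.n_features,):
        raise SchemaError(f"query must have {artifact.n_features} features, got {q.shape}")
    costs = _lut_costs(artifact.lut_features, q)
    best = np.argsort(costs, kind="stable")[:k]
    return artifact.lut_traits[best].mean(axis=0)


def fit(spec: PredictorSpec, features: np.ndarray, traits: np.ndarray) -> FitArtifact:
    """Fit the predictor named by ``spec`` on raw features and traits.

    Features (and, for RF/FFNN, traits) are standardized internally with
    statistics kept in the artifact. Deterministic given ``spec.seed``.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(traits, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise SchemaError(f"feature/trait shapes incompatible: {x.shape} vs {y.shape}")
    if x.shape[0] < 10:
        raise FitError(f"need at least 10 training records, got {x.shape[0]}")
    if np.all(x.std(axis=0) == 0) and np.all(y.std(axis=0) == 0):
        warnings.warn("degenerate training matrix: all features and targets constant",
                      stacklevel=2)
    fnorm = fit_normalization(x)
    xn = apply_normalization(fnorm, x)
    art = FitArtifact(
        spec=spec, feature_norm=fnorm, target_norm=None,
        n_features=x.shape[1], n_targets=y.shape[1],
    )
    if spec.method == "LUT":
        art.lut_features = xn
        art.lut_traits = y.copy()
        return art

    tnorm = fit_normalization(y)
    yn = apply_normalization(tnorm, y)
    art.target_norm = tnorm
    if spec.method == "RF":
        max_feat = max(1, int(math.floor(math.log2(x.shape[1])))) if x.shape[1] > 1 else 1
        est = RandomForestRegressor(
            n_estimators=spec.rf_trees,
            min_samples_leaf=spec.rf_min_leaf,
            max_features=max_feat,
            random_state=spec.seed,
            n_jobs=1,
        )
    else:  # FFNN
        est = MLPRegressor(
            hidden_layer_sizes=(spec.nn_units,) * spec.nn_hidden_layers,
            activation="relu",
            solver="adam",
            learning_rate_init=spec.nn_learning_rate,
            max_iter=spec.nn_max_epochs,
            early_stopping=True,
            validation_fraction=spec.nn_validation_fraction,
            n_iter_no_change=spec.nn_patience,
            random_state=spec.seed,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter from early stopping
        est.fit(xn, yn)
    art.model = est
    return art


def predict(artifact: FitArtifact, queries: np.ndarray) -> np.ndarray:
    """Predict the 4 traits (physical units) for each query row."""
    q = np.atleast_2d(np.asarray(queries, dtype=float))
    if q.shape[1] != artifact.n_features:
        raise SchemaError(
            f"queries have {q.shape[1]} features, artifact expects {artifact.n_features}"
        )
    if artifact.spec.method == "LUT":
        return np.stack([lut_predict(artifact, row) for row in q])
    qn = apply_normalization(artifact.feature_norm, q)
    yn = artifact.model.predict(qn)
    yn = np.atleast_2d(yn)
    return invert_normalization(artifact.target_norm, yn)
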