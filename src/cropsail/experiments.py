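"""The simulation experiment grid and its evaluation metrics.

Sixty experiments cross two dataset variants (cdata/rdata), two angle modes
(with/without SZA and RAA as predictors), five wavelength ranges and three
retrieval methods. Each experiment builds feature vectors, splits 75/25,
fits the predictor and evaluates per-trait correlation, RMSE, relative RMSE
and the regression of prediction on observation over the held-out quarter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .datasets import TARGET_TRAITS, TraitDataset, split
from .errors import DatasetError, SchemaError
from .retrieval import PredictorSpec, fit, predict
from .rtm import WAVELENGTHS

__all__ = [
    "WavelengthRange",
    "WAVELENGTH_RANGES",
    "ExperimentConfig",
    "EvalMetrics",
    "enumerate_grid",
    "feature_matrix",
    "evaluate",
    "run_experiment",
]


@dataclass(frozen=True)
class WavelengthRange:
    """Either a [min, max] nm interval on the 1 nm grid, or the camera bands."""

    name: str
    nm_min: int | None = None
    nm_max: int | None = None
    broadband: bool = False

    @property
    def n_features(self) -> int:
        if self.broadband:
            return 5
        return self.nm_max - self.nm_min + 1


#: the five ranges: interval endpoints inclusive on both sides
WAVELENGTH_RANGES = {
    "VNSWIR": WavelengthRange("VNSWIR", 400, 2500),
    "VIS": WavelengthRange("VIS", 400, 750),
    "SWIR": WavelengthRange("SWIR", 1000, 2500),
    "VNIR": WavelengthRange("VNIR", 400, 1000),
    "mVNIR": WavelengthRange("mVNIR", broadband=True),
}

_RANGE_ORDER = ("VNSWIR", "VIS", "SWIR", "VNIR", "mVNIR")
_METHODS = ("LUT", "RF", "FFNN")


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the experiment grid."""

    dataset_variant: str  # cdata | rdata
    angle_mode: str       # wa | na
    range_name: str
    method: str
    seed: int = 0

    def __post_init__(self):
        if self.dataset_variant not in ("cdata", "rdata"):
            raise DatasetError(f"bad dataset_variant {self.dataset_variant!r}")
        if self.angle_mode not in ("wa", "na"):
            raise DatasetError(f"bad angle_mode {self.angle_mode!r}")
        if self.range_name not in WAVELENGTH_RANGES:
            raise DatasetError(f"bad range_name {self.range_name!r}")
        if self.method not in _METHODS:
            raise DatasetError(f"bad method {self.method!r}")


def enumerate_grid(seed: int = 0) -> list[ExperimentConfig]:
    """All 60 experiment configs in stable order.

    Ordering mirrors the published numbering (range within angle mode
    within variant, rdata first), extended by method as the outer loop.
    """
    configs = []
    for method in _METHODS:
        for variant in ("rdata", "cdata"):
            for angle_mode in ("wa", "na"):
                for rng in _RANGE_ORDER:
                    configs.append(
                        ExperimentConfig(variant, angle_mode, rng, method, seed)
                    )
    return configs


def feature_matrix(dataset: TraitDataset, range_name: str, angle_mode: str) -> np.ndarray:
    """Per-record feature vectors for one range/angle-mode combination.

    Narrow ranges select the inclusive 1 nm sub-grid of the stored spectra;
    the broadband range selects the 5 camera-band values. ``wa`` appends
    SZA then RAA; ``na`` appends nothing.
    """
    rng = WAVELENGTH_RANGES[range_name]
    if rng.broadband:
        x = dataset.band_matrix()
    else:
        i0 = int(rng.nm_min - WAVELENGTHS[0])
        i1 = int(rng.nm_max - WAVELENGTHS[0]) + 1
        x = dataset.spectra()[:, i0:i1]
    if angle_mode == "wa":
        angles = np.array([[r.params.SZA, r.params.RAA] for r in dataset.records])
        x = np.hstack([x, angles])
    return x


@dataclass(frozen=True)
class EvalMetrics:
    """Per-trait evaluation over a test set.

    Maps trait name -> dict with keys r, rmse, rrmse (percent of the mean
    observed value), slope, intercept (prediction regressed on
    observation); n is the test-set size.
    """

    per_trait: dict
    n: int

    def to_json(self) -> str:
        return json.dumps({"per_trait": self.per_trait, "n": self.n}, indent=2)


def evaluate(pred: np.ndarray, obs: np.ndarray,
             trait_names: Sequence[str] = TARGET_TRAITS) -> EvalMetrics:
    """Correlation, RMSE, relative RMSE and prediction-on-observation OLS."""
    p = np.atleast_2d(np.asarray(pred, float))
    o = np.atleast_2d(np.asarray(obs, float))
    if p.shape != o.shape:
        raise SchemaError(f"prediction/observation shapes differ: {p.shape} vs {o.shape}")
    n = p.shape[0]
    if n < 2:
        raise SchemaError(f"need at least 2 rows to evaluate, got {n}")
    per_trait = {}
    for j, name in enumerate(trait_names):
        x, y = o[:, j], p[:, j]
        rmse = float(np.sqrt(np.mean((y - x) ** 2)))
        mean_obs = float(np.mean(x))
        rrmse = float(100.0 * rmse / mean_obs) if mean_obs != 0 else float("nan")
        if np.std(x) == 0:
            warnings.warn(f"trait {name}: zero-variance observations, r undefined",
                          stacklevel=2)
            r = slope = intercept = float("nan")
        else:
            sx = np.std(x)
            sy = np.std(y)
            cov = float(np.mean((x - x.mean()) * (y - y.mean())))
            r = float(cov / (sx * sy)) if sy > 0 else float("nan")
            slope = float(cov / sx**2)
            intercept = float(y.mean() - slope * x.mean())
        per_trait[name] = dict(r=r, rmse=rmse, rrmse=rrmse, slope=slope, intercept=intercept)
    return EvalMetrics(per_trait=per_trait, n=n)


def run_experiment(
    config: ExperimentConfig,
    datasets: dict[str, TraitDataset],
    fraction: float = 0.75,
) -> EvalMetrics:
    """Fit and evaluate one grid cell on its dataset variant.

    ``datasets`` maps variant name to the built TraitDataset. The 75/25
    split is drawn from the config seed, so all cells sharing a seed share
    the partition of a given variant.
    """
    data = datasets[config.dataset_variant]
    x = feature_matrix(data, config.range_name, config.angle_mode)
    y = data.traits()
    train_idx, test_idx = split(len(data), fraction=fraction, seed=config.seed)
    spec = PredictorSpec(method=config.method, seed=config.seed)
    artifact = fit(spec, x[train_idx], y[train_idx])
    pred = predict(artifact, x[test_idx])
    return evaluate(pred, y[test_idx])
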