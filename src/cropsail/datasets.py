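"""Paired trait-reflectance datasets with and without biological constraints.

``cdata`` keeps each forward-model parameter row exactly as the crop
trajectories produced it, so inter-trait associations (LAI with dry matter,
water content with senescence, ...) survive into the training data.
``rdata`` destroys those associations by independently permuting each
varying parameter column across records — marginal distributions are
preserved exactly — and regenerating every spectrum from the recombined
rows. Deterministically linked columns (Car with Cab, hspot with LAI, RAA
with SZA) are permuted jointly with their parents so the recombined rows
still satisfy the coupling identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, train_test_split

from .coupling import RTMParams
from .errors import DatasetError, FitError
from .rtm import ForwardModel, default_model, resample_bands, builtin_micasense_bands

__all__ = [
    "TARGET_TRAITS",
    "SampleRecord",
    "TraitDataset",
    "build_cdata",
    "build_rdata",
    "Normalization",
    "fit_normalization",
    "apply_normalization",
    "invert_normalization",
    "split",
    "cv_folds",
]

#: the four retrieval targets, in canonical order
TARGET_TRAITS = ("LAI", "Cab", "Cm", "Cw")

#: column groups permuted jointly when breaking associations
PERMUTATION_GROUPS = (
    ("Ns",),
    ("Cw",),
    ("Cm",),
    ("Cab", "Car"),
    ("LAI", "hspot"),
    ("SZA", "RAA"),
)


@dataclass(frozen=True)
class SampleRecord:
    """One (parameters, reflectance) pair with provenance metadata."""

    params: RTMParams
    spectrum: np.ndarray  # (2101,) narrow-band reflectance
    band_reflectance: np.ndarray | None = None
    meta: Mapping | None = None


@dataclass
class TraitDataset:
    """A tagged collection of sample records (variant: cdata or rdata)."""

    records: list[SampleRecord]
    variant: str

    def __post_init__(self):
        if self.variant not in ("cdata", "rdata"):
            raise DatasetError(f"variant must be 'cdata' or 'rdata', got {self.variant!r}")

    def __len__(self) -> int:
        return len(self.records)

    def param_frame(self) -> pd.DataFrame:
        """One row per record, one column per forward-model parameter."""
        names = RTMParams.field_names()
        return pd.DataFrame(
            [[getattr(r.params, n) for n in names] for r in self.records], columns=names
        )

    def spectra(self) -> np.ndarray:
        return np.stack([r.spectrum for r in self.records])

    def band_matrix(self) -> np.ndarray:
        if any(r.band_reflectance is None for r in self.records):
            raise DatasetError("records carry no band reflectance; build with bands")
        return np.stack([r.band_reflectance for r in self.records])

    def traits(self) -> np.ndarray:
        """(n, 4) matrix of the retrieval targets LAI, Cab, Cm, Cw."""
        return np.array(
            [[getattr(r.params, t) for t in TARGET_TRAITS] for r in self.records]
        )


def build_cdata(
    params: Sequence[RTMParams],
    meta: Sequence[Mapping] | None = None,
    model: ForwardModel | None = None,
    bands=None,
) -> TraitDataset:
    """Run the forward model on coupled parameter rows (constraints intact)."""
    if len(params) == 0:
        raise DatasetError("cannot build a dataset from an empty parameter sequence")
    model = model or default_model()
    spectra = model.reflectance_batch(list(params))
    band_vals = resample_bands(spectra, bands) if bands is not None else None
    records = [
        SampleRecord(
            params=p,
            spectrum=spectra[i],
            band_reflectance=None if band_vals is None else band_vals[i],
            meta=None if meta is None else meta[i],
        )
        for i, p in enumerate(params)
    ]
    return TraitDataset(records=records, variant="cdata")


def build_rdata(
    cdata: TraitDataset,
    seed: int,
    model: ForwardModel | None = None,
    bands=None,
) -> TraitDataset:
    """Break inter-parameter associations by independent column permutation.

    Each varying column group is permuted with its own stream; fixed fields
    are untouched; spectra are regenerated from the recombined rows. The
    sorted values of every column equal cdata's exactly.
    """
    if len(cdata) == 0:
        raise DatasetError("cdata is empty")
    n = len(cdata)
    rng = np.random.default_rng(seed)
    frame = cdata.param_frame()
    for group in PERMUTATION_GROUPS:
        perm = rng.permutation(n)
        for col in group:
            frame[col] = frame[col].to_numpy()[perm]
    new_params = [
        replace(cdata.records[i].params, **{c: float(frame[c].iloc[i]) for c in frame.columns})
        for i in range(n)
    ]
    model = model or default_model()
    spectra = model.reflectance_batch(new_params)
    if bands is None and cdata.records[0].band_reflectance is not None:
        bands = builtin_micasense_bands()
    band_vals = resample_bands(spectra, bands) if bands is not None else None
    records = [
        SampleRecord(
            params=new_params[i],
            spectrum=spectra[i],
            band_reflectance=None if band_vals is None else band_vals[i],
            meta=cdata.records[i].meta,
        )
        for i in range(n)
    ]
    return TraitDataset(records=records, variant="rdata")


# ---------------------------------------------------------------------------
# normalization

@dataclass(frozen=True)
class Normalization:
    """Per-feature centering/scaling statistics fitted on training data."""

    mean: np.ndarray
    scale: np.ndarray  # std; zero-variance features get scale 1 and map to 0
    center_only: bool = False


def fit_normalization(train: np.ndarray, center_only: bool = False) -> Normalization:
    """Zero-mean normalization: center by the training mean, scale by the
    training standard deviation (unit scale for constant features)."""
    x = np.asarray(train, dtype=float)
    if x.size == 0:
        raise DatasetError("cannot fit normalization on an empty matrix")
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    # exact-constant columns: center on the constant itself so they map to
    # exactly zero (the rounded mean of n identical floats need not equal them)
    constant = x.max(axis=0) == x.min(axis=0)
    mean = np.where(constant, x[0], mean)
    scale = np.where(constant | (std == 0), 1.0, std)
    return Normalization(mean=mean, scale=scale, center_only=center_only)


def apply_normalization(stats: Normalization, x: np.ndarray) -> np.ndarray:
    if stats is None:
        raise FitError("normalization statistics have not been fitted")
    x = np.asarray(x, dtype=float)
    if stats.center_only:
        return x - stats.mean
    return (x - stats.mean) / stats.scale


def invert_normalization(stats: Normalization, z: np.ndarray) -> np.ndarray:
    if stats is None:
        raise FitError("normalization statistics have not been fitted")
    z = np.asarray(z, dtype=float)
    if stats.center_only:
        return z + stats.mean
    return z * stats.scale + stats.mean


# ---------------------------------------------------------------------------
# splitting

def split(n: int, fraction: float = 0.75, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint exhaustive train/test index split (default 75/25)."""
    if not 0.0 < fraction < 1.0:
        raise DatasetError(f"training fraction must be in (0, 1), got {fraction}")
    if n < 2:
        raise DatasetError(f"need at least 2 records to split, got {n}")
    train_idx, test_idx = train_test_split(
        np.arange(n), train_size=fraction, random_state=seed, shuffle=True
    )
    return np.sort(train_idx), np.sort(test_idx)


def cv_folds(n: int, k: int = 4, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """k-fold cross-validation index pairs (default 4-fold), seed-shuffled."""
    if k < 2:
        raise DatasetError(f"fold count must be >= 2, got {k}")
    if n < k:
        raise DatasetError(f"dataset of {n} records cannot be split into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in kf.split(np.arange(n))]
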