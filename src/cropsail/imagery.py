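"""Plot-scale multispectral imagery: masking, correction, extraction.

The pipeline mirrors a UAV plot-trial workflow: compute NDVI from the red
and NIR bands, threshold it into a vegetation/background mask (stage-
dependent thresholds, vegetation at NDVI >= threshold), substitute the
model soil reflectance into background pixels, segment the field into plot
rectangles, trim plot margins and average the background-corrected
reflectance per plot. A synthetic field renderer provides closed-loop test
scenes whose vegetation pixels carry forward-model band reflectance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coupling import RTMParams
from .errors import LayoutError, SchemaError
from .rtm import (
    ForwardModel,
    SpectralBand,
    builtin_micasense_bands,
    default_model,
    resample_bands,
    soil_spectrum,
)

__all__ = [
    "BAND_ORDER",
    "ReflectanceMap",
    "PlotDefinition",
    "ndvi_map",
    "background_mask",
    "background_correct",
    "plot_reflectance",
    "synth_field",
    "read_geotiff",
]

#: fixed band order of a reflectance map
BAND_ORDER = ("blue", "green", "red", "nir", "red_edge")


@dataclass
class ReflectanceMap:
    """rows x cols x 5 per-band reflectance in BAND_ORDER."""

    data: np.ndarray
    geotransform: tuple | None = None

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[2] != len(BAND_ORDER):
            raise SchemaError(
                f"reflectance map must be rows x cols x {len(BAND_ORDER)}, got {d.shape}"
            )
        self.data = d

    def band(self, name: str) -> np.ndarray:
        return self.data[:, :, BAND_ORDER.index(name)]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass(frozen=True)
class PlotDefinition:
    """A plot rectangle in 0-based half-open pixel coordinates, plus trim."""

    plot_id: str
    row_min: int
    row_max: int
    col_min: int
    col_max: int
    trim: int = 0

    def trimmed(self) -> tuple[int, int, int, int]:
        r0, r1 = self.row_min + self.trim, self.row_max - self.trim
        c0, c1 = self.col_min + self.trim, self.col_max - self.trim
        if r0 >= r1 or c0 >= c1:
            raise LayoutError(f"plot {self.plot_id}: empty after trimming {self.trim} px")
        return r0, r1, c0, c1


def ndvi_map(rmap: ReflectanceMap) -> np.ndarray:
    """Per-pixel (NIR - Red)/(NIR + Red); NaN where the denominator is 0."""
    nir = rmap.band("nir")
    red = rmap.band("red")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), np.nan)
    return ndvi


def background_mask(ndvi: np.ndarray, threshold: float) -> np.ndarray:
    """True = vegetation (NDVI >= threshold); missing NDVI counts as background."""
    if not -1.0 <= threshold <= 1.0:
        raise SchemaError(f"NDVI threshold must be in [-1, 1], got {threshold}")
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(np.asarray(ndvi, float), nan=-2.0) >= threshold


def background_correct(
    rmap: ReflectanceMap, mask: np.ndarray, soil_bands: np.ndarray
) -> ReflectanceMap:
    """Replace background pixels with per-band soil reflectance.

    Vegetation pixels pass through untouched; applying the correction twice
    with the same mask is a no-op the second time.
    """
    soil_bands = np.asarray(soil_bands, dtype=float)
    if soil_bands.shape != (len(BAND_ORDER),):
        raise SchemaError(
            f"soil_bands must have one value per band ({len(BAND_ORDER)}), got {soil_bands.shape}"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != rmap.shape:
        raise SchemaError(f"mask shape {mask.shape} does not match map {rmap.shape}")
    out = rmap.data.copy()
    out[~mask] = soil_bands
    return ReflectanceMap(out, rmap.geotransform)


def plot_reflectance(rmap: ReflectanceMap, plot: PlotDefinition) -> np.ndarray:
    """Per-band mean reflectance over the trimmed plot rectangle."""
    r0, r1, c0, c1 = plot.trimmed()
    rows, cols = rmap.shape
    if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
        raise LayoutError(
            f"plot {plot.plot_id} rectangle [{r0}:{r1}, {c0}:{c1}] outside map {rmap.shape}"
        )
    return rmap.data[r0:r1, c0:c1].reshape(-1, len(BAND_ORDER)).mean(axis=0)


def default_soil_bands(psoil: float = 1.0, bands: Sequence[SpectralBand] | None = None) -> np.ndarray:
    """The forward-model soil spectrum resampled to the camera bands."""
    return resample_bands(soil_spectrum(psoil), bands or builtin_micasense_bands())


def synth_field(
    plots: Sequence[PlotDefinition],
    plot_params: Sequence[RTMParams],
    shape: tuple[int, int],
    seed: int = 0,
    soil_psoil: float = 1.0,
    vegetation_fraction: float = 1.0,
    noise_sd: float = 0.0,
    model: ForwardModel | None = None,
    bands: Sequence[SpectralBand] | None = None,
):
    """Render a synthetic plot-trial scene plus its ground-truth table.

    Vegetation pixels inside each (untrimmed) plot rectangle carry the
    forward-model band reflectance of that plot's parameters; a random
    ``1 - vegetation_fraction`` share of plot pixels and all inter-plot
    gaps carry soil reflectance. Optional Gaussian noise perturbs
    vegetation pixels. Deterministic per seed.

    Returns (ReflectanceMap, ground truth list of dicts with plot_id and
    the four traits).
    """
    if len(plots) != len(plot_params):
        raise LayoutError("one parameter set per plot is required")
    bands = list(bands or builtin_micasense_bands())
    model = model or default_model()
    occupied = np.zeros(shape, dtype=bool)
    for p in plots:
        if p.row_min < 0 or p.col_min < 0 or p.row_max > shape[0] or p.col_max > shape[1]:
            raise LayoutError(f"plot {p.plot_id} outside the {shape} scene")
        cell = occupied[p.row_min:p.row_max, p.col_min:p.col_max]
        if cell.any():
            raise LayoutError(f"plot {p.plot_id} overlaps another plot")
        cell[:] = True

    rng = np.random.default_rng(seed)
    soil_bands = resample_bands(soil_spectrum(soil_psoil), bands)
    data = np.broadcast_to(soil_bands, (*shape, len(bands))).copy()
    spectra = model.reflectance_batch(list(plot_params))
    band_vals = resample_bands(spectra, bands)

    truth = []
    for p, params, bv in zip(plots, plot_params, band_vals):
        r0, r1, c0, c1 = p.row_min, p.row_max, p.col_min, p.col_max
        veg = rng.random((r1 - r0, c1 - c0)) < vegetation_fraction
        tile = np.broadcast_to(bv, (r1 - r0, c1 - c0, len(bands))).copy()
        if noise_sd > 0:
            tile = np.clip(tile + noise_sd * rng.standard_normal(tile.shape), 0.0, 1.0)
        tile[~veg] = soil_bands
        data[r0:r1, c0:c1] = tile
        truth.append(
            dict(plot_id=p.plot_id, LAI=params.LAI, Cab=params.Cab,
                 Cm=params.Cm, Cw=params.Cw)
        )
    return ReflectanceMap(data), truth


def read_geotiff(path) -> ReflectanceMap:
    """Read a 5-band GeoTIFF (band order blue, green, red, nir, red_edge)."""
    try:
        import tifffile
    except ImportError as exc:
        raise SchemaError("reading GeoTIFF requires the optional 'tifffile' package") from exc
    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim == 3 and arr.shape[0] == len(BAND_ORDER) and arr.shape[2] != len(BAND_ORDER):
        arr = np.moveaxis(arr, 0, 2)
    return ReflectanceMap(arr)
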