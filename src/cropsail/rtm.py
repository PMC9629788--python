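"""Canopy radiative transfer: forward simulation and band resampling.

The forward model maps the 14 canopy/leaf/geometry parameters to directional
canopy reflectance on the 400-2500 nm, 1 nm grid (2101 values). The module
defines a pluggable :class:`ForwardModel` interface; the shipped
implementation, :class:`PlateSailModel`, is a package-authored model with
two stages:

* **Leaf optics** — a generalized plate-stack model: a single absorbing
  plate with Fresnel interfaces and Beer-Lambert absorption from pigment,
  water and dry-matter contents (parametric specific-absorption spectra
  authored in this module), extended to a continuous number ``Ns`` of
  plates through the transfer-matrix power of the Stokes system.
* **Canopy** — a two-stream multiple-scattering solution with a
  single-scattering directional term carrying a hot-spot kernel, over a
  Lambertian soil whose brightness interpolates between a wet and a dry
  end-member via ``psoil`` (1 = dry).

The model is deterministic and smooth in its inputs, and reproduces the
qualitative spectral physics retrieval rests on (chlorophyll absorption in
the visible, the NIR plateau growing with LAI, water absorption at 970,
1200, 1450 and 1940 nm, dry-matter absorption in the SWIR). If the
canonical PROSPECT-D + 4SAIL distribution is importable, the optional
:class:`ProsailWrapper` exposes it behind the same interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coupling import RTMParams
from .errors import ForwardModelError, SchemaError

__all__ = [
    "WAVELENGTHS",
    "N_WAVELENGTHS",
    "Spectrum",
    "SpectralBand",
    "ForwardModel",
    "PlateSailModel",
    "ProsailWrapper",
    "default_model",
    "forward_reflectance",
    "forward_reflectance_batch",
    "resample_bands",
    "builtin_micasense_bands",
    "load_response_csv",
    "soil_spectrum",
]

WAVELENGTHS = np.arange(400, 2501, dtype=float)
N_WAVELENGTHS = WAVELENGTHS.size  # 2101


@dataclass(frozen=True)
class Spectrum:
    """Directional canopy reflectance on the 1 nm grid, 400-2500 nm."""

    reflectance: np.ndarray
    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS)

    def __post_init__(self):
        r = np.asarray(self.reflectance, dtype=float)
        if r.shape != (N_WAVELENGTHS,):
            raise ForwardModelError(
                f"spectrum must have {N_WAVELENGTHS} values, got shape {r.shape}"
            )
        if not np.all(np.isfinite(r)) or r.min() < 0.0 or r.max() > 1.0:
            raise ForwardModelError("reflectance values must be finite and within [0, 1]")
        object.__setattr__(self, "reflectance", r)


@dataclass(frozen=True)
class SpectralBand:
    """A broad camera band: nm limits plus per-nm response coefficients."""

    name: str
    lambda_min: int
    lambda_max: int
    response: np.ndarray | None = None  # defaults to uniform (boxcar)

    def __post_init__(self):
        if not self.lambda_min < self.lambda_max:
            raise SchemaError(
                f"band {self.name}: lambda_min must be < lambda_max "
                f"({self.lambda_min}, {self.lambda_max})"
            )
        n = self.lambda_max - self.lambda_min + 1
        resp = self.response
        if resp is None:
            resp = np.ones(n)
        resp = np.asarray(resp, dtype=float)
        if resp.shape != (n,):
            raise SchemaError(
                f"band {self.name}: response must have {n} coefficients, got {resp.shape}"
            )
        if resp.min() < 0 or resp.sum() <= 0:
            raise SchemaError(f"band {self.name}: response coefficients must be >= 0, not all zero")
        object.__setattr__(self, "response", resp)


# ---------------------------------------------------------------------------
# parametric optical-property spectra (authored for this package)

def _gauss(center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((WAVELENGTHS - center) / width) ** 2)


def _loglinear(anchors_nm, anchors_val) -> np.ndarray:
    return np.exp(np.interp(WAVELENGTHS, anchors_nm, np.log(anchors_val)))


def _build_coefficients():
    # refractive index of the leaf plate material
    n_refr = 1.34 + 0.17 * np.exp(-(WAVELENGTHS - 400.0) / 800.0)

    # specific absorption, cm2 ug-1: chlorophyll a+b (Soret + red bands)
    k_cab = (0.085 * _gauss(420, 35) + 0.055 * _gauss(470, 28)
             + 0.038 * _gauss(640, 35) + 0.082 * _gauss(675, 22))
    k_cab[WAVELENGTHS > 780] = 0.0

    # carotenoids: blue region only
    k_car = 0.045 * _gauss(425, 25) + 0.055 * _gauss(455, 20) + 0.050 * _gauss(485, 18)
    k_car[WAVELENGTHS > 560] = 0.0

    # anthocyanins: green absorption
    k_ant = 0.06 * _gauss(545, 35)
    k_ant[WAVELENGTHS > 650] = 0.0

    # brown pigments: broad decline through the visible
    k_brown = 1.2 * np.exp(-(WAVELENGTHS - 400.0) / 250.0)

    # water, per g cm-2 (i.e. per cm of water path): peaks near 970, 1200,
    # 1450, 1940, 2500 nm with magnitudes rising into the SWIR
    k_w = _loglinear(
        [400, 800, 900, 970, 1070, 1200, 1300, 1450, 1550, 1650, 1800, 1940,
         2100, 2200, 2350, 2500],
        [1e-4, 0.04, 0.15, 0.55, 0.18, 1.1, 0.9, 31.0, 8.0, 6.5, 9.0, 115.0,
         28.0, 23.0, 45.0, 85.0],
    )

    # dry matter, per g cm-2: negligible in the visible/NIR, cellulose/
    # lignin/protein features through the SWIR
    k_m = _loglinear(
        [400, 800, 1100, 1400, 1700, 1730, 1900, 2050, 2120, 2250, 2320, 2500],
        [1.5, 1.5, 3.0, 9.0, 26.0, 33.0, 40.0, 55.0, 68.0, 58.0, 85.0, 100.0],
    )

    # soil end-members: bright dry soil rising with wavelength, darker wet
    # soil with deeper water dips
    base = 0.08 + 0.30 * (1.0 - np.exp(-(WAVELENGTHS - 400.0) / 900.0))
    dips = 0.05 * _gauss(1450, 70) + 0.08 * _gauss(1940, 90) + 0.03 * _gauss(2200, 120)
    dry = np.clip(base - 0.4 * dips, 0.02, 1.0)
    wet = np.clip(0.5 * base - 1.2 * dips, 0.02, 1.0)
    return n_refr, k_cab, k_car, k_ant, k_brown, k_w, k_m, dry, wet


(_N_REFR, _K_CAB, _K_CAR, _K_ANT, _K_BROWN, _K_W, _K_M, _SOIL_DRY, _SOIL_WET) = (
    _build_coefficients()
)


def soil_spectrum(psoil: float = 1.0) -> np.ndarray:
    """Soil reflectance: psoil interpolates wet (0) to dry (1) end-members."""
    if not 0.0 <= psoil <= 1.0:
        raise ForwardModelError(f"psoil must be in [0, 1], got {psoil}")
    return psoil * _SOIL_DRY + (1.0 - psoil) * _SOIL_WET


# ---------------------------------------------------------------------------
# leaf plate-stack model

def _single_plate(theta: np.ndarray, n_refr: np.ndarray):
    """Reflectance/transmittance of one absorbing plate under diffuse light.

    The external surface reflectance is a diffuse-incidence scaling of the
    normal Fresnel coefficient; the internal interface reflectance is much
    larger because diffuse light inside the plate beyond the critical angle
    is totally internally reflected: ``r_int = 1 - (1 - r_ext) / n^2``.
    This internal trapping is what gives leaves their strong near-infrared
    scattering.
    """
    r_ext = 2.5 * ((n_refr - 1.0) / (n_refr + 1.0)) ** 2
    r_int = 1.0 - (1.0 - r_ext) / n_refr**2
    denom = 1.0 - r_int**2 * theta**2
    R1 = r_ext + (1.0 - r_ext) * (1.0 - r_int) * r_int * theta**2 / denom
    T1 = (1.0 - r_ext) * (1.0 - r_int) * theta / denom
    return R1, T1


def _plate_stack(R1: np.ndarray, T1: np.ndarray, n_plates: float):
    """Continuous-``N`` plate stack via the unit-determinant transfer matrix.

    The flux transfer matrix of one symmetric layer has det 1, so the
    ``N``-th power follows the Chebyshev identity
    ``M^N = (sinh(N phi)/sinh(phi)) M - (sinh((N-1) phi)/sinh(phi)) I``
    with ``cosh(phi) = tr(M)/2``, valid for real ``N >= 1``.
    """
    T1 = np.clip(T1, 1e-12, None)
    half_tr = (T1**2 - R1**2 + 1.0) / (2.0 * T1)
    half_tr = np.clip(half_tr, 1.0 + 1e-12, None)
    phi = np.arccosh(half_tr)
    sinh_phi = np.sinh(phi)
    u_n = np.sinh(n_plates * phi) / sinh_phi        # U_{N-1}(cosh phi)
    u_nm1 = np.sinh((n_plates - 1.0) * phi) / sinh_phi
    # M = (1/T)[[T^2-R^2, R], [-R, 1]]; M^N = u_n*M - u_nm1*I
    m01 = u_n * (R1 / T1)
    m11 = u_n * (1.0 / T1) - u_nm1
    TN = 1.0 / m11
    RN = m01 / m11
    return np.clip(RN, 0.0, 1.0), np.clip(TN, 0.0, 1.0)


def _leaf_optics(p: RTMParams):
    kappa = (
        p.Cab * _K_CAB + p.Car * _K_CAR + p.Cant * _K_ANT + p.Cbrown * _K_BROWN
        + p.Cw * _K_W + p.Cm * _K_M
    ) / max(p.Ns, 1e-6)
    theta = np.exp(-np.clip(kappa, 0.0, 25.0))
    R1, T1 = _single_plate(theta, _N_REFR)
    return _plate_stack(R1, T1, max(p.Ns, 1.0))


# ---------------------------------------------------------------------------
# canopy model

def _g_function(theta_deg: float, leaf_angle_deg: float) -> float:
    """Ross G-function for a fixed leaf inclination with random azimuth."""
    theta = math.radians(theta_deg)
    tl = math.radians(leaf_angle_deg)
    ct, ctl = math.cos(theta), math.cos(tl)
    st, stl = math.sin(theta), math.sin(tl)
    if st * stl < 1e-12 or abs(ct * ctl) >= st * stl:
        return abs(ct * ctl)
    # sun grazes the leaf plane: part of the leaf is lit from behind
    psi = math.acos(max(-1.0, min(1.0, (ct / st) * (ctl / stl))))
    return ct * ctl * (1.0 + (2.0 / math.pi) * (math.tan(psi) - psi))


_GAUSS_NODES, _GAUSS_WEIGHTS = np.polynomial.legendre.leggauss(32)


def _hotspot_gap_integral(ks: float, ko: float, lai: float, hspot: float,
                          sza_deg: float) -> tuple[float, float]:
    """(integral of the bidirectional gap probability over depth, gap at bottom).

    ``P_so(l) = exp(-(ks+ko) l + sqrt(ks ko) (1-exp(-a l))/a)`` with decay
    rate ``a = tan(SZA)/(hspot LAI)``: the sun and nadir-view rays decorrelate
    with their horizontal separation, scaled by the hot-spot parameter.
    """
    if lai <= 0:
        return 0.0, 1.0
    a = math.tan(math.radians(sza_deg)) / max(hspot * lai, 1e-9)
    root = math.sqrt(ks * ko)

    def log_p(l):
        if a < 1e-9:
            corr = root * l
        else:
            corr = root * (1.0 - np.exp(-a * l)) / a
        return -(ks + ko) * l + corr

    x = 0.5 * lai * (_GAUSS_NODES + 1.0)
    w = 0.5 * lai * _GAUSS_WEIGHTS
    integral = float(np.sum(w * np.exp(log_p(x))))
    return integral, float(math.exp(log_p(lai)))


def _check_params(p: RTMParams) -> None:
    for name in ("Cab", "Car", "Cant", "Cbrown", "Cw", "Cm", "LAI", "hspot"):
        if getattr(p, name) < 0:
            raise ForwardModelError(f"parameter {name} must be >= 0, got {getattr(p, name)}")
    if p.Ns <= 0:
        raise ForwardModelError(f"parameter Ns must be > 0, got {p.Ns}")
    if not 0.0 <= p.SZA < 90.0:
        raise ForwardModelError(f"parameter SZA must be in [0, 90), got {p.SZA}")
    if p.VZA != 0.0:
        raise ForwardModelError("this forward model supports nadir viewing only (VZA = 0)")
    if not 0.0 < p.ALA < 90.0:
        raise ForwardModelError(f"parameter ALA must be in (0, 90), got {p.ALA}")


class ForwardModel:
    """Interface: parameters -> directional canopy reflectance spectrum."""

    def reflectance(self, params: RTMParams) -> Spectrum:
        raise NotImplementedError

    def reflectance_batch(self, params: Sequence[RTMParams]) -> np.ndarray:
        """(n, 2101) array of reflectances; default loops over records."""
        return np.stack([self.reflectance(p).reflectance for p in params])

    def soil(self, psoil: float = 1.0) -> np.ndarray:
        return soil_spectrum(psoil)


class PlateSailModel(ForwardModel):
    """Plate-stack leaf optics + two-stream canopy with hot-spot term.

    The nadir reflectance factor is composed of (i) single scattering from
    sunlit foliage with the hot-spot gap correlation, (ii) directly viewed
    sunlit soil, and (iii) the multiple-scattering residue of an analytic
    two-stream solution (its own first-order part removed to avoid double
    counting), treated as isotropic.
    """

    def reflectance(self, params: RTMParams) -> Spectrum:
        return Spectrum(self._brf(params))

    def reflectance_batch(self, params: Sequence[RTMParams]) -> np.ndarray:
        out = np.empty((len(params), N_WAVELENGTHS))
        for i, p in enumerate(params):
            out[i] = self._brf(p)
        return out

    def _brf(self, p: RTMParams) -> np.ndarray:
        _check_params(p)
        rs = soil_spectrum(p.psoil)
        if p.LAI == 0.0:
            return rs.copy()
        rho_l, tau_l = _leaf_optics(p)
        mu_s = math.cos(math.radians(p.SZA))
        g_s = _g_function(p.SZA, p.ALA)
        g_o = _g_function(0.0, p.ALA)
        ks = g_s / mu_s          # direct-beam extinction per unit LAI
        ko = g_o                 # nadir-view extinction per unit LAI

        omega = rho_l + tau_l
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(omega > 0, (rho_l - tau_l) / np.clip(omega, 1e-12, None), 0.0)
        beta0 = np.clip(0.5 + 0.25 * frac, 0.0, 1.0)   # beam upscatter fraction
        cos2 = math.cos(math.radians(p.ALA)) ** 2
        beta_d = np.clip(0.5 + 0.5 * cos2 * frac, 0.0, 1.0)  # diffuse upscatter

        # --- single scattering with hot spot
        gap_int, gap_bottom = _hotspot_gap_integral(ks, ko, p.LAI, p.hspot, p.SZA)
        rho_ss = omega * beta0 * ks * gap_int
        rho_soil_direct = rs * gap_bottom

        # --- two-stream diffuse field under collimated illumination
        sigma_d = 2.0 * 0.5 * (g_o + _g_function(60.0, p.ALA))  # diffuse extinction
        gamma1 = sigma_d * (1.0 - omega * (1.0 - beta_d))
        gamma2 = sigma_d * omega * beta_d
        lam = np.sqrt(np.clip(gamma1**2 - gamma2**2, 1e-12, None))
        K = ks
        # avoid the K == lambda resonance of the particular solution
        K = np.where(np.abs(lam - K) < 1e-6, K * (1.0 + 1e-5), K)

        s_down = K * omega * (1.0 - beta0)
        s_up = K * omega * beta0
        det = (gamma1 - K) * (gamma1 + K) - gamma2**2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        c_down = (-s_down * (gamma1 + K) + gamma2 * s_up) / det
        c_up = (s_up * (gamma1 - K) - gamma2 * s_down) / det

        r_minus = (gamma1 - lam) / np.clip(gamma2, 1e-12, None)
        r_plus = (gamma1 + lam) / np.clip(gamma2, 1e-12, None)
        L = p.LAI
        e_m = np.exp(-lam * L)
        e_p = np.exp(np.clip(lam * L, None, 50.0))
        e_k = np.exp(-K * L)

        # unknowns A, B from E_down(0) = 0 and the soil boundary condition
        # A + B = -c_down
        # A (r- - rs) e_m + B (r+ - rs) e_p = (rs (c_down + 1) - c_up) e_k
        a11, a12 = 1.0, np.ones_like(lam)
        a21 = (r_minus - rs) * e_m
        a22 = (r_plus - rs) * e_p
        b1 = -c_down
        b2 = (rs * (c_down + 1.0) - c_up) * e_k
        den = a11 * a22 - a12 * a21
        den = np.where(np.abs(den) < 1e-300, 1e-300, den)
        A = (b1 * a22 - a12 * b2) / den
        B = (a11 * b2 - a21 * b1) / den
        e_up_top = A * r_minus + B * r_plus + c_up

        # first-order parts already counted directionally
        first_veg = s_up * (1.0 - np.exp(-(K + gamma1) * L)) / (K + gamma1)
        first_soil = rs * np.exp(-(K + gamma1) * L)
        multiple = np.clip(e_up_top - first_veg - first_soil, 0.0, None)

        brf = rho_ss + rho_soil_direct + multiple
        return np.clip(brf, 0.0, 1.0)


class ProsailWrapper(ForwardModel):
    """Optional wrapper around the canonical PROSPECT-D + 4SAIL package."""

    def __init__(self):
        try:
            import prosail  # noqa: F401
        except ImportError as exc:
            raise ForwardModelError(
                "the 'prosail' package is not installed; use PlateSailModel"
            ) from exc
        self._prosail = __import__("prosail")

    def reflectance(self, params: RTMParams) -> Spectrum:
        _check_params(params)
        r = self._prosail.run_prosail(
            n=params.Ns, cab=params.Cab, car=params.Car, cbrown=params.Cbrown,
            cw=params.Cw, cm=params.Cm, ant=params.Cant, lai=params.LAI,
            lidfa=params.ALA, hspot=params.hspot, tts=params.SZA,
            tto=params.VZA, psi=params.RAA, psoil=params.psoil,
            prospect_version="D", typelidf=2,
        )
        return Spectrum(np.clip(np.asarray(r, dtype=float), 0.0, 1.0))


_DEFAULT_MODEL: ForwardModel | None = None


def default_model() -> ForwardModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = PlateSailModel()
    return _DEFAULT_MODEL


def forward_reflectance(params: RTMParams, model: ForwardModel | None = None) -> Spectrum:
    """Directional canopy reflectance for one parameter set."""
    return (model or default_model()).reflectance(params)


def forward_reflectance_batch(
    params: Sequence[RTMParams], model: ForwardModel | None = None
) -> np.ndarray:
    """(n, 2101) reflectance array for a sequence of parameter sets."""
    return (model or default_model()).reflectance_batch(params)


# ---------------------------------------------------------------------------
# band resampling

def resample_bands(spectrum: Spectrum | np.ndarray, bands: Sequence[SpectralBand]) -> np.ndarray:
    """Response-weighted mean reflectance per band, in input band order.

    ``rho_i = sum_j phi_ij rho_j / sum_j phi_ij`` over the band's nm range.
    Accepts a single Spectrum/1-D array or an (n, 2101) batch.
    """
    refl = spectrum.reflectance if isinstance(spectrum, Spectrum) else np.asarray(spectrum, float)
    single = refl.ndim == 1
    refl2 = refl[None, :] if single else refl
    if refl2.shape[1] != N_WAVELENGTHS:
        raise SchemaError(f"spectrum must be on the {N_WAVELENGTHS}-point grid")
    out = np.empty((refl2.shape[0], len(bands)))
    for j, band in enumerate(bands):
        if band.lambda_min < WAVELENGTHS[0] or band.lambda_max > WAVELENGTHS[-1]:
            raise SchemaError(
                f"band {band.name} ({band.lambda_min}-{band.lambda_max} nm) "
                "outside the spectrum grid"
            )
        i0 = int(band.lambda_min - WAVELENGTHS[0])
        i1 = int(band.lambda_max - WAVELENGTHS[0]) + 1
        phi = band.response
        out[:, j] = refl2[:, i0:i1] @ phi / phi.sum()
    return out[0] if single else out


#: MicaSense RedEdge band limits (nm); default responses are uniform
MICASENSE_LIMITS = {
    "blue": (465, 485),
    "green": (550, 570),
    "red": (663, 673),
    "nir": (820, 860),
    "red_edge": (712, 722),
}


def builtin_micasense_bands() -> list[SpectralBand]:
    """The five camera bands (blue, green, red, nir, red_edge), boxcar responses."""
    return [SpectralBand(name, lo, hi) for name, (lo, hi) in MICASENSE_LIMITS.items()]


def load_response_csv(path) -> list[SpectralBand]:
    """Read bands from a CSV with columns ``band, wavelength_nm, response``."""
    df = pd.read_csv(path)
    required = {"band", "wavelength_nm", "response"}
    if not required.issubset(df.columns):
        raise SchemaError(f"response CSV must have columns {sorted(required)}")
    bands = []
    for name, grp in df.groupby("band", sort=False):
        grp = grp.sort_values("wavelength_nm")
        wl = grp["wavelength_nm"].to_numpy(dtype=int)
        if not np.array_equal(wl, np.arange(wl[0], wl[-1] + 1)):
            raise SchemaError(f"band {name}: wavelengths must be a contiguous 1 nm grid")
        bands.append(
            SpectralBand(str(name), int(wl[0]), int(wl[-1]), grp["response"].to_numpy(float))
        )
    return bands
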