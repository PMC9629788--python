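"""Sun-target-sensor geometry from latitude, day of year and apparent solar time.

All interface angles are in degrees; trigonometry runs in radians internally.
The view is assumed nadir (viewing zenith angle 0), so the viewing azimuth is 0
and the relative azimuth equals the solar azimuth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import GeometryDomainError, NightTimeError, UndefinedAzimuthError

__all__ = [
    "ObservationGeometry",
    "solar_declination",
    "hour_angle",
    "solar_zenith",
    "relative_azimuth",
    "observation_geometry",
]

_D2R = math.pi / 180.0
_R2D = 180.0 / math.pi


def solar_declination(doy: int) -> float:
    """Solar declination (degrees) for a day of year.

    Uses the 365-day sinusoidal approximation
    ``delta = 23.45 * sin(360/365 * (284 + DOY))`` with the argument in
    degrees. Day 366 of leap years is mapped to 365.
    """
    if doy == 366:
        doy = 365
    if not 1 <= doy <= 365:
        raise GeometryDomainError(f"day of year must be in 1..365, got {doy}")
    return 23.45 * math.sin(_D2R * (360.0 / 365.0) * (284.0 + doy))


def hour_angle(ast: float) -> float:
    """Hour angle (degrees) from apparent solar time in decimal hours.

    ``h = 15 * (AST - 12)``: zero at solar noon, negative in the morning.
    """
    if not 0.0 <= ast <= 24.0:
        raise GeometryDomainError(f"apparent solar time must be in 0..24 h, got {ast}")
    return 15.0 * (ast - 12.0)


def solar_zenith(latitude: float, declination: float, hour_angle_deg: float) -> float:
    """Solar zenith angle (degrees) from latitude, declination and hour angle.

    ``cos(SZA) = sin(L) sin(delta) + cos(L) cos(delta) cos(h)``. Raises
    :class:`NightTimeError` when the sun is at or below the horizon
    (``cos(SZA) <= 0``).
    """
    if abs(latitude) > 90.0:
        raise GeometryDomainError(f"latitude must be in [-90, 90], got {latitude}")
    lat = latitude * _D2R
    dec = declination * _D2R
    h = hour_angle_deg * _D2R
    cos_sza = math.sin(lat) * math.sin(dec) + math.cos(lat) * math.cos(dec) * math.cos(h)
    if cos_sza <= 1e-12:  # at (or numerically at) the horizon
        raise NightTimeError(
            "sun at or below the horizon for "
            f"latitude={latitude}, declination={declination}, hour_angle={hour_angle_deg}"
        )
    cos_sza = min(cos_sza, 1.0)
    return math.acos(cos_sza) * _R2D


def relative_azimuth(declination: float, hour_angle_deg: float, sza: float) -> float:
    """Relative azimuth angle (degrees) under a nadir view.

    The solar azimuth follows ``sin(SAA) = cos(delta) sin(h) / sin(SZA)``
    (principal arcsine branch, sign carried by the hour angle); with a nadir
    view the viewing azimuth is 0 and ``RAA = SAA``. Solar noon (h = 0) maps
    to RAA = 0. Inputs where ``|cos(delta) sin(h)| > sin(SZA)`` are outside
    the identity's domain and raise :class:`GeometryDomainError`.
    """
    if hour_angle_deg == 0.0:
        return 0.0
    if sza == 0.0:
        raise UndefinedAzimuthError(
            f"solar azimuth undefined at zenith with hour_angle={hour_angle_deg}"
        )
    s = math.cos(declination * _D2R) * math.sin(hour_angle_deg * _D2R)
    sin_sza = math.sin(sza * _D2R)
    ratio = s / sin_sza
    if abs(ratio) > 1.0 + 1e-12:
        raise GeometryDomainError(
            f"|cos(declination)*sin(h)| = {abs(s):.6f} exceeds sin(SZA) = {sin_sza:.6f}; "
            "azimuth identity undefined for these inputs"
        )
    ratio = max(-1.0, min(1.0, ratio))
    return math.asin(ratio) * _R2D


@dataclass(frozen=True)
class ObservationGeometry:
    """All angles describing one nadir observation, in degrees."""

    latitude: float
    doy: int
    ast: float
    declination: float
    hour_angle: float
    SZA: float
    SAA: float
    VAA: float = 0.0
    VZA: float = 0.0

    @property
    def RAA(self) -> float:
        """Relative azimuth = solar azimuth - viewing azimuth (nadir: VAA=0)."""
        return self.SAA - self.VAA


def observation_geometry(latitude: float, doy: int, ast: float) -> ObservationGeometry:
    """Compute the full nadir observation geometry for one site/day/time."""
    dec = solar_declination(doy)
    h = hour_angle(ast)
    sza = solar_zenith(latitude, dec, h)
    saa = relative_azimuth(dec, h, sza)
    return ObservationGeometry(
        latitude=latitude, doy=doy, ast=ast,
        declination=dec, hour_angle=h, SZA=sza, SAA=saa,
    )
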