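"""Annual light-regime site factors from a sky grid.

Site factors express below-canopy light as a fraction of open-sky
light, averaged over one year:

* **ISF** (Indirect Site Factor) — transmittance of diffuse radiation
  under the Standard Overcast Sky (SOC) radiance distribution,
  L(theta)/L_zenith = (1 + 2 cos theta) / 3, received on a horizontal
  sensor (cosine-weighted).
* **DSF** (Direct Site Factor) — transmittance of the direct beam,
  obtained by overlaying the sun's annual track on the gap map and
  weighting each sun position by its relative beam irradiance on a
  horizontal surface.
* **GSF** (Global Site Factor) — the combination
  GSF = 0.65 ISF + 0.35 DSF, the diffuse/direct split recommended for
  UK conditions; the weights are configurable for other climates.

The solar geometry uses solar time and the usual declination / hour
angle relations; site factors are annual *ratios*, so constant
calibration factors of the irradiance model cancel out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gaps import SkyGrid, apply_fov_mask, canopy_openness, grid_gap_fraction
from .geometry import Direction, HemisphereRaster

__all__ = [
    "SunSample",
    "SiteEstimates",
    "GSF_DIFFUSE_WEIGHT",
    "GSF_DIRECT_WEIGHT",
    "soc_relative_radiance",
    "indirect_site_factor",
    "solar_declination",
    "solar_position",
    "build_sun_track",
    "direct_site_factor",
    "global_site_factor",
    "analyze_hemisphere",
]

GSF_DIFFUSE_WEIGHT = 0.65
GSF_DIRECT_WEIGHT = 0.35


@dataclass(frozen=True)
class SunSample:
    """One above-horizon sun position with its direct-beam weight."""

    day_of_year: int
    solar_time: float
    direction: Direction
    weight: float

    def __post_init__(self) -> None:
        if not self.direction.zenith < 90.0:
            raise ValueError("sun sample must be above the horizon")
        if not self.weight > 0.0:
            raise ValueError("sun sample weight must be positive")


@dataclass
class SiteEstimates:
    """Scalar canopy / light descriptors of one sample point."""

    CO: float | None = None
    TG: float | None = None
    ISF: float | None = None
    DSF: float | None = None
    GSF: float | None = None
    CO150: float | None = None
    ISF150: float | None = None
    DSF150: float | None = None
    GSF150: float | None = None
    provenance: str = "circular"

    def __post_init__(self) -> None:
        for name in ("CO", "TG", "ISF", "DSF", "GSF", "CO150", "ISF150", "DSF150", "GSF150"):
            v = getattr(self, name)
            if v is not None and not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 1]")


def soc_relative_radiance(zenith) -> np.ndarray | float:
    """Standard Overcast Sky radiance relative to the zenith.

    L(theta) / L_zenith = (1 + 2 cos theta) / 3: the overcast zenith is
    three times as bright as the horizon.
    """
    z = np.asarray(zenith, dtype=np.float64)
    if np.any(z < 0.0) or np.any(z > 90.0):
        raise ValueError("zenith must lie in [0, 90]")
    out = (1.0 + 2.0 * np.cos(np.radians(z))) / 3.0
    return float(out) if out.ndim == 0 else out


def _diffuse_cell_flux(grid: SkyGrid) -> np.ndarray:
    """Relative diffuse flux on a horizontal sensor from each cell."""
    mid = 0.5 * (grid.zenith_edges[:-1] + grid.zenith_edges[1:])
    lum = soc_relative_radiance(mid) * np.cos(np.radians(mid)) * grid.weights
    return np.repeat(lum[:, None] / grid.n_azimuth, grid.n_azimuth, axis=1)


def indirect_site_factor(grid: SkyGrid) -> float:
    """Diffuse (SOC) transmittance of the gap map; 1 for open sky."""
    flux = _diffuse_cell_flux(grid)
    return float(np.sum(grid.gap_fraction * flux) / np.sum(flux))


def solar_declination(day_of_year: int) -> float:
    """Solar declination (degrees) for a day of a 365-day year."""
    n = int(day_of_year)
    if not 1 <= n <= 365:
        raise ValueError("day_of_year must be in 1..365")
    return 23.45 * math.sin(math.radians(360.0 * (284 + n) / 365.0))


def solar_position(latitude: float, day_of_year: int, solar_time: float):
    """Sun direction at a site and solar time.

    Returns a :class:`Direction` (zenith, azimuth with 0 = North,
    clockwise), or ``None`` when the sun is at or below the horizon.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude must lie in [-90, 90]")
    phi = math.radians(latitude)
    delta = math.radians(solar_declination(day_of_year))
    H = math.radians(15.0 * (solar_time - 12.0))
    cos_z = math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.cos(H)
    if cos_z <= 0.0:
        return None
    zenith = math.degrees(math.acos(min(1.0, cos_z)))
    east = -math.cos(delta) * math.sin(H)
    north = math.cos(phi) * math.sin(delta) - math.sin(phi) * math.cos(delta) * math.cos(H)
    azimuth = math.degrees(math.atan2(east, north)) % 360.0
    return Direction(zenith, azimuth)


def _eccentricity_factor(day_of_year) -> np.ndarray:
    n = np.asarray(day_of_year, dtype=np.float64)
    return 1.0 + 0.033 * np.cos(np.radians(360.0 * n / 365.0))


def build_sun_track(
    latitude: float,
    day_step: int = 1,
    time_step: float = 4.0,
    atmospheric_transmittance: float = 0.6,
) -> list[SunSample]:
    """Sample the sun's annual track above the horizon.

    Days 1..365 every ``day_step`` days, solar times across the day
    every ``time_step`` minutes.  Each above-horizon sample carries the
    relative direct-beam irradiance on a horizontal surface,

        weight = E0(n) * cos(zenith) * tau ** (1 / cos(zenith)),

    with E0 the Sun-Earth eccentricity factor and ``tau`` the clear-sky
    atmospheric transmittance along one air mass.
    """
    if day_step <= 0 or time_step <= 0:
        raise ValueError("steps must be positive")
    tau = atmospheric_transmittance
    if not 0.0 < tau <= 1.0:
        raise ValueError("atmospheric_transmittance must be in (0, 1]")
    samples: list[SunSample] = []
    times = np.arange(0.0, 24.0, time_step / 60.0)
    for n in range(1, 366, day_step):
        e0 = float(_eccentricity_factor(n))
        for t in times:
            d = solar_position(latitude, n, float(t))
            if d is None or d.zenith >= 90.0:
                continue
            cz = math.cos(math.radians(d.zenith))
            w = e0 * cz * tau ** (1.0 / cz)
            if w > 0.0:
                samples.append(SunSample(n, float(t), d, w))
    if not samples:
        raise ValueError("sun never rises at this latitude with these steps")
    return samples


def direct_site_factor(grid: SkyGrid, track: list[SunSample]) -> float:
    """Beam-weighted mean gap fraction along the annual sun track."""
    if not track:
        raise ValueError("empty sun track")
    zen = np.array([s.direction.zenith for s in track])
    az = np.array([s.direction.azimuth for s in track])
    w = np.array([s.weight for s in track])
    iz, ia = grid.cell_index(zen, az)
    gf = grid.gap_fraction[iz, ia]
    return float(np.sum(gf * w) / np.sum(w))


def global_site_factor(
    isf: float,
    dsf: float,
    diffuse_weight: float = GSF_DIFFUSE_WEIGHT,
    direct_weight: float = GSF_DIRECT_WEIGHT,
) -> float:
    """GSF = 0.65 ISF + 0.35 DSF (UK diffuse/direct split by default)."""
    for v in (isf, dsf):
        if not -1e-9 <= v <= 1 + 1e-9:
            raise ValueError("site factors must lie in [0, 1]")
    return diffuse_weight * isf + direct_weight * dsf


def analyze_hemisphere(
    h: HemisphereRaster,
    latitude: float,
    fov150: bool = False,
    track: list[SunSample] | None = None,
    provenance: str = "circular",
    day_step: int = 1,
    time_step: float = 4.0,
) -> SiteEstimates:
    """Full pipeline from a segmented hemisphere to site estimates.

    Bins the raster onto the 24 x 18 sky grid and computes CO, ISF,
    DSF and GSF; with ``fov150`` the FOV-150 variants (zenith 75-90
    treated as obstructed) are added.  A precomputed sun ``track`` can
    be passed to amortise the solar geometry across many images.
    """
    grid = grid_gap_fraction(h)
    if track is None:
        track = build_sun_track(latitude, day_step=day_step, time_step=time_step)
    est = SiteEstimates(provenance=provenance)
    est.CO = canopy_openness(grid)
    est.ISF = indirect_site_factor(grid)
    est.DSF = direct_site_factor(grid, track)
    est.GSF = global_site_factor(est.ISF, est.DSF)
    if fov150:
        g150 = apply_fov_mask(grid, 75.0)
        est.CO150 = canopy_openness(g150)
        est.ISF150 = indirect_site_factor(g150)
        est.DSF150 = direct_site_factor(g150, track)
        est.GSF150 = global_site_factor(est.ISF150, est.DSF150)
    return est
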