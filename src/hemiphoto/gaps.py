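"""Gap-fraction extraction on the sky grid, Total Gap and Canopy Openness.

The segmented hemisphere is summarised on a polar grid of 24 azimuth
sectors (15 deg) by 18 zenith annuli (5 deg).  Each cell's *gap
fraction* is the share of its pixels classified as sky; pixels inside
the hemisphere circle but not covered by any camera count as
obstructed, which is exactly how a merged smartphone pseudo-hemisphere
treats its unobserved corners and its 75-90 deg horizon band.

Two scalar descriptors follow:

* ``TG`` (Total Gap) — raw sky-pixel fraction of a rectangular frame,
  no projection weighting;
* ``CO`` (Canopy Openness) — the unobstructed fraction of hemisphere
  *surface area*: cell gap fractions weighted by their solid angle,
  with the annulus weight w_i = cos(theta_lower) - cos(theta_upper).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import HemisphereRaster, _pixel_center_grid, pixel_to_direction
from .segmentation import SegmentationResult

__all__ = [
    "SkyGrid",
    "annulus_weights",
    "grid_gap_fraction",
    "total_gap",
    "average_total_gap",
    "canopy_openness",
    "apply_fov_mask",
    "grid_to_csv",
    "grid_from_csv",
]


def annulus_weights(n_zenith: int = 18, max_zenith: float = 90.0) -> np.ndarray:
    """Hemisphere-surface-area fraction of each equal-angle annulus."""
    edges = np.radians(np.linspace(0.0, max_zenith, n_zenith + 1))
    return np.cos(edges[:-1]) - np.cos(edges[1:])


@dataclass
class SkyGrid:
    """Per-cell gap fractions on the azimuth x zenith sky grid.

    ``gap_fraction`` and ``pixel_count`` have shape
    (n_zenith, n_azimuth): rows are annuli from the zenith outwards,
    columns are sectors clockwise from North.  ``weights`` holds the
    per-annulus hemisphere-area fractions; each sector of annulus i
    carries weight ``weights[i] / n_azimuth``.
    """

    gap_fraction: np.ndarray
    pixel_count: np.ndarray
    n_azimuth: int = 24
    n_zenith: int = 18

    def __post_init__(self) -> None:
        self.gap_fraction = np.asarray(self.gap_fraction, dtype=np.float64)
        self.pixel_count = np.asarray(self.pixel_count, dtype=np.float64)
        shape = (self.n_zenith, self.n_azimuth)
        if self.gap_fraction.shape != shape or self.pixel_count.shape != shape:
            raise ValueError(f"grid arrays must have shape {shape}")
        if np.any(self.gap_fraction < -1e-12) or np.any(self.gap_fraction > 1 + 1e-12):
            raise ValueError("gap fractions must lie in [0, 1]")

    @property
    def zenith_edges(self) -> np.ndarray:
        return np.linspace(0.0, 90.0, self.n_zenith + 1)

    @property
    def azimuth_edges(self) -> np.ndarray:
        return np.linspace(0.0, 360.0, self.n_azimuth + 1)

    @property
    def weights(self) -> np.ndarray:
        return annulus_weights(self.n_zenith)

    @property
    def cell_weights(self) -> np.ndarray:
        """Solid-angle weight of every cell; sums to 1 over the grid."""
        return np.repeat(
            self.weights[:, None] / self.n_azimuth, self.n_azimuth, axis=1
        )

    def cell_index(self, zenith, azimuth):
        """Grid indices of directions; edge values go to the lower bin."""
        zen = np.asarray(zenith, dtype=np.float64)
        az = np.asarray(azimuth, dtype=np.float64) % 360.0
        zstep = 90.0 / self.n_zenith
        astep = 360.0 / self.n_azimuth
        iz = np.ceil(zen / zstep).astype(np.int64) - 1
        ia = np.ceil(az / astep).astype(np.int64) - 1
        iz = np.clip(iz, 0, self.n_zenith - 1)
        ia = np.clip(ia, 0, self.n_azimuth - 1)
        return iz, ia


def grid_gap_fraction(
    h: HemisphereRaster, n_azimuth: int = 24, n_zenith: int = 18
) -> SkyGrid:
    """Bin a segmented hemisphere into per-cell gap fractions.

    Every pixel whose centre maps inside the projection's field
    contributes to the cell containing its direction; sky pixels to the
    numerator, all pixels (covered or not) to the denominator, so
    uncovered area depresses the gap fraction (counts as obstructed).
    """
    rows, cols = _pixel_center_grid(h.sky_mask.shape)
    zen, az = pixel_to_direction((rows, cols), h.projection)
    infield = np.isfinite(zen)
    if not infield.any():
        raise ValueError("no pixel maps inside the hemisphere field")

    grid = SkyGrid(
        np.zeros((n_zenith, n_azimuth)),
        np.zeros((n_zenith, n_azimuth)),
        n_azimuth,
        n_zenith,
    )
    iz, ia = grid.cell_index(zen[infield], az[infield])
    flat = iz * n_azimuth + ia
    ncell = n_zenith * n_azimuth
    total = np.bincount(flat, minlength=ncell).astype(np.float64)
    sky = np.bincount(
        flat, weights=h.sky_mask[infield].astype(np.float64), minlength=ncell
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        gf = np.where(total > 0, sky / total, 0.0)
    grid.gap_fraction = gf.reshape(n_zenith, n_azimuth)
    grid.pixel_count = total.reshape(n_zenith, n_azimuth)
    return grid


def total_gap(seg: SegmentationResult | np.ndarray) -> float:
    """Total Gap: sky pixels / all pixels of a rectangular frame."""
    mask = seg.sky_mask if isinstance(seg, SegmentationResult) else np.asarray(seg)
    if mask.size == 0:
        raise ValueError("empty raster")
    return float(np.count_nonzero(mask)) / mask.size


def average_total_gap(tg_ns: float, tg_ew: float) -> float:
    """Mean of the N-S and E-W single-frame Total Gaps."""
    for v in (tg_ns, tg_ew):
        if not 0.0 <= v <= 1.0:
            raise ValueError("TG values must lie in [0, 1]")
    return 0.5 * (tg_ns + tg_ew)


def canopy_openness(grid: SkyGrid) -> float:
    """Canopy Openness: solid-angle-weighted mean gap fraction."""
    return float(np.sum(grid.gap_fraction * grid.cell_weights))


def apply_fov_mask(
    grid: SkyGrid, max_zenith: float = 75.0, snap: bool = False
) -> SkyGrid:
    """Treat all annuli beyond ``max_zenith`` as fully obstructed.

    Emulates a narrower lens (e.g. FOV 150 -> max zenith 75).  The
    annulus weights are unchanged: the masked area stays on the
    hemisphere as obstructed surface, so the masked CO can only drop.
    ``max_zenith`` must fall on an annulus boundary unless ``snap``.
    """
    edges = grid.zenith_edges
    if not np.isclose(edges, max_zenith).any():
        if not snap:
            raise ValueError(
                f"max_zenith {max_zenith} is not on an annulus boundary; "
                "pass snap=True to round to the nearest edge"
            )
        max_zenith = float(edges[np.argmin(np.abs(edges - max_zenith))])
    keep = edges[1:] <= max_zenith + 1e-9
    gf = grid.gap_fraction.copy()
    gf[~keep, :] = 0.0
    return replace(grid, gap_fraction=gf, pixel_count=grid.pixel_count.copy())


def grid_to_csv(grid: SkyGrid) -> str:
    """Serialise a grid as CSV: rows = annuli, columns = sectors."""
    ze = grid.zenith_edges
    ae = grid.azimuth_edges
    cols = [f"az_{ae[j]:.0f}_{ae[j+1]:.0f}" for j in range(grid.n_azimuth)]
    df = pd.DataFrame(grid.gap_fraction, columns=cols)
    df.insert(0, "zenith_lo", ze[:-1])
    df.insert(1, "zenith_hi", ze[1:])
    return df.to_csv(index=False)


def grid_from_csv(text: str) -> SkyGrid:
    """Inverse of :func:`grid_to_csv` (pixel counts are not preserved)."""
    df = pd.read_csv(io.StringIO(text))
    gf = df.drop(columns=["zenith_lo", "zenith_hi"]).to_numpy(dtype=np.float64)
    n_zenith, n_azimuth = gf.shape
    return SkyGrid(gf, np.zeros_like(gf), n_azimuth=n_azimuth, n_zenith=n_zenith)
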