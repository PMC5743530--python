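"""Fisheye projection geometry for hemispherical photographs.

A hemispherical (fisheye) photograph maps sky directions onto the image
plane.  All lenses handled here follow the azimuthal *equidistant*
projection: the pixel distance from the optical centre is proportional
to the zenith angle of the viewed direction,

    theta = (r / radius_px) * max_zenith.

Two camera geometries are supported:

* **circular** images, where the full hemisphere (zenith 0-90 deg) fits
  inside the frame as a circle, and
* **diagonal** frames from smartphone fisheye adapters, rectangular
  images whose *diagonal* spans the lens field of view (e.g. 150 deg,
  so the frame corners sit at zenith 75 deg).

Azimuth convention: sky compass bearings, 0 = North increasing
clockwise towards East.  For an upward-looking image displayed
as captured, image-up is North and East appears on the image *left*
(the mirror flag handles images that were flipped before processing).

Two orthogonal diagonal frames taken at the same spot can be merged
into a *pseudo-hemisphere*: a full 0-90 deg circular raster in which
only the union of the two rectangular footprints is observed and the
remaining area is flagged as uncovered (treated downstream as
obstructed canopy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Direction",
    "ProjectionModel",
    "HemisphereRaster",
    "DiagonalFrame",
    "MERGE_FOV_RATIO",
    "pixel_to_direction",
    "direction_to_pixel",
    "diagonal_projection",
    "diagonal_footprint",
    "merge_diagonal_pair",
    "apply_circular_mask",
    "circular_projection",
]

#: Diameter of the pseudo-hemisphere analysis circle in units of the
#: frame diagonal: the diagonal spans 150 deg, the full hemisphere 180,
#: and under the equidistant law angle is proportional to radius.
MERGE_FOV_RATIO = 180.0 / 150.0


@dataclass(frozen=True)
class Direction:
    """A direction on the sky hemisphere.

    Parameters
    ----------
    zenith : float
        Zenith angle in degrees, 0 (straight up) to 90 (horizon).
    azimuth : float
        Compass bearing in degrees, 0 = North, clockwise (East = 90).
        Normalised to [0, 360).
    """

    zenith: float
    azimuth: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.zenith) and math.isfinite(self.azimuth)):
            raise ValueError("direction angles must be finite")
        if not 0.0 <= self.zenith <= 90.0:
            raise ValueError(f"zenith {self.zenith} outside [0, 90]")
        object.__setattr__(self, "azimuth", self.azimuth % 360.0)


@dataclass(frozen=True)
class ProjectionModel:
    """Equidistant fisheye projection calibration.

    Attributes
    ----------
    center : (float, float)
        Optical centre as continuous (row, col) image coordinates.
        Pixel (i, j) has its centre at (i + 0.5, j + 0.5).
    radius_px : float
        Pixel distance corresponding to ``max_zenith``.
    max_zenith : float
        Largest zenith angle imaged, degrees (90 for a full-hemisphere
        circle; 75 for a 150 deg diagonal-FOV lens).
    north_offset : float
        Degrees added to the image bearing to map image-up onto
        compass North.
    mirror : bool
        True if the image was left/right flipped relative to the
        as-captured upward view (swaps East and West).
    """

    center: tuple[float, float]
    radius_px: float
    max_zenith: float = 90.0
    north_offset: float = 0.0
    mirror: bool = False

    def __post_init__(self) -> None:
        if not self.radius_px > 0:
            raise ValueError("radius_px must be positive")
        if not 0.0 < self.max_zenith <= 90.0:
            raise ValueError("max_zenith must be in (0, 90]")

    @property
    def degrees_per_px(self) -> float:
        return self.max_zenith / self.radius_px


@dataclass
class HemisphereRaster:
    """A segmented hemispherical image with its coverage information.

    ``sky_mask`` is 1 where the pixel is classified as sky,
    ``coverage_mask`` is 1 where the pixel was actually observed by a
    camera (inside the image circle / frame footprint).  Sky is only
    allowed where coverage exists: uncovered area is never sky.
    """

    sky_mask: np.ndarray
    coverage_mask: np.ndarray
    projection: ProjectionModel

    def __post_init__(self) -> None:
        self.sky_mask = np.asarray(self.sky_mask, dtype=bool)
        self.coverage_mask = np.asarray(self.coverage_mask, dtype=bool)
        if self.sky_mask.shape != self.coverage_mask.shape:
            raise ValueError("sky_mask and coverage_mask shapes differ")
        if np.any(self.sky_mask & ~self.coverage_mask):
            raise ValueError("sky outside the covered area")


@dataclass
class DiagonalFrame:
    """A rectangular smartphone fisheye frame with known orientation.

    ``orientation`` is the compass bearing of the frame's long axis in
    degrees (0 = the long side runs North-South, 90 = East-West).
    ``fov_diagonal`` is the lens field of view measured along the image
    diagonal (150 deg for the lens emulated here).
    """

    rgb: np.ndarray
    orientation: float
    fov_diagonal: float = 150.0

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] < 3:
            raise ValueError("rgb must be an (H, W, 3) raster")
        h, w = self.rgb.shape[:2]
        if w < h:
            raise ValueError("frame must be landscape (width >= height)")
        if not 0.0 < self.fov_diagonal <= 180.0:
            raise ValueError("fov_diagonal must be in (0, 180]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    @property
    def projection(self) -> ProjectionModel:
        h, w = self.shape
        return diagonal_projection((w, h), self.fov_diagonal, self.orientation)


def _pixel_center_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Continuous (row, col) coordinates of every pixel centre."""
    h, w = shape
    rows = np.arange(h, dtype=np.float64) + 0.5
    cols = np.arange(w, dtype=np.float64) + 0.5
    return np.meshgrid(rows, cols, indexing="ij")


def pixel_to_direction(pixel, proj: ProjectionModel):
    """Map continuous image coordinates to sky directions.

    Parameters
    ----------
    pixel : (row, col) pair of floats or of equally shaped arrays.
    proj : ProjectionModel

    Returns
    -------
    zenith, azimuth : float or ndarray, degrees
        Directions per input point.  Points beyond ``max_zenith``
        (outside the imaged field) carry ``nan`` in both outputs.
        For scalar input a :class:`Direction` is returned, or ``None``
        when the point falls outside the field.
    """
    row = np.asarray(pixel[0], dtype=np.float64)
    col = np.asarray(pixel[1], dtype=np.float64)
    if not (np.all(np.isfinite(row)) and np.all(np.isfinite(col))):
        raise ValueError("non-finite pixel coordinates")
    scalar = row.ndim == 0 and col.ndim == 0

    drow = row - proj.center[0]
    dcol = col - proj.center[1]
    r = np.hypot(drow, dcol)
    zenith = r * proj.degrees_per_px

    # bearing with image-up = 0, increasing towards image-left (the
    # as-captured upward view puts East on the image left)
    bearing = np.degrees(np.arctan2(-dcol, -drow))
    if proj.mirror:
        bearing = -bearing
    azimuth = (bearing + proj.north_offset) % 360.0

    outside = zenith > proj.max_zenith + 1e-9
    zenith = np.where(outside, np.nan, np.minimum(zenith, proj.max_zenith))
    azimuth = np.where(outside, np.nan, azimuth)
    azimuth = np.where(zenith == 0.0, 0.0, azimuth)  # axis: azimuth undefined

    if scalar:
        if outside:
            return None
        return Direction(float(zenith), float(azimuth))
    return zenith, azimuth


def direction_to_pixel(d, proj: ProjectionModel):
    """Inverse of :func:`pixel_to_direction`.

    Accepts a :class:`Direction` or (zenith, azimuth) arrays; returns
    continuous (row, col).  Raises for zenith beyond the projection's
    field when given scalars; array input marks such points ``nan``.
    """
    if isinstance(d, Direction):
        if d.zenith > proj.max_zenith + 1e-9:
            raise ValueError(
                f"zenith {d.zenith} beyond projection max_zenith {proj.max_zenith}"
            )
        zen = np.asarray(d.zenith, dtype=np.float64)
        az = np.asarray(d.azimuth, dtype=np.float64)
        scalar = True
    else:
        zen = np.asarray(d[0], dtype=np.float64)
        az = np.asarray(d[1], dtype=np.float64)
        scalar = zen.ndim == 0

    r = zen / proj.degrees_per_px
    bearing = az - proj.north_offset
    if proj.mirror:
        bearing = -bearing
    b = np.radians(bearing)
    drow = -r * np.cos(b)
    dcol = -r * np.sin(b)
    row = proj.center[0] + drow
    col = proj.center[1] + dcol
    if not scalar:
        bad = zen > proj.max_zenith + 1e-9
        row = np.where(bad, np.nan, row)
        col = np.where(bad, np.nan, col)
    if scalar:
        return float(row), float(col)
    return row, col


def diagonal_projection(
    frame_dims: tuple[int, int], fov_diagonal: float = 150.0, orientation: float = 0.0
) -> ProjectionModel:
    """Projection model of a rectangular diagonal-fisheye frame.

    ``frame_dims`` is (width, height) in pixels.  The optical axis is
    assumed at the frame centre and the image diagonal spans
    ``fov_diagonal`` degrees, so the corner pixels sit at zenith
    ``fov_diagonal / 2``.  ``orientation`` is the compass bearing of
    the long (width) axis; with orientation 0 the left edge of the
    frame points North.
    """
    w, h = frame_dims
    if w <= 0 or h <= 0:
        raise ValueError("frame dimensions must be positive")
    radius = 0.5 * math.hypot(w, h)
    # image-left carries bearing 90 in the as-captured view; steer it
    # onto the long-axis compass bearing
    return ProjectionModel(
        center=(h / 2.0, w / 2.0),
        radius_px=radius,
        max_zenith=fov_diagonal / 2.0,
        north_offset=orientation - 90.0,
    )


def diagonal_footprint(
    frame_dims: tuple[int, int], fov_diagonal: float = 150.0, orientation: float = 0.0
):
    """Projection model plus the per-pixel direction field of a frame.

    Returns ``(proj, zenith, azimuth)`` where the angle arrays give the
    sky direction of every pixel centre (shape height x width).
    """
    proj = diagonal_projection(frame_dims, fov_diagonal, orientation)
    w, h = frame_dims
    rows, cols = _pixel_center_grid((h, w))
    zen, az = pixel_to_direction((rows, cols), proj)
    return proj, zen, az


def _frame_coverage_of(
    proj_out: ProjectionModel,
    out_shape: tuple[int, int],
    frame: DiagonalFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For each output pixel: is it seen by `frame`, and from where.

    Returns (covered, src_row_idx, src_col_idx); index arrays are only
    valid where covered.
    """
    rows, cols = _pixel_center_grid(out_shape)
    zen, az = pixel_to_direction((rows, cols), proj_out)
    fproj = frame.projection
    h, w = frame.shape
    with np.errstate(invalid="ignore"):
        in_fov = np.nan_to_num(zen, nan=np.inf) <= fproj.max_zenith + 1e-9
    zen_c = np.where(in_fov, zen, 0.0)
    az_c = np.where(in_fov, az, 0.0)
    srow, scol = direction_to_pixel((zen_c, az_c), fproj)
    i = np.floor(srow).astype(np.int64)
    j = np.floor(scol).astype(np.int64)
    covered = in_fov & (srow >= 0) & (scol >= 0) & (i < h) & (j < w)
    i = np.clip(i, 0, h - 1)
    j = np.clip(j, 0, w - 1)
    return covered, i, j


def merge_diagonal_pair(
    frame_ew: DiagonalFrame,
    frame_ns: DiagonalFrame,
    out_size: int = 1024,
    orientation_tolerance: float = 15.0,
    fov_ratio: float = MERGE_FOV_RATIO,
):
    """Merge an orthogonal pair of diagonal frames into a pseudo-hemisphere.

    The output is a square raster with an inscribed full-hemisphere
    circle (max zenith 90).  In source-pixel units the circle diameter
    is the frame diagonal multiplied by ``fov_ratio`` (180/150 by
    default), i.e. the two frames are inscribed so that their diagonals
    span 150 deg.  Where both frames see a direction the E-W frame is
    the reference and provides the pixel value; directions seen by
    neither frame remain uncovered (coverage 0) and are treated as
    obstructed downstream.

    Returns
    -------
    rgb : (out_size, out_size, 3) ndarray, same dtype as the inputs
    coverage : (out_size, out_size) bool ndarray
    proj : ProjectionModel of the merged raster
    """
    if not math.isclose(frame_ew.fov_diagonal, frame_ns.fov_diagonal):
        raise ValueError("frames have different diagonal FOVs")
    dori = abs(((frame_ew.orientation - frame_ns.orientation) % 180.0) - 90.0)
    if dori > orientation_tolerance:
        raise ValueError(
            f"frame orientations are {dori:.1f} deg away from orthogonal "
            f"(tolerance {orientation_tolerance})"
        )
    half_fov = frame_ew.fov_diagonal / 2.0
    max_zen_out = min(90.0, half_fov * fov_ratio)
    proj_out = ProjectionModel(
        center=(out_size / 2.0, out_size / 2.0),
        radius_px=out_size / 2.0,
        max_zenith=max_zen_out,
    )

    cov_ew, i_ew, j_ew = _frame_coverage_of(proj_out, (out_size, out_size), frame_ew)
    cov_ns, i_ns, j_ns = _frame_coverage_of(proj_out, (out_size, out_size), frame_ns)

    rgb = np.zeros((out_size, out_size, 3), dtype=frame_ew.rgb.dtype)
    rgb[cov_ns] = frame_ns.rgb[i_ns[cov_ns], j_ns[cov_ns], :3]
    rgb[cov_ew] = frame_ew.rgb[i_ew[cov_ew], j_ew[cov_ew], :3]  # E-W is reference
    coverage = cov_ew | cov_ns
    return rgb, coverage, proj_out


def apply_circular_mask(rgb_shape: tuple[int, int], proj: ProjectionModel) -> np.ndarray:
    """Coverage mask of the image circle of a circular photograph.

    Coverage is 1 where the pixel centre lies within ``radius_px`` of
    the optical centre, i.e. at zenith <= max_zenith (<= 90): for a
    lens wider than 180 deg calibrated with radius_px at the 90 deg
    ring, the outer ring beyond the horizon is excluded.
    """
    h, w = rgb_shape[:2]
    c0, c1 = proj.center
    if (
        c0 - proj.radius_px < 0
        or c1 - proj.radius_px < 0
        or c0 + proj.radius_px > h
        or c1 + proj.radius_px > w
    ):
        raise ValueError("image circle does not fit inside the raster")
    rows, cols = _pixel_center_grid((h, w))
    r = np.hypot(rows - c0, cols - c1)
    return r <= proj.radius_px


def circular_projection(
    size: int, max_zenith: float = 90.0, north_offset: float = 0.0, mirror: bool = False
) -> ProjectionModel:
    """Projection of a square circular image with an inscribed hemisphere."""
    return ProjectionModel(
        center=(size / 2.0, size / 2.0),
        radius_px=size / 2.0,
        max_zenith=max_zenith,
        north_offset=north_offset,
        mirror=mirror,
    )
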