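"""Synthetic canopy scenes with exact ground truth.

A scene is a set of opaque angular disks on the sky hemisphere: a
direction is sky iff it lies outside every disk.  This is the simplest
canopy model with an exactly evaluable gap function, which makes every
pipeline stage testable without field photographs.

Disk centres are drawn with a zenith density proportional to
``sin(theta) * (theta/90)**zenith_exponent``: a positive exponent
concentrates obstruction towards the horizon, the situation real
canopies approximate (long slant paths through foliage) and the
mechanism behind the positive bias of diagonal-frame Total Gap against
circular Canopy Openness.

Renderers produce matched circular and diagonal fisheye views of the
same scene: sky pixels are blue with the red/green channels graded by
the Standard Overcast Sky radiance (horizon sky is dimmer), canopy is
dark green, and a configurable fraction of canopy pixels is drawn as
bright sunlit foliage — high-lightness yellow-green "artifact" pixels
whose blue channel passes a brightness threshold even though they are
vegetation.  Handheld acquisition is emulated by a small random tilt
of the optical axis and azimuth deviation (jitter).

All randomness flows through named streams derived from integer seeds,
so every fixture is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import light
from .gaps import SkyGrid, canopy_openness
from .geometry import (
    DiagonalFrame,
    _pixel_center_grid,
    circular_projection,
    diagonal_projection,
    pixel_to_direction,
)

__all__ = [
    "CanopyScene",
    "SceneTruth",
    "Jitter",
    "generate_scene",
    "is_sky_direction",
    "render_circular",
    "render_diagonal",
    "truth_grid",
    "truth_site_estimates",
    "SKY_RGB",
    "CANOPY_RGB",
    "ARTIFACT_RGB",
]

# render palette (unit RGB); sky red/green are scaled by the SOC
# radiance so the horizon sky is dimmer, blue stays saturated
SKY_RGB = (0.45, 0.60, 1.00)
CANOPY_RGB = (0.08, 0.22, 0.07)
ARTIFACT_RGB = (0.95, 0.98, 0.82)

DEFAULT_N_DISKS = 300
DEFAULT_RADIUS_RANGE = (3.0, 12.0)
DEFAULT_ZENITH_EXPONENT = 1.5
DEFAULT_ARTIFACT_FRACTION = 0.03


@dataclass
class CanopyScene:
    """Opaque angular disks on the hemisphere plus render options."""

    disk_zenith: np.ndarray
    disk_azimuth: np.ndarray
    disk_radius: np.ndarray
    zenith_exponent: float = DEFAULT_ZENITH_EXPONENT
    artifact_fraction: float = DEFAULT_ARTIFACT_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        self.disk_zenith = np.atleast_1d(np.asarray(self.disk_zenith, dtype=np.float64))
        self.disk_azimuth = np.atleast_1d(np.asarray(self.disk_azimuth, dtype=np.float64))
        self.disk_radius = np.atleast_1d(np.asarray(self.disk_radius, dtype=np.float64))
        if not (
            self.disk_zenith.shape == self.disk_azimuth.shape == self.disk_radius.shape
        ):
            raise ValueError("disk arrays must have equal length")
        if self.disk_radius.size and not np.all(self.disk_radius > 0):
            raise ValueError("disk radii must be positive")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction must lie in [0, 1]")

    @property
    def n_disks(self) -> int:
        return self.disk_zenith.size

    def _disk_vectors(self) -> np.ndarray:
        z = np.radians(self.disk_zenith)
        a = np.radians(self.disk_azimuth)
        return np.stack(
            [np.sin(z) * np.cos(a), np.sin(z) * np.sin(a), np.cos(z)], axis=1
        )


@dataclass
class SceneTruth:
    """Exact grid and site estimates of a scene, bypassing imaging."""

    grid: SkyGrid
    estimates: "light.SiteEstimates"


@dataclass(frozen=True)
class Jitter:
    """Handheld acquisition error: optical-axis tilt and azimuth twist.

    ``tilt_sd`` and ``azimuth_sd`` are standard deviations in degrees;
    the realised deviations are drawn deterministically from ``seed``.
    """

    tilt_sd: float = 0.0
    azimuth_sd: float = 0.0
    seed: int = 0


def generate_scene(
    seed: int,
    n_disks: int = DEFAULT_N_DISKS,
    radius_range: tuple[float, float] = DEFAULT_RADIUS_RANGE,
    zenith_exponent: float = DEFAULT_ZENITH_EXPONENT,
    artifact_fraction: float = DEFAULT_ARTIFACT_FRACTION,
) -> CanopyScene:
    """Draw a random canopy scene; deterministic given ``seed``.

    Disk centre zeniths follow the density
    sin(theta) * (theta/90)**zenith_exponent on [0, 90] (rejection
    sampling), azimuths are uniform, radii uniform in ``radius_range``
    (degrees).
    """
    if n_disks < 0:
        raise ValueError("n_disks must be >= 0")
    rng = np.random.default_rng([int(seed), 0xCA])
    zeniths = np.empty(0)
    k = zenith_exponent
    while zeniths.size < n_disks and n_disks > 0:
        cand = rng.uniform(0.0, 90.0, size=max(4 * n_disks, 64))
        accept = rng.uniform(size=cand.size) < np.sin(np.radians(cand)) * (
            cand / 90.0
        ) ** max(k, 0.0)
        zeniths = np.concatenate([zeniths, cand[accept]])
    zeniths = zeniths[:n_disks]
    azimuths = rng.uniform(0.0, 360.0, size=n_disks)
    radii = rng.uniform(radius_range[0], radius_range[1], size=n_disks)
    return CanopyScene(
        zeniths, azimuths, radii,
        zenith_exponent=zenith_exponent,
        artifact_fraction=artifact_fraction,
        seed=int(seed),
    )


def _unit_vectors(zenith, azimuth) -> np.ndarray:
    z = np.radians(np.asarray(zenith, dtype=np.float64))
    a = np.radians(np.asarray(azimuth, dtype=np.float64))
    return np.stack(
        [np.sin(z) * np.cos(a), np.sin(z) * np.sin(a), np.cos(z)], axis=-1
    )


def is_sky_direction(scene: CanopyScene, zenith, azimuth):
    """1 where the direction misses every disk, 0 where obstructed.

    Obstruction is a great-circle distance test against each disk
    centre.  Accepts scalars or arrays (returns bool of that shape).
    """
    zen = np.asarray(zenith, dtype=np.float64)
    scalar = zen.ndim == 0
    vec = _unit_vectors(zenith, azimuth).reshape(-1, 3).astype(np.float32)
    sky = np.ones(vec.shape[0], dtype=bool)
    if scene.n_disks:
        disks = scene._disk_vectors().astype(np.float32)
        cos_r = np.cos(np.radians(scene.disk_radius)).astype(np.float32)
        chunk = max(1, int(16e6 // max(vec.shape[0], 1)))
        for j in range(0, scene.n_disks, chunk):
            dots = vec @ disks[j : j + chunk].T
            sky &= ~(dots >= cos_r[j : j + chunk] - 1e-7).any(axis=1)
    if scalar:
        return bool(sky[0])
    return sky.reshape(zen.shape)


def _paint(
    sky: np.ndarray,
    zenith: np.ndarray,
    valid: np.ndarray,
    artifact_fraction: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Colour a direction field; invalid (out-of-field) pixels black."""
    h, w = sky.shape
    img = np.zeros((h, w, 3), dtype=np.float64)
    soc = np.zeros_like(zenith)
    zc = np.clip(np.nan_to_num(zenith), 0.0, 90.0)
    soc = (1.0 + 2.0 * np.cos(np.radians(zc))) / 3.0
    sky_col = np.empty((h, w, 3))
    sky_col[..., 0] = SKY_RGB[0] * soc
    sky_col[..., 1] = SKY_RGB[1] * soc
    sky_col[..., 2] = SKY_RGB[2]
    img[sky & valid] = sky_col[sky & valid]
    canopy = ~sky & valid
    img[canopy] = CANOPY_RGB
    if artifact_fraction > 0:
        bright = canopy & (rng.uniform(size=(h, w)) < artifact_fraction)
        img[bright] = ARTIFACT_RGB
    if noise_sd > 0:
        img[valid] += rng.normal(0.0, noise_sd, size=(int(valid.sum()), 3))
    np.clip(img, 0.0, 1.0, out=img)
    return np.round(img * 255.0).astype(np.uint8)


def render_circular(
    scene: CanopyScene,
    size_px: int = 1024,
    noise_sd: float = 0.01,
    max_zenith: float = 90.0,
) -> np.ndarray:
    """Render the scene as a circular hemispherical photograph.

    Square image with the hemisphere circle inscribed; outside the
    circle is black.  Returns an (size, size, 3) uint8 raster.
    """
    if size_px < 256:
        raise ValueError("size_px must be at least 256")
    proj = circular_projection(size_px, max_zenith=max_zenith)
    rows, cols = _pixel_center_grid((size_px, size_px))
    zen, az = pixel_to_direction((rows, cols), proj)
    valid = np.isfinite(zen)
    sky = np.zeros_like(valid)
    sky[valid] = is_sky_direction(scene, zen[valid], az[valid])
    rng = np.random.default_rng([scene.seed, 0x01, size_px])
    return _paint(sky, zen, valid, scene.artifact_fraction, noise_sd, rng)


def _jitter_rotation(jitter: Jitter) -> tuple[np.ndarray, float]:
    """Realised rotation matrix (tilt) and azimuth twist in degrees."""
    rng = np.random.default_rng([jitter.seed, 0x07])
    tilt = abs(rng.normal(0.0, jitter.tilt_sd)) if jitter.tilt_sd > 0 else 0.0
    tilt_dir = rng.uniform(0.0, 360.0)
    twist = rng.normal(0.0, jitter.azimuth_sd) if jitter.azimuth_sd > 0 else 0.0
    a = math.radians(tilt)
    b = math.radians(tilt_dir)
    axis = np.array([-math.sin(b), math.cos(b), 0.0])  # horizontal, perp. to tilt dir
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    R = np.eye(3) + math.sin(a) * K + (1.0 - math.cos(a)) * (K @ K)
    return R, twist


def render_diagonal(
    scene: CanopyScene,
    orientation: float,
    jitter: Jitter | None = None,
    frame_dims: tuple[int, int] = (3264, 1836),
    fov_diagonal: float = 150.0,
    noise_sd: float = 0.01,
) -> DiagonalFrame:
    """Render a rectangular diagonal-fisheye frame of the scene.

    ``orientation`` is the *recorded* compass bearing of the long axis
    (what a merge would later use); ``jitter`` perturbs the actual
    camera pose — a random optical-axis tilt and azimuth twist — so the
    sampled sky differs slightly from the nominal footprint, emulating
    handheld acquisition.  Directions tilted below the horizon render
    as canopy.
    """
    w, h = frame_dims
    if w <= 0 or h <= 0:
        raise ValueError("frame dimensions must be positive")
    proj = diagonal_projection(frame_dims, fov_diagonal, orientation)
    rows, cols = _pixel_center_grid((h, w))
    zen, az = pixel_to_direction((rows, cols), proj)
    valid = np.isfinite(zen)  # whole rectangle is in-field by construction
    if jitter is not None and (jitter.tilt_sd > 0 or jitter.azimuth_sd > 0):
        R, twist = _jitter_rotation(jitter)
        vec = _unit_vectors(zen, (az + twist) % 360.0) @ R.T
        zen_w = np.degrees(np.arccos(np.clip(vec[..., 2], -1.0, 1.0)))
        az_w = np.degrees(np.arctan2(vec[..., 1], vec[..., 0])) % 360.0
    else:
        zen_w, az_w = zen, az
    above = zen_w <= 90.0
    sky = np.zeros_like(valid)
    q = valid & above
    sky[q] = is_sky_direction(scene, zen_w[q], az_w[q])
    rng = np.random.default_rng([scene.seed, 0x02, int(round(orientation)) % 360, w])
    rgb = _paint(sky, zen, valid, scene.artifact_fraction, noise_sd, rng)
    return DiagonalFrame(rgb, orientation=orientation, fov_diagonal=fov_diagonal)


def truth_grid(
    scene: CanopyScene,
    n_azimuth: int = 24,
    n_zenith: int = 18,
    sub_zenith: int = 10,
    sub_azimuth: int = 15,
) -> SkyGrid:
    """Exact sky-grid gap fractions from the scene's gap function.

    Each 5 x 15 deg cell is integrated on a sub-lattice (0.5 deg in
    zenith, 1 deg in azimuth by default) with exact sub-annulus
    solid-angle weights.
    """
    nz = n_zenith * sub_zenith
    na = n_azimuth * sub_azimuth
    z_edges = np.radians(np.linspace(0.0, 90.0, nz + 1))
    z_mid = np.degrees(0.5 * (z_edges[:-1] + z_edges[1:]))
    z_w = np.cos(z_edges[:-1]) - np.cos(z_edges[1:])
    a_mid = (np.arange(na) + 0.5) * (360.0 / na)
    zen = np.repeat(z_mid, na)
    az = np.tile(a_mid, nz)
    g = is_sky_direction(scene, zen, az).reshape(nz, na).astype(np.float64)
    w = np.repeat(z_w[:, None] / na, na, axis=1)
    gw = (g * w).reshape(n_zenith, sub_zenith, n_azimuth, sub_azimuth)
    ww = w.reshape(n_zenith, sub_zenith, n_azimuth, sub_azimuth)
    gf = gw.sum(axis=(1, 3)) / ww.sum(axis=(1, 3))
    counts = np.full((n_zenith, n_azimuth), float(sub_zenith * sub_azimuth))
    return SkyGrid(gf, counts, n_azimuth=n_azimuth, n_zenith=n_zenith)


def truth_site_estimates(
    scene: CanopyScene,
    latitude: float,
    track: list["light.SunSample"] | None = None,
    fov150: bool = False,
) -> SceneTruth:
    """Ground-truth CO / ISF / DSF / GSF of a scene at a site."""
    from .gaps import apply_fov_mask

    grid = truth_grid(scene)
    if track is None:
        track = light.build_sun_track(latitude)
    est = light.SiteEstimates(provenance="truth")
    est.CO = canopy_openness(grid)
    est.ISF = light.indirect_site_factor(grid)
    est.DSF = light.direct_site_factor(grid, track)
    est.GSF = light.global_site_factor(est.ISF, est.DSF)
    if fov150:
        g150 = apply_fov_mask(grid, 75.0)
        est.CO150 = canopy_openness(g150)
        est.ISF150 = light.indirect_site_factor(g150)
        est.DSF150 = light.direct_site_factor(g150, track)
        est.GSF150 = light.global_site_factor(est.ISF150, est.DSF150)
    return SceneTruth(grid=grid, estimates=est)
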