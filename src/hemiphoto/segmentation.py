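"""Sky / canopy classification of hemispherical photographs.

Thresholding turns an RGB photograph into a binary sky mask.  Two
automatic methods are provided:

``isodata_blue``
    The Ridler-Calvard iterative-selection (IsoData) threshold applied
    to the blue channel, where the contrast between sky and vegetation
    is strongest.

``enhanced``
    A fuzzy colour classification: every pixel gets a sky-membership
    score from its hue, lightness and chroma, and the IsoData threshold
    is then applied to the score field.  This follows the same idea as
    colour-based canopy classifiers: bright achromatic (cloud) and
    blue-hued pixels are sky-like, green/yellow-hued pixels are
    vegetation-like even when bright, which suppresses the classic
    failure mode of brightness-only thresholds on sunlit foliage.

Both classifiers share deterministic edge rules: a pixel exactly at
the threshold goes to canopy, and a perfectly uniform (covered) image
is classified as all sky.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegmentationResult",
    "isodata_threshold",
    "classify_blue_isodata",
    "sky_membership_score",
    "classify_enhanced",
]


@dataclass
class SegmentationResult:
    """Binary sky mask plus the threshold that produced it."""

    sky_mask: np.ndarray
    threshold: float
    method: str

    def __post_init__(self) -> None:
        self.sky_mask = np.asarray(self.sky_mask, dtype=bool)
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def isodata_threshold(values, initial: float | None = None) -> float:
    """Ridler-Calvard iterative-selection threshold.

    Iterates ``t <- (mean(values <= t) + mean(values > t)) / 2``
    starting from the global mean (or ``initial``), until the update
    moves by less than 0.5 intensity units or 100 iterations elapse.
    If all values are equal, that value is returned.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("isodata_threshold needs at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite intensity values")
    lo, hi = v.min(), v.max()
    if lo == hi:
        return float(lo)
    t = float(np.mean(v)) if initial is None else float(initial)
    for _ in range(100):
        below = v[v <= t]
        above = v[v > t]
        if below.size == 0:
            new_t = float(above.mean())
        elif above.size == 0:
            new_t = float(below.mean())
        else:
            new_t = 0.5 * (float(below.mean()) + float(above.mean()))
        if abs(new_t - t) < 0.5:
            t = new_t
            break
        t = new_t
    return float(t)


def _check_rgb(rgb) -> np.ndarray:
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    return arr


def _coverage_or_full(coverage, shape) -> np.ndarray:
    if coverage is None:
        return np.ones(shape, dtype=bool)
    cov = np.asarray(coverage, dtype=bool)
    if cov.shape != shape:
        raise ValueError("coverage mask shape differs from image")
    if not cov.any():
        raise ValueError("coverage mask is empty")
    return cov


def _threshold_field(
    field: np.ndarray, coverage: np.ndarray, method: str, midpoint: float
) -> SegmentationResult:
    vals = field[coverage]
    if vals.min() == vals.max():
        # uniform covered image: no contrast to threshold, so decide by
        # absolute brightness — all sky above the scale midpoint (a
        # uniform open-sky image), all canopy otherwise.  This also
        # keeps segmentation idempotent on its own binary output.
        v = float(vals.min())
        mask = coverage.copy() if v > midpoint else np.zeros_like(coverage)
        return SegmentationResult(mask, v, method)
    t = isodata_threshold(vals)
    mask = (field > t) & coverage  # ties go to canopy
    return SegmentationResult(mask, t, method)


def classify_blue_isodata(rgb, coverage=None) -> SegmentationResult:
    """IsoData threshold on the blue channel; sky = blue > threshold.

    Uncovered pixels are always canopy.  The threshold is estimated
    from covered pixels only.
    """
    arr = _check_rgb(rgb)
    cov = _coverage_or_full(coverage, arr.shape[:2])
    blue = arr[..., 2].astype(np.float64)
    mid = 0.5 if np.issubdtype(arr.dtype, np.floating) else np.iinfo(arr.dtype).max / 2
    return _threshold_field(blue, cov, "isodata_blue", mid)


def _rescale_unit(rgb: np.ndarray) -> np.ndarray:
    """Linear rescale of 8- or 16-bit (or already unit float) RGB to [0, 1]."""
    arr = rgb[..., :3].astype(np.float64)
    if rgb.dtype == np.uint8:
        return arr / 255.0
    if rgb.dtype == np.uint16:
        return arr / 65535.0
    return arr


def _hue_chroma_lightness(rgb01: np.ndarray):
    """Bi-hexcone (HSL-family) colour attributes from unit RGB."""
    r, g, b = rgb01[..., 0], rgb01[..., 1], rgb01[..., 2]
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    chroma = mx - mn
    lightness = 0.5 * (mx + mn)
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = np.where(mx == r, ((g - b) / chroma) % 6.0, 0.0)
        hg = np.where(mx == g, (b - r) / chroma + 2.0, 0.0)
        hb = np.where(mx == b, (r - g) / chroma + 4.0, 0.0)
    h6 = np.where(mx == r, hr, np.where(mx == g, hg, hb))
    hue = np.where(chroma > 0, 60.0 * h6, 0.0)
    return hue, chroma, lightness


def _hue_membership(hue: np.ndarray) -> np.ndarray:
    """Sky-likeness of a hue: blue sector 1, green/yellow 0.1, rest 0.3."""
    out = np.full(hue.shape, 0.3)
    out[(hue >= 60.0) & (hue < 180.0)] = 0.1
    out[(hue >= 180.0) & (hue <= 300.0)] = 1.0
    return out


def sky_membership_score(rgb01) -> np.ndarray:
    """Fuzzy sky-membership score in [0, 1] from hue/lightness/chroma.

    The score is a fuzzy AND of two conditions: the pixel is *bright*
    (lightness membership rising from 0.1 to 0.55) and it is
    *sky-coloured* — either its hue lies in the blue sector or it is
    achromatic (as chroma falls below ~0.1 the hue becomes
    uninformative and the colour membership relaxes towards 1, so that
    bright white clouds score highly).  Green/yellow hues are strongly
    penalised regardless of brightness.

    Accepts a single RGB triple or an (..., 3) array with channels in
    [0, 1]; returns a scalar or array of the same leading shape.
    """
    arr = np.asarray(rgb01, dtype=np.float64)
    scalar = arr.ndim == 1
    if arr.shape[-1] < 3:
        raise ValueError("expected RGB triples")
    if arr.min() < 0.0 or arr[..., :3].max() > 1.0:
        raise ValueError("channel values must lie in [0, 1]")
    arr = arr.reshape((-1, arr.shape[-1]))[:, :3] if scalar else arr[..., :3]
    hue, chroma, lightness = _hue_chroma_lightness(arr)

    # brightness membership: trapezoid rising on [0.1, 0.55]
    f = np.clip((lightness - 0.1) / 0.45, 0.0, 1.0)
    # colour membership: hue term, relaxed to 1 for achromatic pixels
    g_hue = _hue_membership(hue)
    sat = np.clip((chroma - 0.02) / 0.08, 0.0, 1.0)
    g = (1.0 - sat) + sat * g_hue
    score = f * g
    if scalar:
        return float(score[0])
    return score


def classify_enhanced(rgb, coverage=None) -> SegmentationResult:
    """Fuzzy colour score field thresholded with IsoData.

    The per-pixel :func:`sky_membership_score` replaces raw brightness;
    the Ridler-Calvard threshold is then found on the score field and
    sky = score > threshold.  Bright but green/yellow vegetation
    (sunlit leaves) receives a low score and stays canopy even when its
    blue channel would pass a brightness threshold.
    """
    arr = _check_rgb(rgb)
    cov = _coverage_or_full(coverage, arr.shape[:2])
    score = sky_membership_score(_rescale_unit(arr))
    return _threshold_field(score, cov, "enhanced", 0.5)
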