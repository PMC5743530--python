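import numpy as np
import pytest

import hemiphoto as hp

LAT = 53.0  # typical study latitude (UK)


@pytest.fixture(scope="session")
def sun_track():
    """Annual sun track at the reference latitude (built once)."""
    return hp.build_sun_track(LAT)


@pytest.fixture(scope="session")
def default_scene():
    return hp.generate_scene(11)


@pytest.fixture(scope="session")
def clean_scene():
    """Default scene without bright-leaf artifacts."""
    return hp.generate_scene(11, artifact_fraction=0.0)


def circular_pipeline(scene, size, track, method=hp.classify_enhanced, lat=LAT):
    """Render -> segment -> site estimates for a circular photograph."""
    img = hp.render_circular(scene, size)
    proj = hp.circular_projection(size)
    cov = hp.apply_circular_mask(img.shape, proj)
    seg = method(img, cov)
    h = hp.HemisphereRaster(seg.sky_mask & cov, cov, proj)
    return hp.analyze_hemisphere(h, lat, track=track)


def merged_pipeline(scene, frame_w, out_size, track, jitter=None, lat=LAT):
    """Render an orthogonal pair, merge, segment and analyze."""
    dims = (frame_w, int(round(frame_w * 9 / 16)))

    def _jit(ori):
        if jitter is None:
            return None
        return hp.Jitter(jitter.tilt_sd, jitter.azimuth_sd, jitter.seed + int(ori))

    few = hp.render_diagonal(scene, 90.0, jitter=_jit(90), frame_dims=dims)
    fns = hp.render_diagonal(scene, 0.0, jitter=_jit(0), frame_dims=dims)
    rgb, cov, proj = hp.merge_diagonal_pair(few, fns, out_size=out_size)
    seg = hp.classify_enhanced(rgb, cov)
    h = hp.HemisphereRaster(seg.sky_mask & cov, cov, proj)
    return hp.analyze_hemisphere(h, lat, track=track, provenance="smartphone_merged")


def truth_pixel_mask(scene, size):
    """Ground-truth sky mask of a circular render, from the gap function."""
    proj = hp.circular_projection(size)
    rows, cols = np.meshgrid(
        np.arange(size) + 0.5, np.arange(size) + 0.5, indexing="ij"
    )
    zen, az = hp.pixel_to_direction((rows, cols), proj)
    valid = np.isfinite(zen)
    mask = np.zeros((size, size), dtype=bool)
    mask[valid] = hp.is_sky_direction(scene, zen[valid], az[valid])
    return mask, valid, zen
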