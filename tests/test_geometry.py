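"""Projection model, diagonal footprints and pseudo-hemisphere merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemiphoto as hp
from hemiphoto.geometry import _pixel_center_grid


def square_proj(size=1000.0, **kw):
    return hp.ProjectionModel(center=(size / 2, size / 2), radius_px=size / 2, **kw)


class TestPixelToDirection:
    def test_center_is_zenith(self):
        d = hp.pixel_to_direction((500.0, 500.0), square_proj())
        assert d.zenith == 0.0 and d.azimuth == 0.0

    def test_up_image_is_north_at_max_zenith(self):
        d = hp.pixel_to_direction((0.0, 500.0), square_proj())
        assert d.zenith == pytest.approx(90.0)
        assert d.azimuth == pytest.approx(0.0)

    def test_image_left_is_east(self):
        # as-captured upward view: East appears on the image left
        d = hp.pixel_to_direction((500.0, 0.0), square_proj())
        assert d.azimuth == pytest.approx(90.0)

    def test_mirror_swaps_east_west(self):
        d = hp.pixel_to_direction((500.0, 0.0), square_proj(mirror=True))
        assert d.azimuth == pytest.approx(270.0)

    def test_equidistant_linearity_half_radius(self):
        proj = square_proj(max_zenith=75.0)
        d = hp.pixel_to_direction((250.0, 500.0), proj)
        assert d.zenith == pytest.approx(37.5)

    def test_outside_field_returns_none(self):
        assert hp.pixel_to_direction((0.0, 0.0), square_proj()) is None

    def test_nonfinite_pixel_raises(self):
        with pytest.raises(ValueError):
            hp.pixel_to_direction((np.nan, 0.0), square_proj())

    def test_north_offset_rotates_azimuth(self):
        d = hp.pixel_to_direction((0.0, 500.0), square_proj(north_offset=30.0))
        assert d.azimuth == pytest.approx(30.0)


class TestDirectionToPixel:
    def test_zenith_maps_to_center(self):
        assert hp.direction_to_pixel(hp.Direction(0, 0), square_proj()) == (500.0, 500.0)

    def test_north_at_max_zenith_is_top_of_vertical_axis(self):
        r, c = hp.direction_to_pixel(hp.Direction(90, 0), square_proj())
        assert (r, c) == pytest.approx((0.0, 500.0))

    def test_beyond_field_raises(self):
        with pytest.raises(ValueError):
            hp.direction_to_pixel(hp.Direction(80, 0), square_proj(max_zenith=75))

    @pytest.mark.parametrize("mirror", [False, True])
    @pytest.mark.parametrize("offset", [0.0, 37.0, 270.0])
    def test_round_trip_identity(self, mirror, offset):
        proj = square_proj(mirror=mirror, north_offset=offset)
        rng = np.random.default_rng(42)
        zen = rng.uniform(0.0, 90.0, 1000)
        az = rng.uniform(0.0, 360.0, 1000)
        r, c = hp.direction_to_pixel((zen, az), proj)
        z2, a2 = hp.pixel_to_direction((r, c), proj)
        # 0.5 px corresponds to 0.09 deg of zenith here
        assert np.nanmax(np.abs(z2 - zen)) < 0.5 * proj.degrees_per_px
        r2, c2 = hp.direction_to_pixel((z2, a2), proj)
        assert np.hypot(r2 - r, c2 - c).max() < 0.5

    @settings(max_examples=50, deadline=None)
    @given(
        zen=st.floats(0.1, 89.9),
        az=st.floats(0.0, 359.9),
        offset=st.floats(-180.0, 180.0),
    )
    def test_round_trip_property(self, zen, az, offset):
        proj = square_proj(north_offset=offset)
        r, c = hp.direction_to_pixel(hp.Direction(zen, az), proj)
        d = hp.pixel_to_direction((r, c), proj)
        r2, c2 = hp.direction_to_pixel(d, proj)
        assert abs(r2 - r) < 0.5 and abs(c2 - c) < 0.5


class TestDiagonalFootprint:
    def test_corner_zenith_is_half_fov(self):
        proj, zen, az = hp.diagonal_footprint((3264, 1836), 150.0, 0.0)
        # exact corner of the frame (continuous coordinate) sits at 75 deg
        d = hp.pixel_to_direction((0.0, 0.0), proj)
        assert d.zenith == pytest.approx(75.0, abs=1e-9)
        assert proj.max_zenith == 75.0
        # pixel-centre field stays inside the fov
        assert np.nanmax(zen) <= 75.0

    def test_center_zenith_zero(self):
        proj, zen, az = hp.diagonal_footprint((64, 36), 150.0, 0.0)
        assert hp.pixel_to_direction(proj.center, proj).zenith == 0.0

    def test_half_diagonal_linearity(self):
        proj, _, _ = hp.diagonal_footprint((3264, 1836), 150.0, 0.0)
        h, w = 1836, 3264
        mid = (h / 2 + (0 - h / 2) / 2, w / 2 + (0 - w / 2) / 2)  # halfway to corner
        assert hp.pixel_to_direction(mid, proj).zenith == pytest.approx(37.5)

    def test_direction_field_matches_analytic_law(self):
        proj, zen, _ = hp.diagonal_footprint((320, 180), 150.0, 0.0)
        rows, cols = _pixel_center_grid((180, 320))
        r = np.hypot(rows - proj.center[0], cols - proj.center[1])
        analytic = r / proj.radius_px * proj.max_zenith
        assert np.nanmax(np.abs(zen - analytic)) < 1e-9

    def test_orientation_steers_long_axis(self):
        # long axis N-S: the left edge midpoint should bear North
        proj, _, _ = hp.diagonal_footprint((400, 200), 150.0, 0.0)
        d = hp.pixel_to_direction((100.0, 0.0), proj)
        assert d.azimuth == pytest.approx(0.0)

    def test_bad_dims_raise(self):
        with pytest.raises(ValueError):
            hp.diagonal_footprint((0, 100))


def all_sky_frame(w=3264, h=1836, orientation=0.0, value=255):
    return hp.DiagonalFrame(
        np.full((h, w, 3), value, np.uint8), orientation=orientation
    )


class TestMergeDiagonalPair:
    def test_disk_coverage_fraction_matches_pixel_oracle(self):
        few = all_sky_frame(orientation=90.0)
        fns = all_sky_frame(orientation=0.0)
        _, cov, proj = hp.merge_diagonal_pair(few, fns, out_size=1024)
        rows, cols = _pixel_center_grid(cov.shape)
        disk = np.hypot(rows - proj.center[0], cols - proj.center[1]) <= proj.radius_px
        assert cov[disk].mean() == pytest.approx(0.543, abs=0.005)
        # nothing outside the union footprint (here: outside the disk) covered
        assert not cov[~disk].any()

    def test_ew_frame_is_reference_in_overlap(self):
        few = all_sky_frame(orientation=90.0, value=255)
        fns = all_sky_frame(orientation=0.0, value=10)
        rgb, cov, proj = hp.merge_diagonal_pair(few, fns, out_size=512)
        c = int(proj.center[0])
        assert tuple(rgb[c, c]) == (255, 255, 255)

    def test_coverage_is_union_of_footprints(self):
        few = all_sky_frame(320, 180, orientation=90.0)
        fns = all_sky_frame(320, 180, orientation=0.0)
        _, cov, proj = hp.merge_diagonal_pair(few, fns, out_size=256)
        from hemiphoto.geometry import _frame_coverage_of

        c_ew, _, _ = _frame_coverage_of(proj, cov.shape, few)
        c_ns, _, _ = _frame_coverage_of(proj, cov.shape, fns)
        assert np.array_equal(cov, c_ew | c_ns)

    def test_azimuth_equivariance_quarter_turn(self):
        # rotating both orientations by 90 deg rotates the coverage map
        a = hp.merge_diagonal_pair(
            all_sky_frame(320, 180, 90.0), all_sky_frame(320, 180, 0.0), 256
        )[1]
        b = hp.merge_diagonal_pair(
            all_sky_frame(320, 180, 180.0), all_sky_frame(320, 180, 90.0), 256
        )[1]
        # compass rotation is clockwise; image azimuth runs counter-clockwise
        assert np.array_equal(b, np.rot90(a, -1))

    def test_mismatched_fov_raises(self):
        bad = hp.DiagonalFrame(
            np.zeros((180, 320, 3), np.uint8), orientation=0.0, fov_diagonal=160.0
        )
        with pytest.raises(ValueError, match="FOV"):
            hp.merge_diagonal_pair(all_sky_frame(320, 180, 90.0), bad)

    def test_non_orthogonal_orientations_raise(self):
        with pytest.raises(ValueError, match="orthogonal"):
            hp.merge_diagonal_pair(
                all_sky_frame(320, 180, 90.0), all_sky_frame(320, 180, 50.0)
            )


class TestCircularMask:
    def test_inscribed_circle_area(self):
        cov = hp.apply_circular_mask((512, 512), hp.circular_projection(512))
        assert cov.mean() == pytest.approx(np.pi / 4, abs=0.01)
        for corner in [(0, 0), (0, -1), (-1, 0), (-1, -1)]:
            assert not cov[corner]

    def test_wide_lens_ring_beyond_horizon_excluded(self):
        # a 183-deg lens: the zenith-90 ring sits inside the image circle
        size = 512
        r_image = size / 2.0
        r90 = r_image * 90.0 / 91.5
        proj = hp.ProjectionModel(center=(size / 2, size / 2), radius_px=r90)
        cov = hp.apply_circular_mask((size, size), proj)
        rows, cols = _pixel_center_grid((size, size))
        r = np.hypot(rows - size / 2, cols - size / 2)
        theta = r / r90 * 90.0
        assert not cov[(theta > 90.0) & (r <= r_image)].any()
        assert cov[theta <= 90.0].all()

    def test_circle_exceeding_raster_raises(self):
        with pytest.raises(ValueError):
            hp.apply_circular_mask((100, 100), hp.circular_projection(512))


class TestHemisphereRaster:
    def test_sky_outside_coverage_rejected(self):
        sky = np.ones((4, 4), bool)
        cov = np.zeros((4, 4), bool)
        with pytest.raises(ValueError):
            hp.HemisphereRaster(sky, cov, hp.circular_projection(4))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hp.HemisphereRaster(
                np.zeros((4, 4), bool), np.zeros((4, 5), bool), hp.circular_projection(4)
            )
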