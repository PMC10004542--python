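"""DISC kernel: similarity score, point matching, field assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import discmotion as dm
from discmotion.core import (
    InvalidPointError,
    UndefinedSimilarityError,
    lattice_axes,
    patch_similarity,
)


def _ncc_oracle(a, b):
    """Direct summation of the non-centered cross-correlation score."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


class TestPatchSimilarity:
    def test_identical_patch_is_exactly_one(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 255, (7, 7))
        assert patch_similarity(p, p) == 1.0

    def test_positive_scalar_multiple_is_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1, 255, (5, 5))
        assert patch_similarity(p, 0.5 * p) == 1.0
        assert patch_similarity(0.25 * p, p) == 1.0

    def test_orthogonal_supports_give_zero(self):
        a = np.array([[1.0, 0.0], [0.0, 0.0]])
        b = np.array([[0.0, 0.0], [0.0, 1.0]])
        assert patch_similarity(a, b) == 0.0

    def test_independent_speckle_strictly_between_zero_and_one(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 255, (21, 21))
        b = rng.uniform(0, 255, (21, 21))
        s = patch_similarity(a, b)
        assert 0.0 < s < 1.0
        assert s == pytest.approx(_ncc_oracle(a, b), abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shapes differ"):
            patch_similarity(np.ones((2, 2)), np.ones((3, 3)))

    def test_all_zero_patch_raises_undefined(self):
        with pytest.raises(UndefinedSimilarityError):
            patch_similarity(np.zeros((3, 3)), np.ones((3, 3)))

    @given(
        arrays(np.float64, (4, 4), elements=st.floats(0, 255, allow_nan=False)),
        arrays(np.float64, (4, 4), elements=st.floats(0, 255, allow_nan=False)),
    )
    def test_bounded_and_symmetric(self, a, b):
        """Cauchy-Schwarz bound and argument symmetry for non-negative patches."""
        if a.sum() == 0 or b.sum() == 0:
            return
        s = patch_similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == patch_similarity(b, a)


class TestMatchPoint:
    def test_same_frame_is_exact_null_match(self, speckle_frame, small_grid):
        u, v, peak = dm.match_point(speckle_frame, speckle_frame, (80, 80), small_grid)
        assert (u, v, peak) == (0.0, 0.0, 1.0)

    def test_integer_translation_recovered_exactly(self, speckle_frame, small_grid):
        shifted = dm.GrayFrame(
            np.roll(np.roll(speckle_frame.pixels, 3, axis=0), -2, axis=1)
        )
        u, v, peak = dm.match_point(speckle_frame, shifted, (80, 80), small_grid)
        assert (u, v) == (3.0, -2.0)
        assert peak == pytest.approx(1.0, abs=1e-9)

    def test_translation_beyond_radius_clamps_to_boundary_with_low_peak(
        self, speckle_frame, small_grid
    ):
        r = small_grid.search_radius
        # shift just beyond the radius: the similarity surface still rises
        # toward the true displacement, so the peak sits on the boundary
        big = dm.GrayFrame(np.roll(speckle_frame.pixels, r + 2, axis=0))
        u, v, peak = dm.match_point(speckle_frame, big, (80, 80), small_grid)
        assert abs(u) == r
        _, _, peak_in = dm.match_point(
            speckle_frame,
            dm.GrayFrame(np.roll(speckle_frame.pixels, 2, axis=0)),
            (80, 80),
            small_grid,
        )
        assert peak_in == 1.0
        assert peak < 0.99

    def test_out_of_bounds_center_is_rejected_not_clamped(self, speckle_frame, small_grid):
        with pytest.raises(InvalidPointError):
            dm.match_point(speckle_frame, speckle_frame, (2, 80), small_grid)
        with pytest.raises(InvalidPointError):
            # subset fits but the search window does not
            dm.match_point(speckle_frame, speckle_frame, (11, 80), small_grid)


class TestComputeField:
    def test_self_field_is_zero_with_unit_peaks(self, speckle_frame, analysis_grid):
        fld = dm.compute_field(speckle_frame, speckle_frame, analysis_grid, subpixel=True)
        assert fld.n_valid > 0
        assert np.all(fld.u[fld.valid] == 0.0)
        assert np.all(fld.v[fld.valid] == 0.0)
        assert np.all(fld.peak_similarity[fld.valid] == 1.0)

    def test_global_translation_gives_constant_field(self, speckle_frame, analysis_grid):
        shifted = dm.GrayFrame(
            np.roll(np.roll(speckle_frame.pixels, -4, axis=0), 5, axis=1)
        )
        fld = dm.compute_field(speckle_frame, shifted, analysis_grid, subpixel=False)
        # exact recovery at every interior grid point (rolled texture is periodic)
        assert np.all(fld.u[fld.valid] == -4.0)
        assert np.all(fld.v[fld.valid] == 5.0)

    def test_localized_bump_peaks_at_center_and_decays(self, analysis_grid):
        from discmotion.synthetic import DeformationTemplate, Lobe, make_speckle, template_field, warp

        base = make_speckle((200, 200), seed=3)
        tpl = DeformationTemplate("happy", (Lobe((100, 100), 25.0, (0.6, 0.8)),))
        warped, _ = warp(base, template_field(tpl, (200, 200), scale=4.0))
        fld = dm.compute_field(base, warped, analysis_grid, subpixel=True)
        mag = fld.magnitude
        gx, gy = np.meshgrid(fld.xs, fld.ys, indexing="ij")
        dist = np.hypot(gx - 100.0, gy - 100.0)
        peak_idx = np.unravel_index(np.nanargmax(mag), mag.shape)
        assert dist[peak_idx] <= 25.0  # magnitude peaks near the bump center
        far = fld.valid & (dist > 90.0)
        assert np.nanmax(mag[far]) < 0.2  # and decays to (near) zero away from it

    def test_invariant_under_intensity_rescaling(self, speckle_frame, analysis_grid):
        shifted = dm.GrayFrame(np.roll(speckle_frame.pixels, 2, axis=1))
        a = dm.compute_field(speckle_frame, shifted, analysis_grid, subpixel=True)
        b = dm.compute_field(
            dm.GrayFrame(speckle_frame.pixels * 0.5), shifted, analysis_grid, subpixel=True
        )
        c = dm.compute_field(
            speckle_frame, dm.GrayFrame(shifted.pixels * 0.25), analysis_grid, subpixel=True
        )
        for other in (b, c):
            assert np.array_equal(a.u, other.u, equal_nan=True)
            assert np.array_equal(a.v, other.v, equal_nan=True)

    def test_deterministic_rerun_is_bit_identical(self, speckle_frame, analysis_grid):
        shifted = dm.GrayFrame(np.roll(speckle_frame.pixels, 1, axis=0))
        a = dm.compute_field(speckle_frame, shifted, analysis_grid, subpixel=True)
        b = dm.compute_field(speckle_frame, shifted, analysis_grid, subpixel=True)
        assert np.array_equal(a.u, b.u, equal_nan=True)
        assert np.array_equal(a.peak_similarity, b.peak_similarity, equal_nan=True)

    def test_too_small_frame_raises_lattice_error(self, analysis_grid):
        tiny = dm.GrayFrame(np.full((30, 30), 100.0))
        with pytest.raises(dm.LatticeError):
            dm.compute_field(tiny, tiny, analysis_grid)

    def test_lattice_points_lie_on_regular_grid(self, speckle_frame, analysis_grid):
        xs, ys = lattice_axes(speckle_frame.pixels.shape, analysis_grid)
        assert np.all(np.diff(xs) == analysis_grid.step)
        assert xs[0] == analysis_grid.half
        fld = dm.compute_field(speckle_frame, speckle_frame, analysis_grid)
        pts = fld.points
        assert set(pts[:, 0]).issubset(set(xs))
        assert set(pts[:, 1]).issubset(set(ys))
        # displacement bounded by the search radius
        assert np.all(np.abs(fld.u[fld.valid]) <= analysis_grid.search_radius)
        assert np.all(np.abs(fld.v[fld.valid]) <= analysis_grid.search_radius)


class TestFieldMagnitude:
    def test_three_four_five(self, speckle_frame, analysis_grid):
        fld = dm.compute_field(speckle_frame, speckle_frame, analysis_grid)
        object.__setattr__(fld, "u", np.where(fld.valid, 3.0, np.nan))
        object.__setattr__(fld, "v", np.where(fld.valid, 4.0, np.nan))
        mag = dm.field_magnitude(fld)
        assert np.all(mag[fld.valid] == 5.0)

    def test_matches_elementwise_oracle(self, speckle_frame, analysis_grid):
        rng = np.random.default_rng(4)
        fld = dm.compute_field(speckle_frame, speckle_frame, analysis_grid)
        u = np.where(fld.valid, rng.normal(size=fld.u.shape), np.nan)
        v = np.where(fld.valid, rng.normal(size=fld.v.shape), np.nan)
        object.__setattr__(fld, "u", u)
        object.__setattr__(fld, "v", v)
        expected = np.sqrt(u**2 + v**2)
        assert np.allclose(dm.field_magnitude(fld)[fld.valid], expected[fld.valid])


class TestGridSpec:
    def test_even_subset_adjusted_to_odd(self):
        grid = dm.GridSpec(subset_size=84, step=20, search_radius=10)
        assert grid.subset_size == 85

    @pytest.mark.parametrize("kwargs", [dict(step=0), dict(search_radius=0), dict(subset_size=1)])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            dm.GridSpec(**{"subset_size": 21, "step": 4, "search_radius": 3, **kwargs})


class TestGrayFrame:
    def test_out_of_range_intensities_rejected(self):
        with pytest.raises(ValueError):
            dm.GrayFrame(np.full((4, 4), 300.0))
        with pytest.raises(ValueError):
            dm.GrayFrame(np.full((4, 4), np.nan))

    def test_color_input_converted_with_luma_weights(self):
        rgb = np.zeros((4, 4, 3))
        rgb[..., 1] = 100.0
        frame = dm.GrayFrame(rgb)
        assert np.allclose(frame.pixels, 58.7)
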