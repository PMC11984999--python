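"""Metadata-driven harmonization: rescale, inversion, flip, resize."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fedmammo import (
    DicomMeta,
    PhantomSpec,
    align_laterality,
    apply_rescale,
    generate_phantom,
    invert_pixels,
    preprocess,
    resize_with_spacing,
    should_invert,
)
from fedmammo.preprocess import _resize


class TestApplyRescale:
    @pytest.mark.parametrize(
        "stored, slope, intercept, expected",
        [
            (100, 1.0, 0.0, 100.0),
            (100, 1.0, -1024.0, -924.0),
            (2000, 0.001, 0.0, 2.0),
        ],
    )
    def test_linear_formula(self, stored, slope, intercept, expected):
        out = apply_rescale(np.array([[stored]]), slope, intercept)
        assert out[0, 0] == pytest.approx(expected)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            apply_rescale(np.ones((2, 2)), 0.0, 0.0)

    def test_shape_preserved(self, rng):
        x = rng.integers(0, 100, (5, 7))
        assert apply_rescale(x, 2.0, 1.0).shape == (5, 7)


class TestShouldInvert:
    @pytest.mark.parametrize(
        "sign, photometric, lut, expected",
        [
            (1, "MONOCHROME2", "IDENTITY", True),
            (-1, "MONOCHROME1", "IDENTITY", True),
            (-1, "MONOCHROME2", "INVERSE", True),
            (-1, "MONOCHROME2", "IDENTITY", False),
        ],
    )
    def test_triple_condition(self, sign, photometric, lut, expected):
        meta = DicomMeta(
            pixel_intensity_relationship_sign=sign,
            photometric_interpretation=photometric,
            presentation_lut_shape=lut,
        )
        assert should_invert(meta) is expected

    def test_unknown_photometric_rejected(self):
        meta = DicomMeta()
        meta.photometric_interpretation = "PALETTE COLOR"
        with pytest.raises(ValueError, match="photometric"):
            should_invert(meta)


class TestInvertPixels:
    def test_subtracts_from_image_maximum(self):
        out = invert_pixels(np.array([[0, 5], [10, 2]]))
        assert np.array_equal(out, [[10, 5], [0, 8]])

    def test_constant_image_becomes_zero(self):
        assert np.array_equal(invert_pixels(np.array([[7, 7]])), [[0, 0]])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            invert_pixels(np.array([]))

    @settings(max_examples=25, deadline=None)
    @given(
        hnp.arrays(
            np.int64, hnp.array_shapes(min_dims=2, max_dims=2, max_side=6),
            elements=st.integers(0, 1000),
        )
    )
    def test_involution_when_minimum_is_zero(self, x):
        x.flat[0] = 0  # anchor the minimum at zero
        assert np.array_equal(invert_pixels(invert_pixels(x)), x)


class TestAlignLaterality:
    def test_left_is_identity(self, rng):
        x = rng.random((4, 6))
        assert np.array_equal(align_laterality(x, "L"), x)

    def test_right_reverses_columns(self):
        assert np.array_equal(align_laterality(np.array([[1, 2, 3]]), "R"), [[3, 2, 1]])

    def test_double_flip_identity(self, rng):
        x = rng.random((5, 5))
        assert np.array_equal(align_laterality(align_laterality(x, "R"), "R"), x)

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            align_laterality(np.ones((2, 2)), "B")


class TestResizeWithSpacing:
    def test_isotropic_downsample(self, rng):
        x = rng.random((64, 64))
        out = resize_with_spacing(x, (0.703125, 0.703125), (32, 32))
        assert out.shape == (32, 32)

    def test_anisotropic_restores_physical_aspect(self):
        # a disk of physical radius 20 mm sampled at (1.0, 0.5) mm spacing is
        # an ellipse in pixels; after spacing-aware resize it must be round
        rr, cc = np.mgrid[:100, :200]
        disk = (((rr - 50) * 1.0) ** 2 + ((cc - 100) * 0.5) ** 2 <= 20.0**2).astype(float)
        out = resize_with_spacing(disk, (1.0, 0.5), (100, 100)) > 0.5
        rows = np.nonzero(out.any(axis=1))[0]
        cols = np.nonzero(out.any(axis=0))[0]
        height = rows[-1] - rows[0] + 1
        width = cols[-1] - cols[0] + 1
        assert abs(height - width) <= 2

    def test_identity_when_target_equals_input(self, rng):
        x = rng.random((32, 32))
        out = resize_with_spacing(x, (1.0, 1.0), (32, 32))
        assert np.allclose(out, x)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            resize_with_spacing(np.ones((16, 16)), (0.0, 1.0), (8, 8))

    def test_tiny_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            resize_with_spacing(np.ones((16, 16)), (1.0, 1.0), (4, 4))


class TestPreprocess:
    def test_default_output_is_512(self, plain_phantom):
        out = preprocess(plain_phantom)
        assert out.pixels.shape == (512, 512)

    def test_inverted_presentation_is_normalized(self, inverted_profile):
        rec = generate_phantom(PhantomSpec(image_size=(64, 64), seed=1), inverted_profile)
        out = preprocess(rec, target_size=(64, 64))
        assert out.pixels[out.mask].mean() > out.pixels[~out.mask].mean()

    def test_right_breast_moved_left(self, plain_profile):
        rec = generate_phantom(
            PhantomSpec(image_size=(64, 64), laterality="R", seed=8), plain_profile
        )
        out = preprocess(rec, target_size=(64, 64))
        left_mass = out.mask[:, :32].sum() / out.mask.sum()
        assert left_mass > 0.5

    def test_idempotent_on_harmonized_output(self, plain_phantom):
        once = preprocess(plain_phantom, target_size=(128, 128))
        twice = preprocess(once, target_size=(128, 128))
        assert np.allclose(once.pixels, twice.pixels, atol=1e-6)

    def test_mask_stays_aligned_with_breast(self, inverted_profile):
        rec = generate_phantom(
            PhantomSpec(image_size=(96, 96), laterality="R", seed=21), inverted_profile
        )
        out = preprocess(rec, target_size=(64, 64))
        # threshold at the midpoint between breast and background levels
        level = (out.pixels[out.mask].mean() + out.pixels[~out.mask].mean()) / 2
        thresholded = out.pixels > level
        inter = (thresholded & out.mask).sum()
        dice = 2 * inter / (thresholded.sum() + out.mask.sum())
        assert dice >= 0.95

    def test_provenance_records_all_steps(self, plain_phantom):
        out = preprocess(plain_phantom, target_size=(64, 64))
        steps = [e["step"] for e in out.provenance]
        assert steps == ["rescale", "invert", "clip", "align_laterality", "resize"]

    def test_rank_order_preserved_by_monotone_steps(self, inverted_profile):
        rec = generate_phantom(PhantomSpec(image_size=(64, 64), seed=2), inverted_profile)
        px = apply_rescale(rec.pixels, rec.meta.rescale_slope, rec.meta.rescale_intercept)
        if should_invert(rec.meta):
            px = invert_pixels(px)
        # display-order comparison: MONOCHROME1 stored values are reversed
        a, b = rec.pixels.ravel()[:2].astype(float)
        fa, fb = px.ravel()[:2]
        if a != b:
            assert (a < b) == (fa > fb)


def test_internal_resize_mask_stays_binary(plain_phantom):
    mask = plain_phantom.mask
    out = _resize(mask, (64, 64), order=0)
    assert out.dtype == bool
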