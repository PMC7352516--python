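import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stainslice import (
    DEFAULT_NARROW_RANGES,
    GreyImage,
    IntensityRange,
    binary_mask,
    overlay,
    range_share,
    slice_all,
    slice_image,
)
from stainslice.slicing import kept_mask

BOUNDARY_LEVELS = {130, 160, 180, 200, 220, 240}


def _img(values) -> GreyImage:
    return GreyImage(np.array(values, np.uint8))


class TestMacroSemantics:
    @pytest.mark.parametrize(
        "value,kept",
        [(170, True), (160, False), (180, False), (100, False), (161, True), (179, True)],
    )
    def test_both_boundaries_whitened(self, value, kept):
        sl = slice_image(_img([[value]]), IntensityRange(160, 180))
        assert bool(sl.kept_mask[0, 0]) is kept
        assert sl.image.pixels[0, 0] == (value if kept else 255)

    def test_lo_zero_keeps_level_zero(self):
        sl = slice_image(_img([[0, 129, 130]]), IntensityRange(0, 130))
        assert sl.kept_mask.tolist() == [[True, True, False]]

    def test_worked_3x3(self, worked_3x3):
        sl = slice_image(worked_3x3, IntensityRange(160, 180))
        assert sl.kept_mask.sum() == 1 and sl.kept_mask[0, 2]
        assert sl.image.pixels[0, 2] == 170
        assert (sl.image.pixels[~sl.kept_mask] == 255).all()

    def test_inclusive_lower_mode(self):
        m = kept_mask(np.array([160, 170, 180]), IntensityRange(160, 180), "inclusive-lower")
        assert m.tolist() == [True, True, False]

    def test_level_255_never_kept(self):
        sl = slice_image(_img([[255, 250]]), IntensityRange(240, 255))
        assert sl.kept_mask.tolist() == [[False, True]]


class TestSliceAll:
    def test_partition_one_pixel_per_level(self, one_per_level):
        slices = slice_all(one_per_level)
        assert len(slices) == 7
        total = sum(s.kept_mask.sum() for s in slices)
        assert total == 249  # 256 levels - 6 shared boundaries - white 255
        # every non-boundary level below 255 kept in exactly one range
        for level in range(256):
            n = sum(
                int(s.kept_mask[one_per_level.pixels == level].any()) for s in slices
            )
            expected = 0 if (level in BOUNDARY_LEVELS or level == 255) else 1
            assert n == expected, level

    def test_single_full_range(self, one_per_level):
        (sl,) = slice_all(one_per_level, (IntensityRange(0, 255),))
        assert sl.kept_mask.sum() == 255  # everything but white

    def test_blank_region_keeps_nothing(self):
        img = _img(np.full((5, 5), 255))
        assert all(s.kept_mask.sum() == 0 for s in slice_all(img))

    def test_conservation_random_image(self):
        rng = np.random.default_rng(3)
        img = GreyImage(rng.integers(0, 256, (32, 32)).astype(np.uint8))
        kept = sum(s.kept_mask.sum() for s in slice_all(img))
        boundary = sum((img.pixels == b).sum() for b in BOUNDARY_LEVELS)
        white = (img.pixels == 255).sum()
        assert kept + boundary + white == img.pixels.size

    def test_overlapping_ranges_warn(self, one_per_level):
        with pytest.warns(UserWarning, match="overlap"):
            slice_all(one_per_level, (IntensityRange(0, 100), IntensityRange(50, 150)))

    @given(st.integers(0, 2**31 - 1))
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        img = GreyImage(rng.integers(0, 256, (8, 8)).astype(np.uint8))
        r = IntensityRange(160, 180)
        once = slice_image(img, r)
        twice = slice_image(once.image, r)
        assert (once.image.pixels == twice.image.pixels).all()
        assert (once.kept_mask == twice.kept_mask).all()


class TestRangeShare:
    def test_constant_170(self):
        shares = range_share(_img(np.full((4, 4), 170)))
        assert shares["160-180"] == 1.0
        assert sum(shares.values()) == 1.0

    def test_one_pixel_per_level_by_enumeration(self, one_per_level):
        shares = range_share(one_per_level)
        for r in DEFAULT_NARROW_RANGES:
            lo = 0 if r.lo == 0 else r.lo + 1
            expected = (r.hi - lo) / 256
            assert shares[r.label] == pytest.approx(expected)


class TestMaskOverlay:
    def test_all_kept_mask_white(self):
        sl = slice_image(_img(np.full((3, 3), 100)), IntensityRange(0, 130))
        assert (binary_mask(sl) == 255).all()

    def test_none_kept(self, worked_3x3):
        sl = slice_image(worked_3x3, IntensityRange(10, 20))
        assert (binary_mask(sl) == 0).all()
        rgb = overlay(worked_3x3, sl)
        assert (rgb == worked_3x3.pixels[:, :, None]).all()

    def test_worked_overlay_red_pixel(self, worked_3x3):
        sl = slice_image(worked_3x3, IntensityRange(160, 180))
        assert binary_mask(sl)[0, 2] == 255 and binary_mask(sl).sum() == 255
        rgb = overlay(worked_3x3, sl)
        assert tuple(rgb[0, 2]) == (255, 0, 0)
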