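import math

import numpy as np
import pytest

from stainslice import GreyImage, default_box_sizes, fractal_features, scan_grid
from stainslice.fractal import FRACTAL_FEATURE_NAMES, usable_box_sizes

SIERPINSKI_D = math.log(8) / math.log(3)  # ~1.8928


def naive_counts(px, dx, dy, sizes):
    """Brute-force per-box double-loop oracle (raw counts, full boxes)."""
    H, W = px.shape
    out = []
    for e in sizes:
        nby, nbx = (H - dy) // e, (W - dx) // e
        n = 0.0
        h = e * 256.0 / min(H, W)
        for by in range(nby):
            for bx in range(nbx):
                box = px[dy + by * e : dy + (by + 1) * e, dx + bx * e : dx + (bx + 1) * e]
                n += math.floor(box.max() / h) - math.floor(box.min() / h) + 1
        out.append(n * W * H / (nbx * nby * e * e))
    return np.array(out)


class TestScanGrid:
    def test_default_series_has_191_sizes(self):
        assert len(default_box_sizes()) == 191
        assert default_box_sizes()[0] == 5 and default_box_sizes()[-1] == 575

    def test_constant_image_dimension_two(self):
        img = GreyImage(np.full((200, 200), 128, np.uint8))
        scan = scan_grid(img)
        assert scan.d == pytest.approx(2.0, abs=0.01)
        assert scan.r2 > 0.999

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(4)
        px = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        sizes = np.array([5, 6, 7, 8])
        for off in [(0, 0), (2, 3)]:
            scan = scan_grid(GreyImage(px), off, sizes)
            assert np.allclose(scan.counts, naive_counts(px, off[0], off[1], sizes))

    def test_oversized_boxes_dropped(self):
        img = GreyImage(np.full((64, 64), 10, np.uint8))
        scan = scan_grid(img, box_sizes=np.array([5, 8, 11, 500]))
        assert scan.box_sizes.tolist() == [5, 8, 11]

    def test_too_few_sizes_raise(self):
        img = GreyImage(np.full((64, 64), 10, np.uint8))
        with pytest.raises(ValueError, match="smaller than the smallest"):
            scan_grid(img, box_sizes=np.array([100, 200, 300]))
        with pytest.raises(ValueError, match="fewer than 3"):
            scan_grid(img, box_sizes=np.array([5, 8]))


class TestFractalFeatures:
    def test_exactly_23_features(self):
        assert len(FRACTAL_FEATURE_NAMES) == 23
        img = GreyImage(np.full((80, 80), 100, np.uint8))
        assert len(fractal_features(img, n_grids=2).as_dict()) == 23

    def test_constant_image_analytics(self):
        img = GreyImage(np.full((200, 200), 128, np.uint8))
        f = fractal_features(img)
        assert f.d_b == pytest.approx(2.0, abs=0.01)
        assert f.d_m == pytest.approx(2.0, abs=0.01)
        assert f.sd_d_b == pytest.approx(0.0, abs=1e-12)
        for name in ("lam", "lam_prime", "lam_min", "lam_max", "cv_lam_g", "cv_lam_prime_g"):
            assert getattr(f, name) == 0.0, name
        assert f.d_b_min - 1e-12 <= f.d_b <= f.d_b_max + 1e-12

    def test_sierpinski_binary_dimension(self, sierpinski6):
        scan = scan_grid(sierpinski6, counting="binary")
        assert scan.d == pytest.approx(SIERPINSKI_D, abs=0.06)

    def test_translation_robustness(self, sierpinski6):
        base = scan_grid(sierpinski6, counting="binary").d
        rolled = GreyImage(np.roll(sierpinski6.pixels, (7, 7), axis=(0, 1)))
        shifted = scan_grid(rolled, counting="binary").d
        assert abs(base - shifted) < 0.02

    def test_grid_determinism(self):
        rng = np.random.default_rng(9)
        img = GreyImage(rng.integers(0, 256, (90, 90)).astype(np.uint8))
        f1 = fractal_features(img, n_grids=6, seed=5)
        f2 = fractal_features(img, n_grids=6, seed=5)
        assert f1 == f2
        f3 = fractal_features(img, n_grids=6, seed=6)
        assert f1 != f3

    def test_lacunarity_detects_concentrated_mass(self):
        """One dark blob is gappier than uniform coverage at equal total mass."""
        blob = np.full((100, 100), 255, np.uint8)
        blob[40:60, 40:60] = 0  # 400 px * 255 mass
        uniform = np.full((100, 100), 255 - round(400 * 255 / 10000), np.uint8)
        f_blob = fractal_features(GreyImage(blob), n_grids=4)
        f_uni = fractal_features(GreyImage(uniform), n_grids=4)
        assert f_uni.lam_prime == 0.0
        assert f_blob.lam_prime > f_uni.lam_prime

    def test_blank_image_flags_mass_dimension(self):
        f = fractal_features(GreyImage(np.full((80, 80), 255, np.uint8)), n_grids=2)
        assert math.isnan(f.d_m)  # zero mass everywhere
        assert f.d_b == pytest.approx(2.0, abs=0.01)  # still a flat surface

    def test_sd_vs_se_are_distinct_quantities(self):
        rng = np.random.default_rng(2)
        img = GreyImage(rng.integers(0, 256, (120, 120)).astype(np.uint8))
        f = fractal_features(img, n_grids=6)
        assert f.sd_d_b >= 0 and f.se_d_b >= 0 and not math.isclose(f.sd_d_b, f.se_d_b)


class TestUsableSizes:
    def test_cap_at_45_percent(self):
        sizes = usable_box_sizes((100, 100), default_box_sizes())
        assert sizes.max() <= 45
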