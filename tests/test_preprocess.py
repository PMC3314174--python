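import numpy as np
import pytest
from scipy import ndimage as ndi

from nucshape.preprocess import (
    GrayImage,
    HullPair,
    RegionMask,
    binarize_otsu,
    build_hulls,
    clean_regions,
    equalize_adaptive,
    near_binarize,
    otsu_threshold,
    stretch_contrast,
)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - center[1]) ** 2 + (yy - center[0]) ** 2 <= radius ** 2


# ---------------------------------------------------------------- CLAHE

def test_equalize_constant_image_stays_constant():
    img = GrayImage(np.full((64, 64), 120, np.uint8))
    out = equalize_adaptive(img)
    assert len(np.unique(out.pixels)) == 1


def test_equalize_moves_tiles_toward_rayleigh():
    """On a linear ramp, the per-tile KS distance to the truncated-Rayleigh
    CDF must decrease after equalization (direct CDF evaluation oracle)."""
    sigma = 0.4
    ramp = np.tile(np.linspace(0, 255, 256, dtype=np.uint8), (256, 1))
    out = equalize_adaptive(GrayImage(ramp), (8, 8), 0.02, "rayleigh", sigma)

    def rayleigh_cdf(x):  # truncated to [0, 1]
        f1 = 1.0 - np.exp(-1.0 / (2 * sigma**2))
        return (1.0 - np.exp(-(x**2) / (2 * sigma**2))) / f1

    def ks_to_rayleigh(tile):
        vals = np.sort(tile.ravel()) / 255.0
        emp = np.arange(1, len(vals) + 1) / len(vals)
        return np.max(np.abs(emp - rayleigh_cdf(vals)))

    improved = 0
    for i in range(8):
        for j in range(8):
            sl = np.s_[i * 32:(i + 1) * 32, j * 32:(j + 1) * 32]
            if ks_to_rayleigh(out.pixels[sl]) < ks_to_rayleigh(ramp[sl]):
                improved += 1
    assert improved >= 48  # large majority of tiles move toward the target


def test_equalize_preserves_rank_order_per_tile():
    rng = np.random.default_rng(0)
    two_tone = rng.choice([10, 200], size=(64, 64)).astype(np.uint8)
    out = equalize_adaptive(GrayImage(two_tone), (4, 4))
    # monotone mapping: every dark input pixel <= every bright input pixel
    # within each tile of the output
    for i in range(4):
        for j in range(4):
            sl = np.s_[i * 16:(i + 1) * 16, j * 16:(j + 1) * 16]
            dark = out.pixels[sl][two_tone[sl] == 10]
            bright = out.pixels[sl][two_tone[sl] == 200]
            assert dark.max() <= bright.min()


def test_equalize_rejects_too_small_image():
    with pytest.raises(ValueError, match="tile grid"):
        equalize_adaptive(GrayImage(np.zeros((4, 4), np.uint8)), (8, 8))


# ---------------------------------------------------------------- Otsu

def test_otsu_bimodal_split():
    px = np.full((10, 10), 10, np.uint8)
    px.ravel()[:40] = 200
    mask = binarize_otsu(GrayImage(px))
    t = otsu_threshold(px)
    assert 10 < t < 200
    assert mask.label_grid.sum() == 40


def test_otsu_matches_brute_force_scan():
    """Threshold equals the argmax of between-class variance found by an
    exhaustive scan over candidate thresholds (oracle on a 3-level image)."""
    px = np.repeat(np.array([0, 100, 255], np.uint8), 300).reshape(30, 30)
    t = otsu_threshold(px)

    vals = px.ravel().astype(float)
    best_t, best_var = None, -1.0
    for cand in range(256):
        lo, hi = vals[vals <= cand], vals[vals > cand]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, cand
    # same partition of the pixel values
    assert (px > t).sum() == (px > best_t).sum()


def test_otsu_cross_check_against_skimage():
    from skimage.filters import threshold_otsu

    rng = np.random.default_rng(1)
    px = np.clip(np.concatenate([rng.normal(60, 10, 500),
                                 rng.normal(180, 15, 500)]), 0, 255)
    px = px.astype(np.uint8).reshape(20, 50)
    ours = otsu_threshold(px)
    theirs = threshold_otsu(px)
    assert (px > ours).sum() == (px > theirs).sum()


def test_otsu_disk_on_black_is_exact():
    px = np.zeros((50, 50), np.uint8)
    d = disk_mask((50, 50), (25, 25), 10)
    px[d] = 255
    mask = binarize_otsu(GrayImage(px))
    assert np.array_equal(mask.label_grid > 0, d)


def test_otsu_constant_image_errors():
    with pytest.raises(ValueError, match="constant"):
        binarize_otsu(GrayImage(np.full((8, 8), 7, np.uint8)))


# ---------------------------------------------------------------- regions

def test_clean_regions_area_and_border_rules():
    grid = np.zeros((200, 200), bool)
    # region of 799 px: 47x17=799
    grid[20:67, 20:37] = True
    # region of 900 px: 45x20
    grid[100:145, 60:80] = True
    # region touching the left border, large
    grid[150:190, 0:40] = True
    out = clean_regions(RegionMask.from_binary(grid), min_area=800)
    assert out.region_count == 1
    kept = out.label_grid > 0
    assert kept.sum() == 900


def test_clean_regions_fills_holes():
    d = disk_mask((60, 60), (30, 30), 20)
    holey = d.copy()
    holey[25:30, 28:38] = False  # 50 px^2 interior hole
    out = clean_regions(RegionMask.from_binary(holey), min_area=10)
    assert (out.label_grid > 0).sum() == d.sum()


def test_clean_regions_idempotent():
    rng = np.random.default_rng(3)
    grid = ndi.binary_dilation(rng.random((120, 120)) > 0.995,
                               np.ones((9, 9), bool))
    once = clean_regions(RegionMask.from_binary(grid), min_area=50)
    twice = clean_regions(once, min_area=50)
    assert np.array_equal(once.label_grid, twice.label_grid)
    assert once.region_count == twice.region_count


# ---------------------------------------------------------------- hulls

def _is_convex_ccw(poly):
    a = poly
    b = np.roll(poly, -1, axis=0)
    c = np.roll(poly, -2, axis=0)
    cross = ((b[:, 0] - a[:, 0]) * (c[:, 1] - b[:, 1])
             - (b[:, 1] - a[:, 1]) * (c[:, 0] - b[:, 0]))
    return np.all(cross >= -1e-9)


def _poly_area(poly):
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def test_build_hulls_disk_radii():
    """Erode 3 + dilate 6 nets +3 px on a disk; the extra erode 2 nets +1."""
    grid = disk_mask((120, 120), (60, 60), 40).astype(np.int32)
    pairs = build_hulls(RegionMask(grid, 1))
    assert len(pairs) == 1
    outer, inner = pairs[0].outer_hull, pairs[0].inner_hull
    assert _poly_area(outer) == pytest.approx(np.pi * 43**2, rel=0.03)
    assert _poly_area(inner) == pytest.approx(np.pi * 41**2, rel=0.03)
    assert _is_convex_ccw(outer) and _is_convex_ccw(inner)
    assert _poly_area(inner) <= _poly_area(outer)


def test_build_hulls_square_region():
    grid = np.zeros((80, 80), np.int32)
    grid[20:60, 20:60] = 1
    pairs = build_hulls(RegionMask(grid, 1))
    outer, inner = pairs[0].outer_hull, pairs[0].inner_hull
    assert _is_convex_ccw(outer) and _is_convex_ccw(inner)
    assert _poly_area(inner) < _poly_area(outer)


def test_build_hulls_drops_fully_eroded_region():
    grid = disk_mask((30, 30), (15, 15), 2).astype(np.int32)
    pairs = build_hulls(RegionMask(grid, 1))
    assert pairs == []


# ---------------------------------------------------------------- stretch

def test_stretch_contrast_ramp():
    px = np.arange(100, dtype=np.uint8).reshape(10, 10)
    out = stretch_contrast(GrayImage(px), 0.01).pixels
    assert out.min() == 0 and out.max() == 255
    flat_in, flat_out = px.ravel(), out.ravel()
    order = np.argsort(flat_in)
    assert np.all(np.diff(flat_out[order].astype(int)) >= 0)  # rank preserved


def test_stretch_contrast_idempotent_on_full_range():
    px = np.linspace(0, 255, 256, dtype=np.uint8).reshape(16, 16)
    out = stretch_contrast(GrayImage(px), 0.0).pixels
    assert np.abs(out.astype(int) - px.astype(int)).max() <= 1


def test_stretch_contrast_suppresses_hot_pixel():
    px = np.random.default_rng(0).integers(0, 100, (32, 32)).astype(np.uint16)
    px[5, 5] = 65535
    out = stretch_contrast(GrayImage(px), 0.01).pixels
    assert np.quantile(out[px < 100], 0.95) > 0.5 * 65535


def test_stretch_constant_unchanged():
    px = np.full((8, 8), 42, np.uint8)
    assert np.array_equal(stretch_contrast(GrayImage(px)).pixels, px)


# ---------------------------------------------------------------- near-binarize

def full_hull(shape):
    h, w = shape
    poly = np.array([[-1.0, -1.0], [w + 0.0, -1.0], [w + 0.0, h + 0.0],
                     [-1.0, h + 0.0]])
    return HullPair(poly, poly, 1)


def test_near_binarize_binary_image_fixed_point():
    px = np.zeros((20, 20), np.uint8)
    px[:, 10:] = 255
    out = near_binarize(GrayImage(px), full_hull((20, 20)), saturate_frac=0.0)
    assert set(np.unique(out.pixels)) <= {0, 255}
    assert np.array_equal(out.pixels > 0, px > 0)


def test_band_map_arithmetic():
    """With threshold T = 100: 40 <= 0.7 T maps to min, 160 > 1.3 T to max,
    100 lands mid-range (linear stretch between the band anchors)."""
    from nucshape.preprocess import apply_band

    px = np.array([[40, 100, 160]], np.uint8)
    out = apply_band(px, 100.0, 0.7, 1.3, 255)
    assert out[0, 0] == 0
    assert out[0, 2] == 255
    assert out[0, 1] == 128  # (100 - 70) / 60 of the range


def test_near_binarize_extremes():
    px = np.zeros((20, 20), np.uint8)
    px[:, :10] = 40
    px[:, 10:] = 160
    out = near_binarize(GrayImage(px), full_hull((20, 20)), saturate_frac=0.0)
    assert np.all(out.pixels[px == 40] == 0)
    assert np.all(out.pixels[px == 160] == 255)


def _reconstruct_by_erosion_oracle(seed, mask):
    """Brute-force grayscale reconstruction by erosion (4-neighbor)."""
    out = seed.astype(int).copy()
    while True:
        padded = np.pad(out, 1, mode="constant", constant_values=10**9)
        eroded = np.minimum.reduce([
            padded[:-2, 1:-1], padded[2:, 1:-1],
            padded[1:-1, :-2], padded[1:-1, 2:], out,
        ])
        nxt = np.maximum(eroded, mask.astype(int))
        if np.array_equal(nxt, out):
            return nxt
        out = nxt


def test_near_binarize_fills_dark_interior():
    """A bright rim with a dark interior becomes a filled bright blob; the
    filled interior matches an independent reconstruction-by-erosion oracle
    on a 20x20 instance."""
    px = np.full((20, 20), 5, np.uint8)
    rim = disk_mask((20, 20), (10, 10), 8) & ~disk_mask((20, 20), (10, 10), 5)
    interior = disk_mask((20, 20), (10, 10), 5)
    px[rim] = 250
    px[interior] = 60
    out = near_binarize(GrayImage(px), full_hull((20, 20)), saturate_frac=0.0)
    assert np.all(out.pixels[interior] == out.pixels[rim].min())

    # oracle check of the gray-scale fill step itself
    seed = np.full_like(px, px.max())
    seed[0, :], seed[-1, :], seed[:, 0], seed[:, -1] = (px[0, :], px[-1, :],
                                                        px[:, 0], px[:, -1])
    from nucshape.preprocess import _fill_gray_holes

    assert np.array_equal(_fill_gray_holes(px),
                          _reconstruct_by_erosion_oracle(seed, px))


def test_near_binarize_constant_hull_errors():
    px = np.full((20, 20), 9, np.uint8)
    with pytest.raises(ValueError, match="threshold"):
        near_binarize(GrayImage(px), full_hull((20, 20)))
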