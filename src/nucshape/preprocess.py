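"""Image preprocessing: adaptive equalization, thresholding, region cleanup,
convex-hull construction and near-binarization.

The pipeline mirrors the classical lamin-rim segmentation recipe: CLAHE with
a Rayleigh target distribution evens out staining variability, Otsu's
threshold separates nuclei from background, small and border-touching
regions are discarded, and per-nucleus convex hulls bracket the boundary
search (an enlarged outer hull as hard limit, a slightly smaller inner hull
as snake initialization). A near-binarized copy of the original image
provides the edge map for the external force field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage import morphology
from skimage.draw import polygon as draw_polygon

logger = logging.getLogger(__name__)

_N_BINS = 256


@dataclass
class GrayImage:
    """2-D grayscale intensity image with explicit bit depth.

    ``pixels`` is a uint8 or uint16 array indexed [row, col]; "lowest" and
    "highest intensity" always refer to the dtype range (0 and 255 or 65535).
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage requires a 2-D array")
        if self.pixels.dtype not in (np.uint8, np.uint16):
            raise ValueError("GrayImage pixels must be uint8 or uint16")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("GrayImage must have width, height >= 1")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def bit_depth(self) -> int:
        return 8 if self.pixels.dtype == np.uint8 else 16

    @property
    def max_value(self) -> int:
        return 255 if self.pixels.dtype == np.uint8 else 65535


@dataclass
class RegionMask:
    """Labeled region image: 0 = background, k in 1..region_count = region k."""

    label_grid: np.ndarray
    region_count: int

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid)
        if self.label_grid.ndim != 2:
            raise ValueError("label_grid must be 2-D")

    @classmethod
    def from_binary(cls, fg: np.ndarray) -> "RegionMask":
        fg = np.asarray(fg, bool)
        return cls(fg.astype(np.int32), int(fg.any()))


@dataclass
class HullPair:
    """Outer and inner convex hulls bracketing one nucleus boundary.

    Hull polygons are (m, 2) arrays of (x, y) pixel-center coordinates in
    counter-clockwise order. The outer hull is the hard outer limit for the
    active contour; the inner hull is its initialization.
    """

    outer_hull: np.ndarray
    inner_hull: np.ndarray
    region_label: int


def as_gray(img) -> GrayImage:
    return img if isinstance(img, GrayImage) else GrayImage(np.asarray(img))


# ---------------------------------------------------------------------------
# Contrast-limited adaptive histogram equalization (CLAHE)
# ---------------------------------------------------------------------------

def _tile_lut(tile: np.ndarray, clip_limit: float, distribution: str,
              sigma: float, n_bins: int) -> np.ndarray:
    """Clipped-histogram mapping for one tile, as an ``n_bins``-entry LUT
    in [0, 1]."""
    n_pix = tile.size
    hist = np.bincount(tile.ravel(), minlength=n_bins).astype(float)
    # clip count per bin: at least the uniform bin load, plus the configured
    # fraction of the remaining pixels
    min_clip = np.ceil(n_pix / n_bins)
    clip = min_clip + round(clip_limit * (n_pix - min_clip))
    for _ in range(4):  # redistribute excess; a few passes suffice
        excess = np.sum(np.maximum(hist - clip, 0.0))
        if excess <= 0.5:
            break
        hist = np.minimum(hist, clip)
        hist += excess / n_bins
    cdf = np.cumsum(hist) / np.sum(hist)
    if distribution == "uniform":
        return cdf
    if distribution == "rayleigh":
        # inverse-CDF match to a Rayleigh truncated to the unit output range
        f1 = 1.0 - np.exp(-1.0 / (2.0 * sigma * sigma))
        return sigma * np.sqrt(-2.0 * np.log1p(-cdf * f1))
    raise ValueError(f"unknown target distribution: {distribution!r}")


def equalize_adaptive(img, tile_grid: tuple[int, int] = (8, 8),
                      clip_limit: float = 0.02,
                      target_distribution: str = "rayleigh",
                      rayleigh_sigma: float = 0.4,
                      n_bins: int = 64) -> GrayImage:
    """Contrast-limited adaptive histogram equalization toward a target
    distribution, with bilinear blending between neighboring tile mappings.

    The image is split into a ``tile_grid`` of tiles; each tile's histogram
    is clipped at ``clip_limit`` (fraction of tile pixels above the uniform
    bin load), excess redistributed, and the clipped CDF mapped through the
    inverse CDF of the target distribution (Rayleigh with scale
    ``rayleigh_sigma``, truncated to the intensity range, or uniform).

    ``n_bins`` sets the histogram resolution and thereby how aggressively
    narrow (noise-only) tile histograms are suppressed by the clip limit:
    a coarser histogram concentrates background noise into few bins whose
    counts exceed the clip, so noise-only tiles keep a nearly flat mapping
    instead of being stretched to full range.
    """
    gi = as_gray(img)
    gr, gc = int(tile_grid[0]), int(tile_grid[1])
    if gr < 1 or gc < 1:
        raise ValueError("tile_grid entries must be >= 1")
    h, w = gi.pixels.shape
    if h < gr or w < gc:
        raise ValueError(
            f"image {h}x{w} smaller than tile grid; needs at least "
            f"{gr}x{gc} pixels (one pixel per tile)"
        )
    maxv = gi.max_value
    # pad so tiles divide evenly (reflective padding, cropped afterwards)
    th = -(-h // gr)
    tw = -(-w // gc)
    ph, pw = th * gr - h, tw * gc - w
    padded = np.pad(gi.pixels, ((0, ph), (0, pw)), mode="reflect")
    bins = (padded.astype(np.int64) * (n_bins - 1) + maxv // 2) // maxv

    luts = np.empty((gr, gc, n_bins))
    for i in range(gr):
        for j in range(gc):
            tile = bins[i * th:(i + 1) * th, j * tw:(j + 1) * tw]
            luts[i, j] = _tile_lut(tile, clip_limit, target_distribution,
                                   rayleigh_sigma, n_bins)

    # bilinear blend between the four surrounding tile-center mappings
    rows = np.arange(padded.shape[0])
    cols = np.arange(padded.shape[1])
    fr = np.clip((rows + 0.5) / th - 0.5, 0.0, gr - 1.0)
    fc = np.clip((cols + 0.5) / tw - 0.5, 0.0, gc - 1.0)
    r0 = np.minimum(fr.astype(int), gr - 1)
    c0 = np.minimum(fc.astype(int), gc - 1)
    r1 = np.minimum(r0 + 1, gr - 1)
    c1 = np.minimum(c0 + 1, gc - 1)
    wr = (fr - r0)[:, None]
    wc = (fc - c0)[None, :]
    R0 = r0[:, None]
    R1 = r1[:, None]
    C0 = c0[None, :]
    C1 = c1[None, :]
    out = ((1 - wr) * (1 - wc) * luts[R0, C0, bins]
           + (1 - wr) * wc * luts[R0, C1, bins]
           + wr * (1 - wc) * luts[R1, C0, bins]
           + wr * wc * luts[R1, C1, bins])
    out = out[:h, :w]
    out = np.clip(np.rint(out * maxv), 0, maxv).astype(gi.pixels.dtype)
    return GrayImage(out)


# ---------------------------------------------------------------------------
# Thresholding and region cleanup
# ---------------------------------------------------------------------------

def otsu_threshold(pixels: np.ndarray) -> float:
    """Otsu threshold maximizing between-class variance over the histogram.

    Scans the 256-level histogram of the intensity range and returns the
    threshold (in original intensity units) with maximal between-class
    variance; foreground is defined as ``pixels > threshold``. Ties are
    broken by the lowest threshold.
    """
    pixels = np.asarray(pixels)
    vmin, vmax = int(pixels.min()), int(pixels.max())
    if vmin == vmax:
        raise ValueError("Otsu threshold undefined for a constant image")
    # bin the observed range into 256 levels
    span = vmax - vmin
    bins = ((pixels.astype(np.int64) - vmin) * (_N_BINS - 1) + span // 2) // span
    hist = np.bincount(bins.ravel(), minlength=_N_BINS).astype(float)
    p = hist / hist.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * np.arange(_N_BINS))
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    # tied maxima form a plateau across empty histogram gaps; take its
    # midpoint so the threshold sits between the classes
    k = float(np.mean(np.nonzero(sigma_b == sigma_b.max())[0]))
    # threshold placed between class k and k+1, mapped back to intensity units
    return vmin + (k + 0.5) * span / (_N_BINS - 1)


def binarize_otsu(img) -> RegionMask:
    """Binarize with Otsu's method; pixels above the threshold are foreground."""
    gi = as_gray(img)
    t = otsu_threshold(gi.pixels)
    return RegionMask.from_binary(gi.pixels > t)


def clean_regions(mask: RegionMask, min_area: float = 800.0,
                  connectivity: int = 8) -> RegionMask:
    """Fill holes, drop border-touching and small regions, relabel 1..n.

    Foreground connectivity is 8 by default (with the complementary
    4-connected background for hole filling). Any region with a pixel in the
    first/last row or column is removed, as is any region with fewer than
    ``min_area`` pixels.
    """
    fg = mask.label_grid > 0
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = (np.ones((3, 3), bool) if connectivity == 8
                 else ndi.generate_binary_structure(2, 1))
    # hole filling with the complementary background connectivity
    fill_structure = (ndi.generate_binary_structure(2, 1) if connectivity == 8
                      else np.ones((3, 3), bool))
    fg = ndi.binary_fill_holes(fg, structure=fill_structure)
    labeled, n = ndi.label(fg, structure=structure)
    if n == 0:
        return RegionMask(labeled.astype(np.int32), 0)
    border = np.zeros_like(fg)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_labels = np.unique(labeled[border & fg])
    areas = np.bincount(labeled.ravel(), minlength=n + 1)
    keep = np.ones(n + 1, bool)
    keep[0] = False
    keep[border_labels[border_labels > 0]] = False
    keep[areas < min_area] = False
    remap = np.zeros(n + 1, np.int32)
    remap[keep] = np.arange(1, int(keep.sum()) + 1)
    return RegionMask(remap[labeled], int(keep.sum()))


# ---------------------------------------------------------------------------
# Convex hulls
# ---------------------------------------------------------------------------

def _hull_polygon(region: np.ndarray) -> np.ndarray | None:
    """Convex hull (CCW (x, y) polygon) of the True pixels of a mask."""
    rows, cols = np.nonzero(region)
    if len(rows) < 3:
        return None
    pts = np.column_stack([cols, rows]).astype(float)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None
    return pts[hull.vertices]  # scipy returns CCW order for 2-D


def build_hulls(mask: RegionMask, outer_erode_r: int = 3,
                outer_dilate_r: int = 6,
                inner_erode_r: int = 2) -> list[HullPair]:
    """Per-region outer/inner convex hulls for snake initialization.

    Each region is eroded by a disk of ``outer_erode_r`` then dilated by a
    disk of ``outer_dilate_r``; the convex hull of the result is the outer
    hull (the search limit). The smoothed, enlarged region is then eroded by
    a disk of ``inner_erode_r`` and its convex hull is the inner hull (the
    snake's start). Regions eroded to fewer than 3 pixels are dropped with a
    warning.
    """
    pairs: list[HullPair] = []
    grid = mask.label_grid
    pad = outer_dilate_r + 1
    slices = ndi.find_objects(grid)
    for label_idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        region = grid[sl] == label_idx
        region = np.pad(region, pad)
        smoothed = morphology.erosion(region, morphology.disk(outer_erode_r))
        smoothed = morphology.dilation(smoothed, morphology.disk(outer_dilate_r))
        inner_region = morphology.erosion(smoothed, morphology.disk(inner_erode_r))
        outer = _hull_polygon(smoothed)
        inner = _hull_polygon(inner_region)
        if outer is None or inner is None:
            logger.warning("region %d eroded away during hull construction; dropped",
                           label_idx)
            continue
        offset = np.array([sl[1].start - pad, sl[0].start - pad], float)
        pairs.append(HullPair(outer + offset, inner + offset, label_idx))
    return pairs


# ---------------------------------------------------------------------------
# Intensity adjustment for the external-force image
# ---------------------------------------------------------------------------

def stretch_contrast(img, saturate_frac: float = 0.01) -> GrayImage:
    """Linear contrast stretch saturating ``saturate_frac`` of pixels at each
    end of the intensity range. A constant image is returned unchanged."""
    if not (0.0 <= saturate_frac < 0.5):
        raise ValueError("saturate_frac must be in [0, 0.5)")
    gi = as_gray(img)
    px = gi.pixels
    lo = float(np.quantile(px, saturate_frac))
    hi = float(np.quantile(px, 1.0 - saturate_frac))
    if hi <= lo:
        return GrayImage(px.copy())
    maxv = gi.max_value
    out = (px.astype(float) - lo) / (hi - lo)
    out = np.clip(np.rint(out * maxv), 0, maxv).astype(px.dtype)
    return GrayImage(out)


def _fill_gray_holes(px: np.ndarray) -> np.ndarray:
    """Fill gray-scale holes (intensity basins not reachable from the image
    border) by morphological reconstruction by erosion."""
    seed = np.full_like(px, px.max())
    seed[0, :] = px[0, :]
    seed[-1, :] = px[-1, :]
    seed[:, 0] = px[:, 0]
    seed[:, -1] = px[:, -1]
    return morphology.reconstruction(seed, px, method="erosion").astype(px.dtype)


def hull_raster_mask(hull: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside a hull polygon."""
    rr, cc = draw_polygon(hull[:, 1], hull[:, 0], shape=shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def apply_band(px: np.ndarray, threshold: float, low_frac: float,
               high_frac: float, maxv: int) -> np.ndarray:
    """Near-binarization band map: values below ``low_frac``·T to 0, above
    ``high_frac``·T to ``maxv``, the band between stretched linearly."""
    lo_t, hi_t = low_frac * threshold, high_frac * threshold
    out = (px.astype(float) - lo_t) / (hi_t - lo_t)
    return np.clip(np.rint(out * maxv), 0, maxv).astype(px.dtype)


def near_binarize(img, hull: HullPair, low_frac: float = 0.7,
                  high_frac: float = 1.3,
                  saturate_frac: float = 0.01) -> GrayImage:
    """Near-binarized single-nucleus image for the external force field.

    Pixels outside the outer hull are zeroed; the image is contrast
    stretched; the Otsu threshold T is computed (not applied); pixels below
    ``low_frac``·T are set to the lowest intensity and pixels above
    ``high_frac``·T to the highest, with the band between stretched linearly
    to the full range; finally gray-scale holes (the dark nuclear interior
    enclosed by the bright rim) are filled.

    Raises ``ValueError`` if the hull interior is constant (no threshold).
    """
    gi = as_gray(img)
    maxv = gi.max_value
    inside = hull_raster_mask(hull.outer_hull, gi.pixels.shape)
    px = np.where(inside, gi.pixels, 0).astype(gi.pixels.dtype)
    px = stretch_contrast(GrayImage(px), saturate_frac).pixels
    if px.min() == px.max():
        raise ValueError("constant intensity inside hull: cannot threshold")
    t = otsu_threshold(px)
    out = apply_band(px, t, low_frac, high_frac, maxv)
    out = _fill_gray_holes(out)
    return GrayImage(out)
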