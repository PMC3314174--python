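"""End-to-end nucleus boundary extraction and contour curation."""

from __future__ import annotations

import logging

import numpy as np

from nucshape.contour import Contour, point_in_polygon
from nucshape.gvf import compute_gvf
from nucshape.preprocess import (
    GrayImage,
    HullPair,
    as_gray,
    binarize_otsu,
    build_hulls,
    clean_regions,
    equalize_adaptive,
    near_binarize,
    stretch_contrast,
)
from nucshape.snake import SnakeCollapseError, evolve_snake

logger = logging.getLogger(__name__)

_CROP_MARGIN = 4  # pixels of context kept around the outer hull


def _crop_bounds(hull: np.ndarray, shape: tuple[int, int]) -> tuple[int, int, int, int]:
    x0 = max(int(np.floor(hull[:, 0].min())) - _CROP_MARGIN, 0)
    x1 = min(int(np.ceil(hull[:, 0].max())) + _CROP_MARGIN + 1, shape[1])
    y0 = max(int(np.floor(hull[:, 1].min())) - _CROP_MARGIN, 0)
    y1 = min(int(np.ceil(hull[:, 1].max())) + _CROP_MARGIN + 1, shape[0])
    return x0, x1, y0, y1


def extract_nuclei(img, config, image_id: str = "") -> list[Contour]:
    """Extract one sub-pixel boundary contour per detected nucleus.

    Runs the full chain: adaptive equalization, Otsu binarization, region
    cleanup, hull construction, per-nucleus near-binarization, GVF field and
    snake evolution. Nuclei whose snake collapses or whose hull interior
    cannot be thresholded are skipped with a warning. Deterministic: the
    same image and configuration always produce identical vertex lists.

    ``config`` is a :class:`~nucshape.config.PipelineConfig`.
    """
    gi = as_gray(img)
    pp = config.preprocess
    eq = equalize_adaptive(gi, tuple(pp.tile_grid), pp.clip_limit,
                           pp.distribution, pp.rayleigh_sigma, pp.n_bins)
    try:
        fg = binarize_otsu(eq)
    except ValueError:
        logger.warning("image %s: constant after equalization; no nuclei", image_id)
        return []
    regions = clean_regions(fg, pp.min_area, pp.connectivity)
    hulls = build_hulls(regions, pp.outer_erode_r, pp.outer_dilate_r,
                        pp.inner_erode_r)
    if not hulls:
        return []
    stretched = stretch_contrast(gi, pp.saturate_frac)
    params = config.snake
    contours: list[Contour] = []
    for pair in hulls:
        x0, x1, y0, y1 = _crop_bounds(pair.outer_hull, gi.pixels.shape)
        offset = np.array([x0, y0], float)
        crop = GrayImage(stretched.pixels[y0:y1, x0:x1].copy())
        local = HullPair(pair.outer_hull - offset, pair.inner_hull - offset,
                         pair.region_label)
        try:
            nb = near_binarize(crop, local, pp.low_frac, pp.high_frac,
                               pp.saturate_frac)
        except ValueError as err:
            logger.warning("image %s nucleus %d skipped: %s",
                           image_id, pair.region_label, err)
            continue
        field = compute_gvf(nb, params.gvf_iterations, params.gvf_mu)
        init = Contour(local.inner_hull, image_id, pair.region_label)
        try:
            snake = evolve_snake(init, field, params, local.outer_hull)
        except SnakeCollapseError as err:
            logger.warning("image %s nucleus %d: snake collapsed (%s)",
                           image_id, pair.region_label, err)
            continue
        contours.append(Contour(snake.vertices + offset, image_id,
                                pair.region_label))
    return contours


def curate(contours: list[Contour],
           exclusions: list[tuple[str, tuple[float, float]]]) -> list[Contour]:
    """Remove contours containing any exclusion point.

    ``exclusions`` is a list of (image_id, (x, y)) records, the file-driven
    replacement for interactive click-to-discard curation. A point inside
    several overlapping contours removes all of them; a point hitting no
    contour of its image is logged and ignored.
    """
    drop: set[int] = set()
    for image_id, point in exclusions:
        hit = False
        for i, c in enumerate(contours):
            if c.image_id == image_id and point_in_polygon(c.vertices, tuple(point)):
                drop.add(i)
                hit = True
        if not hit:
            logger.warning("exclusion point %s in image %s matched no contour",
                           point, image_id)
    return [c for i, c in enumerate(contours) if i not in drop]
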