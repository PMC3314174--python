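"""Per-nucleus shape and intensity measures.

Signed boundary curvature is estimated by circle fitting: for each boundary
point the circle through it and the two points ``offset`` vertices away is
found, curvature is the reciprocal circumradius, and the sign follows the
turn direction (convex positive, concave negative). The mean negative
curvature (MNC) — the absolute mean of the concave curvatures only — is the
continuous blebbing statistic; a perfectly convex nucleus has MNC 0 and a
heavily blebbed one a large MNC. Curvatures are in 1/pixel unless a
physical pixel size is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from nucshape.contour import Contour, polygon_centroid, polygon_second_moments


@dataclass
class CurvatureProfile:
    """Signed curvature (1/pixel) at every contour vertex.

    By convention index 0 is the vertex farthest from the centroid once
    :func:`rotate_to_start` has been applied; ``offset`` records the vertex
    offset used for circle fitting.
    """

    kappa: np.ndarray
    offset: int = 25

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, float)
        if self.kappa.ndim != 1 or len(self.kappa) == 0:
            raise ValueError("kappa must be a non-empty 1-D array")
        if not np.isfinite(self.kappa).all():
            raise ValueError("curvatures must be finite")

    def __len__(self) -> int:
        return len(self.kappa)


@dataclass
class NucleusMetrics:
    """One row of shape/intensity measures for a single nucleus."""

    image_id: str
    nucleus_id: int
    mnc: float
    neg_curv_std: float
    max_neg_curvature: float
    mean_pos_curvature: float
    invaginations: int
    area: float
    perimeter: float
    equivalent_diameter: float
    convex_area: float
    solidity: float
    tortuosity: float
    eccentricity: float
    intensity_mean: float | None = None
    intensity_std: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def signed_curvature(c: Contour, offset: int = 25) -> CurvatureProfile:
    """Signed curvature by circle fitting over a vertex offset.

    For vertex i the circle through vertices i−offset, i, i+offset (cyclic)
    gives |κ| = 1/R; the sign is positive where the boundary turns toward
    the interior (convex) and negative in concavities. Collinear triples
    have κ = 0.
    """
    n = len(c)
    if n <= 2 * offset:
        raise ValueError(
            f"contour has {n} vertices; curvature with offset {offset} "
            f"requires at least {2 * offset + 1}"
        )
    v = c.vertices
    orient = 1.0 if c.is_ccw() else -1.0
    p0 = np.roll(v, offset, axis=0)   # i - offset
    p2 = np.roll(v, -offset, axis=0)  # i + offset
    d01 = v - p0
    d12 = p2 - v
    d02 = p2 - p0
    cross = d01[:, 0] * d12[:, 1] - d01[:, 1] * d12[:, 0]
    a = np.hypot(d01[:, 0], d01[:, 1])
    b = np.hypot(d12[:, 0], d12[:, 1])
    cc = np.hypot(d02[:, 0], d02[:, 1])
    denom = a * b * cc
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = 2.0 * cross / denom
    kappa[denom == 0] = 0.0
    kappa[~np.isfinite(kappa)] = 0.0
    return CurvatureProfile(orient * kappa, offset)


def rotate_to_start(c: Contour, prof: CurvatureProfile) -> tuple[Contour, CurvatureProfile]:
    """Cyclically rotate contour and profile so index 0 is the vertex
    farthest from the polygon centroid (ties: lowest original index)."""
    if len(c) != len(prof):
        raise ValueError("contour and profile lengths differ")
    ctr = polygon_centroid(c.vertices)
    d = np.hypot(c.vertices[:, 0] - ctr[0], c.vertices[:, 1] - ctr[1])
    i0 = int(np.argmax(d))
    verts = np.roll(c.vertices, -i0, axis=0)
    kappa = np.roll(prof.kappa, -i0)
    return (Contour(verts, c.image_id, c.nucleus_id),
            CurvatureProfile(kappa, prof.offset))


def mean_negative_curvature(prof: CurvatureProfile) -> float:
    """MNC: absolute mean of the strictly negative curvatures (0 if none)."""
    neg = prof.kappa[prof.kappa < 0]
    if len(neg) == 0:
        return 0.0
    return float(abs(neg.mean()))


def count_invaginations(prof: CurvatureProfile) -> int:
    """Number of maximal cyclic runs of strictly negative curvature.

    Zero-curvature vertices count as non-negative and interrupt a run; a run
    wrapping around the start is counted once.
    """
    neg = prof.kappa < 0
    if not neg.any():
        return 0
    if neg.all():
        return 1
    starts = neg & ~np.roll(neg, 1)
    return int(starts.sum())


def eccentricity(c: Contour) -> float:
    """Eccentricity of the ellipse with the same second moments as the shape.

    Uses exact polygon moment integrals of the enclosed region; 0 for a
    circle, 1 for a line segment. A degenerate (zero-area) contour falls
    back to point-based vertex moments with a warning, giving exactly 1 for
    collinear points.
    """
    try:
        uxx, uyy, uxy = polygon_second_moments(c.vertices)
    except ValueError:
        warnings.warn("zero-area contour: eccentricity from point moments",
                      stacklevel=2)
        v = c.vertices - c.vertices.mean(axis=0)
        uxx = float(np.mean(v[:, 0] ** 2))
        uyy = float(np.mean(v[:, 1] ** 2))
        uxy = float(np.mean(v[:, 0] * v[:, 1]))
    return _moment_eccentricity(uxx, uyy, uxy)


def _moment_eccentricity(uxx: float, uyy: float, uxy: float) -> float:
    common = np.sqrt((uxx - uyy) ** 2 + 4.0 * uxy ** 2)
    lam1 = 0.5 * (uxx + uyy + common)
    lam2 = 0.5 * (uxx + uyy - common)
    if lam1 <= 0:
        return 1.0
    ratio = max(lam2, 0.0) / lam1
    return float(np.sqrt(max(0.0, 1.0 - ratio)))


def _intensity_stats(c: Contour, pixels: np.ndarray) -> tuple[float | None, float | None]:
    h, w = pixels.shape
    v = c.vertices
    if (v[:, 0].min() < -0.5 or v[:, 1].min() < -0.5
            or v[:, 0].max() > w - 0.5 or v[:, 1].max() > h - 0.5):
        warnings.warn("contour outside image bounds: intensity stats omitted",
                      stacklevel=3)
        return None, None
    rr, cc = draw_polygon(v[:, 1], v[:, 0], shape=pixels.shape)
    if len(rr) == 0:
        return None, None
    vals = pixels[rr, cc].astype(float)
    return float(vals.mean()), float(vals.std())


def metric_table(c: Contour, prof: CurvatureProfile, img=None,
                 pixel_size: float = 1.0) -> NucleusMetrics:
    """Assemble the full measure panel for one nucleus.

    Curvature-derived measures come from ``prof``; geometry from the polygon
    (shoelace area, arc-length perimeter, convex hull via exact polygon
    operations); intensity statistics over the enclosed pixels of ``img``
    when given. ``pixel_size`` (length units per pixel) converts lengths,
    areas and curvatures to physical units; the default leaves everything in
    pixels.
    """
    if len(c) != len(prof):
        raise ValueError("contour and profile lengths differ")
    s = pixel_size
    poly = Polygon(c.vertices)
    hull = poly.convex_hull
    area = poly.area * s * s
    perim = poly.length * s
    kappa = prof.kappa / s
    neg = kappa[kappa < 0]
    pos = kappa[kappa > 0]
    mnc = float(abs(neg.mean())) if len(neg) else 0.0
    neg_std = float(neg.std()) if len(neg) else 0.0
    max_neg = float(-neg.min()) if len(neg) else 0.0
    mean_pos = float(pos.mean()) if len(pos) else 0.0
    if img is not None:
        pixels = img.pixels if hasattr(img, "pixels") else np.asarray(img)
        imean, istd = _intensity_stats(c, pixels)
    else:
        imean = istd = None
    return NucleusMetrics(
        image_id=c.image_id,
        nucleus_id=c.nucleus_id,
        mnc=mnc,
        neg_curv_std=neg_std,
        max_neg_curvature=max_neg,
        mean_pos_curvature=mean_pos,
        invaginations=count_invaginations(prof),
        area=float(area),
        perimeter=float(perim),
        equivalent_diameter=float(2.0 * np.sqrt(area / np.pi)),
        convex_area=float(hull.area * s * s),
        solidity=float(poly.area / hull.area) if hull.area > 0 else 1.0,
        tortuosity=float(poly.length / hull.length) if hull.length > 0 else 1.0,
        eccentricity=eccentricity(c),
        intensity_mean=imean,
        intensity_std=istd,
    )
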