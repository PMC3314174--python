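"""Closed sub-pixel contours and polygon geometry primitives.

A :class:`Contour` is an ordered, closed polygon of sub-pixel vertices in
(x, y) = (column, row) image coordinates, oriented counter-clockwise in the
standard mathematical sense (positive shoelace area with y pointing up; on
screen, with y pointing down, this winds clockwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Contour:
    """Closed polygon boundary of one nucleus.

    Parameters
    ----------
    vertices : (n, 2) float array
        Ordered (x, y) vertex coordinates. The closing edge from the last
        vertex back to the first is implicit.
    image_id : str
        Identifier of the source image ("" for analytic contours).
    nucleus_id : int
        Region label within the source image.
    """

    vertices: np.ndarray
    image_id: str = ""
    nucleus_id: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise ValueError("a contour needs at least 3 vertices")

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def x(self) -> np.ndarray:
        return self.vertices[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.vertices[:, 1]

    def signed_area(self) -> float:
        return signed_area(self.vertices)

    def area(self) -> float:
        return abs(signed_area(self.vertices))

    def perimeter(self) -> float:
        return perimeter(self.vertices)

    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.vertices)

    def side_lengths(self) -> np.ndarray:
        d = np.roll(self.vertices, -1, axis=0) - self.vertices
        return np.hypot(d[:, 0], d[:, 1])

    def is_ccw(self) -> bool:
        return signed_area(self.vertices) > 0

    def ensure_ccw(self) -> "Contour":
        """Return a copy wound counter-clockwise (positive signed area)."""
        if self.is_ccw():
            return Contour(self.vertices.copy(), self.image_id, self.nucleus_id)
        return Contour(self.vertices[::-1].copy(), self.image_id, self.nucleus_id)

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.vertices + [dx, dy], self.image_id, self.nucleus_id)


def signed_area(verts: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise winding."""
    x, y = verts[:, 0], verts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * y1 - x1 * y))


def perimeter(verts: np.ndarray) -> float:
    d = np.roll(verts, -1, axis=0) - verts
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polygon_centroid(verts: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon (vertex mean if area degenerate)."""
    x, y = verts[:, 0], verts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-12:
        return verts.mean(axis=0)
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    return np.array([cx, cy])


def polygon_second_moments(verts: np.ndarray) -> tuple[float, float, float]:
    """Normalized central second moments (uxx, uyy, uxy) of the region
    enclosed by a simple polygon, by exact Green's-theorem integrals.

    uxx = E[(x-cx)^2], uyy = E[(y-cy)^2], uxy = E[(x-cx)(y-cy)] with the
    expectation over the enclosed area. Orientation-independent.
    """
    x, y = verts[:, 0], verts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-12:
        raise ValueError("degenerate polygon: zero enclosed area")
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    ixx = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    iyy = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    ixy = np.sum((x * y1 + 2.0 * x * y + 2.0 * x1 * y1 + x1 * y) * cross) / 24.0
    uxx = ixx / a - cx * cx
    uyy = iyy / a - cy * cy
    uxy = ixy / a - cx * cy
    return float(uxx), float(uyy), float(uxy)


def arc_positions(verts: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each vertex, starting at 0 for vertex 0."""
    d = verts - np.roll(verts, 1, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    seg[0] = 0.0
    return np.cumsum(seg)


def resample_closed(verts: np.ndarray, n_out: int) -> np.ndarray:
    """Resample a closed polygon to ``n_out`` vertices equally spaced in
    arc length, keeping vertex 0 fixed."""
    pos = arc_positions(verts)
    total = pos[-1] + float(np.hypot(*(verts[0] - verts[-1])))
    if total <= 0:
        raise ValueError("zero-perimeter contour")
    # closed curve: append the wrap-around point for interpolation
    pos_ext = np.append(pos, total)
    vx = np.append(verts[:, 0], verts[0, 0])
    vy = np.append(verts[:, 1], verts[0, 1])
    target = np.linspace(0.0, total, n_out, endpoint=False)
    return np.column_stack([np.interp(target, pos_ext, vx), np.interp(target, pos_ext, vy)])


def resample_contour(c: Contour, d_min: float, d_max: float | None = None,
                     final: bool = True) -> Contour:
    """Redistribute contour vertices by spacing.

    With ``final=True`` (the output convention), the polygon is resampled by
    arc length to sides of constant length ``d_min`` (within 10%). With
    ``final=False`` (used between deformation batches), long sides are split
    at their midpoint and runs of short sides merged until every side length
    lies in [d_min, d_max]; vertex positions on retained vertices are not
    moved, which preserves fine boundary detail during evolution.
    """
    verts = c.vertices
    total = perimeter(verts)
    if total < 3.0 * d_min:
        raise ValueError(
            f"degenerate contour: perimeter {total:.3g} < 3*d_min = {3.0 * d_min:.3g}"
        )
    if final:
        n_out = max(3, int(round(total / d_min)))
        out = resample_closed(verts, n_out)
        return Contour(out, c.image_id, c.nucleus_id)
    if d_max is None:
        raise ValueError("d_max required for in-evolution interpolation")
    v = verts
    for _ in range(12):
        d = np.roll(v, -1, axis=0) - v
        seg = np.hypot(d[:, 0], d[:, 1])
        if np.all((seg >= d_min) & (seg <= d_max)):
            break
        pieces = []
        n = len(v)
        i = 0
        while i < n:
            pieces.append(v[i])
            if seg[i] > d_max:
                pieces.append(0.5 * (v[i] + v[(i + 1) % n]))
                i += 1
            elif seg[i] < d_min and i + 1 < n and n > 3:
                i += 2  # merge: drop the following vertex
            else:
                i += 1
        v = np.asarray(pieces)
        if len(v) < 3:
            raise ValueError("contour collapsed during interpolation")
    return Contour(v, c.image_id, c.nucleus_id)


def point_in_polygon(verts: np.ndarray, point: tuple[float, float]) -> bool:
    """Even-odd ray-casting containment test (boundary counts as inside)."""
    x, y = point
    px, py = verts[:, 0], verts[:, 1]
    px1, py1 = np.roll(px, -1), np.roll(py, -1)
    inside = False
    for ax, ay, bx, by in zip(px, py, px1, py1):
        if (ay > y) != (by > y):
            t = (y - ay) / (by - ay)
            xi = ax + t * (bx - ax)
            if x < xi:
                inside = not inside
            elif x == xi:
                return True
    return inside
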