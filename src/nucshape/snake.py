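"""Active contour (snake) evolution under internal and GVF external forces.

The snake is a closed polygon x(s) minimizing

    E = ∮ ½ (alpha |x'|² + beta |x''|²) ds − ∮ E_ext(x) ds

evolved by the semi-implicit update (I + gamma A) x_{t+1} = x_t +
gamma kappa F_ext(x_t), where A is the cyclic pentadiagonal stiffness
matrix assembled from the tension (alpha) and rigidity (beta) weights. The
circulant system is solved exactly per step via the FFT. Deformations run
in batches; after each batch the polygon is re-interpolated to keep vertex
spacing within [d_min, d_max] and vertices that escaped the outer convex
hull are projected back onto it. Evolution stops when the enclosed area
changes by no more than ``area_tol`` between consecutive batches, or after
``max_deformations`` vertex updates in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from nucshape.contour import Contour, resample_contour, signed_area
from nucshape.gvf import VectorField

logger = logging.getLogger(__name__)


class SnakeCollapseError(RuntimeError):
    """Raised when a contour shrinks below the minimum valid perimeter."""


@dataclass
class SnakeParams:
    """Snake and GVF parameters (defaults follow the published recipe)."""

    gvf_iterations: int = 80
    gvf_mu: float = 0.2
    d_min: float = 0.5
    d_max: float = 2.0
    alpha: float = 0.02
    beta: float = 0.05
    gamma: float = 1.0
    kappa: float = 0.6
    batch_size: int = 75
    area_tol: float = 10.0
    max_deformations: int = 50025

    def __post_init__(self) -> None:
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be < d_max")
        for name in ("gvf_mu", "d_min", "alpha", "beta", "gamma", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.batch_size < 1 or self.max_deformations < self.batch_size:
            raise ValueError("max_deformations must be >= batch_size >= 1")


def _internal_eigenvalues(n: int, alpha: float, beta: float,
                          gamma: float) -> np.ndarray:
    """Eigenvalues of (I + gamma A) for the circulant stiffness matrix A."""
    w = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(n) / n)
    return 1.0 + gamma * (alpha * w + beta * w * w)


def _project_into_hull(verts: np.ndarray, hull: np.ndarray) -> np.ndarray:
    """Project vertices lying outside a convex CCW polygon onto its boundary."""
    a = hull
    b = np.roll(hull, -1, axis=0)
    e = b - a  # (m, 2) edges
    # signed area term of each vertex w.r.t. each edge: > 0 means left of edge
    cross = (e[None, :, 0] * (verts[:, None, 1] - a[None, :, 1])
             - e[None, :, 1] * (verts[:, None, 0] - a[None, :, 0]))
    outside = np.any(cross < 0.0, axis=1)
    if not outside.any():
        return verts
    out = verts.copy()
    idx = np.nonzero(outside)[0]
    ee = np.einsum("ij,ij->i", e, e)
    for i in idx:
        p = verts[i]
        t = np.clip(np.einsum("ij,ij->i", p - a, e) / ee, 0.0, 1.0)
        cand = a + t[:, None] * e
        d2 = np.einsum("ij,ij->i", cand - p, cand - p)
        out[i] = cand[int(np.argmin(d2))]
    return out


def _sample_force(field: VectorField, verts: np.ndarray) -> np.ndarray:
    coords = [verts[:, 1], verts[:, 0]]  # (row, col)
    fx = map_coordinates(field.u, coords, order=1, mode="nearest")
    fy = map_coordinates(field.v, coords, order=1, mode="nearest")
    return np.column_stack([fx, fy])


def evolve_snake(init: Contour, field: VectorField, params: SnakeParams,
                 outer_limit: np.ndarray) -> Contour:
    """Evolve a snake from an initial contour until area convergence.

    ``outer_limit`` is a convex CCW polygon the contour may not leave.
    Returns the converged contour re-interpolated to constant side length
    ``d_min``. Raises :class:`SnakeCollapseError` if the contour shrinks
    below a valid perimeter.
    """
    c = resample_contour(init.ensure_ccw(), params.d_min, params.d_max,
                         final=False)
    verts = _project_into_hull(c.vertices, outer_limit)
    prev_area = abs(signed_area(verts))
    deformations = 0
    while deformations < params.max_deformations:
        n = len(verts)
        eig = _internal_eigenvalues(n, params.alpha, params.beta, params.gamma)
        z = verts[:, 0] + 1j * verts[:, 1]
        gk = params.gamma * params.kappa
        for _ in range(params.batch_size):
            pts = np.column_stack([z.real, z.imag])
            f = _sample_force(field, pts)
            rhs = z + gk * (f[:, 0] + 1j * f[:, 1])
            z = np.fft.ifft(np.fft.fft(rhs) / eig)
        deformations += params.batch_size
        verts = np.column_stack([z.real, z.imag])
        verts = _project_into_hull(verts, outer_limit)
        try:
            c = resample_contour(Contour(verts, init.image_id, init.nucleus_id),
                                 params.d_min, params.d_max, final=False)
        except ValueError as err:
            raise SnakeCollapseError(str(err)) from err
        verts = c.vertices
        area = abs(signed_area(verts))
        if abs(area - prev_area) <= params.area_tol:
            break
        prev_area = area
    final = resample_contour(
        Contour(verts, init.image_id, init.nucleus_id).ensure_ccw(),
        params.d_min, final=True)
    return final
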