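"""Finite-element slit-in-plate solver: numerical oracle for crack openings.

Solves plane-stress linear elasticity on a large rectangular plate with a
traction-free line slit under remote tension perpendicular to the slit, and
returns the opening at the slit centre.  The mesh is a rectilinear grid,
graded geometrically away from the slit; the slit itself is modelled by
duplicating the grid nodes on its interior so the two faces can separate.

This is deliberately independent of the closed-form anisotropic
crack-opening factor in :mod:`embryomech.plane_elasticity`: it discretises
the governing equations directly and is used to validate the closed form,
never to replace it.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .plane_elasticity import Axis, ComplianceMatrix

__all__ = ["slit_plate_opening"]

_GAUSS = 1.0 / np.sqrt(3.0)


def _element_stiffness(a: float, b: float, Q: np.ndarray) -> np.ndarray:
    """8x8 stiffness of a bilinear rectangle (width a, height b), unit thickness."""
    ke = np.zeros((8, 8))
    for xi in (-_GAUSS, _GAUSS):
        for eta in (-_GAUSS, _GAUSS):
            # shape function derivatives in physical coords
            dN_dx = np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)]) / (2 * a)
            dN_dy = np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)]) / (2 * b)
            B = np.zeros((3, 8))
            B[0, 0::2] = dN_dx
            B[1, 1::2] = dN_dy
            B[2, 0::2] = dN_dy
            B[2, 1::2] = dN_dx
            ke += B.T @ Q @ B * (a * b / 4.0)
    return ke


def _graded_axis(l: float, half_extent: float, n_tip: int, ratio: float) -> np.ndarray:
    """Symmetric 1-D coordinates: uniform spacing l/n_tip near 0, graded outward."""
    h = l / n_tip
    # uniform zone covering the slit plus a small margin; tips land on nodes
    n_fine = n_tip // 2 + 4
    coords = [i * h for i in range(n_fine + 1)]
    step = h
    while coords[-1] < half_extent:
        step *= ratio
        coords.append(coords[-1] + step)
    pos = np.asarray(coords)
    return np.concatenate([-pos[::-1][:-1], pos])


def slit_plate_opening(
    compliance: ComplianceMatrix,
    load_perp: float,
    cut_axis: Axis = "AP",
    l: float = 1.0,
    domain_factor: float = 20.0,
    n_tip: int = 24,
    grading_ratio: float = 1.3,
) -> float:
    """Centre opening (minor axis b, length units of ``l``) of a slit plate.

    Parameters
    ----------
    compliance : material compliance in the AP/DV frame.
    load_perp : remote tensile stress perpendicular to the slit, in the
        inverse units of the compliance entries.
    cut_axis : axis the slit lies along; the material frame is mapped so
        the slit is always along the mesh x axis.
    l : slit length; the plate is a square of side ``domain_factor * l``.
    n_tip : elements per slit length in the uniform zone (mesh resolution).
    """
    if load_perp < 0:
        raise ValueError("compressive load: slit closes, model invalid")
    s = compliance if cut_axis == "AP" else compliance.swap_axes()
    Q = s.stiffness()

    xs = _graded_axis(l, domain_factor * l / 2.0, n_tip, grading_ratio)
    ys = _graded_axis(l, domain_factor * l / 2.0, n_tip, grading_ratio)
    nx, ny = len(xs), len(ys)
    iy0 = int(np.argmin(np.abs(ys)))  # row of the slit (y = 0)
    assert abs(ys[iy0]) < 1e-12 * l

    def nid(ix: int, iy: int) -> int:
        return iy * nx + ix

    n_base = nx * ny
    # interior slit nodes (tips excluded) get bottom-face duplicates
    slit_ix = np.where(np.abs(xs) < l / 2.0 - 1e-12 * l)[0]
    dup_of = {int(ix): n_base + k for k, ix in enumerate(slit_ix)}
    n_nodes = n_base + len(slit_ix)

    rows, cols, vals = [], [], []
    ke_cache: dict[tuple[float, float], np.ndarray] = {}
    for iy in range(ny - 1):
        below_slit_row = iy + 1 == iy0  # element's top edge lies on y = 0
        b = ys[iy + 1] - ys[iy]
        for ix in range(nx - 1):
            a = xs[ix + 1] - xs[ix]
            key = (round(a, 12), round(b, 12))
            ke = ke_cache.get(key)
            if ke is None:
                ke = _element_stiffness(a, b, Q)
                ke_cache[key] = ke
            conn = [nid(ix, iy), nid(ix + 1, iy), nid(ix + 1, iy + 1), nid(ix, iy + 1)]
            if below_slit_row:
                # top corners on the slit interior attach to the bottom face
                if ix + 1 in dup_of:
                    conn[2] = dup_of[ix + 1]
                if ix in dup_of:
                    conn[3] = dup_of[ix]
            dofs = np.array([[2 * n, 2 * n + 1] for n in conn]).ravel()
            rows.append(np.repeat(dofs, 8))
            cols.append(np.tile(dofs, 8))
            vals.append(ke.ravel())

    ndof = 2 * n_nodes
    K = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    ).tocsr()

    # consistent nodal loads: sigma_yy = load_perp on top and bottom edges
    f = np.zeros(ndof)
    trib_x = np.zeros(nx)
    trib_x[:-1] += np.diff(xs) / 2.0
    trib_x[1:] += np.diff(xs) / 2.0
    for ix in range(nx):
        f[2 * nid(ix, ny - 1) + 1] += load_perp * trib_x[ix]
        f[2 * nid(ix, 0) + 1] -= load_perp * trib_x[ix]

    # remove rigid-body motion (loads are self-equilibrated)
    fixed = [2 * nid(0, 0), 2 * nid(0, 0) + 1, 2 * nid(nx - 1, 0) + 1]
    free = np.setdiff1d(np.arange(ndof), fixed)
    u = np.zeros(ndof)
    u[free] = spsolve(K[np.ix_(free, free)], f[free])

    ix_c = int(np.argmin(np.abs(xs)))  # slit centre (x = 0)
    if ix_c not in dup_of:
        raise RuntimeError("slit centre node was not duplicated; mesh too coarse")
    jump = u[2 * nid(ix_c, iy0) + 1] - u[2 * dup_of[ix_c] + 1]
    return float(jump)
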