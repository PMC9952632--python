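"""Linear (P1) simplex finite-element kernels on triangle/tetrahedral meshes.

Everything here is dimension-agnostic: cells are (M, d+1) index arrays into an
(N, d) node array, d = 2 or 3.  Shape-function gradients are constant per
cell, so assembly reduces to vectorized gathers and `np.bincount` scatters.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu


def cell_geometry(nodes: np.ndarray, cells: np.ndarray):
    """Signed-volume magnitudes and P1 shape-function gradients per cell.

    Returns (volumes (M,), grads (M, d+1, d)).  Gradients satisfy
    sum_i grads[c, i] = 0 and grad of the barycentric coordinate of vertex i.
    """
    d = nodes.shape[1]
    verts = nodes[cells]  # (M, d+1, d)
    edges = verts[:, 1:, :] - verts[:, :1, :]  # (M, d, d)
    det = np.linalg.det(edges)
    vols = np.abs(det) / math.factorial(d)
    inv = np.linalg.inv(edges)  # rows: dual basis of edge vectors
    # gradient of barycentric lambda_i (i>=1) is column i-1 of inv
    g = np.transpose(inv, (0, 2, 1))  # (M, d, d): g[:, i-1, :] = grad lambda_i
    grads = np.empty((cells.shape[0], d + 1, d))
    grads[:, 1:, :] = g
    grads[:, 0, :] = -g.sum(axis=1)
    return vols, grads


def min_cell_volume(nodes, cells) -> float:
    vols, _ = cell_geometry(nodes, cells)
    return float(vols.min())


def stiffness_matrix(nodes, cells, vols, grads, coeff=None) -> sp.csr_matrix:
    """Assemble the scalar stiffness matrix ∫ c ∇u·∇v, coeff constant per cell."""
    n = nodes.shape[0]
    nv = cells.shape[1]
    w = vols if coeff is None else vols * coeff
    ke = np.einsum("mid,mjd->mij", grads, grads) * w[:, None, None]
    rows = np.repeat(cells, nv, axis=1).ravel()
    cols = np.tile(cells, (1, nv)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def lumped_mass(nodes, cells, vols) -> np.ndarray:
    """Row-sum (lumped) mass vector: each cell gives V/(d+1) to each vertex."""
    n = nodes.shape[0]
    nv = cells.shape[1]
    contrib = np.repeat(vols / nv, nv)
    return np.bincount(cells.ravel(), weights=contrib, minlength=n)


def _scatter(cells, values, n):
    """Scatter per-(cell, vertex) values (M, d+1) or (M, d+1, k) to nodes."""
    if values.ndim == 2:
        return np.bincount(cells.ravel(), weights=values.ravel(), minlength=n)
    k = values.shape[2]
    out = np.empty((n, k))
    flat = cells.ravel()
    for j in range(k):
        out[:, j] = np.bincount(flat, weights=values[:, :, j].ravel(), minlength=n)
    return out


def velocity_gradients(cells, grads, u) -> np.ndarray:
    """Per-cell velocity gradient G[c, a, b] = ∂u_a/∂x_b (constant per cell)."""
    return np.einsum("mia,mib->mab", u[cells], grads)


def convection_rhs(nodes, cells, vols, grads, u) -> np.ndarray:
    """Galerkin convection vector ∫ ((u·∇)u)·v for P1 velocity u (N, d).

    (u·∇)u is linear within each cell, so the vertex-wise exact rule
    ∫ f φ_i = V/((d+1)(d+2)) (Σ_j f_j + f_i) applies.
    """
    n, d = u.shape
    nv = cells.shape[1]
    G = velocity_gradients(cells, grads, u)  # (M, d, d)
    uv = u[cells]  # (M, d+1, d)
    a = np.einsum("mjb,mab->mja", uv, G)  # (M, d+1, d): (u_j·∇)u per vertex
    s = a.sum(axis=1, keepdims=True)
    w = vols[:, None, None] / (nv * (nv + 1))
    return _scatter(cells, w * (s + a), n)


def divergence_rhs(nodes, cells, vols, grads, u) -> np.ndarray:
    """∫ q ∇·u for all P1 test functions q; returns (N,)."""
    n = u.shape[0]
    nv = cells.shape[1]
    div = np.einsum("mia,mia->m", u[cells], grads)
    contrib = np.repeat(vols * div / nv, nv)
    return np.bincount(cells.ravel(), weights=contrib, minlength=n)


def gradient_rhs(nodes, cells, vols, grads, p) -> np.ndarray:
    """∫ v·∇p for all P1 vector test functions; returns (N, d)."""
    n = p.shape[0]
    nv = cells.shape[1]
    gp = np.einsum("mi,mia->ma", p[cells], grads)  # (M, d) constant per cell
    vals = np.broadcast_to(gp[:, None, :], (cells.shape[0], nv, gp.shape[1]))
    vals = vals * (vols / nv)[:, None, None]
    return _scatter(cells, np.ascontiguousarray(vals), n)


def load_rhs(nodes, cells, vols, f_cell) -> np.ndarray:
    """∫ f·v for a per-cell constant vector load f_cell (M, d)."""
    n = nodes.shape[0]
    nv = cells.shape[1]
    vals = np.broadcast_to(f_cell[:, None, :], (cells.shape[0], nv, f_cell.shape[1]))
    vals = vals * (vols / nv)[:, None, None]
    return _scatter(cells, np.ascontiguousarray(vals), n)


class DirichletSystem:
    """Sparse SPD-ish system with strongly eliminated Dirichlet dofs.

    The reduced matrix A_ff is factorized once (SuperLU) and reused for every
    right-hand side; `solve` accepts one rhs or a stack of them.
    """

    def __init__(self, A: sp.csr_matrix, fixed: np.ndarray):
        n = A.shape[0]
        self.n = n
        self.fixed = np.asarray(fixed, dtype=np.int64)
        mask = np.ones(n, dtype=bool)
        mask[self.fixed] = False
        self.free = np.nonzero(mask)[0]
        A = A.tocsc()
        self._A_ff = A[self.free][:, self.free].tocsc()
        self._A_fd = A[self.free][:, self.fixed].tocsr()
        self._lu = splu(self._A_ff)

    def lift(self, fixed_values: np.ndarray) -> np.ndarray:
        """A_fd @ fixed_values — the Dirichlet forcing felt by the free dofs."""
        return self._A_fd @ np.asarray(fixed_values, dtype=float)

    def solve(self, b: np.ndarray, fixed_values: np.ndarray) -> np.ndarray:
        """Solve A x = b with x[fixed] = fixed_values; b, x shape (N,) or (N, k)."""
        b = np.asarray(b, dtype=float)
        fv = np.asarray(fixed_values, dtype=float)
        single = b.ndim == 1
        if single:
            b = b[:, None]
            fv = fv[:, None] if fv.ndim == 1 else fv
        if fv.ndim == 1:
            fv = np.broadcast_to(fv[:, None], (len(self.fixed), b.shape[1]))
        rhs = b[self.free] - self._A_fd @ fv
        xf = self._lu.solve(np.ascontiguousarray(rhs))
        x = np.empty((self.n, b.shape[1]))
        x[self.free] = xf
        x[self.fixed] = fv
        return x[:, 0] if single else x


# ---------------------------------------------------------------------------
# boundary-facet quadrature


def facet_areas_normals(nodes: np.ndarray, facets: np.ndarray,
                        owner_centroids: np.ndarray | None = None):
    """Areas (lengths in 2D) and unit normals of boundary facets.

    If `owner_centroids` is given, normals are oriented outward (away from the
    owning cell's centroid).
    """
    d = nodes.shape[1]
    pts = nodes[facets]
    if d == 2:
        t = pts[:, 1] - pts[:, 0]
        areas = np.linalg.norm(t, axis=1)
        normals = np.column_stack([t[:, 1], -t[:, 0]]) / areas[:, None]
    else:
        a = pts[:, 1] - pts[:, 0]
        b = pts[:, 2] - pts[:, 0]
        cr = np.cross(a, b)
        nr = np.linalg.norm(cr, axis=1)
        areas = 0.5 * nr
        normals = cr / nr[:, None]
    if owner_centroids is not None:
        mid = pts.mean(axis=1)
        flip = np.einsum("fd,fd->f", normals, mid - owner_centroids) < 0
        normals[flip] *= -1.0
    return areas, normals


def facet_flux(u: np.ndarray, facets: np.ndarray, areas: np.ndarray,
               normals: np.ndarray) -> float:
    """∫ u·n over the given facets; exact for P1 velocity (vertex mean rule)."""
    u_mean = u[facets].mean(axis=1)
    return float(np.einsum("fd,fd,f->", u_mean, normals, areas))
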