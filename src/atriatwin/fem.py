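"""First-order (P1) finite elements on tetrahedral meshes.

Provides the three numerical primitives every later stage builds on:

* scalar Laplace--Dirichlet solves (harmonic interpolation between labeled
  boundary sets, homogeneous Neumann elsewhere),
* small-strain linear elasticity with incremental (updated-Lagrangian)
  load stepping,
* exact per-element gradients of piecewise-linear nodal fields.

All solves are sparse and symmetric: a direct factorization is used below
``DIRECT_SOLVE_MAX_NODES`` unknowns, conjugate gradients with diagonal
preconditioning above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, splu

from .mesh import LabeledMesh

DIRECT_SOLVE_MAX_NODES = 50_000
CG_RTOL = 1e-10


@dataclass
class DirichletSpec:
    """Dirichlet boundary data: list of (node set, value) constraints.

    Each entry is ``(nodes, value)`` where ``nodes`` is either the name of a
    mesh node set or an explicit index array, and ``value`` is a scalar or a
    per-node array.  Later entries override earlier ones on shared nodes.
    """

    items: list

    def resolve(self, mesh: LabeledMesh, ncomp: int = 1):
        """Return (node indices, values) arrays; values is (n,) or (n, ncomp)."""
        if not self.items:
            raise ValueError("DirichletSpec is empty: at least one constrained node is required")
        n = mesh.n_nodes
        mask = np.zeros(n, dtype=bool)
        vals = np.zeros((n, ncomp))
        for nodes, value in self.items:
            idx = mesh.require_set(nodes) if isinstance(nodes, str) else np.asarray(nodes, dtype=np.int64)
            if idx.size == 0:
                raise ValueError("Dirichlet entry references an empty node set")
            v = np.asarray(value, dtype=float)
            if v.ndim == 0:
                v = np.full((idx.size, ncomp), float(v))
            elif v.ndim == 1 and ncomp == 1:
                v = v[:, None]
            if v.shape != (idx.size, ncomp):
                raise ValueError(f"Dirichlet values shape {v.shape} does not match {idx.size} nodes x {ncomp} comps")
            mask[idx] = True
            vals[idx] = v
        idx = np.flatnonzero(mask)
        out = vals[idx, 0] if ncomp == 1 else vals[idx]
        return idx, out


def shape_gradients(points: np.ndarray, tets: np.ndarray):
    """Gradients of the four P1 basis functions per tet.

    Returns ``(grads, vols)`` with grads of shape (n_tets, 4, 3) and signed
    volumes (n_tets,).  Raises on degenerate (zero-volume) elements.
    """
    p = points[tets]  # (m, 4, 3)
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    vols = np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0
    if np.any(vols == 0):
        bad = int(np.flatnonzero(vols == 0)[0])
        raise ValueError(f"degenerate tetrahedron (zero volume) at element {bad}")
    # Rows of the inverse edge matrix give grads of lambda_1..3.
    J = np.stack([a, b, c], axis=1)  # (m, 3, 3), rows are edge vectors
    Jinv = np.linalg.inv(J)  # columns correspond to lambda_1..3 grads
    g123 = np.transpose(Jinv, (0, 2, 1))  # (m, 3, 3): [elem, basis-1, xyz]
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (m, 4, 3)
    return grads, vols


def element_gradient(mesh: LabeledMesh, field: np.ndarray) -> np.ndarray:
    """Exact gradient of the P1 interpolant of ``field``, constant per tet."""
    field = np.asarray(field, dtype=float)
    if field.shape != (mesh.n_nodes,):
        raise ValueError("field must have one value per mesh node")
    grads, _ = shape_gradients(mesh.points, mesh.tets)
    return np.einsum("mk,mkd->md", field[mesh.tets], grads)


def stiffness_matrix(points: np.ndarray, tets: np.ndarray) -> sparse.csr_matrix:
    """Assemble the P1 Laplace stiffness matrix (homogeneous Neumann natural BC)."""
    grads, vols = shape_gradients(points, tets)
    vols = np.abs(vols)
    ke = np.einsum("mid,mjd,m->mij", grads, grads, vols)  # (m, 4, 4)
    m = tets.shape[0]
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    K = sparse.coo_matrix((ke.ravel(), (rows, cols)), shape=(points.shape[0],) * 2)
    return K.tocsr()


def _solve_spd(K: sparse.csr_matrix, rhs: np.ndarray) -> np.ndarray:
    """Solve a symmetric positive-definite sparse system."""
    if K.shape[0] <= DIRECT_SOLVE_MAX_NODES:
        return splu(K.tocsc()).solve(rhs)
    d = K.diagonal()
    M = sparse.diags(1.0 / np.where(d > 0, d, 1.0))
    x, info = cg(K, rhs, rtol=CG_RTOL, maxiter=20_000, M=M)
    if info != 0:
        raise RuntimeError(f"conjugate-gradient solve failed to converge (info={info})")
    return x


def solve_dirichlet(K: sparse.csr_matrix, fixed: np.ndarray, fixed_vals: np.ndarray,
                    rhs: np.ndarray | None = None) -> np.ndarray:
    """Solve ``K x = rhs`` with prescribed values on ``fixed`` via reduction."""
    n = K.shape[0]
    if fixed.size == 0:
        raise ValueError("singular system: no Dirichlet nodes")
    free = np.setdiff1d(np.arange(n), fixed, assume_unique=False)
    x = np.zeros(n)
    x[fixed] = fixed_vals
    b = np.zeros(n) if rhs is None else rhs.copy()
    b = b - K @ x
    if free.size:
        Kff = K[free][:, free].tocsr()
        x[free] = _solve_spd(Kff, b[free])
        x[fixed] = fixed_vals  # exact, independent of solver tolerance
    return x


def solve_laplace(mesh: LabeledMesh, dbc: DirichletSpec,
                  points: np.ndarray | None = None) -> np.ndarray:
    """Harmonic field with the given Dirichlet data; Neumann on the rest.

    Returns one value per node.  Dirichlet nodes carry their prescribed
    values exactly; the interior satisfies the discrete maximum principle
    up to solver tolerance.
    """
    pts = mesh.points if points is None else points
    K = stiffness_matrix(pts, mesh.tets)
    fixed, vals = dbc.resolve(mesh)
    return solve_dirichlet(K, fixed, vals)


# ---------------------------------------------------------------------------
# Linear elasticity
# ---------------------------------------------------------------------------

@dataclass
class ElasticMaterial:
    """Isotropic small-strain material (dimensionless by default)."""

    young: float = 1.0
    poisson: float = 0.3

    def lame(self):
        E, nu = self.young, self.poisson
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        return lam, mu


def elasticity_matrix(points: np.ndarray, tets: np.ndarray,
                      material: ElasticMaterial) -> sparse.csr_matrix:
    """Assemble the P1 linear-elasticity stiffness matrix (3 dof per node)."""
    lam, mu = material.lame()
    grads, vols = shape_gradients(points, tets)
    vols = np.abs(vols)
    m = tets.shape[0]
    # B: (m, 6, 12) strain-displacement in Voigt order xx, yy, zz, xy, yz, zx
    B = np.zeros((m, 6, 12))
    for i in range(4):
        gx, gy, gz = grads[:, i, 0], grads[:, i, 1], grads[:, i, 2]
        c = 3 * i
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    ke = np.einsum("msi,st,mtj,m->mij", B, D, B, vols)
    dof = (3 * tets[:, :, None] + np.arange(3)).reshape(m, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sparse.coo_matrix((ke.ravel(), (rows, cols)), shape=(3 * points.shape[0],) * 2)
    return K.tocsr()


def solve_linear_elasticity(mesh: LabeledMesh, dbc_displacements: DirichletSpec,
                            material: ElasticMaterial | None = None,
                            n_load_steps: int = 5,
                            points: np.ndarray | None = None,
                            check_inversion: bool = True) -> np.ndarray:
    """Displacement field for prescribed boundary displacements.

    The total prescribed displacement is applied incrementally over
    ``n_load_steps`` small-strain solves, updating nodal coordinates between
    steps (updated-Lagrangian).  Returns the total displacement (n_nodes, 3)
    relative to the starting configuration.
    """
    if n_load_steps < 1:
        raise ValueError("n_load_steps must be >= 1")
    material = material or ElasticMaterial()
    pts0 = (mesh.points if points is None else points).astype(float).copy()
    fixed, targets = dbc_displacements.resolve(mesh, ncomp=3)
    if not np.all(np.isfinite(targets)):
        raise ValueError("prescribed displacements must be finite")
    pts = pts0.copy()
    fdof = (3 * fixed[:, None] + np.arange(3)).ravel()
    for step in range(n_load_steps):
        remaining = (pts0[fixed] + targets) - pts[fixed]
        inc = remaining / (n_load_steps - step)
        K = elasticity_matrix(pts, mesh.tets, material)
        try:
            u = solve_dirichlet(K, fdof, inc.ravel())
        except RuntimeError as exc:
            raise RuntimeError(f"elasticity solve failed at load step {step + 1}") from exc
        pts = pts + u.reshape(-1, 3)
        if check_inversion:
            _, vols = shape_gradients(pts, mesh.tets)
            ref_sign = np.sign(mesh.volumes())
            if np.any(np.sign(vols) != ref_sign):
                bad = np.flatnonzero(np.sign(vols) != ref_sign)
                raise RuntimeError(
                    f"inverted element(s) after load step {step + 1}: {bad[:10].tolist()}"
                )
    # enforce exact Dirichlet values on the final configuration
    pts[fixed] = pts0[fixed] + targets
    return pts - pts0
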