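"""First-order tetrahedral FEM for the quasi-static scalar potential.

Solves the pure-Neumann conduction problem

    div( sigma grad(phi) ) = div( F ),      n.(sigma grad(phi) - F) = 0 on the scalp,

whose weak form is  A phi = b  with  A[m,n] = int sigma grad(lam_m).grad(lam_n)
and  b[m] = int grad(lam_m).F  over the head.  ``F`` is ``sigma * E_p`` for an
applied primary field or an impressed volume current density ``M``.  The
operator is symmetric positive semi-definite with the constants as nullspace;
solutions are gauge-fixed to zero mean.

Assembly and solves are in SI metres (mesh coordinates are mm).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh_core import CellField, HeadMesh, MeshError

MM = 1e-3  # mm -> m

__all__ = [
    "ConductionOperator", "NodalPotential", "assemble_conduction_system",
    "build_rhs", "solve_neumann", "gradient_field", "solve_direct_tms",
]


class FEMError(RuntimeError):
    pass


def _p1_geometry(mesh: HeadMesh):
    """Per-tet P1 shape-function gradients (1/m) and volumes (m^3), cached."""
    cache = getattr(mesh, "_p1_cache", None)
    if cache is not None:
        return cache
    p = mesh.nodes[mesh.tets] * MM                  # (K, 4, 3) in m
    J = p[:, 1:] - p[:, :1]                         # columns-as-rows: J[k,i] = v_{i+1}-v_0
    Jinv = np.linalg.inv(J)                         # (K, 3, 3); grad lam_{i+1} = Jinv[:, :, i]
    grads = np.empty((mesh.n_tets, 4, 3))
    grads[:, 1:, :] = np.swapaxes(Jinv, 1, 2)
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    vol = mesh.tet_volume * MM**3
    mesh._p1_cache = (grads, vol)
    return mesh._p1_cache


class NodalPotential:
    """Scalar potential sample per mesh node (volts), zero-mean gauge."""

    def __init__(self, values: np.ndarray, mesh: HeadMesh):
        values = np.asarray(values, dtype=float)
        if values.shape != (mesh.n_nodes,):
            raise MeshError("potential length != node count")
        if not np.all(np.isfinite(values)):
            raise FEMError("non-finite potential")
        self.values = values - values.mean()
        self.mesh = mesh


class ConductionOperator:
    """Assembled stiffness operator with a shared reusable factorization.

    The pure-Neumann system is singular (constants nullspace); the cached
    factorization is of the system with node 0 removed, which for a
    compatible right-hand side yields the exact projected solution.
    """

    def __init__(self, matrix: sp.csr_matrix, mesh: HeadMesh):
        self.matrix = matrix
        self.mesh = mesh
        self._lu = None

    @property
    def shape(self):
        return self.matrix.shape

    def factor(self):
        if self._lu is None:
            n = self.matrix.shape[0]
            keep = np.arange(1, n)
            reduced = self.matrix[keep][:, keep].tocsc()
            self._lu = spla.splu(reduced)
        return self._lu


def assemble_conduction_system(mesh: HeadMesh) -> ConductionOperator:
    """Assemble A[m,n] = int sigma grad(lam_m).grad(lam_n) (S*m entries)."""
    if np.any(mesh.tet_volume <= 0):
        raise MeshError("zero-volume tet encountered during assembly")
    if np.any(mesh.conductivity < 0):
        raise MeshError("negative conductivity")
    grads, vol = _p1_geometry(mesh)
    coeff = (mesh.conductivity * vol)[:, None, None]
    ke = coeff * np.einsum("kid,kjd->kij", grads, grads)   # (K, 4, 4)
    rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.tets, (1, 4)).reshape(-1)
    A = sp.coo_matrix((ke.reshape(-1), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    return ConductionOperator(A, mesh)


def build_rhs(mesh: HeadMesh, cell_source: CellField) -> np.ndarray:
    """Weak-form load vector b[m] = int grad(lam_m).F over the head.

    ``cell_source`` carries F per tet in SI units per metre bookkeeping
    (values themselves are unit-agnostic; only grad operations use metres).
    The result sums to zero (compatibility of the pure-Neumann problem).
    """
    if cell_source.mesh is not mesh:
        raise MeshError("cell source defined on a different mesh")
    F = cell_source.to_full()
    grads, vol = _p1_geometry(mesh)
    be = vol[:, None] * np.einsum("kid,kd->ki", grads, F)  # (K, 4)
    b = np.zeros(mesh.n_nodes)
    np.add.at(b, mesh.tets.reshape(-1), be.reshape(-1))
    return b


def solve_neumann(A: ConductionOperator, b: np.ndarray, tol: float = 1e-10,
                  method: str = "direct", on_incompatible: str = "project",
                  maxiter: int = 5000) -> NodalPotential:
    """Solve A phi = b for the zero-mean potential.

    The right-hand side is projected onto range(A) (its constant component
    removed); an incompatible b raises if ``on_incompatible='raise'``.
    ``method='direct'`` reuses one sparse LU of the reduced system across
    calls; ``method='cg'`` runs Jacobi-preconditioned conjugate gradients.
    """
    b = np.asarray(b, dtype=float)
    n = A.shape[0]
    norm_b = np.linalg.norm(b)
    if norm_b == 0.0:
        return NodalPotential(np.zeros(n), A.mesh)
    drift = abs(b.sum()) / (np.sqrt(n) * norm_b)
    if drift > 1e-8 and on_incompatible == "raise":
        raise FEMError(f"incompatible RHS: constant component {drift:.3g}")
    bp = b - b.sum() / n
    if np.linalg.norm(bp) == 0.0:
        return NodalPotential(np.zeros(n), A.mesh)

    if method == "direct":
        lu = A.factor()
        x = np.empty(n)
        x[0] = 0.0
        x[1:] = lu.solve(bp[1:])
    elif method == "cg":
        diag = A.matrix.diagonal()
        M = sp.diags(1.0 / np.where(diag > 0, diag, 1.0))
        residuals = []

        def cb(xk):
            residuals.append(np.linalg.norm(A.matrix @ xk - bp))

        x, info = spla.cg(A.matrix, bp, rtol=tol * 0.1, atol=0.0, M=M,
                          maxiter=maxiter, callback=cb)
        if info != 0:
            raise FEMError(f"CG failed to converge in {maxiter} iterations; "
                           f"residual history tail {residuals[-5:]}")
    else:
        raise ValueError(f"unknown method {method!r}")

    res = np.linalg.norm(A.matrix @ x - bp) / np.linalg.norm(bp)
    if res > tol:
        raise FEMError(f"solver residual {res:.3g} exceeds tol {tol:.3g}")
    return NodalPotential(x, A.mesh)


def gradient_field(mesh: HeadMesh, phi: NodalPotential) -> CellField:
    """Per-tet constant grad(phi) in V/m from P1 shape functions."""
    if phi.mesh is not mesh:
        raise MeshError("potential defined on a different mesh")
    grads, _ = _p1_geometry(mesh)
    g = np.einsum("kid,ki->kd", grads, phi.values[mesh.tets])
    return CellField(g, mesh, units="V/m")


def solve_direct_tms(mesh: HeadMesh, coil, placement, dIdt: float = 6.6e7,
                     operator: "ConductionOperator | None" = None,
                     tol: float = 1e-10, full_head: bool = False) -> CellField:
    """Reference TMS solve: E = dIdt * (E_p - grad phi) on the ROI.

    The coil is transformed into head coordinates directly (no grid
    interpolation) and its primary field is evaluated at every tet centroid;
    the conduction correction comes from one FEM solve.  ``operator`` may be
    a pre-assembled (and factored) system to share across placements.
    Warns if any coil element lies inside the head bounding volume.
    """
    from .coil import coil_primary_fields, transform_coil

    placed = transform_coil(coil, placement)
    r_max = np.linalg.norm(mesh.nodes - mesh.nodes.mean(axis=0), axis=1).max()
    if np.any(np.linalg.norm(placed.positions - mesh.nodes.mean(axis=0), axis=1) < r_max * 0.98):
        import warnings
        warnings.warn("coil element(s) possibly intersect the head volume", stacklevel=2)

    E_p, _ = coil_primary_fields(placed, mesh.tet_centroid, dIdt=1.0)
    src = CellField(mesh.conductivity[:, None] * E_p, mesh, units="A/m^2")
    op = operator if operator is not None else assemble_conduction_system(mesh)
    phi = solve_neumann(op, build_rhs(mesh, src), tol=tol)
    E = E_p - gradient_field(mesh, phi).values
    if full_head:
        return CellField(dIdt * E, mesh, units="V/m")
    return CellField(dIdt * E[mesh.roi_mask], mesh, units="V/m", on_roi=True)
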