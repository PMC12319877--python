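"""Offline precompute driver and the real-time coefficient/reconstruction path.

``precompute_session`` runs the full offline pipeline — white-noise probing,
FEM solves, volume-weighted SVD modes, impressed-current solves, Huygens
equivalent currents, the reciprocity operator, the coil primary-field grid,
and mode samples at the evaluation surface — into a self-contained
:class:`RealtimeSession` (persistable as HDF5).  ``realtime_solve`` then maps
any rigid coil placement to the brain E-field with two dense mat-vecs and a
trilinear interpolation, in single precision.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .coil import CoilModel, Placement
from .fem import (assemble_conduction_system, build_rhs, gradient_field,
                  solve_neumann)
from .grid_interp import PrimaryFieldGrid, build_primary_grid, interpolate_fields
from .huygens import (ReciprocityOperator, build_reciprocity_operator,
                      equivalent_currents, surface_fields_from_volume_currents)
from .mesh_core import CellField, HeadMesh, TriSurface
from .noise_basis import ModeBasis, build_basis, magnetic_current_primary_efield, \
    sample_white_noise_currents

logger = logging.getLogger(__name__)

__all__ = [
    "RealtimeSession", "precompute_session", "build_noise_mode_basis",
    "compute_coefficients", "reconstruct_field", "realtime_solve",
    "sample_modes_at_surface", "locate_points", "save_session", "load_session",
]


# ---------------------------------------------------------------------------
# Point location
# ---------------------------------------------------------------------------

def locate_points(mesh: HeadMesh, points: np.ndarray, candidates: int = 64,
                  tol: float = 1e-9) -> np.ndarray:
    """Tet index containing each point (KD-tree candidates + barycentric test).

    Raises listing the count of points not inside any tet.
    """
    from scipy.spatial import cKDTree

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tree = cKDTree(mesh.tet_centroid)
    k = min(candidates, mesh.n_tets)
    _, cand = tree.query(pts, k=k)
    cand = np.atleast_2d(cand)
    result = np.full(len(pts), -1, dtype=np.int64)
    v0 = mesh.nodes[mesh.tets[:, 0]]
    from .fem import _p1_geometry
    grads, _ = _p1_geometry(mesh)          # grad(lambda) in 1/m; coords in mm
    for rank in range(k):
        todo = result < 0
        if not np.any(todo):
            break
        t = cand[todo, rank]
        d = (pts[todo] - v0[t]) * 1e-3
        lam = np.einsum("kid,kd->ki", grads[t][:, 1:, :], d)
        lam0 = 1.0 - lam.sum(axis=1)
        ok = (lam0 >= -tol) & np.all(lam >= -tol, axis=1)
        idx = np.nonzero(todo)[0][ok]
        result[idx] = t[ok]
    missing = int(np.sum(result < 0))
    if missing:
        raise ValueError(f"{missing} point(s) not inside any mesh tet")
    return result


def sample_modes_at_surface(basis: ModeBasis, mesh: HeadMesh,
                            surface: TriSurface):
    """Mode values at facet barycenters: the containing ROI tet's constant value.

    Returns ``(samples, roi_rows)`` with samples (n_facets, 3, n_modes) and
    ``roi_rows`` the ROI-array row of each barycenter's tet.  Errors listing
    the count of barycenters outside the ROI.
    """
    tets = locate_points(mesh, surface.facet_center)
    roi_row = np.full(mesh.n_tets, -1, dtype=np.int64)
    roi_row[basis.roi_index] = np.arange(len(basis.roi_index))
    rows = roi_row[tets]
    n_out = int(np.sum(rows < 0))
    if n_out:
        raise ValueError(f"{n_out} evaluation point(s) fall outside the ROI")
    return basis.modes[rows], rows


# ---------------------------------------------------------------------------
# Session
# ---------------------------------------------------------------------------

@dataclass
class RealtimeSession:
    """Everything the online stage needs, detached from mesh and FEM machinery."""

    modes_at_eval: np.ndarray          # (n_eval, 3, N_m) float32
    singular_values: np.ndarray
    operator: ReciprocityOperator
    grid: PrimaryFieldGrid
    huygens_centers: np.ndarray        # (N_d, 3) mm, head frame
    eval_centers: np.ndarray           # (n_eval, 3) mm
    eval_roi_rows: np.ndarray          # ROI row per evaluation point
    dIdt: float = 6.6e7
    meta: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.modes_at_eval.shape[2]


def _probe_fields(mesh: HeadMesh, huygens: TriSurface, W: np.ndarray, op,
                  fem_tol: float) -> np.ndarray:
    """Total brain E-field per probe current sheet: E_W = E_WP - grad(phi)."""
    E_wp = magnetic_current_primary_efield(W, huygens, mesh.tet_centroid)
    roi = mesh.roi_mask
    n = W.shape[2]
    fields = np.empty((int(roi.sum()), 3, n))
    for i in range(n):
        src = CellField(mesh.conductivity[:, None] * E_wp[:, :, i], mesh)
        phi = solve_neumann(op, build_rhs(mesh, src), tol=fem_tol)
        fields[:, :, i] = (E_wp[:, :, i] - gradient_field(mesh, phi).values)[roi]
    return fields


def _probe_adjoint(mesh: HeadMesh, huygens: TriSurface, fields: np.ndarray,
                   op, fem_tol: float) -> np.ndarray:
    """Adjoint of the probe-to-field map under the volume-weighted inner product.

    Maps ROI fields back to surface current sheets; used by the randomized
    subspace iteration to sharpen the probed range toward the operator's
    leading singular directions.
    """
    from ._kernels import cross_sum
    from .fem import _p1_geometry

    grads, vol = _p1_geometry(mesh)
    roi_idx = mesh.roi_index
    n = fields.shape[2]
    W_out = np.empty((huygens.facet_count, 3, n))
    y = np.zeros((mesh.n_tets, 3, n))
    y[roi_idx] = fields * (mesh.tet_volume[roi_idx] * 1e-9)[:, None, None]
    # u = G^T y (nodal), v = A^-1 u, w = sigma * vol * grad(v) per cell
    u = np.zeros((mesh.n_nodes, n))
    be = np.einsum("kid,kdC->kiC", grads, y)
    np.add.at(u, mesh.tets.reshape(-1), be.reshape(-1, n))
    w = np.empty_like(y)
    for i in range(n):
        v = solve_neumann(op, u[:, i], tol=fem_tol)
        w[:, :, i] = (mesh.conductivity * vol)[:, None] * \
            np.einsum("kid,ki->kd", grads, v.values[mesh.tets])
    # C^T (y - w): transposed magnetic-current kernel
    resid = y - w
    cs = cross_sum(huygens.facet_center * 1e-3, mesh.tet_centroid * 1e-3,
                   np.ones(mesh.n_tets), resid)
    W_out = -(huygens.facet_area * 1e-6)[:, None, None] * cs
    return W_out


def build_noise_mode_basis(mesh: HeadMesh, huygens: TriSurface, n_modes: int,
                           seed: int, operator=None, fem_tol: float = 1e-10,
                           oversample: float = 1.5,
                           power_iterations: int = 2) -> ModeBasis:
    """Offline steps 1-2: white-noise probing solves and the SVD mode basis.

    ``oversample`` draws ``ceil(oversample * n_modes)`` noise realizations and
    ``power_iterations`` applies that many rounds of randomized subspace
    iteration (adjoint + forward passes) before the QR+SVD, then truncates to
    the leading ``n_modes`` modes.  ``oversample=1, power_iterations=0``
    reproduces the plain range finder (one field per requested mode), which
    suffices when the probe spectrum decays fast; the defaults recover
    near-optimal subspaces on coarse desk-scale phantoms whose spectra have
    heavy tails.
    """
    op = operator if operator is not None else assemble_conduction_system(mesh)
    n_probe = int(np.ceil(oversample * n_modes))
    noise = sample_white_noise_currents(huygens, n_probe, seed)
    W = noise.W
    fields = _probe_fields(mesh, huygens, W, op, fem_tol)
    for _ in range(power_iterations):
        W = _probe_adjoint(mesh, huygens, fields, op, fem_tol)
        # re-orthonormalize probe block to stop the iteration collapsing
        Wf = W.reshape(-1, n_probe)
        Wq, _ = np.linalg.qr(Wf)
        W = Wq.reshape(W.shape)
        fields = _probe_fields(mesh, huygens, W, op, fem_tol)
    return build_basis(fields, mesh, n_keep=n_modes)


def precompute_session(mesh: HeadMesh, huygens: TriSurface, coil: CoilModel,
                       n_modes: int, seed: int, eval_surface: TriSurface,
                       dIdt: float = 6.6e7, grid_spacing: float = 4.0,
                       grid_bounds=None, fem_tol: float = 1e-10,
                       standoff: float = 5.0, basis: "ModeBasis | None" = None,
                       oversample: float = 1.5, power_iterations: int = 2,
                       **surface_field_kwargs) -> RealtimeSession:
    """Offline stage: build modes, equivalent currents, grid, and eval samples.

    Deterministic for a fixed ``seed``.  All heavy lineal algebra runs in
    double precision; the stored online operators are cast to single.
    ``basis`` may be passed to reuse a previously built mode basis.
    """
    t0 = time.perf_counter()
    op = assemble_conduction_system(mesh)
    op.factor()
    logger.info("assembled + factored conduction system (%.1fs)", time.perf_counter() - t0)

    if basis is None:
        basis = build_noise_mode_basis(mesh, huygens, n_modes, seed, operator=op,
                                       fem_tol=fem_tol, oversample=oversample,
                                       power_iterations=power_iterations)
        logger.info("built %d-mode basis (%.1fs)", basis.n_modes, time.perf_counter() - t0)
    if basis.n_modes < n_modes:
        raise ValueError(f"basis provides {basis.n_modes} modes < requested {n_modes}")

    # impressed-current solves: total current J = M + sigma * (-grad phi)
    J = np.zeros((mesh.n_tets, 3, n_modes))
    for i in range(n_modes):
        M_full = basis.mode_field(i, mesh)
        phi = solve_neumann(op, build_rhs(mesh, M_full), tol=fem_tol)
        J[:, :, i] = M_full.values - mesh.conductivity[:, None] * \
            gradient_field(mesh, phi).values
    logger.info("impressed-current solves done (%.1fs)", time.perf_counter() - t0)

    sfields = surface_fields_from_volume_currents(mesh, J, huygens,
                                                  **surface_field_kwargs)
    del J
    currents = equivalent_currents(sfields, huygens)
    recip = build_reciprocity_operator(currents, huygens,
                                       charge_potential=sfields.psi)
    logger.info("Huygens currents + reciprocity operator (%.1fs)", time.perf_counter() - t0)

    grid = build_primary_grid(coil, spacing=grid_spacing, bounds=grid_bounds,
                              huygens=huygens, standoff=standoff)
    logger.info("primary grid %s = %d nodes (%.1fs)", grid.counts, grid.n_points,
                time.perf_counter() - t0)

    samples, rows = sample_modes_at_surface(basis, mesh, eval_surface)

    meta = {
        "mesh_hash": mesh_hash(mesh),
        "coil_name": coil.name,
        "seed": int(seed),
        "n_modes": int(n_modes),
        "grid_spacing": float(grid_spacing),
        "standoff": float(standoff),
    }
    return RealtimeSession(samples.astype(np.float32), basis.singular_values,
                           recip, grid, huygens.facet_center.copy(),
                           eval_surface.facet_center.copy(), rows, dIdt, meta)


# ---------------------------------------------------------------------------
# Online stage
# ---------------------------------------------------------------------------

def compute_coefficients(session: RealtimeSession, E_p: np.ndarray,
                         H_p: np.ndarray) -> np.ndarray:
    """Mode coefficients a = B.[E_p; H_p] from unit-dI/dt primary fields."""
    if np.asarray(E_p).shape != (len(session.huygens_centers), 3):
        raise ValueError("primary fields must be sampled at the session's facet centers")
    return session.operator.coefficients(E_p, H_p)


def reconstruct_field(session: RealtimeSession, a: np.ndarray,
                      n_use: "int | None" = None) -> np.ndarray:
    """Mode expansion E = dIdt * sum_i a_i M_i at the evaluation points."""
    a = np.asarray(a, dtype=np.float32)
    if n_use is None:
        n_use = session.n_modes
    if n_use > session.n_modes or n_use > len(a):
        raise ValueError(f"n_use={n_use} exceeds available modes")
    if n_use == 0:
        return np.zeros((len(session.eval_centers), 3))
    return session.dIdt * (session.modes_at_eval[:, :, :n_use] @ a[:n_use])


def realtime_solve(session: RealtimeSession, T: Placement,
                   n_use: "int | None" = None):
    """Full online path for one placement; returns (E, coefficients).

    Transforms the Huygens facet centers by T^-1 into the coil frame,
    interpolates the primary fields, evaluates the reciprocity mat-vec, and
    reconstructs the mode expansion.  Stage timings are logged.
    """
    from .grid_interp import transform_points

    t0 = time.perf_counter()
    pts = transform_points(session.huygens_centers, T, inverse=True)
    t1 = time.perf_counter()
    E_p, H_p = interpolate_fields(session.grid, pts)
    # grid samples are coil-frame vectors; rotate into the head frame
    R = T.rotation
    E_p = E_p @ R.T
    H_p = H_p @ R.T
    t2 = time.perf_counter()
    a = compute_coefficients(session, E_p, H_p)
    t3 = time.perf_counter()
    E = reconstruct_field(session, a, n_use)
    logger.debug("realtime stages: transform %.2f ms, interp %.2f ms, "
                 "coeff %.2f ms, recon %.2f ms", 1e3 * (t1 - t0),
                 1e3 * (t2 - t1), 1e3 * (t3 - t2),
                 1e3 * (time.perf_counter() - t3))
    return E, a


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def mesh_hash(mesh: HeadMesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.nodes).tobytes())
    h.update(np.ascontiguousarray(mesh.tets).tobytes())
    h.update(np.ascontiguousarray(mesh.region_label).tobytes())
    return h.hexdigest()[:16]


def save_session(session: RealtimeSession, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("basis")
        g.create_dataset("modes_at_eval", data=session.modes_at_eval)
        g.create_dataset("singular_values", data=session.singular_values)
        g = f.create_group("huygens")
        g.create_dataset("B", data=session.operator.B)
        g.create_dataset("centers", data=session.huygens_centers)
        g = f.create_group("grid")
        g.create_dataset("E", data=session.grid.E.astype(np.float32))
        g.create_dataset("H", data=session.grid.H.astype(np.float32))
        g.attrs["origin"] = session.grid.origin
        g.attrs["spacing"] = session.grid.spacing
        g.attrs["counts"] = session.grid.counts
        g = f.create_group("eval")
        g.create_dataset("centers", data=session.eval_centers)
        g.create_dataset("roi_rows", data=session.eval_roi_rows)
        g = f.create_group("meta")
        g.attrs["dIdt"] = session.dIdt
        for k, v in session.meta.items():
            g.attrs[k] = v


def load_session(path) -> RealtimeSession:
    import h5py

    from .huygens import ReciprocityOperator

    with h5py.File(path, "r") as f:
        huy_centers = f["huygens/centers"][()]
        # the online stage needs only B and the facet centers, not the surface
        op = ReciprocityOperator.__new__(ReciprocityOperator)
        op.B = f["huygens/B"][()]
        op.surface = None
        g = f["grid"]
        grid = PrimaryFieldGrid(g.attrs["origin"], float(g.attrs["spacing"]),
                                tuple(int(c) for c in g.attrs["counts"]),
                                g["E"][()].astype(float), g["H"][()].astype(float))
        meta = {k: v for k, v in f["meta"].attrs.items() if k != "dIdt"}
        return RealtimeSession(
            f["basis/modes_at_eval"][()], f["basis/singular_values"][()],
            op, grid, huy_centers, f["eval/centers"][()],
            f["eval/roi_rows"][()], float(f["meta"].attrs["dIdt"]), meta)
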