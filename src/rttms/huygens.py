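"""Mode fields on the Huygens surface and equivalent surface currents.

Each orthonormal brain mode, impressed as a volume current density M(i), adds
to the conduction response sigma*E it drives; the total current
J = M + sigma*E radiates the quasistatic fields evaluated at the Huygens
facet centers (peak-normalized spatial parts):

    E(r) = -(mu0/4pi) sum_k V_k J_k / |r - c_k|          (-dA/dt term)
    H(r) =  (1/4pi)   sum_k V_k J_k x (r - c_k)/|r-c_k|^3  (Biot-Savart)

The surface equivalence principle then gives the equivalent currents
J_S = n x H and K_S = -n x E, which assemble into the reciprocity operator B
so that mode coefficients follow from a = B.[E_p; H_p] for any coil primary
field on the surface.

A single-point quadrature per tet is used everywhere except for source tets
close to an observer (within ``near_threshold`` tet diameters), whose
contribution is re-integrated on a recursive 8-fold tet subdivision; this
keeps the surface fields accurate when tets are larger than the 1 mm
scalp-to-surface gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import FOUR_PI, coulomb_sum, cross_sum, dot_sum
from .mesh_core import CellField, HeadMesh, TriSurface

MU0 = 4.0e-7 * np.pi
MM = 1e-3

__all__ = [
    "SurfaceFieldSet", "HuygensCurrentSet", "ReciprocityOperator",
    "mode_fields_on_surface", "surface_fields_from_volume_currents",
    "equivalent_currents", "build_reciprocity_operator",
]


@dataclass
class SurfaceFieldSet:
    """Per-facet E and H samples per mode at Huygens facet centers.

    Shapes are (n_facets, 3, n_modes); units V*s/m for E (per unit dI/dt)
    and A/m for H (per unit peak current).  ``psi`` is the dipole (scalar)
    potential of the source current's irrotational component,

        psi(r) = (1/4pi) sum_k V_k J_k . (r - c_k) / |r - c_k|^3,

    used as a charge-consistency correction in the reciprocity operator: the
    discretized volume current is only weakly divergence-free, and the term
    ``+ A_j psi(r_j) (E_p . n)`` restores the surface/volume reciprocity
    identity (it vanishes as the current becomes solenoidal).
    """

    E: np.ndarray
    H: np.ndarray
    surface: TriSurface
    psi: np.ndarray = None  # type: ignore[assignment]


@dataclass
class HuygensCurrentSet:
    """Tangential equivalent currents J_S = n x H and K_S = -n x E per mode."""

    J_S: np.ndarray
    K_S: np.ndarray
    surface: TriSurface


@dataclass
class ReciprocityOperator:
    """Dense map from stacked surface primary fields to mode coefficients.

    Row i holds [A_j * J_S(i)(r_j) ; -A_j * K_S(i)(r_j)] over facets j
    (areas in m^2), so that a = B @ concat(E_p.ravel(), H_p.ravel())
    reproduces the single-point quadrature of the reciprocity integral.
    Stored in single precision (adequate online; built in double).
    """

    B: np.ndarray
    surface: TriSurface

    @property
    def n_modes(self) -> int:
        return self.B.shape[0]

    def coefficients(self, E_p: np.ndarray, H_p: np.ndarray) -> np.ndarray:
        x = np.concatenate([np.asarray(E_p, dtype=np.float32).ravel(),
                            np.asarray(H_p, dtype=np.float32).ravel()])
        if x.shape[0] != self.B.shape[1]:
            raise ValueError("primary field length does not match the operator")
        return self.B @ x


# ---------------------------------------------------------------------------
# Volume-current radiation onto the surface
# ---------------------------------------------------------------------------

_MIDPOINT_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
# octasection of a tet into 8 equal-volume children (corner + interior tets)
_CHILD_TETS = [
    (0, 4, 5, 6), (4, 1, 7, 8), (5, 7, 2, 9), (6, 8, 9, 3),
    (4, 5, 6, 8), (4, 5, 8, 7), (5, 6, 8, 9), (5, 7, 8, 9),
]


def _subdivide_points(verts: np.ndarray, depth: int):
    """Centroids and equal weights of the depth-fold octasection of tets.

    ``verts``: (P, 4, 3) -> centroids (P, 8**depth, 3), weight fraction 8**-depth.
    """
    current = verts[:, None, :, :]                       # (P, 1, 4, 3)
    for _ in range(depth):
        P, Q = current.shape[:2]
        mids = 0.5 * (current[:, :, [p[0] for p in _MIDPOINT_PAIRS]]
                      + current[:, :, [p[1] for p in _MIDPOINT_PAIRS]])
        allpts = np.concatenate([current, mids], axis=2)  # (P, Q, 10, 3)
        children = allpts[:, :, _CHILD_TETS, :]           # (P, Q, 8, 4, 3)
        current = children.reshape(P, Q * 8, 4, 3)
    return current.mean(axis=2), 8.0 ** (-depth)


def surface_fields_from_volume_currents(
    mesh: HeadMesh, currents: np.ndarray, surface: TriSurface,
    near_threshold: float = 3.0, near_depth: int = 2,
    min_gap_mm: float = 0.3, chunk_pairs: int = 4096,
) -> SurfaceFieldSet:
    """Radiate per-tet volume currents (n_tets, 3[, m]) onto facet centers.

    Uses the centroid rule globally plus subdivided quadrature for (facet,
    tet) pairs closer than ``near_threshold`` tet diameters (``near_depth``
    recursion levels; 0 disables the correction and reproduces the pure
    single-point rule).  Raises if any facet center is within ``min_gap_mm``
    of a tet centroid (surface touching or inside the head).
    """
    from scipy.spatial import cKDTree

    J = np.asarray(currents, dtype=float)
    squeeze = J.ndim == 2
    if squeeze:
        J = J[:, :, None]
    if J.shape[:2] != (mesh.n_tets, 3):
        raise ValueError("currents must be given per tet on the full mesh")

    obs = surface.facet_center * MM
    src = mesh.tet_centroid * MM
    vol = mesh.tet_volume * MM**3

    E = -MU0 * coulomb_sum(obs, src, vol, J, min_dist=min_gap_mm * MM)
    H = cross_sum(obs, src, vol, J)
    psi = dot_sum(obs, src, vol, J)

    if near_depth > 0:
        import scipy.sparse as sp

        p = mesh.nodes[mesh.tets] * MM
        diam = np.max([np.linalg.norm(p[:, a] - p[:, b], axis=1)
                       for a, b in _MIDPOINT_PAIRS], axis=0)
        tree = cKDTree(obs)
        radius = near_threshold * diam
        # active: only tets whose correction ball can reach the surface
        d_surf, _ = tree.query(src, k=1)
        active = np.nonzero(d_surf < radius)[0]
        balls = tree.query_ball_point(src[active], radius[active])
        pair_t = np.repeat(active, [len(b) for b in balls])
        pair_o = np.concatenate([np.asarray(b, dtype=np.int64) for b in balls]) \
            if len(pair_t) else np.empty(0, dtype=np.int64)
        if len(pair_t):
            uniq, inv = np.unique(pair_t, return_inverse=True)
            subpts, frac = _subdivide_points(p[uniq], near_depth)   # (U, S, 3)
            gE = np.empty(len(pair_t))
            gH = np.empty((len(pair_t), 3))
            for a in range(0, len(pair_t), chunk_pairs):
                sl = slice(a, min(a + chunk_pairs, len(pair_t)))
                t, o, u = pair_t[sl], pair_o[sl], inv[sl]
                d_sub = obs[o][:, None, :] - subpts[u]               # (P, S, 3)
                r_sub = np.linalg.norm(d_sub, axis=2)
                if r_sub.min() < min_gap_mm * MM:
                    raise ValueError("surface point touches the head during "
                                     "near-field quadrature")
                d0 = obs[o] - src[t]
                r0 = np.linalg.norm(d0, axis=1)
                w = vol[t] * frac
                # scalar Coulomb and vector Biot-Savart geometric corrections
                gE[sl] = w * (1.0 / r_sub).sum(axis=1) - vol[t] / r0
                gH[sl] = (w[:, None] * (d_sub / r_sub[..., None] ** 3).sum(axis=1)
                          - (vol[t] / r0**3)[:, None] * d0)
            # apply as sparse (facet x tet) operators against the mode columns
            shape = (len(obs), mesh.n_tets)
            S_e = sp.csr_matrix((gE, (pair_o, pair_t)), shape=shape)
            S = [sp.csr_matrix((gH[:, c], (pair_o, pair_t)), shape=shape)
                 for c in range(3)]
            Jx, Jy, Jz = J[:, 0], J[:, 1], J[:, 2]
            E += (-MU0 / FOUR_PI) * np.stack(
                [S_e @ Jx, S_e @ Jy, S_e @ Jz], axis=1)
            # J x gH = (Jy gz - Jz gy, Jz gx - Jx gz, Jx gy - Jy gx)
            H[:, 0] += (S[2] @ Jy - S[1] @ Jz) / FOUR_PI
            H[:, 1] += (S[0] @ Jz - S[2] @ Jx) / FOUR_PI
            H[:, 2] += (S[1] @ Jx - S[0] @ Jy) / FOUR_PI
            psi += (S[0] @ Jx + S[1] @ Jy + S[2] @ Jz) / FOUR_PI

    if squeeze:
        E, H, psi = E[:, :, 0], H[:, :, 0], psi[:, 0]
    return SurfaceFieldSet(E, H, surface, psi)


def mode_fields_on_surface(mesh: HeadMesh, mode: CellField,
                           conduction_field: CellField, surface: TriSurface,
                           **kwargs) -> SurfaceFieldSet:
    """Fields of one impressed mode current on the Huygens surface.

    ``mode`` is the impressed current M(i) (ROI or full mesh), and
    ``conduction_field`` the FEM E-field it drives inside the head; the total
    source is J = M + sigma*E over the whole conducting head.
    """
    J = mode.to_full() + mesh.conductivity[:, None] * conduction_field.to_full()
    return surface_fields_from_volume_currents(mesh, J, surface, **kwargs)


# ---------------------------------------------------------------------------
# Equivalent currents and the reciprocity operator
# ---------------------------------------------------------------------------

def equivalent_currents(fields: SurfaceFieldSet, surface: TriSurface) -> HuygensCurrentSet:
    """Love equivalence: J_S = n x H, K_S = -n x E (tangential by construction)."""
    n = surface.outward_normal
    if fields.E.shape[0] != surface.facet_count:
        raise ValueError("field set does not match the surface")
    E, H = fields.E, fields.H
    squeeze = E.ndim == 2
    if squeeze:
        E, H = E[:, :, None], H[:, :, None]
    J_S = np.cross(n[:, None, :], H.transpose(0, 2, 1)).transpose(0, 2, 1)
    K_S = -np.cross(n[:, None, :], E.transpose(0, 2, 1)).transpose(0, 2, 1)
    if squeeze:
        J_S, K_S = J_S[:, :, 0], K_S[:, :, 0]
    return HuygensCurrentSet(J_S, K_S, surface)


def build_reciprocity_operator(currents: HuygensCurrentSet, surface: TriSurface,
                               charge_potential: "np.ndarray | None" = None
                               ) -> ReciprocityOperator:
    """Pack area-weighted currents into the coefficient matrix B (single precision).

    When ``charge_potential`` (the per-facet, per-mode dipole potential ``psi``
    of the mode current's irrotational residue) is supplied, the E-field block
    carries the charge-consistency correction ``A_j (J_S + psi n)``; without
    it the operator is the plain single-point reciprocity quadrature.
    """
    J_S, K_S = currents.J_S, currents.K_S
    if J_S.ndim == 2:
        J_S, K_S = J_S[:, :, None], K_S[:, :, None]
    e_block = J_S
    if charge_potential is not None:
        psi = np.asarray(charge_potential, dtype=float)
        if psi.ndim == 1:
            psi = psi[:, None]
        if psi.shape != (J_S.shape[0], J_S.shape[2]):
            raise ValueError("charge potential shape does not match the currents")
        e_block = J_S + psi[:, None, :] * surface.outward_normal[:, :, None]
    areas = surface.facet_area * MM**2
    rows_e = (areas[:, None, None] * e_block).reshape(-1, J_S.shape[2]).T
    rows_h = (areas[:, None, None] * -K_S).reshape(-1, K_S.shape[2]).T
    B = np.concatenate([rows_e, rows_h], axis=1).astype(np.float32)
    return ReciprocityOperator(B, surface)
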