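"""White-noise magnetic surface currents and the orthonormal E-field mode basis.

The basis construction probes the head with ``N_m`` random magnetic surface
current sheets on the Huygens surface, solves the conduction problem for
each, and orthogonalizes the induced brain E-fields under the volume-weighted
inner product

    <f, g> = int_ROI f.g dV = sum_k V_k f_k.g_k .

Stacking sqrt(V_k)-weighted field components as columns of Z makes plain
column dot products equal this inner product, so an economic QR of Z followed
by an SVD of R yields modes M(i) (the columns of U = Q*U~ divided by
sqrt(V_k)) that are exactly orthonormal under <.,.>, ordered by non-increasing
singular value, and nested under truncation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import cross_sum
from .mesh_core import CellField, HeadMesh, TriSurface

logger = logging.getLogger(__name__)

MM = 1e-3

__all__ = [
    "NoiseRealizationSet", "ModeBasis", "sample_white_noise_currents",
    "magnetic_current_primary_efield", "build_basis", "gram_matrix",
]


@dataclass
class NoiseRealizationSet:
    """I.i.d. standard-normal magnetic surface currents, one sheet per realization.

    ``W`` has shape (n_facets, 3, n_realizations), in arbitrary source units
    (the SVD normalizes any global scale away).  Realization ``i`` is drawn
    from a counter-based Philox stream keyed by ``(seed, i)``, so it does not
    depend on how many realizations are requested.
    """

    W: np.ndarray
    seed: int
    surface: TriSurface


def sample_white_noise_currents(surface: TriSurface, n_realizations: int,
                                seed: int) -> NoiseRealizationSet:
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    n_d = surface.facet_count
    W = np.empty((n_d, 3, n_realizations))
    for i in range(n_realizations):
        gen = np.random.Generator(np.random.Philox(key=np.array([seed, i], dtype=np.uint64)))
        W[:, :, i] = gen.standard_normal((n_d, 3))
    return NoiseRealizationSet(W, seed, surface)


def magnetic_current_primary_efield(W: np.ndarray, surface: TriSurface,
                                    points: np.ndarray,
                                    min_gap_mm: float = 1e-6) -> np.ndarray:
    """Free-space E-field of piecewise-constant magnetic surface currents.

    Single-point quadrature per facet:

        E(r) = - sum_j A_j W_j x (r - r_j) / (4 pi |r - r_j|^3)

    ``W`` is (n_facets, 3) for one realization or (n_facets, 3, m) for a
    batch; the result matches (n_points, 3[, m]).  Points must stay off the
    facet centers (singular kernel).
    """
    W = np.asarray(W, dtype=float)
    if W.shape[0] != surface.facet_count or W.shape[1] != 3:
        raise ValueError("W shape does not match the surface facet count")
    obs = np.asarray(points, dtype=float) * MM
    src = surface.facet_center * MM
    areas = surface.facet_area * MM**2
    return -cross_sum(obs, src, areas, W, min_dist=min_gap_mm * MM)


@dataclass
class ModeBasis:
    """Orthonormal per-tet vector modes on the ROI with singular values.

    ``modes`` has shape (n_roi, 3, n_modes) with units m^(-3/2) (unit norm
    under the volume-weighted inner product); ``volumes_m3`` are the ROI tet
    volumes used for the weighting; ``roi_index`` maps ROI rows to mesh tets.
    """

    modes: np.ndarray
    singular_values: np.ndarray
    volumes_m3: np.ndarray
    roi_index: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.modes.shape[2]

    def truncated(self, n_keep: int) -> "ModeBasis":
        if n_keep > self.n_modes:
            raise ValueError(f"cannot keep {n_keep} of {self.n_modes} modes")
        return ModeBasis(self.modes[:, :, :n_keep], self.singular_values[:n_keep],
                         self.volumes_m3, self.roi_index)

    def mode_field(self, i: int, mesh: HeadMesh) -> CellField:
        """Mode ``i`` as an impressed-current CellField on the full mesh."""
        full = np.zeros((mesh.n_tets, 3))
        full[self.roi_index] = self.modes[:, :, i]
        return CellField(full, mesh, units="mode")


def build_basis(noise_fields: "list[CellField] | np.ndarray", mesh: HeadMesh,
                n_keep: "int | None" = None,
                rank_rtol: float = 1e-12) -> ModeBasis:
    """Volume-weighted QR+SVD orthogonalization of ROI noise E-fields.

    ``noise_fields`` is a list of ROI CellFields or an (n_roi, 3, n) array.
    Modes are ordered by non-increasing singular value and truncated to
    ``n_keep``; a numerically rank-deficient tail (relative singular value
    below ``rank_rtol``) is truncated with a warning.
    """
    import scipy.linalg as sla

    if isinstance(noise_fields, (list, tuple)):
        arr = np.stack([f.values for f in noise_fields], axis=2)
    else:
        arr = np.asarray(noise_fields, dtype=float)
    roi_index = mesh.roi_index
    n_roi = len(roi_index)
    if arr.shape[:2] != (n_roi, 3):
        raise ValueError("noise fields must be sampled on the mesh ROI")
    n = arr.shape[2]
    if n_keep is None:
        n_keep = n
    if n_keep > n:
        raise ValueError(f"n_keep={n_keep} exceeds {n} realizations")

    vol = mesh.tet_volume[roi_index] * MM**3
    sqrt_v = np.sqrt(vol)
    Z = (arr * sqrt_v[:, None, None]).reshape(3 * n_roi, n)
    Q, R = sla.qr(Z, mode="economic")
    U_t, svals, _ = sla.svd(R)
    U = Q @ U_t

    rank = int(np.sum(svals > rank_rtol * svals[0])) if svals[0] > 0 else 0
    if rank < n_keep:
        logger.warning("basis rank %d below requested %d modes; truncating", rank, n_keep)
        n_keep = rank
    modes = (U[:, :n_keep].reshape(n_roi, 3, n_keep)) / sqrt_v[:, None, None]
    return ModeBasis(modes, svals[:n_keep], vol, roi_index)


def gram_matrix(basis: ModeBasis) -> np.ndarray:
    """Gram matrix of the modes under the volume-weighted inner product."""
    Z = basis.modes * np.sqrt(basis.volumes_m3)[:, None, None]
    Zf = Z.reshape(-1, basis.n_modes)
    return Zf.T @ Zf
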