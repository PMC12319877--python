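"""Cartesian primary-field grids in the coil frame and rigid-transform lookup.

The coil's primary E and H fields are translation-invariant in the coil
frame, so they are precomputed once on an axis-aligned grid below the coil
plane and fetched online by mapping the Huygens facet centers through the
inverse placement transform and trilinearly interpolating the six field
components.  Out-of-bounds queries are a hard error (no extrapolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coil import CoilModel, Placement, coil_primary_fields
from .mesh_core import TriSurface

__all__ = ["PrimaryFieldGrid", "build_primary_grid", "transform_points",
           "interpolate_fields", "envelope_bounds"]


@dataclass
class PrimaryFieldGrid:
    """E_p/H_p samples (unit dI/dt, unit peak current) on a coil-frame grid.

    ``E`` and ``H`` have shape (nx, ny, nz, 3); axes are in mm.
    """

    origin: np.ndarray
    spacing: float
    counts: tuple
    E: np.ndarray
    H: np.ndarray
    axes: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = tuple(self.origin[d] + self.spacing * np.arange(self.counts[d])
                          for d in range(3))

    @property
    def bounds(self):
        hi = self.origin + self.spacing * (np.asarray(self.counts) - 1)
        return self.origin.copy(), hi

    @property
    def n_points(self) -> int:
        return int(np.prod(self.counts))


def envelope_bounds(huygens: TriSurface, standoff: float = 5.0,
                    max_tilt_deg: float = 25.0, margin: float = 10.0):
    """Coil-frame bounding box covering the Huygens surface for any tangential
    placement with the given standoff and scalp-normal tilt budget.

    The head (circumradius ``rho`` about its centroid) sits roughly
    ``d = rho + standoff`` below the coil origin along -z, fanned out by the
    tilt of scalp normals against the head-center direction.
    """
    c = huygens.nodes.mean(axis=0)
    rho = float(np.linalg.norm(huygens.nodes - c, axis=1).max())
    d = rho + standoff
    tilt = np.deg2rad(max_tilt_deg)
    lateral = rho + d * np.sin(tilt) + margin
    z_min = -(d + rho + margin)
    z_max = rho - (d - standoff) * np.cos(tilt) - standoff + margin
    lo = np.array([-lateral, -lateral, z_min])
    hi = np.array([lateral, lateral, z_max])
    return lo, hi


def build_primary_grid(coil: CoilModel, spacing: float = 4.0,
                       bounds=None, huygens: "TriSurface | None" = None,
                       **envelope_kwargs) -> PrimaryFieldGrid:
    """Sample the coil primary fields on a grid covering the placement envelope.

    ``bounds=(lo, hi)`` may be given explicitly; otherwise they are derived
    from the Huygens surface via :func:`envelope_bounds`.
    """
    if bounds is None:
        if huygens is None:
            raise ValueError("need explicit bounds or a Huygens surface")
        bounds = envelope_bounds(huygens, **envelope_kwargs)
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    if np.any(hi <= lo):
        raise ValueError("invalid grid bounds")
    counts = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    axes = [lo[d] + spacing * np.arange(counts[d]) for d in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    E, H = coil_primary_fields(coil, pts, dIdt=1.0)
    return PrimaryFieldGrid(lo, spacing, counts,
                            E.reshape(*counts, 3), H.reshape(*counts, 3))


def transform_points(points: np.ndarray, T: Placement,
                     inverse: bool = False) -> np.ndarray:
    """Apply a rigid placement (or its inverse, the online default) to points."""
    if not isinstance(T, Placement):
        T = Placement(T)
    return (T.inverse() if inverse else T).apply(np.asarray(points, dtype=float))


def interpolate_fields(grid: PrimaryFieldGrid, points: np.ndarray):
    """Trilinear E_p/H_p at coil-frame points (mm); errors on out-of-bounds."""
    from scipy.interpolate import RegularGridInterpolator

    pts = np.asarray(points, dtype=float)
    lo, hi = grid.bounds
    outside = np.any((pts < lo - 1e-9) | (pts > hi + 1e-9), axis=1)
    n_out = int(outside.sum())
    if n_out:
        ext_lo, ext_hi = pts.min(axis=0), pts.max(axis=0)
        raise ValueError(
            f"{n_out} point(s) outside the primary-field grid bounds "
            f"(query extent {ext_lo.round(1)}..{ext_hi.round(1)}, "
            f"grid {lo.round(1)}..{hi.round(1)}); no extrapolation")
    pts = np.clip(pts, lo, hi)
    interp = RegularGridInterpolator(
        grid.axes, np.concatenate([grid.E, grid.H], axis=3), method="linear")
    vals = interp(pts)
    return vals[:, :3], vals[:, 3:]
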