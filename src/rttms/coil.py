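"""TMS coil models as weighted element clouds, and rigid coil placements.

A coil is a cloud of elements in its own frame (coil flat on and centered
about the x-y plane, head in the z<0 half-space).  Two representations are
supported: ``electric`` elements carry straight current-segment vectors
I*dl (A*mm per unit peak coil current), ``magnetic`` elements carry dipole
moments (A*mm^2).  Primary fields at unit peak current are

    electric:  E_p = -(mu0 dIdt / 4pi) sum w_j / |r-r_j|
               H_p =  (1/4pi)          sum w_j x (r-r_j) / |r-r_j|^3
    magnetic:  E_p = -(mu0 dIdt / 4pi) sum m_j x (r-r_j) / |r-r_j|^3
               H_p =  (1/4pi)          sum [3(m_j.u)u - m_j] / |r-r_j|^3

with u the unit separation vector.  E_p scales with the current slew rate
dI/dt, H_p with the (unit peak) current itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import FOUR_PI, coulomb_sum, cross_sum

MU0 = 4.0e-7 * np.pi  # H/m
MM = 1e-3

__all__ = [
    "CoilModel", "Placement", "build_figure8_coil", "load_coil_file",
    "save_coil_file", "coil_primary_fields", "transform_coil",
    "tangential_placement",
]


@dataclass
class CoilModel:
    positions: np.ndarray          # (N, 3) mm, coil frame
    weights: np.ndarray            # (N, 3) A*mm (electric) or A*mm^2 (magnetic)
    representation: str = "electric"
    name: str = "coil"

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.representation not in ("electric", "magnetic"):
            raise ValueError(f"unknown representation {self.representation!r}")
        if len(self.positions) < 1 or self.positions.shape != self.weights.shape:
            raise ValueError("coil needs >= 1 element with matching weight shape")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.weights))):
            raise ValueError("non-finite coil data")

    @property
    def n_elements(self) -> int:
        return len(self.positions)


@dataclass
class Placement:
    """Rigid transform T = [R|t; 0 1] from the coil frame to head coordinates."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("placement must be a 4x4 matrix")
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("placement rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("placement rotation is improper (det < 0)")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-12):
            raise ValueError("last placement row must be [0 0 0 1]")

    @classmethod
    def identity(cls) -> "Placement":
        return cls(np.eye(4))

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "Placement":
        Rt = self.rotation.T
        out = np.eye(4)
        out[:3, :3] = Rt
        out[:3, 3] = -Rt @ self.translation
        return Placement(out)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


def tangential_placement(scalp_point: np.ndarray, outward_normal: np.ndarray,
                         standoff: float = 5.0, angle: float = 0.0) -> Placement:
    """Coil centered ``standoff`` mm above a scalp landmark, tangent-oriented.

    The coil z-axis maps onto the outward normal (head below the coil plane);
    ``angle`` rotates the coil about its own axis.
    """
    n = np.asarray(outward_normal, dtype=float)
    n = n / np.linalg.norm(n)
    seed = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(seed, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    c, s = np.cos(angle), np.sin(angle)
    x_axis = c * u + s * v
    y_axis = np.cross(n, x_axis)
    T = np.eye(4)
    T[:3, 0], T[:3, 1], T[:3, 2] = x_axis, y_axis, n
    T[:3, 3] = np.asarray(scalp_point, dtype=float) + standoff * n
    return Placement(T)


def transform_coil(coil: CoilModel, placement: Placement) -> CoilModel:
    """Coil expressed in head coordinates (positions and weights rotated)."""
    return CoilModel(placement.apply(coil.positions),
                     coil.weights @ placement.rotation.T,
                     coil.representation, coil.name)


# ---------------------------------------------------------------------------
# Figure-8 builder
# ---------------------------------------------------------------------------

def build_figure8_coil(inner_diam: float = 53.0, outer_diam: float = 88.0,
                       turns: int = 9, segments_per_turn: int = 32,
                       name: str = "fig8") -> CoilModel:
    """Figure-8 coil: two wings of concentric circular loops, counter-wound.

    Each wing holds ``turns`` closed circular loops with radii linearly
    spaced between the inner and outer radius, discretized into
    ``segments_per_turn`` straight current elements; wing centers sit at
    +/- outer radius on the x-axis so the windings are externally tangent.
    Counter-winding makes the two wings' fields add under the coil center.
    Element weights of each closed loop sum to zero exactly.
    """
    if segments_per_turn < 16:
        raise ValueError("segments_per_turn must be >= 16")
    if inner_diam >= outer_diam:
        warnings.warn("figure-8 windings overlap: inner diameter >= outer", stacklevel=2)
    r_in, r_out = inner_diam / 2.0, outer_diam / 2.0
    radii = np.linspace(r_in, r_out, turns)
    theta = np.linspace(0.0, 2.0 * np.pi, segments_per_turn + 1)
    positions, weights = [], []
    for sense, xc in ((+1.0, -r_out), (-1.0, +r_out)):
        for rho in radii:
            pts = np.column_stack([xc + rho * np.cos(theta), sense * rho * np.sin(theta),
                                   np.zeros_like(theta)])
            mid = 0.5 * (pts[1:] + pts[:-1])
            dl = pts[1:] - pts[:-1]
            positions.append(mid)
            weights.append(dl)
    return CoilModel(np.concatenate(positions), np.concatenate(weights),
                     "electric", name)


# ---------------------------------------------------------------------------
# ASCII coil files
# ---------------------------------------------------------------------------

_HEADER_PREFIX = "# rttms-coil"


def save_coil_file(coil: CoilModel, path) -> None:
    lines = [f"{_HEADER_PREFIX} representation={coil.representation} units=mm name={coil.name}"]
    for p, w in zip(coil.positions, coil.weights):
        lines.append(" ".join(f"{v:.17g}" for v in (*p, *w)))
    Path(path).write_text("\n".join(lines) + "\n")


def load_coil_file(path) -> CoilModel:
    """Read an ASCII coil file: header line, then one `x y z wx wy wz` per line."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(_HEADER_PREFIX):
        raise ValueError(f"{path}: missing '{_HEADER_PREFIX}' header line")
    fields = dict(kv.split("=", 1) for kv in lines[0][len(_HEADER_PREFIX):].split())
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        try:
            if len(parts) != 6:
                raise ValueError
            rows.append([float(v) for v in parts])
        except ValueError:
            raise ValueError(f"{path}: malformed element on line {lineno}: {line!r}") from None
    rows = np.asarray(rows)
    return CoilModel(rows[:, :3], rows[:, 3:],
                     fields.get("representation", "electric"),
                     fields.get("name", "coil"))


# ---------------------------------------------------------------------------
# Primary fields
# ---------------------------------------------------------------------------

def coil_primary_fields(coil: CoilModel, points: np.ndarray, dIdt: float = 1.0,
                        min_dist_mm: float = 1e-6):
    """Primary E (V/m, scaled by dIdt) and H (A/m, unit peak current) at points (mm)."""
    obs = np.asarray(points, dtype=float) * MM
    src = coil.positions * MM
    min_d = min_dist_mm * MM
    if coil.representation == "electric":
        w = coil.weights * MM                      # A*m
        E = -MU0 * dIdt * coulomb_sum(obs, src, np.ones(len(src)), w, min_dist=min_d)
        H = cross_sum(obs, src, np.ones(len(src)), w, min_dist=min_d)
    else:
        m = coil.weights * MM**2                   # A*m^2
        E = -MU0 * dIdt * cross_sum(obs, src, np.ones(len(src)), m, min_dist=min_d)
        H = _dipole_h(obs, src, m, min_d)
    return E, H


def _dipole_h(obs: np.ndarray, src: np.ndarray, moments: np.ndarray,
              min_dist: float) -> np.ndarray:
    out = np.zeros((len(obs), 3))
    chunk = max(16, int(2**24 / max(len(src), 1)))
    for a in range(0, len(obs), chunk):
        b = min(a + chunk, len(obs))
        d = obs[a:b, None, :] - src[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        if r.min() < min_dist:
            raise ValueError("evaluation at a dipole position; singular kernel")
        u = d / r[..., None]
        mu = np.einsum("jk,ijk->ij", moments, u)
        out[a:b] = np.einsum("ij,ijk->ik", mu / r**3, 3.0 * u) \
            - (1.0 / r**3) @ moments
    return out / FOUR_PI
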