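"""Chunked dense quasistatic field kernels.

All functions work in SI metres and use BLAS matmuls over observer chunks so
that memory stays bounded while throughput stays high.  The two primitives
are the Coulomb-type kernel sum

    out(r) = (1/4pi) * sum_j w_j * v_j / |r - s_j|

and the cross-product (Biot-Savart-type) kernel sum

    out(r) = (1/4pi) * sum_j w_j * v_j x (r - s_j) / |r - s_j|^3,

where ``s_j`` are source points, ``w_j`` scalar quadrature weights (areas or
volumes) and ``v_j`` per-source vectors, possibly for many right-hand
columns at once (``values`` of shape (n_src, 3, m)).
"""

from __future__ import annotations

import numpy as np

FOUR_PI = 4.0 * np.pi


def _chunk_size(n_src: int, budget_bytes: int = 2 << 28) -> int:
    # ~4 dense (chunk x n_src) float64 scratch arrays
    return max(16, int(budget_bytes / (4 * 8 * max(n_src, 1))))


def _as_columns(values: np.ndarray) -> np.ndarray:
    """Normalize values to shape (n_src, 3, m)."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[:, :, None]
    return values


def coulomb_sum(obs: np.ndarray, src: np.ndarray, weights: np.ndarray,
                values: np.ndarray, min_dist: float = 0.0) -> np.ndarray:
    """(1/4pi) sum_j w_j v_j / |r-s_j| -> (n_obs, 3, m) (squeezed if m==1)."""
    obs = np.asarray(obs, dtype=float)
    src = np.asarray(src, dtype=float)
    w = np.asarray(weights, dtype=float)
    v = _as_columns(values)
    m = v.shape[2]
    out = np.empty((len(obs), 3, m))
    vm = (v * w[:, None, None]).reshape(len(src), 3 * m)
    for a in range(0, len(obs), _chunk_size(len(src))):
        b = min(a + _chunk_size(len(src)), len(obs))
        d = obs[a:b, None, :] - src[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        _check_min_dist(r, min_dist)
        out[a:b] = (1.0 / (FOUR_PI * r) @ vm).reshape(b - a, 3, m)
    return out[:, :, 0] if np.asarray(values).ndim == 2 else out


def cross_sum(obs: np.ndarray, src: np.ndarray, weights: np.ndarray,
              values: np.ndarray, min_dist: float = 0.0) -> np.ndarray:
    """(1/4pi) sum_j w_j v_j x (r - s_j)/|r-s_j|^3 -> (n_obs, 3, m)."""
    obs = np.asarray(obs, dtype=float)
    src = np.asarray(src, dtype=float)
    w = np.asarray(weights, dtype=float)
    v = _as_columns(values)
    n_src, _, m = v.shape
    vx, vy, vz = (v[:, c, :] * w[:, None] for c in range(3))
    out = np.empty((len(obs), 3, m))
    for a in range(0, len(obs), _chunk_size(n_src)):
        b = min(a + _chunk_size(n_src), len(obs))
        d = obs[a:b, None, :] - src[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        _check_min_dist(r, min_dist)
        inv_r3 = 1.0 / (FOUR_PI * r**3)
        kx = d[:, :, 0] * inv_r3
        ky = d[:, :, 1] * inv_r3
        kz = d[:, :, 2] * inv_r3
        # v x d = (vy dz - vz dy, vz dx - vx dz, vx dy - vy dx)
        out[a:b, 0] = kz @ vy - ky @ vz
        out[a:b, 1] = kx @ vz - kz @ vx
        out[a:b, 2] = ky @ vx - kx @ vy
    return out[:, :, 0] if np.asarray(values).ndim == 2 else out


def dot_sum(obs: np.ndarray, src: np.ndarray, weights: np.ndarray,
            values: np.ndarray, min_dist: float = 0.0) -> np.ndarray:
    """(1/4pi) sum_j w_j v_j . (r - s_j)/|r-s_j|^3 -> (n_obs, m) (dipole potential)."""
    obs = np.asarray(obs, dtype=float)
    src = np.asarray(src, dtype=float)
    w = np.asarray(weights, dtype=float)
    v = _as_columns(values)
    n_src, _, m = v.shape
    vx, vy, vz = (v[:, c, :] * w[:, None] for c in range(3))
    out = np.empty((len(obs), m))
    for a in range(0, len(obs), _chunk_size(n_src)):
        b = min(a + _chunk_size(n_src), len(obs))
        d = obs[a:b, None, :] - src[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        _check_min_dist(r, min_dist)
        inv_r3 = 1.0 / (FOUR_PI * r**3)
        out[a:b] = (d[:, :, 0] * inv_r3) @ vx + (d[:, :, 1] * inv_r3) @ vy \
            + (d[:, :, 2] * inv_r3) @ vz
    return out[:, 0] if np.asarray(values).ndim == 2 else out


def _check_min_dist(r: np.ndarray, min_dist: float) -> None:
    if min_dist > 0.0 and r.min() < min_dist:
        n = int(np.sum(r.min(axis=1) < min_dist))
        raise ValueError(
            f"{n} observation point(s) closer than {min_dist} to a source "
            f"(min distance {r.min():.3g}); singular kernel")
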