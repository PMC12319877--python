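"""Error metrics and the placement-sweep validation driver.

Global errors compare the full evaluation-point sets as stacked vectors:

    GVE = ||E_est - E_ref|| / ||E_ref|| * 100
    GME = || |E_est| - |E_ref| || / ||E_ref|| * 100

with ||.|| the (unweighted) 2-norm over all samples and |.| the pointwise
magnitude.  Local errors are pointwise, normalized by the peak reference
magnitude over the ROI:

    LVE = |E_est - E_ref| / max|E_ref| * 100
    LME = ||E_est| - |E_ref|| / max|E_ref| * 100.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .coil import Placement, tangential_placement
from .fem import assemble_conduction_system, solve_direct_tms
from .mesh_core import HeadMesh, TriSurface
from .realtime import RealtimeSession, realtime_solve

logger = logging.getLogger(__name__)

__all__ = ["ErrorReport", "global_errors", "local_errors",
           "sample_scalp_placements", "convergence_study", "phantom_benchmark"]


def _check(E_est, E_ref):
    E_est = np.asarray(E_est, dtype=float)
    E_ref = np.asarray(E_ref, dtype=float)
    if E_est.shape != E_ref.shape:
        raise ValueError("field shapes differ")
    norm_ref = np.linalg.norm(E_ref)
    if norm_ref == 0.0:
        raise ValueError("reference field is identically zero")
    return E_est, E_ref, norm_ref


def global_errors(E_est: np.ndarray, E_ref: np.ndarray,
                  weights: "np.ndarray | None" = None):
    """(GVE %, GME %); optional per-point weights (e.g. facet areas)."""
    E_est, E_ref, _ = _check(E_est, E_ref)
    w = np.ones(len(E_ref)) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    norm_ref = np.linalg.norm(E_ref * sw[:, None])
    gve = np.linalg.norm((E_est - E_ref) * sw[:, None]) / norm_ref * 100.0
    dmag = (np.linalg.norm(E_est, axis=1) - np.linalg.norm(E_ref, axis=1)) * sw
    gme = np.linalg.norm(dmag) / norm_ref * 100.0
    return float(gve), float(gme)


def local_errors(E_est: np.ndarray, E_ref: np.ndarray):
    """(LVE %, LME %) per evaluation point, normalized by max |E_ref|."""
    E_est, E_ref, _ = _check(E_est, E_ref)
    peak = np.linalg.norm(E_ref, axis=1).max()
    if peak == 0.0:
        raise ValueError("reference field is identically zero")
    lve = np.linalg.norm(E_est - E_ref, axis=1) / peak * 100.0
    lme = np.abs(np.linalg.norm(E_est, axis=1) - np.linalg.norm(E_ref, axis=1)) / peak * 100.0
    return lve, lme


@dataclass
class ErrorReport:
    placement: int
    n_modes: int
    gve: float
    gme: float
    gve_hotspot: float
    gme_hotspot: float


def sample_scalp_placements(scalp: TriSurface, n: int, seed: int,
                            standoff: float = 5.0,
                            equator_z: "float | None" = None) -> "list[Placement]":
    """Seeded random tangential coil placements over the upper scalp.

    Facets with centers above ``equator_z`` (default: the scalp centroid
    height) are drawn with probability proportional to area; the coil sits
    ``standoff`` mm along the facet normal with a uniform random in-plane
    rotation.
    """
    rng = np.random.default_rng(seed)
    if equator_z is None:
        equator_z = float(scalp.nodes[:, 2].mean())
    upper = np.nonzero(scalp.facet_center[:, 2] > equator_z)[0]
    if len(upper) == 0:
        raise ValueError("no scalp facets above the equator plane")
    p = scalp.facet_area[upper] / scalp.facet_area[upper].sum()
    facets = rng.choice(upper, size=n, p=p)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return [tangential_placement(scalp.facet_center[f], scalp.outward_normal[f],
                                 standoff=standoff, angle=a)
            for f, a in zip(facets, angles)]


def convergence_study(session: RealtimeSession, mesh: HeadMesh, coil,
                      placements: "list[Placement]",
                      mode_counts: "list[int]",
                      hotspot_fraction: float = 0.7,
                      fem_tol: float = 1e-10,
                      report_path=None) -> dict:
    """Per-placement GVE/GME of the mode expansion against direct FEM.

    For every placement the reference field is a direct first-order FEM solve
    (coil transformed exactly, no grid interpolation), sampled at the same
    evaluation barycenters as the real-time path; errors are reported per
    mode count on all points and on the hotspot subset where
    ``|E_ref| >= hotspot_fraction * max|E_ref|``.
    Returns ``{"rows": [...], "summary": {...}}`` (JSON-serializable).
    """
    op = assemble_conduction_system(mesh)
    op.factor()
    rows: list[ErrorReport] = []
    for ip, T in enumerate(placements):
        try:
            ref = solve_direct_tms(mesh, coil, T, dIdt=session.dIdt,
                                   operator=op, tol=fem_tol)
        except Exception as exc:  # record-and-skip per failed reference
            logger.warning("reference solve failed for placement %d: %s", ip, exc)
            continue
        E_ref = ref.values[session.eval_roi_rows]
        mag = np.linalg.norm(E_ref, axis=1)
        hot = mag >= hotspot_fraction * mag.max()
        _, a = realtime_solve(session, T)
        for nm in mode_counts:
            from .realtime import reconstruct_field
            E_est = reconstruct_field(session, a, n_use=nm)
            gve, gme = global_errors(E_est, E_ref)
            gve_h, gme_h = global_errors(E_est[hot], E_ref[hot])
            rows.append(ErrorReport(ip, nm, gve, gme, gve_h, gme_h))

    summary = {}
    for nm in mode_counts:
        sel = [r for r in rows if r.n_modes == nm]
        if not sel:
            continue
        summary[str(nm)] = {
            "n_placements": len(sel),
            "mean_gve": float(np.mean([r.gve for r in sel])),
            "max_gve": float(np.max([r.gve for r in sel])),
            "mean_gme": float(np.mean([r.gme for r in sel])),
            "max_gme": float(np.max([r.gme for r in sel])),
            "mean_gve_hotspot": float(np.mean([r.gve_hotspot for r in sel])),
            "mean_gme_hotspot": float(np.mean([r.gme_hotspot for r in sel])),
        }
    report = {"rows": [asdict(r) for r in rows], "summary": summary}
    if report_path is not None:
        with open(report_path, "w") as f:
            json.dump(report, f, indent=1)
    return report


def phantom_benchmark(seed: int = 1, n_placements: int = 100, n_modes: int = 450,
                      mode_counts: "tuple[int, ...]" = (325, 400, 450),
                      radii: "tuple[float, ...]" = (70.0, 75.0, 78.0, 82.0, 85.0),
                      target_edge: float = 9.0, n_oracle: int = 5,
                      segments_per_turn: int = 24,
                      report_path=None) -> dict:
    """End-to-end accuracy benchmark on the layered-sphere phantom.

    Builds the phantom and a printed-geometry Figure-8 coil, precomputes an
    ``n_modes`` real-time session (noise seed = ``seed``), draws
    ``n_placements`` random tangential placements (seed = ``seed + 1``, 5 mm
    standoff), and reports GVE/GME per placement and mode count against the
    direct first-order FEM reference, plus the reciprocity oracle: for the
    first ``n_oracle`` placements, the relative difference between the
    surface-integral coefficients and the exact volume projections
    <M(i), E_ref>.
    """
    from .coil import build_figure8_coil, coil_primary_fields, transform_coil
    from .mesh_core import extrude_surface, make_layered_sphere_phantom
    from .realtime import build_noise_mode_basis, precompute_session

    mesh, scalp, eval_surface = make_layered_sphere_phantom(
        radii=radii, target_edge=target_edge)
    coil = build_figure8_coil(segments_per_turn=segments_per_turn)
    huygens = extrude_surface(scalp, 1.0)
    op = assemble_conduction_system(mesh)
    op.factor()
    basis = build_noise_mode_basis(mesh, huygens, n_modes, seed, operator=op)
    session = precompute_session(mesh, huygens, coil, n_modes, seed,
                                 eval_surface, basis=basis)
    placements = sample_scalp_placements(scalp, n_placements, seed=seed + 1,
                                         standoff=5.0)
    report = convergence_study(session, mesh, coil, placements,
                               list(mode_counts))

    oracle = []
    for T in placements[:n_oracle]:
        ref = solve_direct_tms(mesh, coil, T, dIdt=1.0, operator=op)
        a_direct = np.einsum("kd,kdi,k->i", ref.values, basis.modes,
                             basis.volumes_m3)
        placed = transform_coil(coil, T)
        E_p, H_p = coil_primary_fields(placed, huygens.facet_center, dIdt=1.0)
        a_recip = session.operator.coefficients(E_p, H_p)
        oracle.append(float(np.linalg.norm(a_recip - a_direct)
                            / np.linalg.norm(a_direct)))
    report["oracle_rel_coeff_err"] = oracle
    report["n_tets"] = int(mesh.n_tets)
    report["n_placements"] = int(n_placements)
    if report_path is not None:
        with open(report_path, "w") as f:
            json.dump(report, f, indent=1)
    return report
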