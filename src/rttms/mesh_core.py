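"""Tetrahedral head meshes, triangle surfaces, and the layered-sphere phantom.

Geometry is stored in millimetres (the SimNIBS file convention); all field
physics elsewhere in the package converts to SI metres internally.  Tissue
tags follow the SimNIBS-like convention 1..5 = WM, GM, CSF, skull, scalp.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Default tissue conductivity table in S/m, tags 1..5 = WM, GM, CSF, skull, scalp.
DEFAULT_CONDUCTIVITIES: dict[int, float] = {
    1: 0.126,   # white matter
    2: 0.275,   # grey matter
    3: 1.654,   # cerebrospinal fluid
    4: 0.01,    # skull
    5: 0.465,   # scalp
}

#: Tags counted as brain for the region-of-interest mask (WM + GM).
DEFAULT_ROI_TAGS: tuple[int, ...] = (1, 2)


class MeshError(ValueError):
    """Raised for invalid mesh/surface inputs."""


# ---------------------------------------------------------------------------
# Triangle surfaces
# ---------------------------------------------------------------------------

@dataclass
class TriSurface:
    """Triangle surface mesh with per-facet geometry.

    Attributes
    ----------
    nodes : (N, 3) float array, positions in mm.
    tris : (M, 3) int array of node indices; winding defines the normal.
    facet_area : (M,) areas in mm^2.
    facet_center : (M, 3) barycenters in mm.
    outward_normal : (M, 3) unit normals.
    closed : whether the surface is flagged as a closed orientable shell.
    """

    nodes: np.ndarray
    tris: np.ndarray
    facet_area: np.ndarray = field(default=None)  # type: ignore[assignment]
    facet_center: np.ndarray = field(default=None)  # type: ignore[assignment]
    outward_normal: np.ndarray = field(default=None)  # type: ignore[assignment]
    closed: bool = False

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tris = np.ascontiguousarray(self.tris, dtype=np.int64)
        if self.tris.max(initial=-1) >= len(self.nodes) or self.tris.min(initial=0) < 0:
            raise MeshError("triangle node indices out of range")
        if self.facet_area is None:
            surface_geometry(self)

    @property
    def facet_count(self) -> int:
        return len(self.tris)

    def copy(self) -> "TriSurface":
        return TriSurface(self.nodes.copy(), self.tris.copy(),
                          self.facet_area.copy(), self.facet_center.copy(),
                          self.outward_normal.copy(), self.closed)


def surface_geometry(surface: TriSurface) -> TriSurface:
    """Recompute facet areas, barycenters and unit normals in place.

    Must be called after any edit of ``surface.nodes``.  Raises on
    degenerate (zero-area) triangles.
    """
    p = surface.nodes[surface.tris]            # (M, 3, 3)
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area2 = np.linalg.norm(cross, axis=1)
    scale = np.linalg.norm(np.ptp(surface.nodes, axis=0)) + 1.0
    bad = np.nonzero(area2 <= 1e-14 * scale**2)[0]
    if bad.size:
        raise MeshError(f"degenerate zero-area triangle(s) at indices {bad[:20].tolist()}")
    surface.facet_area = 0.5 * area2
    surface.facet_center = p.mean(axis=1)
    surface.outward_normal = cross / area2[:, None]
    return surface


def _angle_weighted_node_normals(surface: TriSurface) -> np.ndarray:
    """Node normals as angle-weighted averages of incident facet normals."""
    nodes, tris = surface.nodes, surface.tris
    normals = np.zeros_like(nodes)
    p = nodes[tris]
    for corner in range(3):
        a = p[:, corner]
        u = p[:, (corner + 1) % 3] - a
        v = p[:, (corner + 2) % 3] - a
        cu = u / np.linalg.norm(u, axis=1, keepdims=True)
        cv = v / np.linalg.norm(v, axis=1, keepdims=True)
        ang = np.arccos(np.clip((cu * cv).sum(axis=1), -1.0, 1.0))
        np.add.at(normals, tris[:, corner], ang[:, None] * surface.outward_normal)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise MeshError("isolated node with no incident facets")
    return normals / norms


def extrude_surface(surface: TriSurface, distance: float = 1.0) -> TriSurface:
    """Offset a closed surface along angle-weighted node normals.

    ``distance`` is in mm (default 1 mm, the Huygens-surface standoff from
    the scalp).  Connectivity is unchanged.  If any facet normal flips,
    a self-intersection warning with the flipped-facet count is emitted and
    the surface is returned as-is (warn-and-proceed policy).
    """
    out = surface.copy()
    if distance != 0.0:
        out.nodes = out.nodes + distance * _angle_weighted_node_normals(surface)
        old_normals = surface.outward_normal
        surface_geometry(out)
        flipped = int(np.sum((out.outward_normal * old_normals).sum(axis=1) < 0.0))
        if flipped:
            warnings.warn(
                f"extrusion by {distance} mm flipped {flipped} facet normal(s); "
                "surface likely self-intersecting — proceeding", stacklevel=2)
    return out


def check_closed(surface: TriSurface) -> bool:
    """Check the surface is a closed orientable 2-manifold with consistent winding."""
    tris = surface.tris
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    keys = np.sort(edges, axis=1)
    _, counts = np.unique(keys, axis=0, return_counts=True)
    if not np.all(counts == 2):
        return False
    # consistent winding: each undirected edge appears once in each direction
    directed = edges[:, 0] * (tris.max() + 1) + edges[:, 1]
    return len(np.unique(directed)) == len(directed)


# ---------------------------------------------------------------------------
# Head meshes
# ---------------------------------------------------------------------------

@dataclass
class HeadMesh:
    """Labeled tetrahedral head mesh with piecewise-constant conductivity.

    Attributes
    ----------
    nodes : (N, 3) positions in mm.
    tets : (K, 4) node indices, positively oriented (volume > 0).
    region_label : (K,) integer tissue tags.
    conductivity : (K,) sigma per tet in S/m.
    roi_mask : (K,) bool, True on brain (ROI) tets.
    tet_volume : (K,) volumes in mm^3.
    tet_centroid : (K, 3) centroids in mm.
    """

    nodes: np.ndarray
    tets: np.ndarray
    region_label: np.ndarray
    conductivity: np.ndarray
    roi_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    tet_volume: np.ndarray = field(default=None)  # type: ignore[assignment]
    tet_centroid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.region_label = np.asarray(self.region_label, dtype=np.int64)
        self.conductivity = np.asarray(self.conductivity, dtype=float)
        if self.tets.max(initial=-1) >= len(self.nodes) or self.tets.min(initial=0) < 0:
            raise MeshError("tet node indices out of range")
        self._fix_orientation()
        if self.roi_mask is None:
            self.roi_mask = np.isin(self.region_label, DEFAULT_ROI_TAGS)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if np.any(self.conductivity[self.roi_mask] <= 0):
            raise MeshError("ROI tets must have nonzero conductivity")

    def _fix_orientation(self):
        p = self.nodes[self.tets]
        vol6 = np.einsum("ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                         p[:, 3] - p[:, 0])
        neg = vol6 < 0
        if np.any(neg):
            self.tets[neg] = self.tets[neg][:, [0, 2, 1, 3]]
            vol6 = np.abs(vol6)
        if np.any(vol6 <= 0):
            raise MeshError(f"zero-volume tet(s): {np.nonzero(vol6 <= 0)[0][:20].tolist()}")
        self.tet_volume = vol6 / 6.0
        self.tet_centroid = p.mean(axis=1)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def roi_index(self) -> np.ndarray:
        return np.nonzero(self.roi_mask)[0]


@dataclass
class CellField:
    """Per-tet constant 3-vector field (e.g. E in V/m, or impressed current).

    ``values`` has shape (n_tets, 3) when defined on the whole mesh or
    (n_roi, 3) when restricted to the ROI (``on_roi=True``).
    """

    values: np.ndarray
    mesh: HeadMesh
    units: str = "V/m"
    on_roi: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = int(self.mesh.roi_mask.sum()) if self.on_roi else self.mesh.n_tets
        if self.values.shape != (n, 3):
            raise MeshError(f"CellField shape {self.values.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.values)):
            raise MeshError("CellField contains non-finite entries")

    def to_full(self) -> np.ndarray:
        """Values padded with zeros outside the ROI, shape (n_tets, 3)."""
        if not self.on_roi:
            return self.values
        full = np.zeros((self.mesh.n_tets, 3))
        full[self.mesh.roi_mask] = self.values
        return full


# ---------------------------------------------------------------------------
# Boundary extraction
# ---------------------------------------------------------------------------

_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
# Opposite-vertex convention: face i excludes local vertex i and is wound so
# that its normal points away from that vertex (outward on the boundary of a
# positively oriented tet).


def extract_boundary_surface(mesh: HeadMesh) -> TriSurface:
    """Extract the outer boundary (faces belonging to exactly one tet).

    Normals point out of the volume by the opposite-vertex winding of the
    owning tet.  Raises on non-manifold boundary configurations.
    """
    faces = mesh.tets[:, _TET_FACES].reshape(-1, 3)           # (4K, 3) wound outward
    keys = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    if np.any(counts > 2):
        bad = np.nonzero(counts[inverse] > 2)[0]
        raise MeshError(f"non-manifold faces shared by >2 tets: {bad[:20].tolist()}")
    boundary = faces[counts[inverse] == 1]
    used = np.unique(boundary)
    remap = np.full(mesh.n_nodes, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    surf = TriSurface(mesh.nodes[used], remap[boundary])
    if not check_closed(surf):
        raise MeshError("boundary surface is not a closed orientable manifold")
    surf.closed = True
    return surf


# ---------------------------------------------------------------------------
# Layered-sphere phantom
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int, radius: float, phase: float = 0.0) -> np.ndarray:
    """Quasi-uniform points on a sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = golden * i + phase
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return radius * np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _n_for_spacing(radius: float, spacing: float) -> int:
    # area per vertex of an equilateral triangulation with edge h is sqrt(3)/2 h^2
    return max(14, int(round(4.0 * np.pi * radius**2 / (np.sqrt(3.0) / 2.0 * spacing**2))))


def make_sphere_surface(radius: float, spacing: float, phase: float = 0.0) -> TriSurface:
    """Closed triangulated sphere (convex hull of a Fibonacci lattice)."""
    from scipy.spatial import ConvexHull

    pts = _fibonacci_sphere(_n_for_spacing(radius, spacing), radius, phase)
    hull = ConvexHull(pts)
    tris = hull.simplices.copy()
    # orient outward
    p = pts[tris]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = np.einsum("ij,ij->i", cross, p.mean(axis=1)) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    surf = TriSurface(pts, tris)
    surf.closed = True
    return surf


def make_layered_sphere_phantom(
    radii: "list[float] | np.ndarray" = (70.0, 75.0, 78.0, 82.0, 85.0),
    target_edge: float = 10.0,
    conductivities: "list[float] | None" = None,
    core_coarsening: float = 1.5,
    eval_spacing_factor: float = 0.8,
    jitter: float = 1e-3,
    max_radial_spacing: "float | None" = None,
) -> "tuple[HeadMesh, TriSurface, TriSurface]":
    """Concentric-shell sphere phantom standing in for an MRI-derived head.

    Shell interfaces are meshed conformally: one Fibonacci point layer sits
    exactly on every interface radius, the core is filled with radial layers
    coarsened by ``core_coarsening``, and the volume is tetrahedralized with
    a Delaunay triangulation.  Tets are labeled 1..n (inner to outer shell)
    by centroid radius; with the default 5 radii this is WM/GM/CSF/skull/
    scalp.  ROI = tags (1, 2).

    Returns ``(mesh, scalp_surface, middle_gm_surface)`` where the last is an
    independent evaluation sphere at the mid-radius of the grey-matter shell
    (second shell), mimicking a middle-grey-matter surface.

    ``target_edge`` (mm) sets the lateral point spacing on the interfaces.
    Radial resolution equals the shell thicknesses, so edges much larger than
    ~4x the thinnest shell cannot resolve the layering and raise an error.
    """
    from scipy.spatial import Delaunay

    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or len(radii) < 1 or np.any(np.diff(radii) <= 0):
        raise MeshError("radii must be strictly increasing")
    if conductivities is None:
        if len(radii) != 5:
            raise MeshError("default conductivities require exactly 5 radii")
        conductivities = [DEFAULT_CONDUCTIVITIES[t] for t in (1, 2, 3, 4, 5)]
    conductivities = np.asarray(conductivities, dtype=float)
    if len(conductivities) != len(radii):
        raise MeshError("need one conductivity per shell")
    thickness = np.diff(np.concatenate([[0.0], radii]))
    min_thick = thickness[1:].min() if len(radii) > 1 else radii[0]
    if len(radii) > 1 and target_edge > 4.0 * min_thick:
        raise MeshError(
            f"target_edge={target_edge} mm too coarse to resolve the thinnest "
            f"shell ({min_thick} mm); maximum feasible edge is {4.0 * min_thick} mm")

    layers = []
    # one layer per interface (plus intermediate layers in shells thicker than
    # max_radial_spacing); a single angular lattice scaled to every radius
    # keeps points radially aligned so Delaunay tets do not cross interfaces
    if max_radial_spacing is None:
        max_radial_spacing = target_edge
    unit = _fibonacci_sphere(_n_for_spacing(radii[-1], target_edge), 1.0)
    layer_radii = []
    prev = 0.0
    for i, r in enumerate(radii):
        if i > 0:
            n_sub = int(np.ceil((r - prev) / max_radial_spacing)) - 1
            for s in range(1, n_sub + 1):
                layer_radii.append(prev + (r - prev) * s / (n_sub + 1))
        layer_radii.append(r)
        prev = r
    for r in layer_radii:
        layers.append(r * unit)
    # graded core fill inside the innermost interface
    core_h = core_coarsening * target_edge
    r = radii[0] - core_h
    j = 1
    while r > 0.6 * core_h:
        layers.append(_fibonacci_sphere(_n_for_spacing(r, core_h), r, phase=1.31 * j))
        r -= core_h
        j += 1
    layers.append(np.zeros((1, 3)))
    points = np.concatenate(layers)

    # deterministic jitter on interior points breaks Delaunay degeneracies;
    # the outermost layer stays exact so the scalp sits on the sphere
    # tiny deterministic jitter breaks Delaunay degeneracies; interface points
    # are perturbed tangentially and renormalized so radii stay exact
    rng = np.random.default_rng(12345)
    eps = jitter * target_edge
    delta = rng.uniform(-eps, eps, size=points.shape)
    n_interface = sum(len(l) for l in layers[: len(layer_radii)])
    r_exact = np.linalg.norm(points[:n_interface], axis=1, keepdims=True)
    head = points[:n_interface] + delta[:n_interface]
    points[:n_interface] = head * (r_exact / np.linalg.norm(head, axis=1, keepdims=True))
    points[n_interface:] += delta[n_interface:]

    tri = Delaunay(points)
    tets = tri.simplices

    centroid_r = np.linalg.norm(points[tets].mean(axis=1), axis=1)
    label = np.searchsorted(radii, centroid_r) + 1
    label = np.minimum(label, len(radii))  # hull centroids marginally outside
    sigma = conductivities[label - 1]
    roi = label <= min(2, len(radii))

    mesh = HeadMesh(points, tets, label, sigma, roi_mask=roi)
    scalp = extract_boundary_surface(mesh)

    if len(radii) >= 2:
        mid_gm_radius = 0.5 * (radii[0] + radii[1])
    else:
        mid_gm_radius = 0.5 * radii[0]
    eval_surface = make_sphere_surface(mid_gm_radius, eval_spacing_factor * target_edge,
                                       phase=2.17)
    logger.info("phantom: %d nodes, %d tets (%d ROI), scalp %d facets, eval %d facets",
                mesh.n_nodes, mesh.n_tets, int(roi.sum()), scalp.facet_count,
                eval_surface.facet_count)
    return mesh, scalp, eval_surface


# ---------------------------------------------------------------------------
# Gmsh .msh v2.2 ASCII I/O
# ---------------------------------------------------------------------------

def load_head_mesh(path, conductivity_table: "dict[int, float] | None" = None,
                   roi_tags: "tuple[int, ...]" = DEFAULT_ROI_TAGS) -> HeadMesh:
    """Read a Gmsh v2.2 ASCII mesh with tetrahedral physical tags.

    ``conductivity_table`` maps physical tag -> sigma in S/m; defaults to the
    WM/GM/CSF/skull/scalp table.  Non-tet elements are ignored (a count is
    logged).  An unknown tag raises naming the tag.
    """
    table = dict(DEFAULT_CONDUCTIVITIES if conductivity_table is None else conductivity_table)
    text = Path(path).read_text().split("\n")

    def find(tag):
        for i, line in enumerate(text):
            if line.strip() == tag:
                return i
        raise MeshError(f"section {tag} not found in {path}")

    i = find("$Nodes")
    n_nodes = int(text[i + 1])
    nodes = np.empty((n_nodes, 3))
    idmap = {}
    for k in range(n_nodes):
        parts = text[i + 2 + k].split()
        idmap[int(parts[0])] = k
        nodes[k] = [float(parts[1]), float(parts[2]), float(parts[3])]

    i = find("$Elements")
    n_elem = int(text[i + 1])
    tets, labels = [], []
    skipped = 0
    for k in range(n_elem):
        parts = text[i + 2 + k].split()
        etype = int(parts[1])
        ntags = int(parts[2])
        if etype != 4:  # 4 = linear tetrahedron
            skipped += 1
            continue
        tag = int(parts[3]) if ntags >= 1 else 0
        conn = [idmap[int(v)] for v in parts[3 + ntags: 7 + ntags]]
        tets.append(conn)
        labels.append(tag)
    if skipped:
        logger.info("load_head_mesh: ignored %d non-tetrahedral elements", skipped)
    labels = np.asarray(labels, dtype=np.int64)
    missing = sorted(set(labels.tolist()) - set(table))
    if missing:
        raise MeshError(f"no conductivity for physical tag(s) {missing}")
    sigma = np.array([table[t] for t in labels])
    roi = np.isin(labels, roi_tags)
    return HeadMesh(nodes, np.asarray(tets, dtype=np.int64), labels, sigma, roi_mask=roi)


def save_head_mesh(mesh: HeadMesh, path) -> None:
    """Write a Gmsh v2.2 ASCII mesh (tetrahedra with physical tags)."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.17g} {y:.17g} {z:.17g}")
    lines += ["$EndNodes", "$Elements", str(mesh.n_tets)]
    for i, (conn, tag) in enumerate(zip(mesh.tets + 1, mesh.region_label), start=1):
        lines.append(f"{i} 4 2 {tag} {tag} {conn[0]} {conn[1]} {conn[2]} {conn[3]}")
    lines += ["$EndElements", ""]
    Path(path).write_text("\n".join(lines))


def load_surface_stl(path) -> TriSurface:
    """Read a triangle surface from STL (binary or ASCII) via trimesh."""
    import trimesh

    tm = trimesh.load(str(path), file_type="stl", process=True)
    surf = TriSurface(np.asarray(tm.vertices, dtype=float),
                      np.asarray(tm.faces, dtype=np.int64))
    surf.closed = check_closed(surf)
    return surf


def save_surface_stl(surface: TriSurface, path) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=surface.nodes, faces=surface.tris, process=False)
    tm.export(str(path))
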