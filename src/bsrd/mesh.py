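"""Simplicial meshes of the unit disk/ball and their induced surface meshes.

The bulk is meshed with triangles (disk) or tetrahedra (ball); the surface mesh
is *induced*: its facets are exactly the boundary facets of the bulk mesh and
its vertices are the bulk boundary vertices, so bulk and surface fields share
nodes on the boundary.  Generators are deterministic.  I/O covers Gmsh MSH 2.2
ASCII, legacy VTK (unstructured grid) and OFF (surface only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class MeshParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line is not None else ""))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _simplex_volumes(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Signed areas (2D) or volumes (3D) of simplices."""
    p = points[cells]
    edges = p[:, 1:] - p[:, :1]
    if points.shape[1] == 2:
        return 0.5 * np.linalg.det(edges)
    return np.linalg.det(edges) / 6.0


@dataclass
class BulkMesh:
    """Simplicial bulk mesh: 0-based vertex indices, positively oriented cells."""

    points: np.ndarray  # (n, dim)
    cells: np.ndarray   # (m, dim+1)
    h: float            # characteristic edge length

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def volumes(self) -> np.ndarray:
        return _simplex_volumes(self.points, self.cells)

    def total_measure(self) -> float:
        return float(self.volumes().sum())

    def orient(self) -> None:
        """Reorder cell vertices so all signed volumes are positive."""
        vols = self.volumes()
        bad = vols < 0
        if bad.any():
            self.cells[bad, -2:] = self.cells[bad, -2:][:, ::-1]

    def validate(self) -> None:
        vols = self.volumes()
        if (vols <= 0).any():
            raise ValueError(f"{int((vols <= 0).sum())} cells have non-positive volume")


@dataclass
class SurfaceMesh:
    """Induced surface mesh: facets reference *bulk* vertex indices."""

    facets: np.ndarray       # (f, dim) boundary facets, outward-oriented, bulk indices
    vertex_map: np.ndarray   # (ns,) surface-local -> bulk vertex index
    facets_local: np.ndarray  # (f, dim) facets in surface-local indices
    measures: np.ndarray     # (f,) facet length (2D bulk) or area (3D bulk)

    @property
    def n_points(self) -> int:
        return self.vertex_map.shape[0]

    def total_measure(self) -> float:
        return float(self.measures.sum())


# ---------------------------------------------------------------------------
# disk generator: concentric rings, deterministic merge triangulation
# ---------------------------------------------------------------------------

def _ring_angles(count: int, stagger: bool) -> np.ndarray:
    offset = math.pi / count if stagger else 0.0
    return offset + 2.0 * math.pi * np.arange(count) / count


def _merge_annulus(inner: np.ndarray, inner_ang: np.ndarray,
                   outer: np.ndarray, outer_ang: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate the annulus between two concentric vertex rings by merging
    the two angle sequences; advances whichever side's next angle is smaller."""
    p, q = len(inner), len(outer)
    # rotate the outer ring so its first vertex is angularly nearest inner[0]
    rel = np.mod(outer_ang - inner_ang[0] + math.pi, 2.0 * math.pi) - math.pi
    shift = int(np.argmin(np.abs(rel)))
    outer = np.roll(outer, -shift)
    outer_ang = np.roll(outer_ang, -shift)
    a = np.unwrap(inner_ang - inner_ang[0])
    b = np.unwrap(outer_ang - inner_ang[0])
    b = b - 2.0 * math.pi * round((b[0] - a[0]) / (2.0 * math.pi))
    a_ext = np.append(a, a[0] + 2.0 * math.pi)
    b_ext = np.append(b, b[0] + 2.0 * math.pi)
    tris = []
    i = j = 0
    while i < p or j < q:
        take_outer = j < q and (i == p or b_ext[j + 1] <= a_ext[i + 1])
        if take_outer:
            tris.append((inner[i % p], outer[j % q], outer[(j + 1) % q]))
            j += 1
        else:
            tris.append((inner[i % p], outer[j % q], inner[(i + 1) % p]))
            i += 1
    return tris


MAX_DISK_VERTICES = 2_000_000


def generate_disk_mesh(h: float) -> BulkMesh:
    """Triangulate the unit disk with target edge length h.

    Vertices sit on concentric rings spaced h apart with arc spacing ~h
    (alternate rings staggered by half a step); boundary vertices lie exactly
    on the unit circle.
    """
    if not (0.0 < h < 1.0):
        raise ValueError("require 0 < h < 1")
    n = max(2, round(1.0 / h))
    counts = [max(6, round(2.0 * math.pi * i)) for i in range(1, n + 1)]
    if 1 + sum(counts) > MAX_DISK_VERTICES:
        raise MemoryError(f"h={h} would require more than {MAX_DISK_VERTICES} vertices")
    points = [np.zeros((1, 2))]
    ring_idx: list[np.ndarray] = []
    ring_ang: list[np.ndarray] = []
    start = 1
    for i, cnt in enumerate(counts, start=1):
        ang = _ring_angles(cnt, stagger=(i % 2 == 0))
        radius = i / n
        points.append(radius * np.column_stack([np.cos(ang), np.sin(ang)]))
        ring_idx.append(start + np.arange(cnt))
        ring_ang.append(ang)
        start += cnt
    pts = np.vstack(points)
    tris: list[tuple[int, int, int]] = []
    first = ring_idx[0]
    for j in range(len(first)):
        tris.append((0, first[j], first[(j + 1) % len(first)]))
    for i in range(len(counts) - 1):
        tris.extend(_merge_annulus(ring_idx[i], ring_ang[i],
                                   ring_idx[i + 1], ring_ang[i + 1]))
    mesh = BulkMesh(points=pts, cells=np.asarray(tris, dtype=np.int64), h=1.0 / n)
    mesh.orient()
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# ball generator: red-refined octahedral seed, boundary projected to the sphere
# ---------------------------------------------------------------------------

def _octahedron_ball() -> tuple[np.ndarray, np.ndarray]:
    pts = np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0], [0.0, -1.0, 0.0],
        [0.0, 0.0, 1.0], [0.0, 0.0, -1.0],
    ])
    cells = []
    for z in (5, 6):
        for x in (1, 2):
            for y in (3, 4):
                cells.append((0, x, y, z))
    return pts, np.asarray(cells, dtype=np.int64)


def _refine_tets(points: np.ndarray, cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Uniform red refinement (each tetrahedron into eight)."""
    midpoint: dict[tuple[int, int], int] = {}
    new_pts = [points]
    next_id = len(points)

    def mid(i: int, j: int) -> int:
        nonlocal next_id
        key = (i, j) if i < j else (j, i)
        idx = midpoint.get(key)
        if idx is None:
            idx = next_id
            midpoint[key] = idx
            new_pts.append(0.5 * (points[key[0]] + points[key[1]])[None, :])
            next_id += 1
        return idx

    children = []
    for v0, v1, v2, v3 in cells:
        m01, m02, m03 = mid(v0, v1), mid(v0, v2), mid(v0, v3)
        m12, m13, m23 = mid(v1, v2), mid(v1, v3), mid(v2, v3)
        children += [
            (v0, m01, m02, m03), (v1, m01, m12, m13),
            (v2, m02, m12, m23), (v3, m03, m13, m23),
            # inner octahedron split along the (m01, m23) diagonal
            (m01, m23, m02, m12), (m01, m23, m12, m13),
            (m01, m23, m13, m03), (m01, m23, m03, m02),
        ]
    return np.vstack(new_pts), np.asarray(children, dtype=np.int64)


def _boundary_facet_counts(cells: np.ndarray) -> dict[tuple[int, ...], list]:
    """Map sorted facet -> [count, owner_cell_index]."""
    d = cells.shape[1] - 1
    counts: dict[tuple[int, ...], list] = {}
    for ci, cell in enumerate(cells):
        for drop in range(d + 1):
            facet = tuple(sorted(np.delete(cell, drop)))
            rec = counts.get(facet)
            if rec is None:
                counts[facet] = [1, ci]
            else:
                rec[0] += 1
    return counts


def _boundary_vertices(cells: np.ndarray) -> np.ndarray:
    counts = _boundary_facet_counts(cells)
    verts = {v for facet, (cnt, _) in counts.items() if cnt == 1 for v in facet}
    return np.fromiter(sorted(verts), dtype=np.int64)


def generate_ball_mesh(level: int = 0) -> BulkMesh:
    """Tetrahedralize the unit ball; boundary vertices lie exactly on the sphere.

    The level-0 seed is a twice-refined octahedral ball (512 tetrahedra); each
    level applies one more uniform red refinement, projecting boundary vertices
    onto the unit sphere after every refinement.
    """
    if level < 0:
        raise ValueError("level must be nonnegative")
    if level > 3:
        raise MemoryError("level > 3 exceeds the supported vertex budget")
    pts, cells = _octahedron_ball()
    for _ in range(level + 2):
        pts, cells = _refine_tets(pts, cells)
        bverts = _boundary_vertices(cells)
        norms = np.linalg.norm(pts[bverts], axis=1)
        pts[bverts] /= norms[:, None]
    edge = pts[cells[0, 0]] - pts[cells[0, 1]]
    mesh = BulkMesh(points=pts, cells=cells, h=float(np.linalg.norm(edge)))
    mesh.orient()
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# induced surface extraction
# ---------------------------------------------------------------------------

def extract_induced_surface(bulk: BulkMesh) -> SurfaceMesh:
    """Boundary facets of the bulk mesh as an outward-oriented surface mesh.

    Raises when the boundary is non-manifold (a facet shared by more than two
    cells, or a surface ridge not shared by exactly two facets).
    """
    counts = _boundary_facet_counts(bulk.cells)
    if any(cnt > 2 for cnt, _ in counts.values()):
        raise ValueError("non-manifold bulk mesh: a facet is shared by more than two cells")
    boundary = [(facet, owner) for facet, (cnt, owner) in counts.items() if cnt == 1]
    if not boundary:
        raise ValueError("mesh has no boundary facets")
    facets = []
    for facet, owner in boundary:
        facets.append(_orient_outward(np.asarray(facet), bulk, owner))
    facets = np.asarray(facets, dtype=np.int64)

    # closedness: every ridge (vertex in 2D, edge in 3D) on exactly two facets
    ridge_count: dict[tuple[int, ...], int] = {}
    for facet in facets:
        for drop in range(len(facet)):
            ridge = tuple(sorted(np.delete(facet, drop)))
            ridge_count[ridge] = ridge_count.get(ridge, 0) + 1
    if any(c != 2 for c in ridge_count.values()):
        raise ValueError("boundary surface is not closed")

    vertex_map = np.unique(facets)
    inverse = np.full(bulk.n_points, -1, dtype=np.int64)
    inverse[vertex_map] = np.arange(len(vertex_map))
    facets_local = inverse[facets]
    measures = _facet_measures(bulk.points, facets)
    return SurfaceMesh(facets=facets, vertex_map=vertex_map,
                       facets_local=facets_local, measures=measures)


def _orient_outward(facet: np.ndarray, bulk: BulkMesh, owner: int) -> np.ndarray:
    cell_centroid = bulk.points[bulk.cells[owner]].mean(axis=0)
    p = bulk.points[facet]
    mid = p.mean(axis=0)
    if bulk.dim == 2:
        t = p[1] - p[0]
        normal = np.array([t[1], -t[0]])
    else:
        normal = np.cross(p[1] - p[0], p[2] - p[0])
    if normal @ (mid - cell_centroid) < 0:
        facet = facet[::-1] if bulk.dim == 2 else facet[[0, 2, 1]]
    return facet


def _facet_measures(points: np.ndarray, facets: np.ndarray) -> np.ndarray:
    p = points[facets]
    if facets.shape[1] == 2:
        return np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
    return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def surface_euler_characteristic(surface: SurfaceMesh) -> int:
    """V - E + F of the surface mesh (2 for a topological sphere)."""
    V = surface.n_points
    F = surface.facets.shape[0]
    edges = set()
    for facet in surface.facets:
        k = len(facet)
        for i in range(k):
            edges.add(tuple(sorted((facet[i], facet[(i + 1) % k]))))
    return V - len(edges) + F


# ---------------------------------------------------------------------------
# mesh I/O: Gmsh MSH 2.2 ASCII, legacy VTK, OFF (surface only)
# ---------------------------------------------------------------------------

_FMT = "%.17g"


def _coords3(points: np.ndarray) -> np.ndarray:
    if points.shape[1] == 3:
        return points
    return np.column_stack([points, np.zeros(len(points))])


def write_mesh(mesh: BulkMesh, path: str | Path) -> None:
    """Write a bulk mesh; format chosen from the extension (.msh or .vtk)."""
    path = Path(path)
    if path.suffix == ".msh":
        _write_msh(mesh, path)
    elif path.suffix == ".vtk":
        write_vtk(mesh, path)
    else:
        raise ValueError(f"unsupported mesh extension {path.suffix!r} (use .msh or .vtk)")


def read_mesh(path: str | Path, repair_orientation: bool = True) -> BulkMesh:
    """Read a bulk mesh (.msh or .vtk).  Negative-volume cells are reoriented
    when ``repair_orientation`` is set, otherwise reported as an error."""
    path = Path(path)
    if path.suffix == ".msh":
        mesh = _read_msh(path)
    elif path.suffix == ".vtk":
        mesh = _read_vtk(path)
    else:
        raise ValueError(f"unsupported mesh extension {path.suffix!r} (use .msh or .vtk)")
    if repair_orientation:
        mesh.orient()
    mesh.validate()
    return mesh


def _infer_dim(points3: np.ndarray, cell_size: int) -> np.ndarray:
    if cell_size == 3 and np.all(points3[:, 2] == 0.0):
        return points3[:, :2]
    return points3


def _mean_edge(points: np.ndarray, cells: np.ndarray) -> float:
    p = points[cells[: min(len(cells), 200)]]
    return float(np.linalg.norm(p[:, 1] - p[:, 0], axis=1).mean())


def _write_msh(mesh: BulkMesh, path: Path) -> None:
    pts = _coords3(mesh.points)
    etype = 2 if mesh.cells.shape[1] == 3 else 4
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{len(pts)}\n")
        for i, (x, y, z) in enumerate(pts, start=1):
            fh.write(f"{i} {_FMT % x} {_FMT % y} {_FMT % z}\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{len(mesh.cells)}\n")
        for i, cell in enumerate(mesh.cells, start=1):
            nodes = " ".join(str(v + 1) for v in cell)
            fh.write(f"{i} {etype} 2 0 0 {nodes}\n")
        fh.write("$EndElements\n")


def _read_msh(path: Path) -> BulkMesh:
    lines = Path(path).read_text().splitlines()
    try:
        n0 = lines.index("$Nodes")
        e0 = lines.index("$Elements")
    except ValueError as exc:
        raise MeshParseError(f"missing section in MSH file: {exc}") from exc
    try:
        n_nodes = int(lines[n0 + 1])
    except (IndexError, ValueError):
        raise MeshParseError("bad node count", line=n0 + 2)
    pts = np.empty((n_nodes, 3))
    for k in range(n_nodes):
        ln = n0 + 2 + k
        parts = lines[ln].split()
        if len(parts) != 4:
            raise MeshParseError("expected 'id x y z'", line=ln + 1)
        pts[int(parts[0]) - 1] = [float(v) for v in parts[1:]]
    try:
        n_elems = int(lines[e0 + 1])
    except (IndexError, ValueError):
        raise MeshParseError("bad element count", line=e0 + 2)
    cells = []
    for k in range(n_elems):
        ln = e0 + 2 + k
        parts = lines[ln].split()
        if len(parts) < 4:
            raise MeshParseError("truncated element record", line=ln + 1)
        etype, ntags = int(parts[1]), int(parts[2])
        nodes = [int(v) - 1 for v in parts[3 + ntags:]]
        if etype == 2 and len(nodes) == 3:
            cells.append(nodes)
        elif etype == 4 and len(nodes) == 4:
            cells.append(nodes)
        elif etype in (2, 4):
            raise MeshParseError(f"element type {etype} with {len(nodes)} nodes", line=ln + 1)
        # other element types (points, lines) are skipped
    if not cells:
        raise MeshParseError("no triangles or tetrahedra found")
    sizes = {len(c) for c in cells}
    if len(sizes) != 1:
        raise MeshParseError("mixed triangle/tetrahedron meshes are not supported")
    cells_arr = np.asarray(cells, dtype=np.int64)
    points = _infer_dim(pts, cells_arr.shape[1])
    return BulkMesh(points=points, cells=cells_arr, h=_mean_edge(points, cells_arr))


def write_vtk(mesh: BulkMesh, path: str | Path,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a legacy-VTK unstructured grid, optionally with nodal scalar fields."""
    pts = _coords3(mesh.points)
    ncell, k = mesh.cells.shape
    vtk_type = 5 if k == 3 else 10
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbsrd mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for x, y, z in pts:
            fh.write(f"{_FMT % x} {_FMT % y} {_FMT % z}\n")
        fh.write(f"CELLS {ncell} {ncell * (k + 1)}\n")
        for cell in mesh.cells:
            fh.write(f"{k} " + " ".join(map(str, cell)) + "\n")
        fh.write(f"CELL_TYPES {ncell}\n")
        fh.write("\n".join([str(vtk_type)] * ncell) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {len(pts)}\n")
            for name, values in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(_FMT % v for v in np.asarray(values)) + "\n")


def _read_vtk(path: Path) -> BulkMesh:
    lines = Path(path).read_text().splitlines()
    i = 0
    pts = None
    cells = None
    while i < len(lines):
        parts = lines[i].split()
        if parts and parts[0] == "POINTS":
            n = int(parts[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            pts = np.asarray(vals).reshape(n, 3)
            continue
        if parts and parts[0] == "CELLS":
            m = int(parts[1])
            rows = []
            for k in range(m):
                rec = [int(v) for v in lines[i + 1 + k].split()]
                if len(rec) != rec[0] + 1:
                    raise MeshParseError("malformed CELLS record", line=i + 2 + k)
                rows.append(rec[1:])
            cells = np.asarray(rows, dtype=np.int64)
            i += 1 + m
            continue
        i += 1
    if pts is None or cells is None:
        raise MeshParseError("missing POINTS or CELLS section")
    points = _infer_dim(pts, cells.shape[1])
    return BulkMesh(points=points, cells=cells, h=_mean_edge(points, cells))


def write_off(surface: SurfaceMesh, points: np.ndarray, path: str | Path) -> None:
    """Write the surface mesh (triangles in 3D, segments written as degenerate
    polygons are rejected) as an OFF file in surface-local indexing."""
    if surface.facets.shape[1] != 3:
        raise ValueError("OFF export requires a triangulated surface (3D bulk)")
    pts = points[surface.vertex_map]
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(pts)} {len(surface.facets_local)} 0\n")
        for x, y, z in pts:
            fh.write(f"{_FMT % x} {_FMT % y} {_FMT % z}\n")
        for tri in surface.facets_local:
            fh.write("3 " + " ".join(map(str, tri)) + "\n")


def read_off(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an OFF file; returns (points, faces)."""
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines or lines[0].strip() != "OFF":
        raise MeshParseError("not an OFF file", line=1)
    nv, nf, _ = (int(v) for v in lines[1].split())
    pts = np.asarray([[float(v) for v in lines[2 + k].split()] for k in range(nv)])
    faces = []
    for k in range(nf):
        rec = [int(v) for v in lines[2 + nv + k].split()]
        if len(rec) != rec[0] + 1:
            raise MeshParseError("malformed face record", line=3 + nv + k)
        faces.append(rec[1:])
    return pts, np.asarray(faces, dtype=np.int64)
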