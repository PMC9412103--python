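"""Sketch, fill, stretch: from a vein skeleton to a screw-holed solid.

The 2D *sketch* is the boundary feature curve: the leaf endpoints of the
laid-out skeleton, joined by straight segments in counter-clockwise angular
order around the skeleton centroid (interior feature points stay interior).
*Filling* triangulates the boundary-minus-holes region with a constrained
Delaunay triangulation; *stretching* extrudes the planar surface to the
plate thickness; screw holes are punched as faceted through-cylinders
(64 segments) before extrusion so the prism stays watertight.

All dimensions are millimetres.  The extrusion is flat (the sketch plane is
z = 0); conforming the plate to a curved bone is out of scope here — the fit
metrics in :mod:`bionicvein.fitness` work on arbitrary 3D point sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh
from shapely.geometry import Point, Polygon

from .errors import DomainError, GeometryError, UsageError
from .vein_core import VeinGraph

__all__ = [
    "Sketch",
    "SurfaceMesh",
    "SolidModel",
    "sketch_from_graph",
    "fill_surface",
    "extrude_solid",
    "punch_holes",
    "place_holes_along_main",
    "export_model",
    "HOLE_SEGMENTS",
]

#: Facet count for screw-hole cylinders; at 64 segments the polygonal hole
#: area is within 0.17% of the true circle.
HOLE_SEGMENTS = 64


@dataclass
class Sketch:
    """Closed CCW boundary polyline plus screw-hole disks (center, diameter)."""

    boundary: np.ndarray  # (n, 2) float, CCW, not repeated at the end
    holes: list[tuple[tuple[float, float], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2 or len(self.boundary) < 3:
            raise GeometryError("boundary needs at least 3 2D vertices")
        poly = Polygon(self.boundary)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError("boundary is self-intersecting or degenerate")
        if _signed_area(self.boundary) < 0:
            self.boundary = self.boundary[::-1].copy()
        for (cx, cy), d in self.holes:
            if d <= 0:
                raise GeometryError(f"hole at ({cx}, {cy}): diameter must be > 0")
            if not poly.contains(Point(cx, cy).buffer(d / 2.0, quad_segs=16)):
                raise GeometryError(
                    f"hole at ({cx}, {cy}) d={d} is not strictly inside the boundary"
                )

    def polygon(self) -> Polygon:
        """Boundary minus hole disks as a shapely polygon."""
        rings = [_hole_ring(c, d) for c, d in self.holes]
        poly = Polygon(self.boundary, holes=rings)
        if not poly.is_valid:
            raise GeometryError("holes overlap each other")
        return poly

    @property
    def area(self) -> float:
        return self.polygon().area


@dataclass
class SurfaceMesh:
    """Planar (z=0) triangulated surface."""

    vertices: np.ndarray  # (n, 3)
    triangles: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)

    @property
    def area(self) -> float:
        v = self.vertices
        t = self.triangles
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        return float(np.linalg.norm(np.cross(a, b), axis=1).sum() / 2.0)


@dataclass
class SolidModel:
    """Watertight extruded plate; keeps its base polygon for hole punching."""

    mesh: trimesh.Trimesh
    thickness: float
    base: Polygon

    @property
    def volume(self) -> float:
        return float(self.mesh.volume)


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _hole_ring(center: tuple[float, float], diameter: float) -> list[tuple[float, float]]:
    cx, cy = center
    r = diameter / 2.0
    ang = np.linspace(0.0, 2.0 * math.pi, HOLE_SEGMENTS, endpoint=False)
    # clockwise so the ring is an interior ring of a CCW polygon
    return [(cx + r * math.cos(a), cy - r * math.sin(a)) for a in ang]


# ---------------------------------------------------------------------------
# sketch
# ---------------------------------------------------------------------------

def sketch_from_graph(graph: VeinGraph, end_cap: float = 0.0) -> Sketch:
    """Boundary curve through the skeleton's leaf endpoints.

    Leaves are traversed counter-clockwise by angle around the centroid of
    all skeleton points and joined by straight segments.  ``end_cap`` > 0
    adds two pad points continuing the main-vein axis beyond the root and
    beyond the farthest point along it (the tail/tip of the plate), so the
    boundary encloses the main vein ends as well.
    """
    if not graph.has_positions():
        raise GeometryError("graph has no positions; call layout_graph first")
    pos = {p.id: np.array(p.position) for p in graph.points}
    srcs = {e.src for e in graph.edges}
    leaves = [p.id for p in graph.points if p.id not in srcs]
    candidates = [pos[i] for i in leaves]

    if end_cap > 0.0:
        from .vein_core import _unit_vector

        root = graph.root()
        outgoing = graph.children(root.id)
        if not outgoing:
            raise GeometryError("cannot cap: root has no outgoing vein")
        # cap along the main vein: prefer the edge continuing to a MAIN point
        main = next(
            (e for e in outgoing if graph.point(e.dst).grade.name == "MAIN"),
            outgoing[0],
        )
        axis = np.array(_unit_vector(main.gamma))
        proj = [(float(np.dot(pos[p.id] - pos[root.id], axis)), p.id) for p in graph.points]
        tip_id = max(proj)[1]
        candidates.append(pos[root.id] - end_cap * axis)
        candidates.append(pos[tip_id] + end_cap * axis)

    if len(candidates) < 3:
        raise GeometryError(
            f"need at least 3 boundary candidates, got {len(candidates)} "
            "(too few leaf endpoints)"
        )
    pts = np.array(candidates)
    centroid = np.array([p for p in pos.values()]).mean(axis=0)
    ang = np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0])
    order = np.lexsort((np.hypot(*(pts - centroid).T), ang))
    boundary = pts[order]
    poly = Polygon(boundary)
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError("leaf traversal produced a self-intersecting boundary")
    return Sketch(boundary=boundary)


def place_holes_along_main(
    graph: VeinGraph, diameter: float
) -> list[tuple[tuple[float, float], float]]:
    """Convenience screw-hole layout: equal spacing along the main vein.

    Hole count is ``floor(h_main / (3 * diameter))`` where ``h_main`` is the
    total main-vein length (root-to-tip along MAIN points).
    """
    if diameter <= 0:
        raise DomainError("hole diameter must be > 0")
    if not graph.has_positions():
        raise GeometryError("graph has no positions")
    root = graph.root()
    chain = [root.id]
    length = 0.0
    cur = root.id
    while True:
        nxt = [
            e for e in graph.children(cur)
            if graph.point(e.dst).grade.name == "MAIN"
        ]
        if not nxt:
            break
        e = nxt[0]
        length += e.length
        chain.append(e.dst)
        cur = e.dst
    n_holes = int(length // (3.0 * diameter))
    if n_holes == 0:
        return []
    p0 = np.array(graph.point(chain[0]).position)
    p1 = np.array(graph.point(chain[-1]).position)
    fracs = (np.arange(n_holes) + 0.5) / n_holes
    return [((*(p0 + f * (p1 - p0)),), diameter) for f in fracs]


# ---------------------------------------------------------------------------
# fill / stretch / punch
# ---------------------------------------------------------------------------

def _triangulate(poly: Polygon) -> tuple[np.ndarray, np.ndarray]:
    tris = shapely.constrained_delaunay_triangles(poly)
    verts: list[tuple[float, float]] = []
    index: dict[tuple[float, float], int] = {}
    faces: list[tuple[int, int, int]] = []
    for t in tris.geoms:
        coords = list(t.exterior.coords)[:3]
        if _signed_area(np.array(coords)) < 0:
            coords = coords[::-1]
        ids = []
        for c in coords:
            c = (float(c[0]), float(c[1]))
            if c not in index:
                index[c] = len(verts)
                verts.append(c)
            ids.append(index[c])
        faces.append(tuple(ids))
    v2 = np.array(verts)
    v3 = np.column_stack([v2, np.zeros(len(v2))])
    return v3, np.array(faces, dtype=np.int64)


def fill_surface(sketch: Sketch) -> SurfaceMesh:
    """Constrained triangulation of the boundary-minus-holes region."""
    poly = sketch.polygon()
    verts, faces = _triangulate(poly)
    mesh = SurfaceMesh(vertices=verts, triangles=faces)
    if abs(mesh.area - poly.area) > 0.005 * poly.area:
        raise GeometryError(
            f"triangulation lost area: {mesh.area:.4f} vs polygon {poly.area:.4f}"
        )
    return mesh


def extrude_solid(surface: SurfaceMesh, thickness: float, base: Polygon | None = None) -> SolidModel:
    """Stretch a planar surface into a watertight prism of given thickness."""
    if thickness <= 0:
        raise DomainError(f"thickness must be > 0, got {thickness}")
    mesh = trimesh.creation.extrude_triangulation(
        surface.vertices[:, :2], surface.triangles, float(thickness)
    )
    mesh.process(validate=True)
    if not mesh.is_watertight:
        raise GeometryError("extrusion is not watertight")
    if base is None:
        base = _footprint(surface)
    return SolidModel(mesh=mesh, thickness=float(thickness), base=base)


def _footprint(surface: SurfaceMesh) -> Polygon:
    tris = [
        Polygon(surface.vertices[t][:, :2]) for t in surface.triangles
    ]
    return shapely.union_all(tris)


def punch_holes(
    solid: SolidModel, holes: list[tuple[tuple[float, float], float]]
) -> SolidModel:
    """Remove through-holes; each entry is ((cx, cy), diameter).

    The base polygon is re-triangulated with the hole rings as interior
    boundaries and re-extruded, so the result is exactly watertight and the
    volume drops by the faceted-cylinder volume (within 1% of pi r^2 h).
    """
    if not holes:
        return solid
    base = solid.base
    disks = []
    for (cx, cy), d in holes:
        if d <= 0:
            raise DomainError(f"hole at ({cx}, {cy}): diameter must be > 0")
        disk = Polygon(_hole_ring((cx, cy), d))
        if not base.contains(disk):
            raise GeometryError(
                f"hole at ({cx}, {cy}) d={d} is outside or crosses the plate boundary"
            )
        for other in disks:
            if disk.intersects(other):
                raise GeometryError(f"hole at ({cx}, {cy}) overlaps another hole")
        disks.append(disk)
    remaining = base
    for disk in disks:
        remaining = remaining.difference(disk)
    if remaining.geom_type != "Polygon":
        raise GeometryError("hole punching split the plate into pieces")
    verts, faces = _triangulate(remaining)
    surf = SurfaceMesh(vertices=verts, triangles=faces)
    return extrude_solid(surf, solid.thickness, base=remaining)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_model(obj, path, format: str) -> None:
    """Write a Sketch (SVG) or mesh (binary STL / OBJ) to ``path``."""
    fmt = format.upper()
    if fmt == "SVG":
        if not isinstance(obj, Sketch):
            raise UsageError("SVG export is only defined for Sketch objects")
        _write_svg(obj, path)
        return
    if fmt not in ("STL", "OBJ"):
        raise UsageError(f"unsupported export format {format!r}")
    if isinstance(obj, SolidModel):
        mesh = obj.mesh
    elif isinstance(obj, SurfaceMesh):
        mesh = trimesh.Trimesh(vertices=obj.vertices, faces=obj.triangles, process=False)
    else:
        raise UsageError(f"cannot export {type(obj).__name__} as {fmt}")
    mesh.export(path, file_type=fmt.lower())


def _write_svg(sketch: Sketch, path) -> None:
    pts = sketch.boundary
    xmin, ymin = pts.min(axis=0) - 2
    xmax, ymax = pts.max(axis=0) + 2
    w, h = xmax - xmin, ymax - ymin
    # flip y so +y (anatomically 'up') points up on screen
    d = "M " + " L ".join(f"{x - xmin:.4f},{ymax - y:.4f}" for x, y in pts) + " Z"
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.4f}mm" height="{h:.4f}mm" '
        f'viewBox="0 0 {w:.4f} {h:.4f}">',
        f'  <path d="{d}" fill="none" stroke="black" stroke-width="0.5"/>',
    ]
    for (cx, cy), dia in sketch.holes:
        lines.append(
            f'  <circle cx="{cx - xmin:.4f}" cy="{ymax - cy:.4f}" r="{dia / 2.0:.4f}" '
            'fill="none" stroke="black" stroke-width="0.5"/>'
        )
    lines.append("</svg>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
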