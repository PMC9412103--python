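"""Vein-graph data model and the morphological/dimensional adjacency codec.

An implant's abutted-surface skeleton is modelled on a leaf: a *main vein*
(the plate centre line), *lateral veins* branching off it, and *minor veins*
branching off the laterals.  The skeleton is a rooted tree drawn in the 2D
sketch plane (x right, y up, all lengths in millimetres).  Every vein edge
carries two weights:

``gamma``
    a dimensionless direction code in ``[0, 2)``: 0 points along +x and each
    counter-clockwise quarter turn adds 0.5 (so ``gamma * 180`` is the planar
    angle in degrees).
``length``
    the vein length in mm.

After canonical numbering (parents before children, bottom-to-top and
left-to-right otherwise) the edge weights populate two strictly
upper-triangular matrices: the *morphological* matrix ``M1`` of gamma codes
and the *dimensional* matrix ``M2`` of lengths.  The pair of matrices is the
retrieval key of the feature database.

Because ``gamma = 0`` is a legal direction (rightward) while absent matrix
entries are also stored as 0, an explicit boolean ``edge_mask`` accompanies
the matrices and is the source of truth for which entries are edges.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, FormatError, StructureError

__all__ = [
    "VeinGrade",
    "HeadBranch",
    "Direction",
    "VeinPoint",
    "VeinEdge",
    "VeinGraph",
    "AdjacencyPair",
    "Diagnostic",
    "alpha_to_gamma",
    "gamma_to_direction",
    "gamma_to_angle",
    "angle_to_gamma",
    "build_adjacency",
    "graph_from_adjacency",
    "layout_graph",
    "canonical_numbering",
    "validate_graph",
    "graph_to_json",
    "graph_from_json",
]


class VeinGrade(enum.Enum):
    """Vein grades, ordered MAIN > LATERAL > MINOR."""

    MAIN = 3
    LATERAL = 2
    MINOR = 1

    def __ge__(self, other: "VeinGrade") -> bool:
        return self.value >= other.value

    def __gt__(self, other: "VeinGrade") -> bool:
        return self.value > other.value

    def __le__(self, other: "VeinGrade") -> bool:
        return self.value <= other.value

    def __lt__(self, other: "VeinGrade") -> bool:
        return self.value < other.value


class HeadBranch(enum.Enum):
    """Which branch of the head-angle relation maps an angle alpha to gamma.

    The left head lateral always uses ``LEFT_HEAD``; the right head lateral
    uses ``RIGHT_HEAD_OBTUSE`` for alpha >= 90 deg and ``RIGHT_HEAD_ACUTE``
    for alpha < 90 deg (the two right-hand branches describe the same
    direction, the split only keeps gamma inside [0, 2)).
    """

    LEFT_HEAD = "left_head"
    RIGHT_HEAD_OBTUSE = "right_head_obtuse"
    RIGHT_HEAD_ACUTE = "right_head_acute"


class Direction(enum.Enum):
    """Quadrant / axis labels for a gamma code."""

    RIGHT = "right"
    UPPER_RIGHT = "upper_right"
    UP = "up"
    UPPER_LEFT = "upper_left"
    LEFT = "left"
    LOWER_LEFT = "lower_left"
    DOWN = "down"
    LOWER_RIGHT = "lower_right"


@dataclass(frozen=True)
class VeinPoint:
    """One vein feature point."""

    id: int
    grade: VeinGrade
    label: str = ""
    position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.id < 0:
            raise DomainError(f"point id must be >= 0, got {self.id}")
        if self.position is not None:
            x, y = self.position
            if not (math.isfinite(x) and math.isfinite(y)):
                raise DomainError(f"point {self.label or self.id}: non-finite position")
            object.__setattr__(self, "position", (float(x), float(y)))


@dataclass(frozen=True)
class VeinEdge:
    """One directed vein, from the higher-grade point to the lower."""

    src: int
    dst: int
    gamma: float
    length: float

    def __post_init__(self) -> None:
        if self.src == self.dst:
            raise StructureError(f"self-loop at point {self.src}")
        if not 0.0 <= self.gamma < 2.0:
            raise DomainError(f"edge {self.src}->{self.dst}: gamma {self.gamma} outside [0, 2)")
        if not self.length > 0.0:
            raise DomainError(f"edge {self.src}->{self.dst}: length {self.length} must be > 0")


@dataclass
class VeinGraph:
    """A rooted vein skeleton: ordered points plus directed vein edges."""

    points: list[VeinPoint] = field(default_factory=list)
    edges: list[VeinEdge] = field(default_factory=list)

    # -- basic accessors -------------------------------------------------
    def point(self, pid: int) -> VeinPoint:
        for p in self.points:
            if p.id == pid:
                return p
        raise KeyError(f"no point with id {pid}")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def root(self) -> VeinPoint:
        """The unique point with no incoming vein."""
        targets = {e.dst for e in self.edges}
        roots = [p for p in self.points if p.id not in targets]
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, found {len(roots)}")
        return roots[0]

    def children(self, pid: int) -> list[VeinEdge]:
        return [e for e in self.edges if e.src == pid]

    def parent_edge(self, pid: int) -> VeinEdge | None:
        incoming = [e for e in self.edges if e.dst == pid]
        if len(incoming) > 1:
            raise StructureError(f"point {pid} has {len(incoming)} incoming veins")
        return incoming[0] if incoming else None

    def has_positions(self) -> bool:
        return all(p.position is not None for p in self.points)

    def structurally_equal(self, other: "VeinGraph", tol: float = 1e-9) -> bool:
        """Equality of ids, grades and edge topology; weights within ``tol``."""
        if [(p.id, p.grade) for p in self.points] != [(p.id, p.grade) for p in other.points]:
            return False
        if len(self.edges) != len(other.edges):
            return False
        key = lambda e: (e.src, e.dst)
        for a, b in zip(sorted(self.edges, key=key), sorted(other.edges, key=key)):
            if (a.src, a.dst) != (b.src, b.dst):
                return False
            if abs(a.gamma - b.gamma) > tol or abs(a.length - b.length) > tol:
                return False
        return True


@dataclass
class AdjacencyPair:
    """Morphological (gamma) and dimensional (length) matrices of one graph.

    Both matrices are strictly upper triangular over the canonical point
    numbering; ``edge_mask`` marks which entries are true veins.
    """

    n: int
    m1: np.ndarray
    m2: np.ndarray
    edge_mask: np.ndarray

    def __post_init__(self) -> None:
        for name, m in (("M1", self.m1), ("M2", self.m2), ("edge_mask", self.edge_mask)):
            m = np.asarray(m)
            if m.shape != (self.n, self.n):
                raise StructureError(f"{name} must be {self.n}x{self.n}, got {m.shape}")
        self.m1 = np.asarray(self.m1, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        self.edge_mask = np.asarray(self.edge_mask, dtype=bool)
        lower = ~np.triu(np.ones((self.n, self.n), dtype=bool), k=1)
        if self.edge_mask[lower].any():
            raise StructureError("edge_mask has entries on or below the diagonal")
        if self.m1[lower].any() or self.m2[lower].any():
            raise StructureError("M1/M2 must be strictly upper triangular")
        off = ~self.edge_mask
        if self.m1[off].any() or self.m2[off].any():
            raise StructureError("M1/M2 non-zero outside the edge mask")
        if self.edge_mask.any():
            g = self.m1[self.edge_mask]
            v = self.m2[self.edge_mask]
            if (g < 0).any() or (g >= 2).any():
                raise StructureError("gamma entries outside [0, 2)")
            if (v <= 0).any():
                raise StructureError("length entries must be > 0")

    @property
    def n_edges(self) -> int:
        return int(self.edge_mask.sum())

    def equal(self, other: "AdjacencyPair", tol: float = 1e-9) -> bool:
        return (
            self.n == other.n
            and bool((self.edge_mask == other.edge_mask).all())
            and bool(np.allclose(self.m1, other.m1, atol=tol, rtol=0))
            and bool(np.allclose(self.m2, other.m2, atol=tol, rtol=0))
        )


@dataclass(frozen=True)
class Diagnostic:
    """One invariant violation reported by :func:`validate_graph`."""

    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.code}] {self.message}"


# ---------------------------------------------------------------------------
# gamma encoding
# ---------------------------------------------------------------------------

def alpha_to_gamma(alpha: float, branch: HeadBranch) -> float:
    """Convert a head angle alpha (degrees, between main vein and lateral)
    to the gamma direction code of the lateral.

    With the main vein pointing up, a left lateral at interior angle alpha
    points along ``270 - alpha`` degrees and a right lateral along
    ``alpha - 90`` degrees; gamma is that angle divided by 180 and wrapped
    into [0, 2).
    """
    a = math.radians(alpha)
    if branch is HeadBranch.LEFT_HEAD:
        if not 0.0 <= alpha <= 180.0:
            raise DomainError(f"LEFT_HEAD requires 0 <= alpha <= 180, got {alpha}")
        g = (1.5 * math.pi - a) / math.pi
    elif branch is HeadBranch.RIGHT_HEAD_OBTUSE:
        if not 90.0 <= alpha <= 180.0:
            raise DomainError(f"RIGHT_HEAD_OBTUSE requires 90 <= alpha <= 180, got {alpha}")
        g = (-0.5 * math.pi + a) / math.pi
    elif branch is HeadBranch.RIGHT_HEAD_ACUTE:
        if not 0.0 <= alpha < 90.0:
            raise DomainError(f"RIGHT_HEAD_ACUTE requires 0 <= alpha < 90, got {alpha}")
        g = (1.5 * math.pi + a) / math.pi
    else:  # pragma: no cover - enum is closed
        raise DomainError(f"unknown branch {branch}")
    if g >= 2.0:  # alpha = 90 on the acute bound is excluded, so only wrap
        g -= 2.0
    return g


def gamma_to_direction(gamma: float) -> Direction:
    """Map a gamma code to its quadrant (or axis, on the boundaries)."""
    if not 0.0 <= gamma < 2.0:
        raise DomainError(f"gamma {gamma} outside [0, 2)")
    axes = {0.0: Direction.RIGHT, 0.5: Direction.UP, 1.0: Direction.LEFT, 1.5: Direction.DOWN}
    if gamma in axes:
        return axes[gamma]
    if gamma < 0.5:
        return Direction.UPPER_RIGHT
    if gamma < 1.0:
        return Direction.UPPER_LEFT
    if gamma < 1.5:
        return Direction.LOWER_LEFT
    return Direction.LOWER_RIGHT


def gamma_to_angle(gamma: float) -> float:
    """Planar angle in degrees counter-clockwise from +x (gamma * 180)."""
    if not 0.0 <= gamma < 2.0:
        raise DomainError(f"gamma {gamma} outside [0, 2)")
    return gamma * 180.0


def angle_to_gamma(angle_deg: float) -> float:
    """Inverse of :func:`gamma_to_angle`, wrapping the angle into [0, 360)."""
    g = (angle_deg % 360.0) / 180.0
    return 0.0 if g == 2.0 else g


# ---------------------------------------------------------------------------
# graph <-> matrices
# ---------------------------------------------------------------------------

def _index_of(graph: VeinGraph) -> dict[int, int]:
    ids = [p.id for p in graph.points]
    if len(set(ids)) != len(ids):
        raise StructureError("duplicate point ids")
    return {pid: i for i, pid in enumerate(ids)}


def build_adjacency(graph: VeinGraph) -> AdjacencyPair:
    """Encode a canonically numbered graph as its (M1, M2) matrix pair."""
    idx = _index_of(graph)
    n = graph.n_points
    m1 = np.zeros((n, n))
    m2 = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for e in graph.edges:
        i, j = idx[e.src], idx[e.dst]
        if i >= j:
            raise StructureError(
                f"edge {e.src}->{e.dst} not in canonical order (src index must precede dst)"
            )
        m1[i, j] = e.gamma
        m2[i, j] = e.length
        mask[i, j] = True
    return AdjacencyPair(n=n, m1=m1, m2=m2, edge_mask=mask)


def graph_from_adjacency(
    pair: AdjacencyPair,
    grades: Sequence[VeinGrade],
    labels: Sequence[str] | None = None,
) -> VeinGraph:
    """Decode an adjacency pair back into a vein graph.

    The mask must describe a tree rooted at vertex 0: every vertex except 0
    has exactly one incoming edge, and edges run from lower to higher index.
    """
    n = pair.n
    if len(grades) != n:
        raise StructureError(f"need {n} grades, got {len(grades)}")
    if labels is not None and len(labels) != n:
        raise StructureError(f"need {n} labels, got {len(labels)}")
    indeg = pair.edge_mask.sum(axis=0)
    if n > 0 and indeg[0] != 0:
        raise StructureError("vertex 0 must be the root (no incoming edge)")
    bad = np.nonzero(indeg > 1)[0]
    if bad.size:
        raise StructureError(f"vertices {bad.tolist()} have more than one incoming vein")
    orphans = [j for j in range(1, n) if indeg[j] == 0]
    if orphans:
        raise StructureError(f"vertices {orphans} are disconnected from the root")
    points = [
        VeinPoint(id=i, grade=grades[i], label=labels[i] if labels else "")
        for i in range(n)
    ]
    edges = [
        VeinEdge(src=int(i), dst=int(j), gamma=float(pair.m1[i, j]), length=float(pair.m2[i, j]))
        for i, j in zip(*np.nonzero(pair.edge_mask))
    ]
    return VeinGraph(points=points, edges=edges)


# ---------------------------------------------------------------------------
# layout and numbering
# ---------------------------------------------------------------------------

def _unit_vector(gamma: float) -> tuple[float, float]:
    """Unit direction of a gamma code; exact on the four axis directions so
    horizontal/vertical veins stay exactly horizontal/vertical."""
    quarter = gamma * 2.0
    if quarter == int(quarter):
        return [(1.0, 0.0), (0.0, 1.0), (-1.0, 0.0), (0.0, -1.0)][int(quarter) % 4]
    ang = gamma * math.pi
    return (math.cos(ang), math.sin(ang))


def layout_graph(graph: VeinGraph, root_position: tuple[float, float] = (0.0, 0.0)) -> VeinGraph:
    """Realize gamma/length weights as 2D positions.

    The root sits at ``root_position``; each child sits at
    ``parent + length * (cos(gamma*pi), sin(gamma*pi))``.
    """
    root = graph.root()
    pos: dict[int, tuple[float, float]] = {root.id: (float(root_position[0]), float(root_position[1]))}
    frontier = [root.id]
    while frontier:
        pid = frontier.pop()
        px, py = pos[pid]
        for e in graph.children(pid):
            ux, uy = _unit_vector(e.gamma)
            pos[e.dst] = (px + e.length * ux, py + e.length * uy)
            frontier.append(e.dst)
    missing = [p.id for p in graph.points if p.id not in pos]
    if missing:
        raise StructureError(f"points {missing} unreachable from the root; graph is disconnected")
    points = [replace(p, position=pos[p.id]) for p in graph.points]
    return VeinGraph(points=points, edges=list(graph.edges))


def canonical_numbering(graph: VeinGraph) -> VeinGraph:
    """Renumber points bottom-to-top, left-to-right, parents first.

    Vertices are assigned indices in the order a Kahn traversal releases
    them, always taking the ready vertex with the smallest
    ``(y, x, previous index)`` key.  The parents-first constraint is what
    keeps the adjacency matrices strictly upper triangular even when a vein
    runs horizontally or downward (e.g. tail laterals at the root height or
    laterals with an attachment angle below 90 deg).
    """
    if not graph.has_positions():
        raise StructureError("canonical numbering needs positions; call layout_graph first")
    order_index = {p.id: k for k, p in enumerate(graph.points)}
    parent = {}
    for e in graph.edges:
        if e.dst in parent:
            raise StructureError(f"point {e.dst} has more than one incoming vein")
        parent[e.dst] = e.src
    ready = sorted(
        (p for p in graph.points if p.id not in parent),
        key=lambda p: (p.position[1], p.position[0], order_index[p.id]),
    )
    if len(ready) != 1:
        raise StructureError(f"expected exactly one root, found {len(ready)}")
    key = lambda p: (p.position[1], p.position[0], order_index[p.id])
    new_id: dict[int, int] = {}
    points_by_id = {p.id: p for p in graph.points}
    children = {p.id: [e.dst for e in graph.children(p.id)] for p in graph.points}
    heap = list(ready)
    while heap:
        heap.sort(key=key)
        p = heap.pop(0)
        new_id[p.id] = len(new_id)
        heap.extend(points_by_id[c] for c in children[p.id])
    if len(new_id) != graph.n_points:
        raise StructureError("graph contains a cycle or disconnected points")
    points = sorted(
        (replace(p, id=new_id[p.id]) for p in graph.points), key=lambda p: p.id
    )
    edges = sorted(
        (replace(e, src=new_id[e.src], dst=new_id[e.dst]) for e in graph.edges),
        key=lambda e: (e.src, e.dst),
    )
    return VeinGraph(points=points, edges=edges)


def validate_graph(graph: VeinGraph) -> list[Diagnostic]:
    """Check all graph invariants; return one diagnostic per violation."""
    out: list[Diagnostic] = []
    ids = [p.id for p in graph.points]
    dup = {i for i in ids if ids.count(i) > 1}
    for d in sorted(dup):
        out.append(Diagnostic("duplicate-id", f"point id {d} appears more than once"))
    known = set(ids)
    grade = {p.id: p.grade for p in graph.points}
    indeg: dict[int, int] = {i: 0 for i in known}
    for e in graph.edges:
        tag = f"edge {e.src}->{e.dst}"
        if e.src not in known or e.dst not in known:
            out.append(Diagnostic("dangling-edge", f"{tag} references unknown point"))
            continue
        indeg[e.dst] += 1
        if not 0.0 <= e.gamma < 2.0:
            out.append(Diagnostic("gamma-range", f"{tag}: gamma {e.gamma} outside [0, 2)"))
        if not e.length > 0:
            out.append(Diagnostic("length-range", f"{tag}: length {e.length} must be > 0"))
        if grade[e.src] < grade[e.dst]:
            out.append(
                Diagnostic(
                    "grade-order",
                    f"{tag}: grade {grade[e.src].name} -> {grade[e.dst].name} "
                    "runs from lower to higher grade",
                )
            )
    multi = [i for i, d in indeg.items() if d > 1]
    for i in sorted(multi):
        out.append(Diagnostic("multi-parent", f"point {i} has {indeg[i]} incoming veins"))
    roots = [i for i, d in indeg.items() if d == 0]
    if graph.points and len(roots) != 1:
        out.append(Diagnostic("root-count", f"expected 1 root, found {len(roots)}: {sorted(roots)}"))
    elif graph.points and not multi:
        # reachability / acyclicity from the single root
        adj: dict[int, list[int]] = {i: [] for i in known}
        for e in graph.edges:
            if e.src in known and e.dst in known:
                adj[e.src].append(e.dst)
        seen: set[int] = set()
        stack = [roots[0]]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(adj[v])
        stray = known - seen
        if stray:
            out.append(Diagnostic("disconnected", f"points {sorted(stray)} unreachable from root"))
    for p in graph.points:
        if p.position is not None:
            x, y = p.position
            if not (math.isfinite(x) and math.isfinite(y)):
                out.append(Diagnostic("position", f"point {p.id} has non-finite position"))
    return out


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------

def graph_to_json(graph: VeinGraph) -> dict:
    """Serialize to the on-disk interchange schema used by the feature db."""
    return {
        "points": [
            {
                "id": p.id,
                "grade": p.grade.name,
                "label": p.label,
                "x": None if p.position is None else p.position[0],
                "y": None if p.position is None else p.position[1],
            }
            for p in graph.points
        ],
        "edges": [
            {"src": e.src, "dst": e.dst, "gamma": e.gamma, "length_mm": e.length}
            for e in graph.edges
        ],
    }


def graph_from_json(obj: dict) -> VeinGraph:
    try:
        points = [
            VeinPoint(
                id=int(p["id"]),
                grade=VeinGrade[p["grade"]],
                label=p.get("label", ""),
                position=None if p.get("x") is None else (float(p["x"]), float(p["y"])),
            )
            for p in obj["points"]
        ]
        edges = [
            VeinEdge(
                src=int(e["src"]), dst=int(e["dst"]),
                gamma=float(e["gamma"]), length=float(e["length_mm"]),
            )
            for e in obj["edges"]
        ]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed vein-graph JSON: {exc}") from exc
    return VeinGraph(points=points, edges=edges)


def graph_dump(graph: VeinGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(graph_to_json(graph), fh, indent=2)
        fh.write("\n")


def graph_load(path) -> VeinGraph:
    with open(path, encoding="utf-8") as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    return graph_from_json(obj)
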