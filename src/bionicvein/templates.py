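"""Parametric vein-skeleton templates for the four implant topologies.

Each template turns a named semantic-parameter set (vein lengths in mm,
inter-vein angles in degrees) into a laid-out, canonically numbered
:class:`~bionicvein.vein_core.VeinGraph`:

``T_PLATE``
    overall structure of a T-shaped plate: vertical main vein, two
    horizontal tail laterals, two angled head laterals each carrying a pair
    of minor veins perpendicular to it.
``L_PLATE_LEFT`` / ``L_PLATE_RIGHT``
    L-shaped plate: like the T tail, but the head has a single free-angle
    lateral whose opposite vein continues collinearly, with one minor pair
    on the branch side.  The right-hand plate is the mirror image.
``CLOVER_HEAD``
    interest region of a clover plate head: a two-segment main vein
    (middle branch) with branch laterals at the bottom, adjuster lateral
    pairs at the centre and top, collinear branch extensions, and four
    minor pairs (32 semantic parameters).
``FEMORAL_STEM_REGION``
    interest region of a femoral stem: three branching levels on the main
    vein; at each level a left and right lateral, each with a minor vein
    leaving its midpoint (18 semantic parameters).

All child directions follow one rule: a *left* child at interior angle
``alpha`` to its parent vein points ``180 - alpha`` degrees counter-clockwise
of the parent direction, a *right* child the same amount clockwise.  For a
vertical main vein this reduces to the T-plate head-angle relation
implemented by :func:`~bionicvein.vein_core.alpha_to_gamma`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import pandas as pd

from .errors import FormatError, ValidationError
from .vein_core import (
    VeinEdge,
    VeinGraph,
    VeinGrade,
    VeinPoint,
    canonical_numbering,
    layout_graph,
)

__all__ = [
    "ImplantType",
    "ParameterSet",
    "Relation",
    "ConstraintSet",
    "TemplateDefinition",
    "make_template",
    "count_free_parameters",
    "check_constraints",
    "load_parameter_table",
    "packaged_table_path",
    "template_definition",
    "SOLID_PARAMETERS",
]

MAIN, LATERAL, MINOR = VeinGrade.MAIN, VeinGrade.LATERAL, VeinGrade.MINOR

#: Solid parameters (plate thickness, screw-hole diameter); accepted by every
#: template but not counted among the semantic shape parameters.
SOLID_PARAMETERS = ("n1", "d1")


class ImplantType(enum.Enum):
    T_PLATE = "t_plate"
    L_PLATE_LEFT = "l_plate_left"
    L_PLATE_RIGHT = "l_plate_right"
    CLOVER_HEAD = "clover_head"
    FEMORAL_STEM_REGION = "femoral_stem_region"


@dataclass(frozen=True)
class ParameterSet:
    """Named semantic parameters of one template instance."""

    implant_type: ImplantType
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", {str(k): float(v) for k, v in self.values.items()}
        )

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise KeyError(
                f"parameter {name!r} missing for {self.implant_type.value}"
            ) from None

    def get(self, name: str, default: float | None = None) -> float | None:
        return self.values.get(name, default)


# ---------------------------------------------------------------------------
# constraint relations
# ---------------------------------------------------------------------------

_EQ_TOL = 1e-9


@dataclass(frozen=True)
class Relation:
    """One relation ``lhs <op> rhs`` over parameter-name expressions."""

    lhs: str
    op: str
    rhs: str

    def holds(self, values: dict[str, float]) -> bool:
        a = _eval_expr(self.lhs, values)
        b = _eval_expr(self.rhs, values)
        if self.op == "<":
            return a < b
        if self.op == "<=":
            return a <= b
        if self.op == "==":
            return abs(a - b) <= _EQ_TOL * max(1.0, abs(a), abs(b))
        if self.op == ">":
            return a > b
        if self.op == ">=":
            return a >= b
        raise ValueError(f"unknown comparator {self.op!r}")

    def __str__(self) -> str:
        return f"{self.lhs} {self.op} {self.rhs}"


def _eval_expr(expr: str, values: dict[str, float]) -> float:
    # expressions are authored inside this module (names, numbers, + - * /)
    return float(eval(expr, {"__builtins__": {}}, dict(values)))  # noqa: S307


@dataclass(frozen=True)
class ConstraintSet:
    relations: tuple[Relation, ...] = ()

    def violations(self, values: dict[str, float]) -> list[str]:
        out = []
        for r in self.relations:
            try:
                ok = r.holds(values)
            except NameError as exc:
                out.append(f"{r}: {exc}")
                continue
            if not ok:
                out.append(str(r))
        return out


def _rel(lhs: str, op: str, rhs: str) -> Relation:
    return Relation(lhs, op, rhs)


#: The T-plate relation set, verbatim.  ``d1 < 2*t1`` is only evaluated when
#: the optional screw-hole diameter is supplied.
_T_RELATIONS = (
    _rel("90", "<", "alpha1"),
    _rel("alpha1", "<", "180"),
    _rel("90", "<", "alpha2"),
    _rel("alpha2", "<", "180"),
    _rel("u1", "==", "t1"),
    _rel("u2", "==", "t2"),
    _rel("l1", "==", "m1"),
    _rel("l1", "<", "l2"),
    _rel("l2", "<", "h1"),
)
_T_SOLID_RELATION = _rel("d1", "<", "2*t1")


# ---------------------------------------------------------------------------
# direction helpers
# ---------------------------------------------------------------------------

def _left_gamma(parent_gamma: float, alpha: float) -> float:
    """Gamma of a left child at interior angle ``alpha`` (deg) to its parent."""
    return (parent_gamma + (1.0 - alpha / 180.0)) % 2.0


def _right_gamma(parent_gamma: float, alpha: float) -> float:
    return (parent_gamma - (1.0 - alpha / 180.0)) % 2.0


def _perp_forward(parent_gamma: float) -> tuple[float, float]:
    """The two perpendiculars to a vein, (left/upper first).

    'Forward' ordering: the first has the larger +y component; for a
    vertical vein the +x perpendicular comes first.
    """
    a = (parent_gamma + 0.5) % 2.0
    b = (parent_gamma - 0.5) % 2.0
    ya, yb = math.sin(a * math.pi), math.sin(b * math.pi)
    if ya > yb or (abs(ya - yb) < 1e-12 and math.cos(a * math.pi) > math.cos(b * math.pi)):
        return a, b
    return b, a


class _Builder:
    """Accumulates points/edges with provisional ids, then lays out."""

    def __init__(self) -> None:
        self.points: list[VeinPoint] = []
        self.edges: list[VeinEdge] = []

    def add_point(self, label: str, grade: VeinGrade) -> int:
        pid = len(self.points)
        self.points.append(VeinPoint(id=pid, grade=grade, label=label))
        return pid

    def add_edge(self, src: int, dst: int, gamma: float, length: float) -> None:
        self.edges.append(VeinEdge(src=src, dst=dst, gamma=gamma, length=length))

    def finish(self) -> VeinGraph:
        g = VeinGraph(points=self.points, edges=self.edges)
        return canonical_numbering(layout_graph(g))


# ---------------------------------------------------------------------------
# topology builders
# ---------------------------------------------------------------------------

def _build_t_plate(p: ParameterSet) -> VeinGraph:
    b = _Builder()
    o1 = b.add_point("O1", MAIN)
    o2 = b.add_point("O2", MAIN)
    b.add_edge(o1, o2, 0.5, p["h1"])
    # tail laterals: horizontal, define the tail width
    a1 = b.add_point("A1", LATERAL)
    b1 = b.add_point("B1", LATERAL)
    b.add_edge(o1, a1, 1.0, p["l1"])
    b.add_edge(o1, b1, 0.0, p["m1"])
    # head laterals at the printed angles, minors perpendicular to them
    g_a2 = _left_gamma(0.5, p["alpha1"])
    g_b2 = _right_gamma(0.5, p["alpha2"])
    a2 = b.add_point("A2", LATERAL)
    b2 = b.add_point("B2", LATERAL)
    b.add_edge(o2, a2, g_a2, p["l2"])
    b.add_edge(o2, b2, g_b2, p["m2"])
    for parent, g_par, left_len, right_len, left_lab, right_lab in (
        (a2, g_a2, p["u1"], p["t1"], "C1", "D1"),
        (b2, g_b2, p["u2"], p["t2"], "C2", "D2"),
    ):
        c = b.add_point(left_lab, MINOR)
        d = b.add_point(right_lab, MINOR)
        b.add_edge(parent, c, (g_par + 0.5) % 2.0, left_len)
        b.add_edge(parent, d, (g_par - 0.5) % 2.0, right_len)
    return b.finish()


def _build_l_plate(p: ParameterSet, mirror: bool = False) -> VeinGraph:
    b = _Builder()
    o1 = b.add_point("O1", MAIN)
    o2 = b.add_point("O2", MAIN)
    b.add_edge(o1, o2, 0.5, p["h2"])
    a1 = b.add_point("A1", LATERAL)
    b1 = b.add_point("B1", LATERAL)
    b.add_edge(o1, a1, 1.0, p["l3"])
    b.add_edge(o1, b1, 0.0, p["m3"])
    # head: free-direction branch lateral; opposite vein collinear with it
    g3 = p["gamma3"] % 2.0
    a2 = b.add_point("A2", LATERAL)
    b2 = b.add_point("B2", LATERAL)
    b.add_edge(o2, a2, g3, p["l4"])
    b.add_edge(o2, b2, (g3 + 1.0) % 2.0, p["m4"])
    c = b.add_point("C1", MINOR)
    d = b.add_point("D1", MINOR)
    b.add_edge(a2, c, (g3 + 0.5) % 2.0, p["u3"])
    b.add_edge(a2, d, (g3 - 0.5) % 2.0, p["t3"])
    if mirror:
        # reflect across the main vein: x -> -x, gamma -> (1 - gamma) mod 2
        b.edges = [
            VeinEdge(e.src, e.dst, (1.0 - e.gamma) % 2.0, e.length) for e in b.edges
        ]
    return b.finish()


def _build_clover_head(p: ParameterSet) -> VeinGraph:
    b = _Builder()
    o1 = b.add_point("O1", MAIN)
    o2 = b.add_point("O2", MAIN)
    o3 = b.add_point("O3", MAIN)
    b.add_edge(o1, o2, 0.5, p["h3"])
    b.add_edge(o2, o3, 0.5, p["h4"])
    # branch laterals at the lower end of the main vein
    g_la = _left_gamma(0.5, p["alpha4"])
    g_rb = _right_gamma(0.5, p["alpha5"])
    la1 = b.add_point("LA1", LATERAL)
    rb1 = b.add_point("RB1", LATERAL)
    b.add_edge(o1, la1, g_la, p["l5"])
    b.add_edge(o1, rb1, g_rb, p["m5"])
    # adjuster pairs at the centre and top of the main vein
    cl = b.add_point("CL", LATERAL)
    cr = b.add_point("CR", LATERAL)
    b.add_edge(o2, cl, _left_gamma(0.5, p["alpha6"]), p["l6"])
    b.add_edge(o2, cr, _right_gamma(0.5, p["alpha7"]), p["m6"])
    tl = b.add_point("TL", LATERAL)
    tr = b.add_point("TR", LATERAL)
    b.add_edge(o3, tl, _left_gamma(0.5, p["alpha8"]), p["l7"])
    b.add_edge(o3, tr, _right_gamma(0.5, p["alpha9"]), p["m7"])
    # collinear extensions of the branch laterals
    la2 = b.add_point("LA2", LATERAL)
    rb2 = b.add_point("RB2", LATERAL)
    b.add_edge(la1, la2, g_la, p["l8"])
    b.add_edge(rb1, rb2, g_rb, p["m8"])
    # minor pairs: two on each branch side
    for parent, g_par, a_l, a_r, len_l, len_r, lab in (
        (la1, g_la, p["alpha10"], p["alpha11"], p["u4"], p["t4"], "L1"),
        (la2, g_la, p["alpha12"], p["alpha13"], p["u5"], p["t5"], "L2"),
        (rb1, g_rb, p["alpha14"], p["alpha15"], p["u6"], p["t6"], "R1"),
        (rb2, g_rb, p["alpha16"], p["alpha17"], p["u7"], p["t7"], "R2"),
    ):
        c = b.add_point(f"C{lab}", MINOR)
        d = b.add_point(f"D{lab}", MINOR)
        b.add_edge(parent, c, _left_gamma(g_par, a_l), len_l)
        b.add_edge(parent, d, _right_gamma(g_par, a_r), len_r)
    return b.finish()


#: Distance between consecutive branching levels of the femoral-stem main
#: vein (mm).  Not one of the 18 semantic parameters; the printed tables
#: parameterize the branches only.
STEM_LEVEL_SPACING = 30.0


def _build_stem_region(p: ParameterSet, spacing: float = STEM_LEVEL_SPACING) -> VeinGraph:
    b = _Builder()
    mains = [b.add_point(f"O{i}", MAIN) for i in range(5)]
    for lo, hi in zip(mains, mains[1:]):
        b.add_edge(lo, hi, 0.5, spacing)
    for i in (1, 2, 3):
        for side, angle_name, lat_name, minor_name, mid_lab, end_lab, minor_lab in (
            ("left", f"beta{i}", f"l{i}", f"u{i}", f"C{i}", f"A{i}1", f"A{i}0"),
            ("right", f"theta{i}", f"m{i}", f"t{i}", f"D{i}", f"B{i}1", f"B{i}0"),
        ):
            g = (
                _left_gamma(0.5, p[angle_name])
                if side == "left"
                else _right_gamma(0.5, p[angle_name])
            )
            half = p[lat_name] / 2.0
            mid = b.add_point(mid_lab, LATERAL)
            end = b.add_point(end_lab, LATERAL)
            tip = b.add_point(minor_lab, MINOR)
            b.add_edge(mains[i], mid, g, half)
            b.add_edge(mid, end, g, half)
            # minor leaves the lateral midpoint perpendicular, forward side
            fwd, _ = _perp_forward(g)
            b.add_edge(mid, tip, fwd, p[minor_name])
    return b.finish()


# ---------------------------------------------------------------------------
# template registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateDefinition:
    implant_type: ImplantType
    parameter_names: tuple[str, ...]
    constraints: ConstraintSet
    builder: Callable[[ParameterSet], VeinGraph]
    main_vein_names: tuple[str, ...]
    key_lateral_labels: tuple[str, str]


def _names(*groups: Sequence[str]) -> tuple[str, ...]:
    out: list[str] = []
    for g in groups:
        out.extend(g)
    return tuple(out)


_TEMPLATES: dict[ImplantType, TemplateDefinition] = {
    ImplantType.T_PLATE: TemplateDefinition(
        ImplantType.T_PLATE,
        _names(["h1"], ["l1", "m1", "l2", "m2"], ["u1", "t1", "u2", "t2"],
               ["alpha1", "alpha2"]),
        ConstraintSet(_T_RELATIONS),
        _build_t_plate,
        ("h1",),
        ("A2", "B2"),
    ),
    ImplantType.L_PLATE_LEFT: TemplateDefinition(
        ImplantType.L_PLATE_LEFT,
        _names(["h2"], ["l3", "m3", "l4", "m4"], ["u3", "t3"], ["gamma3"]),
        ConstraintSet(),
        _build_l_plate,
        ("h2",),
        ("A2", "B2"),
    ),
    ImplantType.L_PLATE_RIGHT: TemplateDefinition(
        ImplantType.L_PLATE_RIGHT,
        _names(["h2"], ["l3", "m3", "l4", "m4"], ["u3", "t3"], ["gamma3"]),
        ConstraintSet(),
        lambda p: _build_l_plate(p, mirror=True),
        ("h2",),
        ("A2", "B2"),
    ),
    ImplantType.CLOVER_HEAD: TemplateDefinition(
        ImplantType.CLOVER_HEAD,
        _names(
            [f"alpha{i}" for i in range(4, 18)],
            ["h3", "h4"],
            ["l5", "l6", "m5", "m6", "l7", "m7", "l8", "m8"],
            ["u4", "t4", "u5", "t5", "u6", "t6", "u7", "t7"],
        ),
        ConstraintSet(),
        _build_clover_head,
        ("h3", "h4"),
        ("LA1", "RB1"),
    ),
    ImplantType.FEMORAL_STEM_REGION: TemplateDefinition(
        ImplantType.FEMORAL_STEM_REGION,
        _names(
            ["beta1", "beta2", "beta3"],
            ["theta1", "theta2", "theta3"],
            ["l1", "l2", "l3"],
            ["m1", "m2", "m3"],
            ["u1", "u2", "u3"],
            ["t1", "t2", "t3"],
        ),
        ConstraintSet(),
        _build_stem_region,
        (),
        ("C1", "D1"),
    ),
}

_ANGLE_PREFIXES = ("alpha", "beta", "theta")


def template_definition(implant_type: ImplantType) -> TemplateDefinition:
    try:
        return _TEMPLATES[implant_type]
    except KeyError:
        raise KeyError(f"unknown implant type {implant_type!r}") from None


def count_free_parameters(implant_type: ImplantType) -> int:
    """Number of semantic shape parameters the template consumes
    (solid parameters n1/d1 excluded)."""
    return len(template_definition(implant_type).parameter_names)


def _range_violations(tdef: TemplateDefinition, values: dict[str, float]) -> list[str]:
    out = []
    for name in tdef.parameter_names:
        if name not in values:
            continue
        v = values[name]
        if not math.isfinite(v):
            out.append(f"{name} must be finite")
        elif name.startswith(_ANGLE_PREFIXES):
            if not 0.0 < v <= 180.0:
                out.append(f"0 < {name} <= 180")
        elif name == "gamma3":
            if not 0.0 <= v < 2.0:
                out.append(f"0 <= {name} < 2")
        elif v <= 0.0:
            out.append(f"{name} > 0")
    return out


def check_constraints(params: ParameterSet) -> list[str]:
    """Return all violated relations (empty list means the set is valid)."""
    tdef = template_definition(params.implant_type)
    out = _range_violations(tdef, params.values)
    out.extend(tdef.constraints.violations(params.values))
    if (
        params.implant_type is ImplantType.T_PLATE
        and "d1" in params.values
        and "t1" in params.values
    ):
        if not _T_SOLID_RELATION.holds(params.values):
            out.append(str(_T_SOLID_RELATION))
    return out


def make_template(
    implant_type: ImplantType, params: ParameterSet, *, check: bool = True
) -> VeinGraph:
    """Build the laid-out, canonically numbered skeleton of one template.

    Raises :class:`KeyError` for a missing parameter and
    :class:`ValidationError` when ``check`` is on and a relation fails.
    """
    if params.implant_type is not implant_type:
        raise ValidationError(
            f"parameter set is for {params.implant_type.value}, not {implant_type.value}"
        )
    tdef = template_definition(implant_type)
    for name in tdef.parameter_names:
        if name not in params.values:
            raise KeyError(f"parameter {name!r} missing for {implant_type.value}")
    if check:
        violations = check_constraints(params)
        if violations:
            raise ValidationError(
                f"{implant_type.value}: {len(violations)} constraint violation(s): "
                + "; ".join(violations),
                violations=violations,
            )
    return tdef.builder(params)


def main_vein_length(params: ParameterSet) -> float:
    """Total main-vein length of a template instance (mm); the size key of
    retrieval.  The stem region's main vein is structural (fixed spacing)."""
    tdef = template_definition(params.implant_type)
    if not tdef.main_vein_names:
        return 4.0 * STEM_LEVEL_SPACING
    return sum(params[name] for name in tdef.main_vein_names)


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

def packaged_table_path(which: int):
    """Path to the packaged parameter table (1 = clover head, 2 = stem)."""
    name = {1: "table1_clover.csv", 2: "table2_stem.csv"}.get(which)
    if name is None:
        raise KeyError(f"no packaged table {which}; choose 1 or 2")
    return resources.files("bionicvein.data") / name


def load_parameter_table(source, implant_type: ImplantType) -> list[ParameterSet]:
    """Read one ParameterSet per CSV row.

    The header must contain every parameter name of the template; extra
    columns (a row number, solid parameters) are carried along for n1/d1
    and otherwise ignored.
    """
    tdef = template_definition(implant_type)
    try:
        df = pd.read_csv(source)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse parameter table: {exc}") from exc
    missing = [n for n in tdef.parameter_names if n not in df.columns]
    if missing:
        raise FormatError(f"parameter table is missing column(s): {', '.join(missing)}")
    keep = list(tdef.parameter_names) + [c for c in SOLID_PARAMETERS if c in df.columns]
    out: list[ParameterSet] = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=1):
        values: dict[str, float] = {}
        for col in keep:
            try:
                values[col] = float(row[col])
            except (TypeError, ValueError):
                raise FormatError(
                    f"row {row_no}, column {col!r}: non-numeric value {row[col]!r}"
                ) from None
            if math.isnan(values[col]):
                raise FormatError(f"row {row_no}, column {col!r}: missing value")
        out.append(ParameterSet(implant_type=implant_type, values=values))
    if not out:
        raise FormatError("parameter table has no data rows")
    return out
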