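"""Feature database of vein-structure records and shape-then-size retrieval.

A :class:`FeatureRecord` stores one template instance: its implant type, the
semantic parameters, and the cached morphological/dimensional adjacency pair.
Retrieval proceeds in three stages, shape first, size second:

1. **Vertex count** — only records whose adjacency matrices have the same
   dimension as the query template survive (the matrix dimension equals the
   number of vein feature points, e.g. 10x10 for the T-plate).
2. **Morphology** — the gamma codes of the two key lateral veins are
   compared.  With ``delta1``/``delta2`` the query-minus-candidate gamma
   differences, a candidate is a shape match when both magnitudes are within
   ``gamma_tol`` (default 0.005, which admits head-angle discrepancies up to
   0.9 degrees — within one degree).  The surviving candidate minimizing
   ``|delta1| + |delta2|`` wins.
3. **Size** — ``delta3`` compares main-vein lengths (relative error by
   default, tolerance 0.1).  Inside tolerance the stored record is returned
   as ``MATCHED``; outside, its main vein is adjusted to the query
   (``SHAPE_MATCH_SIZE_ADJUSTED``).  When no shape candidate survives, a
   fresh record is instantiated from the query parameters and inserted into
   the database (``INSTANTIATED``).
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
import os
import tempfile
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, ValidationError, VersionError
from .templates import (
    ImplantType,
    ParameterSet,
    make_template,
    main_vein_length,
    template_definition,
)
from .vein_core import AdjacencyPair, VeinGraph, build_adjacency

__all__ = [
    "FeatureRecord",
    "FeatureDatabase",
    "RetrievalConfig",
    "RetrievalResult",
    "RetrievalStatus",
    "SizeTolMode",
    "add_record",
    "retrieve",
    "instantiate",
    "save_db",
    "load_db",
]

SCHEMA_VERSION = 1


class SizeTolMode(enum.Enum):
    RELATIVE = "relative"
    ABSOLUTE = "absolute"


class RetrievalStatus(enum.Enum):
    MATCHED = "matched"
    SHAPE_MATCH_SIZE_ADJUSTED = "shape_match_size_adjusted"
    INSTANTIATED = "instantiated"


@dataclass(frozen=True)
class RetrievalConfig:
    """Tolerances of the retrieval stages.

    ``gamma_tol`` is in gamma units (0.005 ~ 0.9 deg on a head angle);
    ``size_tol`` is a relative fraction by default, millimetres in
    ``ABSOLUTE`` mode.
    """

    gamma_tol: float = 0.005
    size_tol: float = 0.1
    size_tol_mode: SizeTolMode = SizeTolMode.RELATIVE

    def __post_init__(self) -> None:
        if self.gamma_tol <= 0 or self.size_tol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass(frozen=True)
class FeatureRecord:
    record_id: str
    implant_type: ImplantType
    params: ParameterSet
    adjacency: AdjacencyPair
    graph: VeinGraph
    created: str = ""


@dataclass(frozen=True)
class RetrievalResult:
    status: RetrievalStatus
    record: FeatureRecord | None
    delta1: float
    delta2: float
    delta3: float


@dataclass
class FeatureDatabase:
    records: list[FeatureRecord] = field(default_factory=list)
    _next_id: int = 1

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def fresh_id(self) -> str:
        rid = f"rec-{self._next_id:04d}"
        self._next_id += 1
        return rid


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def add_record(
    db: FeatureDatabase, implant_type: ImplantType, params: ParameterSet
) -> FeatureRecord:
    """Build, validate and store one template instance."""
    graph = make_template(implant_type, params)  # raises on invalid params
    rec = FeatureRecord(
        record_id=db.fresh_id(),
        implant_type=implant_type,
        params=params,
        adjacency=build_adjacency(graph),
        graph=graph,
        created=_now(),
    )
    db.records.append(rec)
    return rec


def instantiate(
    db: FeatureDatabase, implant_type: ImplantType, params: ParameterSet
) -> FeatureRecord:
    """Generate the required feature from desired parameters and insert it."""
    return add_record(db, implant_type, params)


def _key_gammas(implant_type: ImplantType, graph: VeinGraph) -> tuple[float, float]:
    """Gamma codes of the two key lateral veins (left, right) of a template."""
    left_lab, right_lab = template_definition(implant_type).key_lateral_labels
    out = {}
    for e in graph.edges:
        dst = graph.point(e.dst)
        if dst.label in (left_lab, right_lab):
            out[dst.label] = e.gamma
    return out[left_lab], out[right_lab]


def retrieve(
    db: FeatureDatabase,
    implant_type: ImplantType,
    params: ParameterSet,
    config: RetrievalConfig | None = None,
) -> RetrievalResult:
    """Find the stored feature best matching the desired parameters.

    See the module docstring for the three stages.  ``INSTANTIATED`` and
    ``SHAPE_MATCH_SIZE_ADJUSTED`` results create a new record in ``db``.
    """
    config = config or RetrievalConfig()
    if params.implant_type is not implant_type:
        raise ValidationError(
            f"query parameters are for {params.implant_type.value}, "
            f"not {implant_type.value}"
        )
    query_graph = make_template(implant_type, params)
    query_adj = build_adjacency(query_graph)
    q_n = query_graph.n_points
    q_g1, q_g2 = _key_gammas(implant_type, query_graph)
    q_size = main_vein_length(params)

    # stage 1: vertex count (matrix dimension)
    candidates = [r for r in db.records if r.adjacency.n == q_n]

    # stage 2: morphology within gamma tolerance; the "maximum matching
    # degree" candidate minimizes |d1|+|d2|, ties broken by |d3|, then by
    # whole-matrix proximity (records identical in the key laterals can
    # still differ elsewhere), then by record id for determinism
    best: FeatureRecord | None = None
    best_key: tuple[float, float, float, str] | None = None
    best_d = (0.0, 0.0, 0.0)
    for rec in candidates:
        r_g1, r_g2 = _key_gammas(rec.implant_type, rec.graph)
        d1, d2 = q_g1 - r_g1, q_g2 - r_g2
        if abs(d1) > config.gamma_tol or abs(d2) > config.gamma_tol:
            continue
        d3 = _size_delta(q_size, main_vein_length(rec.params), config)
        matrix_dist = float(
            np.abs(query_adj.m1 - rec.adjacency.m1).sum()
            + np.abs(query_adj.m2 - rec.adjacency.m2).sum()
        )
        key = (abs(d1) + abs(d2), abs(d3), matrix_dist, rec.record_id)
        if best_key is None or key < best_key:
            best, best_key, best_d = rec, key, (d1, d2, d3)

    if best is None:
        rec = instantiate(db, implant_type, params)
        return RetrievalResult(RetrievalStatus.INSTANTIATED, rec, 0.0, 0.0, 0.0)

    d1, d2, d3 = best_d
    # stage 3: size
    if abs(d3) <= config.size_tol:
        return RetrievalResult(RetrievalStatus.MATCHED, best, d1, d2, d3)

    # shape fits, size does not: adjust the main vein to the query and store
    # the adjusted feature as a new record (stored records are never mutated)
    adjusted_params = _with_main_vein(best.params, params)
    rec = add_record(db, implant_type, adjusted_params)
    return RetrievalResult(RetrievalStatus.SHAPE_MATCH_SIZE_ADJUSTED, rec, d1, d2, d3)


def _size_delta(q_size: float, r_size: float, config: RetrievalConfig) -> float:
    if config.size_tol_mode is SizeTolMode.ABSOLUTE:
        return q_size - r_size
    return (q_size - r_size) / q_size


def _with_main_vein(base: ParameterSet, query: ParameterSet) -> ParameterSet:
    names = template_definition(base.implant_type).main_vein_names
    values = dict(base.values)
    for n in names:
        values[n] = query[n]
    return ParameterSet(implant_type=base.implant_type, values=values)


# ---------------------------------------------------------------------------
# persistence (JSON, schema version 1)
# ---------------------------------------------------------------------------

def _record_to_json(rec: FeatureRecord) -> dict:
    from .vein_core import graph_to_json

    return {
        "record_id": rec.record_id,
        "implant_type": rec.implant_type.value,
        "params": rec.params.values,
        "graph": graph_to_json(rec.graph),
        "created": rec.created,
    }


def _record_from_json(obj: dict) -> FeatureRecord:
    from .vein_core import graph_from_json

    try:
        implant_type = ImplantType(obj["implant_type"])
        params = ParameterSet(implant_type=implant_type, values=obj["params"])
        graph = graph_from_json(obj["graph"])
        rec = FeatureRecord(
            record_id=str(obj["record_id"]),
            implant_type=implant_type,
            params=params,
            adjacency=build_adjacency(graph),
            graph=graph,
            created=obj.get("created", ""),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise FormatError(f"malformed feature record: {exc}") from exc
    return rec


def save_db(db: FeatureDatabase, path) -> None:
    """Write the database atomically (temp file + rename)."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "records": [_record_to_json(r) for r in db.records],
    }
    path = os.fspath(path)
    fd, tmp = tempfile.mkstemp(dir=os.path.dirname(path) or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_db(path) -> FeatureDatabase:
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if isinstance(payload, list):  # bare record array: accept as version 1
        records_json = payload
    else:
        version = payload.get("schema_version")
        if version != SCHEMA_VERSION:
            raise VersionError(
                f"{path}: schema version {version!r} unsupported (expected {SCHEMA_VERSION})"
            )
        records_json = payload.get("records", [])
    records = [_record_from_json(o) for o in records_json]
    max_id = 0
    for r in records:
        if r.record_id.startswith("rec-"):
            try:
                max_id = max(max_id, int(r.record_id[4:]))
            except ValueError:
                pass
    return FeatureDatabase(records=records, _next_id=max_id + 1)
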