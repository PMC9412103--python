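"""Fit-degree assessment between implant and bone surface point sets.

Two pre-aligned 3D point sets (mm) are compared with:

* the symmetric **Hausdorff distance** ``max(h(A,B), h(B,A))`` where
  ``h(A,B) = max_a min_b |a-b|`` — the fit degree is *valid* when it is
  below 0.3 mm;
* the **average distance** from each plate point to its nearest bone point,
  summarized by a **fitting index** ``1 / (1 + avg/2)``, a monotone map of
  the average distance onto (0, 1] calibrated so that a 2 mm average
  corresponds to an index of exactly 0.5 — the index verdict is *valid*
  (excellent fit) when it exceeds 0.5.

The index formula is a documented stand-in satisfying that calibration; a
different monotone map can be passed via ``index_fn``.  Nearest neighbours
use an exact KD-tree; no correspondence between the sets is assumed.  For
protocols with known point pairings use :func:`assess_fit_corresponded`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .errors import DomainError, FormatError, UsageError

__all__ = [
    "FitReport",
    "as_point_set",
    "directed_hausdorff",
    "assess_fit",
    "assess_fit_corresponded",
    "default_fitting_index",
    "HAUSDORFF_VALID_MM",
    "INDEX_VALID_MIN",
    "read_xyz",
    "write_xyz",
    "read_point_set",
]

#: Fit degree is valid when the symmetric Hausdorff distance is below this.
HAUSDORFF_VALID_MM = 0.3
#: The fitting property is excellent when the index exceeds this.
INDEX_VALID_MIN = 0.5


def as_point_set(points) -> np.ndarray:
    """Validate and coerce to an (n, 3) float array."""
    a = np.asarray(points, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise DomainError(f"point set must be (n, 3), got shape {a.shape}")
    if a.shape[0] == 0:
        raise DomainError("point set is empty")
    if not np.isfinite(a).all():
        raise DomainError("point set contains non-finite coordinates")
    return a


def _nearest_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d, _ = cKDTree(b).query(a, k=1)
    return np.asarray(d, dtype=float)


def directed_hausdorff(a, b) -> float:
    """``max over a of min over b`` of the Euclidean distance (mm)."""
    a = as_point_set(a)
    b = as_point_set(b)
    return float(_nearest_distances(a, b).max())


def default_fitting_index(average_mm: float) -> float:
    return 1.0 / (1.0 + average_mm / 2.0)


@dataclass(frozen=True)
class FitReport:
    hausdorff: float
    directed_ab: float
    directed_ba: float
    average: float
    fitting_index: float

    @property
    def hausdorff_valid(self) -> bool:
        return self.hausdorff < HAUSDORFF_VALID_MM

    @property
    def index_valid(self) -> bool:
        return self.fitting_index > INDEX_VALID_MIN

    def to_json(self) -> dict:
        return {
            "hausdorff_mm": self.hausdorff,
            "directed_ab_mm": self.directed_ab,
            "directed_ba_mm": self.directed_ba,
            "average_mm": self.average,
            "fitting_index": self.fitting_index,
            "hausdorff_valid": self.hausdorff_valid,
            "index_valid": self.index_valid,
        }


def assess_fit(
    plate, bone, index_fn: Callable[[float], float] = default_fitting_index
) -> FitReport:
    """Full fit report between plate and bone point sets (both non-empty)."""
    plate = as_point_set(plate)
    bone = as_point_set(bone)
    d_pb = _nearest_distances(plate, bone)
    d_bp = _nearest_distances(bone, plate)
    ab, ba = float(d_pb.max()), float(d_bp.max())
    avg = float(d_pb.mean())
    return FitReport(
        hausdorff=max(ab, ba),
        directed_ab=ab,
        directed_ba=ba,
        average=avg,
        fitting_index=float(index_fn(avg)),
    )


def assess_fit_corresponded(
    plate, bone, index_fn: Callable[[float], float] = default_fitting_index
) -> FitReport:
    """Fit report for paired point lists (i-th plate point vs i-th bone point)."""
    plate = as_point_set(plate)
    bone = as_point_set(bone)
    if plate.shape != bone.shape:
        raise UsageError(
            f"corresponded sets must have equal shapes, got {plate.shape} vs {bone.shape}"
        )
    d = np.linalg.norm(plate - bone, axis=1)
    h = float(d.max())
    avg = float(d.mean())
    return FitReport(
        hausdorff=h, directed_ab=h, directed_ba=h, average=avg,
        fitting_index=float(index_fn(avg)),
    )


# ---------------------------------------------------------------------------
# point-set I/O
# ---------------------------------------------------------------------------

def write_xyz(points, path) -> None:
    """One 'x y z' line per point, millimetres."""
    a = as_point_set(points)
    with open(path, "w", encoding="utf-8") as fh:
        for x, y, z in a:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


def read_xyz(path) -> np.ndarray:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                rows.append([float(v) for v in parts])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from None
    if not rows:
        raise FormatError(f"{path}: no points")
    return as_point_set(rows)


def read_point_set(path) -> np.ndarray:
    """Read points from .xyz text, or the vertices of a PLY/STL/OBJ file."""
    import os

    ext = os.path.splitext(os.fspath(path))[1].lower()
    if ext in ("", ".xyz", ".txt"):
        return read_xyz(path)
    if ext in (".ply", ".stl", ".obj"):
        import trimesh

        obj = trimesh.load(path)
        verts = np.asarray(obj.vertices)
        return as_point_set(verts)
    raise FormatError(f"unsupported point-set format {ext!r}")
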