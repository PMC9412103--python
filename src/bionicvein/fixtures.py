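"""Seeded synthetic generators: random vein trees, bone patches, offsets.

No real bone geometry ships with the package; a cylindrical patch stands in
for a long-bone diaphysis (which is approximately cylindrical) so that the
fit metrics can be exercised with analytically known answers.  All
generators are pure functions of their arguments — the same spec and seed
reproduce byte-identical output on any platform.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, UsageError
from .vein_core import (
    VeinEdge,
    VeinGraph,
    VeinGrade,
    VeinPoint,
    canonical_numbering,
    layout_graph,
)

__all__ = [
    "BonePatchSpec",
    "BonePatch",
    "OffsetMode",
    "random_vein_tree",
    "synthetic_bone_patch",
    "offset_copy",
]


class OffsetMode(enum.Enum):
    NORMAL = "normal"
    TRANSLATE_Z = "translate_z"


@dataclass(frozen=True)
class BonePatchSpec:
    """Synthetic bone patch: a noisy cylindrical section.

    ``radius`` is the cylinder radius (mm, default 20 — a typical adult
    diaphysis scale), ``extent`` the (arc width, axial length) of the patch
    in mm, ``noise_sd`` the standard deviation of Gaussian noise applied
    along the surface normal.
    """

    radius: float = 20.0
    extent: tuple[float, float] = (60.0, 30.0)
    n_points: int = 2000
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.extent[0] <= 0 or self.extent[1] <= 0:
            raise DomainError("radius and extents must be > 0")
        if self.n_points <= 0:
            raise DomainError("n_points must be > 0")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.extent[0] > 2 * math.pi * self.radius:
            raise DomainError("arc extent exceeds the cylinder circumference")


@dataclass(frozen=True)
class BonePatch:
    """Point set sampled from a cylinder patch, with its analytic normals."""

    points: np.ndarray  # (n, 3)
    normals: np.ndarray  # (n, 3) outward unit normals of the noiseless surface
    spec: BonePatchSpec


def random_vein_tree(n_points: int, seed: int) -> VeinGraph:
    """A random valid skeleton: root MAIN, depth-1 LATERAL, deeper MINOR.

    Edge directions are uniform on [0, 2), lengths uniform on [5, 50] mm.
    The result is laid out and canonically numbered.
    """
    if n_points < 2:
        raise DomainError(f"need at least 2 points, got {n_points}")
    rng = np.random.default_rng(seed)
    grades = {0: VeinGrade.MAIN}
    depth = {0: 0}
    points = [VeinPoint(id=0, grade=VeinGrade.MAIN, label="O1")]
    edges: list[VeinEdge] = []
    for i in range(1, n_points):
        parent = 0 if i == 1 else int(rng.integers(0, i))
        d = depth[parent] + 1
        if i == 1:
            grade = VeinGrade.MAIN  # the main vein itself
        elif d == 1:
            grade = VeinGrade.LATERAL
        else:
            grade = VeinGrade.MINOR
        # a MINOR parent cannot sprout a LATERAL child; depth rule prevents it
        grades[i] = grade
        depth[i] = d
        points.append(VeinPoint(id=i, grade=grade, label=f"P{i}"))
        gamma = float(rng.uniform(0.0, 2.0))
        length = float(rng.uniform(5.0, 50.0))
        edges.append(VeinEdge(src=parent, dst=i, gamma=gamma, length=length))
    g = VeinGraph(points=points, edges=edges)
    return canonical_numbering(layout_graph(g))


def synthetic_bone_patch(spec: BonePatchSpec) -> BonePatch:
    """Sample ``n_points`` on a cylinder section plus normal Gaussian noise.

    The cylinder axis is y; the patch is centred on the top line of the
    cylinder and shifted so the noiseless crest passes through z = 0.
    Surface: ``(r sin(phi), y, r (cos(phi) - 1))`` for
    ``phi in [-w/2r, w/2r]``, ``y in [0, l]``.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.radius
    phi_max = spec.extent[0] / (2.0 * r)
    phi = rng.uniform(-phi_max, phi_max, spec.n_points)
    y = rng.uniform(0.0, spec.extent[1], spec.n_points)
    normals = np.column_stack([np.sin(phi), np.zeros_like(phi), np.cos(phi)])
    base = np.column_stack([r * np.sin(phi), y, r * (np.cos(phi) - 1.0)])
    if spec.noise_sd > 0:
        base = base + normals * rng.normal(0.0, spec.noise_sd, spec.n_points)[:, None]
    return BonePatch(points=base, normals=normals, spec=spec)


def offset_copy(points, d: float, mode: OffsetMode = OffsetMode.TRANSLATE_Z):
    """Copy of a point set moved by ``d`` mm.

    ``TRANSLATE_Z`` shifts every point along +z and accepts any (n, 3)
    array or :class:`BonePatch`.  ``NORMAL`` moves each point along the
    analytic surface normal and therefore requires a :class:`BonePatch`.
    Returns the same kind of object it was given.
    """
    if d < 0:
        raise DomainError(f"offset distance must be >= 0, got {d}")
    if mode is OffsetMode.NORMAL:
        if not isinstance(points, BonePatch):
            raise UsageError("NORMAL offset requires a BonePatch (analytic normals)")
        return BonePatch(
            points=points.points + d * points.normals,
            normals=points.normals,
            spec=points.spec,
        )
    if isinstance(points, BonePatch):
        shifted = points.points.copy()
        shifted[:, 2] += d
        return BonePatch(points=shifted, normals=points.normals, spec=points.spec)
    a = np.array(points, dtype=float)
    a[:, 2] += d
    return a
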