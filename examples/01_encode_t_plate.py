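"""Encode a T-shaped plate skeleton as its adjacency-matrix pair.

Builds the T-plate template from semantic parameters (vein lengths in mm,
head angles in degrees), prints the canonical point numbering and the
morphological (gamma direction codes) and dimensional (mm) matrices.
"""

import numpy as np

from bionicvein import ImplantType, ParameterSet, build_adjacency, make_template

params = ParameterSet(
    ImplantType.T_PLATE,
    dict(
        h1=40.0,                       # main-vein length
        l1=8.0, m1=8.0,                # tail lateral lengths (left, right)
        l2=12.0, m2=12.0,              # head lateral lengths
        u1=4.0, t1=4.0, u2=4.0, t2=4.0,  # minor-vein lengths (head width)
        alpha1=120.0, alpha2=120.0,    # head angles, main vein vs laterals
    ),
)

graph = make_template(ImplantType.T_PLATE, params)
pair = build_adjacency(graph)

print("points (canonical order, bottom to top):")
for p in graph.points:
    print(f"  {p.id}: {p.label:3s} {p.grade.name:7s} at ({p.position[0]:7.2f}, {p.position[1]:7.2f})")
print(f"\nmorphological matrix M1 ({pair.n}x{pair.n}, gamma codes):")
print(np.array_str(pair.m1, precision=3, suppress_small=True))
print(f"\ndimensional matrix M2 (mm):")
print(np.array_str(pair.m2, precision=1, suppress_small=True))
print(f"\n{graph.n_points} vein feature points, {graph.n_edges} veins;"
      f" a nonzero M1[i, j] is the direction code of the vein i -> j"
      f" (0 = rightward, +0.5 per quarter turn CCW), M2[i, j] its length.")
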