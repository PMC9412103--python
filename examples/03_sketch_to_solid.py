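"""Sketch, fill, stretch and hole-punch a clover plate into an STL solid.

Builds clover structure No. 7 from the packaged table, derives the
boundary sketch from the skeleton's leaf endpoints, triangulates it,
extrudes to 3 mm and punches 2 mm screw holes along the main vein.
Writes structure7.svg and structure7.stl next to the script.
"""

import math
from pathlib import Path

from bionicvein import ImplantType
from bionicvein.geometry import (
    export_model,
    extrude_solid,
    fill_surface,
    place_holes_along_main,
    punch_holes,
    sketch_from_graph,
)
from bionicvein.templates import load_parameter_table, make_template, packaged_table_path

out_dir = Path(__file__).parent
rows = load_parameter_table(packaged_table_path(1), ImplantType.CLOVER_HEAD)
graph = make_template(ImplantType.CLOVER_HEAD, rows[6])  # structure No. 7

sketch = sketch_from_graph(graph, end_cap=3.0)
surface = fill_surface(sketch)
solid = extrude_solid(surface, thickness=3.0)
holes = place_holes_along_main(graph, diameter=2.0)
plate = punch_holes(solid, holes)

export_model(sketch, out_dir / "structure7.svg", "SVG")
export_model(plate, out_dir / "structure7.stl", "STL")

removed = len(holes) * math.pi * 1.0**2 * 3.0
print(f"sketch: {len(sketch.boundary)} boundary points, area {surface.area:.1f} mm^2")
print(f"solid:  volume {solid.volume:.1f} mm^3 (= area x 3 mm thickness)")
print(f"holes:  {len(holes)} x d=2 mm -> removed {removed:.1f} mm^3, "
      f"final volume {plate.volume:.1f} mm^3, watertight={plate.mesh.is_watertight}")
print(f"wrote {out_dir / 'structure7.svg'} and {out_dir / 'structure7.stl'}")
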