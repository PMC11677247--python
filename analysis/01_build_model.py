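"""Build the scaled mandibular-segment benchmark and summarize its structure.

Writes a VTK point cloud of the region/material layout to results/ so the
geometry (layers, implant, peri-implant shell, applicator plate) can be
inspected in any VTK viewer.
"""

from pathlib import Path

import numpy as np

from osseowave.geometry import ModelSpec, Region, build_model
from osseowave.pipeline import write_fields

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

spec = ModelSpec()
model = build_model(spec)
print(f"benchmark block {spec.Lx*1e3:g} x {spec.Ly*1e3:g} x {spec.Lz*1e3:g} mm, "
      f"d = {spec.d*1e6:.0f} um -> {model.n_elements} elements, {len(model.pairs)} pairs")
for code, count in zip(*np.unique(model.regions, return_counts=True)):
    print(f"  {Region(int(code)).label:18s} {count:6d}")
path = write_fields(model, {}, OUT / "benchmark_model.vtk")
print(f"wrote {path}")
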