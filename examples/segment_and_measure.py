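"""Detect cells on phase contrast and measure their geometry.

Each dark capsule is traced pole-to-pole with a perpendicular slit walk;
the local diameter profile then gives volume (disk integration) and
envelope area (surface of revolution).
"""

import numpy as np

import rodquant as rq
from rodquant.synthgen import OpticsSpec, PatternSpec

SCALE = 14.98  # px per um

pop = rq.sample_population(40, seed=3)
scene = rq.render_scene(
    pop, [PatternSpec("cytoplasmic_uniform", 1000)], OpticsSpec(), seed=4
)
cells = rq.detect_cells(scene.hyperstack[0], SCALE)
accepted = [c for c in cells if c.accepted]
print(f"detected {len(cells)} objects, accepted {len(accepted)}")

c = accepted[0]
vol = rq.cell_volume(c.diameters, c.step_um)
wall = rq.envelope_area(c.diameters, c.step_um)
print(f"first cell: length {c.axis_length_um:.2f} um, "
      f"mean diameter {c.mean_diameter_um:.2f} um")
print(f"  volume {vol:.2f} um^3, envelope area {wall:.2f} um^2")
# For a ~1 um wide rod, volume is close to pi/4 * L and the envelope area
# close to pi * L: both follow from rotational symmetry about the axis.

constr = rq.detect_constriction(c.diameters)
if constr:
    print(f"  central minimum diameter {constr[0]:.2f} um at relative "
          f"position {constr[1]:.2f} (constriction if well below the mean)")

true_len = np.sort(scene.truth["length_um"]) * SCALE
meas_len = np.sort([c.axis_length_px for c in accepted])
print(f"max length error vs truth: {np.abs(meas_len - true_len).max():.2f} px")
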