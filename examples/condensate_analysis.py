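"""Polycomb-condensate quantification: aggregation index and shell profile.

Generates a nucleus with bright condensate spots holding 25% of the total
nuclear intensity, placed peripherally, then measures (i) the relative
aggregation with the ground-truth masks, (ii) the condensate count from
the built-in detector, and (iii) the erosion-shell profile that localizes
signal relative to the nuclear periphery (0.4 µm dilation, 20 bands of
0.15 µm).
"""

import numpy as np

from nucleomech import synthetic
from nucleomech.condensates import (count_condensates, detect_condensates,
                                    relative_aggregation, shell_profile)

ds = synthetic.gen_condensate_image(aggregate_fraction=0.25,
                                    radial_bias="peripheral",
                                    n_spots=4, seed=21)
scene = ds.payload

agg = relative_aggregation(scene)
det = detect_condensates(scene, min_contrast=1.0)
n_det, areas = count_condensates(det)
prof = shell_profile(scene, dilation=0.4, n_shells=20, shell_thickness=0.15)

print(f"true aggregate fraction      : {ds.truth.params['aggregate_fraction']}")
print(f"relative aggregation (truth masks): {agg.relative_aggregation:.3f}")
print(f"condensates detected         : {n_det} "
      f"(areas {np.round(areas, 3)} um^2)")
print()
print("shell profile (index 1 = outermost band, ratio = band mean over")
print("whole-nucleus mean):")
print(prof.shells.round(3).to_string(index=False))
print()
print("Peripherally biased condensates push the ratios of the first")
print("interior bands above 1 while central bands fall below the diffuse")
print("level - the readout used to show condensates enriching at the")
print("nuclear periphery.")
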