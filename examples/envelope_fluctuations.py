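"""Measure nuclear-envelope fluctuation amplitude on a synthetic movie.

Generates a 200-frame movie of a single nucleus whose boundary fluctuates
with a known radial amplitude (0.2 µm), runs the full pipeline (rigid
registration, edge sampling along 16 boundary normals, temporal SD per
anchor) and compares the recovered amplitude with the truth.
"""

import numpy as np

from nucleomech import synthetic
from nucleomech.fluctuations import analyze_movie

ds = synthetic.gen_boundary_movie(n_frames=200, pixel_size=0.05,
                                  mean_radius=5.0, radial_sigma=0.2, seed=11)
res = analyze_movie(ds.payload, n_anchors=16, line_half_length=1.0)

truth = ds.truth.params["radial_sigma"]
print(f"true radial fluctuation amplitude : {truth:.3f} um")
print(f"recovered nucleus mean SD         : {res.nucleus_mean_sd:.3f} um")
print(f"anchors used                      : {res.n_anchors_used}/16")
print(f"per-anchor SD range               : "
      f"{np.nanmin(res.per_anchor_sd):.3f}-{np.nanmax(res.per_anchor_sd):.3f} um")
print()
print("The nucleus mean SD is the envelope fluctuation amplitude: the")
print("temporal standard deviation of the boundary position along its")
print("local normal, averaged over the sampling anchors. Stiffer or more")
print("osmotically compressed nuclei fluctuate less.")
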