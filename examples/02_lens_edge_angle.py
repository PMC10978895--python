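"""Continuous edge-angle recovery on a biconvex lens.

A lens made of two spherical caps sharing a rim circle has the same edge
angle everywhere: arcsin(a/R_up) + arcsin(a/R_down). The profile should
be flat at that value all the way around the perimeter.
"""

import numpy as np

from lithedge import analyze_mesh, RunConfig
from lithedge.shapes import lens_radius_for_cr, make_lens

R = lens_radius_for_cr(0.5, 0.4)  # c/R = 0.5 -> edge angle 120 deg
mesh, oracle = make_lens(R, R, a=0.4, n=50_000)
analysis = analyze_mesh(mesh, RunConfig(), "lens", rotation=np.eye(3))
angles = analysis.profile.angle

print(f"closed-form edge angle : {oracle.edge_angle_deg:.2f} deg")
print(f"profile mean           : {angles.mean():.2f} deg")
print(f"largest deviation      : {np.abs(angles - oracle.edge_angle_deg).max():.2f} deg")
print(f"segments found         : {analysis.report.n_segments}")
# A constant-angle solid must come back as a single segment; the small
# negative bias (~1-1.5 deg) is the known resolution effect of measuring
# chord directions on a curved surface at 50k vertices.
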