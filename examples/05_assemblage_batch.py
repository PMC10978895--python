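"""Batch analysis of a small synthetic assemblage.

Writes a directory of mixed shapes, analyzes them all in one call, and
prints the assemblage summary: segment counts, percent-sharp statistics,
and the pooled angle distribution (with its trough-derived threshold when
enough segments are pooled).
"""

import tempfile
from pathlib import Path

from lithedge import RunConfig, run_batch
from lithedge.shapes import lens_radius_for_cr, make_blunt_lens, make_lens

workdir = Path(tempfile.mkdtemp(prefix="lithedge_assemblage_"))
R = lens_radius_for_cr(0.7, 0.4)
for i in range(2):
    mesh, _ = make_lens(R, R, 0.4, n=20_000, seed=i)
    mesh.as_trimesh().export(str(workdir / f"sharp_{i}.obj"))
mesh, _ = make_blunt_lens(R, R, 0.4, f=0.25, n=20_000)
mesh.as_trimesh().export(str(workdir / "banded.obj"))

result = run_batch(workdir, RunConfig(target_vertices=20_000), workdir / "out")
print(f"status: {result.status}; artifacts analyzed: {len(result.analyses)}")
summary = result.summary
print(f"segments per artifact (mean): {summary['segments_per_artifact_mean']:.2f}")
print(f"segment-count proportions   : {summary['segment_count_proportions']}")
print(f"percent sharp, mean +/- CI  : {summary['percent_sharp_mean']:.1f}"
      f" +/- {summary['percent_sharp_ci95']:.1f}")
print(f"artifacts with blunt stretch: {summary['pct_artifacts_with_blunt_perimeter']:.0f}%")
print(f"tables written to           : {workdir / 'out'}")
# segments.csv holds one row per discrete edge (length, angle, sharpness,
# asymmetry, concavity); artifacts.csv one row per artifact — the input
# for any downstream assemblage statistics.
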