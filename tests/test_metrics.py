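"""Per-segment measurements: threshold, sharpness, asymmetry, concavity,
refinement, report assembly."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from lithedge._kde import kde_on_grid, silverman_bandwidth
from lithedge.config import RunConfig
from lithedge.mesh_core import OrientedMesh, TriMesh, orient_artifact
from lithedge.metrics import (
    classify_segments,
    concavity_label,
    percent_sharp,
    refinement,
    segment_arc_lengths,
    sharp_threshold,
    vertex_concavity,
)
from lithedge.outline import GeometryError
from lithedge.pipeline import analyze_mesh
from lithedge.segmentation import segment_profile
from lithedge.shapes import make_lens, lens_radius_for_cr, make_piecewise_signal

IDENTITY = np.eye(3)


# --------------------------------------------------------------------------
# sharp/blunt threshold from the pooled distribution


def test_bimodal_trough_matches_kde_oracle():
    """Seeded sharp/blunt mixture: the trough equals a brute-force grid
    argmin of the same KDE, and lands between the modes."""
    rng = np.random.default_rng(100)
    pooled = np.concatenate(
        [rng.normal(80, 10, 500), rng.normal(150, 10, 500)]
    )
    result = sharp_threshold(pooled)
    assert not result.unimodal
    assert 105 <= result.trough_deg <= 125
    assert result.rounded_deg == np.floor(result.trough_deg / 10) * 10
    # independent oracle: evaluate the same estimator directly
    grid = np.arange(0.0, 180.05, 0.1)
    dens = kde_on_grid(pooled, grid, silverman_bandwidth(pooled, 2.0))
    lo = np.searchsorted(grid, min(result.mode_degs))
    hi = np.searchsorted(grid, max(result.mode_degs))
    oracle = grid[lo + np.argmin(dens[lo : hi + 1])]
    assert result.trough_deg == pytest.approx(oracle, abs=0.05)


def test_unimodal_falls_back_to_default():
    rng = np.random.default_rng(4)
    result = sharp_threshold(rng.normal(90, 10, 400))
    assert result.unimodal
    assert result.rounded_deg == 120.0


def test_small_sample_raises():
    with pytest.raises(ValueError, match="120"):
        sharp_threshold(np.full(10, 90.0))


# --------------------------------------------------------------------------
# classification and percent sharp


def _fake_segmentation(means, lengths):
    signal = np.concatenate(
        [np.full(l, m, dtype=float) for m, l in zip(means, lengths)]
    )
    return segment_profile(signal, min_seg=25)


def test_classification_rule_and_tie():
    seg = _fake_segmentation([65, 100, 160], [100, 100, 100])
    assert classify_segments(seg, 120.0).tolist() == [True, True, False]

    class Exact:
        segment_means = [120.0]

    assert classify_segments(Exact(), 120.0).tolist() == [False]  # tie = blunt


def test_percent_sharp_partition_and_monotonicity(blunt_lens_analysis):
    analysis = blunt_lens_analysis["analysis"]
    outline, seg = analysis.outline, analysis.segmentation
    lengths = segment_arc_lengths(outline, seg)
    assert lengths.sum() == pytest.approx(outline.perimeter(), abs=1e-6)
    previous = -1.0
    for threshold in (60, 100, 140, 181):
        value = percent_sharp(
            outline, seg, classify_segments(seg, threshold)
        )
        assert value >= previous
        previous = value
    assert percent_sharp(outline, seg, classify_segments(seg, 181)) == 100.0


# --------------------------------------------------------------------------
# transverse asymmetry (pipeline-level checks live in test_acceptance)


def test_symmetric_lens_asymmetry_near_one(small_lens):
    mesh, _ = small_lens
    analysis = analyze_mesh(
        mesh, RunConfig(target_vertices=8000), "lens", rotation=IDENTITY
    )
    assert np.nanmean(analysis.asymmetry_profile) > 0.95


def test_asymmetry_mirror_consistency(small_lens):
    """min/max ratio is unchanged by flipping the mesh through z = 0."""
    mesh, _ = small_lens
    flipped = mesh.copy()
    flipped.vertices = flipped.vertices * np.array([1.0, 1.0, -1.0])
    flipped.faces = flipped.faces[:, ::-1]
    a1 = analyze_mesh(
        mesh, RunConfig(target_vertices=8000), "a", rotation=IDENTITY
    ).asymmetry_profile
    a2 = analyze_mesh(
        flipped, RunConfig(target_vertices=8000), "b", rotation=IDENTITY
    ).asymmetry_profile
    assert abs(np.nanmean(a1) - np.nanmean(a2)) < 0.02


# --------------------------------------------------------------------------
# concavity


def _patch_mesh(z_fn):
    g = np.linspace(-1, 1, 90)
    X, Y = np.meshgrid(g, g)
    # jitter in-plane so neighbor distances have no exact ties
    rng = np.random.default_rng(77)
    X = X + rng.uniform(-2e-3, 2e-3, X.shape)
    Y = Y + rng.uniform(-2e-3, 2e-3, Y.shape)
    V = np.column_stack([X.ravel(), Y.ravel(), z_fn(X, Y).ravel()])
    from scipy.spatial import Delaunay

    tri = Delaunay(V[:, :2])
    mesh = TriMesh(V, np.asarray(tri.simplices, np.int64))
    interior = (np.abs(V[:, 0]) < 0.8) & (np.abs(V[:, 1]) < 0.8)
    return OrientedMesh(mesh, rotation=IDENTITY), interior


def test_concavity_plane_is_half():
    patch, interior = _patch_mesh(lambda X, Y: np.zeros_like(X))
    values = vertex_concavity(patch)
    assert np.abs(values[interior] - 0.5).max() < 0.05


def test_concavity_bowl_is_low():
    patch, interior = _patch_mesh(lambda X, Y: X**2 + Y**2)
    values = vertex_concavity(patch)
    assert values[interior].max() <= 0.1


def test_concavity_sphere_is_high():
    sphere = trimesh.creation.icosphere(subdivisions=5)
    mesh = OrientedMesh(
        TriMesh(np.asarray(sphere.vertices, float), np.asarray(sphere.faces, np.int64)),
        rotation=IDENTITY,
    )
    values = vertex_concavity(mesh)
    assert values.min() >= 0.95


def test_concavity_scale_invariance():
    patch, interior = _patch_mesh(lambda X, Y: 0.3 * (X**2 - Y**2))
    big = OrientedMesh(
        TriMesh(patch.mesh.vertices * 10.0, patch.mesh.faces.copy()),
        rotation=IDENTITY,
    )
    v1 = vertex_concavity(patch)
    v2 = vertex_concavity(big)
    assert np.abs(v1[interior] - v2[interior]).max() <= 0.01


def test_concavity_labels():
    assert concavity_label((0.2, 0.9)) == "concave-convex"
    assert concavity_label((0.5, 0.5)) == "planar-planar"
    assert concavity_label((0.41, 0.39)) == "concave-planar"
    assert concavity_label((0.9, 0.2)) == "concave-convex"  # order-free


def test_plano_convex_distinguishes_faces():
    """Near-flat top over a convex cap: the profile reads the upper face
    planar (~0.5), the lower convex (~1), and the edge maximally
    asymmetric (ratio matching the cone/cap closed form)."""
    from lithedge.shapes import make_plano_convex

    mesh, oracle = make_plano_convex(
        lens_radius_for_cr(0.5, 0.4), 0.4, n=50_000
    )
    analysis = analyze_mesh(mesh, RunConfig(), "pc", rotation=IDENTITY)
    upper = np.nanmean(analysis.concavity_profile[:, 0])
    lower = np.nanmean(analysis.concavity_profile[:, 1])
    assert abs(upper - 0.5) < 0.15
    assert lower > 0.9
    assert abs(np.nanmean(analysis.asymmetry_profile) - oracle.asymmetry) < 0.05
    assert analysis.report.segments[0].concavity_label == "planar-convex"


def test_bowl_top_concavity_aggregation():
    """Dished-top solid: bowl vertices read concave per-vertex, and the
    per-face KDE-mode profile over a band excluding the connecting wall
    separates the faces cleanly (upper ~ 0, lower ~ 1).

    The full-band profile is not asserted here: whatever surface
    physically borders the edge (here the short wall) dominates the
    nearest-neighbor aggregation there.
    """
    from lithedge.metrics import face_concavity_profile
    from lithedge.shapes import make_bowl_top

    mesh, _ = make_bowl_top(lens_radius_for_cr(0.7, 0.4), a=0.4, n=50_000)
    analysis = analyze_mesh(
        mesh, RunConfig(), "bt", rotation=IDENTITY
    )
    V = analysis.mesh.vertices
    r = np.hypot(V[:, 0], V[:, 1])
    concavity = vertex_concavity(analysis.mesh)
    bowl = (V[:, 2] > 0.02) & (r < 0.45)
    assert concavity[bowl].mean() <= 0.2

    off_wall = analysis.band_mask & ~(analysis.faces.upper & (r > 0.46))
    profile = face_concavity_profile(
        analysis.mesh,
        analysis.outline,
        analysis.faces,
        off_wall,
        concavity,
    )
    assert np.nanmean(profile[:, 0]) <= 0.1
    assert np.nanmean(profile[:, 1]) >= 0.9


# --------------------------------------------------------------------------
# refinement and report


def test_refinement_ellipsoid():
    sphere = trimesh.creation.icosphere(subdivisions=3)
    vertices = sphere.vertices * np.array([0.3, 0.5, 0.15])
    mesh = OrientedMesh(
        TriMesh(vertices, np.asarray(sphere.faces, np.int64)), rotation=IDENTITY
    )
    assert refinement(mesh) == pytest.approx(2.0, abs=1e-9)


def test_refinement_scale_invariant(small_lens):
    from lithedge.mesh_core import rescale_mesh

    mesh, _ = small_lens
    oriented = orient_artifact(mesh, rotation=IDENTITY)
    assert refinement(oriented) == pytest.approx(
        refinement(rescale_mesh(oriented)), abs=1e-9
    )


def test_report_constant_lens(small_lens):
    mesh, oracle = small_lens
    analysis = analyze_mesh(
        mesh, RunConfig(target_vertices=8000), "lens", rotation=IDENTITY
    )
    report = analysis.report
    assert report.n_segments == 1
    assert report.n_sharp_edges == 1
    assert report.percent_sharp_perimeter == 100.0
    assert abs(report.segments[0].mean_angle - oracle.edge_angle_deg) < 3.0
    assert report.segments[0].concavity_label == "convex-convex"
    frame = report.segment_frame()
    assert list(frame["segment_index"]) == [0]
    assert report.summary_row()["n_segments"] == 1


def test_report_missing_stage_raises(small_lens):
    from lithedge.metrics import build_report

    mesh, _ = small_lens
    analysis = analyze_mesh(
        mesh, RunConfig(target_vertices=8000), "lens", rotation=IDENTITY
    )
    with pytest.raises(ValueError, match="segmentation"):
        build_report(
            "x",
            analysis.mesh,
            analysis.outline,
            analysis.profile,
            None,
            analysis.asymmetry_profile,
            analysis.concavity_profile,
        )
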