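"""Mesh I/O, cleanup, orientation, resolution and scale normalization."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from lithedge.mesh_core import (
    MeshContentError,
    MeshFormatError,
    TriMesh,
    orient_artifact,
    read_mesh,
    resample_mesh,
    rescale_mesh,
)
from lithedge.shapes import make_lens, lens_radius_for_cr
from lithedge.vrml import VrmlParseError, read_vrml

TETRA_OBJ = """\
v 0 0 0
v 1 0 0
v 0 1 0
v 0 0 1
f 1 2 3
f 1 2 4
f 1 3 4
f 2 3 4
"""


def test_read_obj_tetrahedron(tmp_path):
    path = tmp_path / "tetra.obj"
    path.write_text(TETRA_OBJ)
    mesh = read_mesh(path)
    assert mesh.n_vertices == 4
    assert len(mesh.faces) == 4


def test_read_ply_cube(tmp_path):
    box = trimesh.creation.box()
    path = tmp_path / "cube.ply"
    box.export(str(path))
    mesh = read_mesh(path)
    assert mesh.n_vertices == 8
    assert len(mesh.faces) == 12


def test_read_stl_roundtrip(tmp_path):
    box = trimesh.creation.box()
    path = tmp_path / "cube.stl"
    box.export(str(path))
    mesh = read_mesh(path)
    # STL stores triangle soup; cleanup must merge shared vertices back
    assert mesh.n_vertices == 8
    assert len(mesh.faces) == 12


def test_degenerate_face_dropped(tmp_path):
    path = tmp_path / "degen.obj"
    path.write_text(TETRA_OBJ + "f 1 1 2\n")
    mesh = read_mesh(path)
    assert len(mesh.faces) == 4
    assert mesh.provenance["dropped_faces"] >= 1


def test_largest_component_kept(tmp_path):
    box = trimesh.creation.box()
    far = trimesh.creation.box()
    far.apply_translation([10, 10, 10])
    far = trimesh.Trimesh(far.vertices, far.faces[:4], process=False)
    combined = trimesh.util.concatenate([box, far])
    path = tmp_path / "two.obj"
    combined.export(str(path))
    mesh = read_mesh(path)
    assert len(mesh.faces) == 12


def test_unparseable_file_raises(tmp_path):
    path = tmp_path / "bad.ply"
    path.write_text("this is not a ply file at all")
    with pytest.raises((MeshFormatError, MeshContentError)):
        read_mesh(path)


def test_read_vrml_indexedfaceset(tmp_path):
    wrl = """#VRML V2.0 utf8
Shape {
  geometry IndexedFaceSet {
    coord Coordinate {
      point [ 0 0 0, 1 0 0, 0 1 0, 0 0 1 ]
    }
    coordIndex [ 0, 1, 2, -1, 0, 1, 3, -1, 0, 2, 3, -1, 1, 2, 3, -1 ]
  }
}
"""
    path = tmp_path / "tetra.wrl"
    path.write_text(wrl)
    mesh = read_mesh(path)
    assert mesh.n_vertices == 4
    assert len(mesh.faces) == 4


def test_vrml_quad_triangulation(tmp_path):
    wrl = """#VRML V2.0 utf8
Shape { geometry IndexedFaceSet {
  coord Coordinate { point [ 0 0 0, 1 0 0, 1 1 0, 0 1 0, 0.5 0.5 1 ] }
  coordIndex [ 0, 3, 2, 1, -1, 0, 1, 4, -1, 1, 2, 4, -1, 2, 3, 4, -1, 3, 0, 4, -1 ]
} }
"""
    path = tmp_path / "pyramid.wrl"
    path.write_text(wrl)
    vertices, faces = read_vrml(path)
    assert len(vertices) == 5
    assert len(faces) == 6  # quad base fans into 2 triangles


def test_vrml_bad_index(tmp_path):
    path = tmp_path / "bad.wrl"
    path.write_text(
        "#VRML V2.0 utf8\nShape { geometry IndexedFaceSet {"
        " coord Coordinate { point [ 0 0 0, 1 0 0, 0 1 0 ] }"
        " coordIndex [ 0, 1, 9, -1 ] } }"
    )
    with pytest.raises(VrmlParseError):
        read_vrml(path)


# --------------------------------------------------------------------------
# orientation


def _ellipsoid_mesh(semi_axes, attitude=None, n=4):
    sphere = trimesh.creation.icosphere(subdivisions=n)
    vertices = sphere.vertices * np.asarray(semi_axes)
    if attitude is not None:
        vertices = vertices @ attitude.T
    return TriMesh(np.asarray(vertices, float), np.asarray(sphere.faces, np.int64))


def test_orient_ellipsoid_principal_axes():
    """Semi-axes (3, 2, 1) in a random attitude land on (x, y, z) = (2, 3, 1).

    Oracle: the extents of an axis-aligned ellipsoid are twice its
    semi-axes, with the longest on y, verified by brute-force moments.
    """
    rng = np.random.default_rng(11)
    random_rotation = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(random_rotation) < 0:
        random_rotation[:, 0] = -random_rotation[:, 0]
    mesh = _ellipsoid_mesh((3, 2, 1), attitude=random_rotation)
    oriented = orient_artifact(mesh)
    extents = oriented.extents()
    assert np.allclose(extents, [4.0, 6.0, 2.0], atol=0.05)
    # brute-force moment check: variance ordering matches axis ordering
    var = oriented.vertices.var(axis=0)
    assert var[1] > var[0] > var[2]


def test_orient_identity_rotation_only_centers(small_lens):
    mesh, _ = small_lens
    shifted = mesh.copy()
    shifted.vertices = shifted.vertices + np.array([5.0, -2.0, 1.0])
    oriented = orient_artifact(shifted, rotation=np.eye(3))
    assert np.allclose(
        oriented.vertices,
        mesh.vertices - mesh.vertices.mean(axis=0),
        atol=1e-9,
    )


def test_orient_sphere_flags_ambiguous():
    mesh = _ellipsoid_mesh((1, 1, 1))
    with pytest.warns(UserWarning, match="ambiguous"):
        oriented = orient_artifact(mesh)
    assert oriented.ambiguous


def test_orient_idempotent():
    mesh = _ellipsoid_mesh((3, 2, 1))
    once = orient_artifact(mesh)
    twice = orient_artifact(once.mesh)
    assert np.abs(twice.vertices - once.vertices).max() < 1e-6


def test_orient_rejects_bad_rotation(small_lens):
    mesh, _ = small_lens
    with pytest.raises(ValueError):
        orient_artifact(mesh, rotation=np.diag([2.0, 1.0, 1.0]))
    with pytest.raises(ValueError):
        orient_artifact(mesh, rotation=np.diag([-1.0, 1.0, 1.0]))  # improper


def test_tip_at_positive_y():
    """The narrower half (the tip of a teardrop) must point to +y."""
    rng = np.random.default_rng(3)
    sphere = trimesh.creation.icosphere(subdivisions=4)
    vertices = sphere.vertices.copy()
    # teardrop: shrink x-width linearly toward +y
    width = 1.0 - 0.5 * (vertices[:, 1] + 1) / 2
    vertices[:, 0] *= width
    vertices[:, 1] *= 2.0
    vertices[:, 2] *= 0.5
    mesh = TriMesh(vertices, np.asarray(sphere.faces, np.int64))
    oriented = orient_artifact(mesh)
    upper = oriented.vertices[:, 1] > 0
    assert (
        np.abs(oriented.vertices[upper, 0]).mean()
        < np.abs(oriented.vertices[~upper, 0]).mean()
    )


# --------------------------------------------------------------------------
# resolution and scale


def test_resample_sphere_preserves_area():
    sphere = trimesh.creation.icosphere(subdivisions=6)  # 40962 vertices
    mesh = TriMesh(
        np.asarray(sphere.vertices, float), np.asarray(sphere.faces, np.int64)
    )
    out = resample_mesh(mesh, 20_000)
    assert abs(out.n_vertices - 20_000) <= 0.02 * 20_000
    area = out.as_trimesh().area
    assert abs(area - 4 * np.pi) / (4 * np.pi) < 0.01


def test_resample_upsamples_sparse_mesh():
    sphere = trimesh.creation.icosphere(subdivisions=3)  # 642 vertices
    mesh = TriMesh(
        np.asarray(sphere.vertices, float), np.asarray(sphere.faces, np.int64)
    )
    out = resample_mesh(mesh, 5_000)
    assert abs(out.n_vertices - 5_000) <= 0.02 * 5_000


def test_resample_near_target_is_identity(small_lens):
    mesh, _ = small_lens
    out = resample_mesh(mesh, mesh.n_vertices)
    assert out.n_vertices == mesh.n_vertices
    assert np.array_equal(out.vertices, mesh.vertices)


def test_resample_rejects_tiny_target(small_lens):
    mesh, _ = small_lens
    with pytest.raises(ValueError):
        resample_mesh(mesh, 50)


def test_resample_preserves_bounding_box(small_lens):
    mesh, _ = small_lens
    out = resample_mesh(mesh, 4_000)
    assert np.allclose(out.extents(), mesh.extents(), rtol=0.02)


def test_rescale_unit_length(small_lens):
    mesh, _ = small_lens
    oriented = orient_artifact(mesh, rotation=np.eye(3))
    scaled = rescale_mesh(oriented)
    extents = scaled.extents()
    assert abs(extents[1] - 1.0) < 1e-9
    # isotropy: shape ratios unchanged
    before = oriented.extents()
    assert abs(extents[0] / extents[1] - before[0] / before[1]) < 1e-9
    assert abs(extents[2] / extents[1] - before[2] / before[1]) < 1e-9


def test_rescale_is_isotropic(small_lens):
    """All pairwise distances scale by one constant."""
    mesh, _ = small_lens
    oriented = orient_artifact(mesh, rotation=np.eye(3))
    scaled = rescale_mesh(oriented)
    rng = np.random.default_rng(0)
    idx = rng.integers(0, mesh.n_vertices, size=(50, 2))
    d_before = np.linalg.norm(
        oriented.vertices[idx[:, 0]] - oriented.vertices[idx[:, 1]], axis=1
    )
    d_after = np.linalg.norm(
        scaled.vertices[idx[:, 0]] - scaled.vertices[idx[:, 1]], axis=1
    )
    ratios = d_after / d_before
    assert ratios.std() < 1e-12 * ratios.mean() + 1e-12
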