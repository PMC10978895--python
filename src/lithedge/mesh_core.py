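"""Mesh input, cleanup, orientation and normalization.

Artifacts arrive as closed triangle meshes in arbitrary units, poses and
scan resolutions. Before any edge measurement they are brought to a common
frame: length axis = y with the tip at +y, plan view = x-y plane, thickness
axis = z; length rescaled to 1; vertex count resampled to a common target so
scan resolution cannot bias the angle measurements (sparser meshes read
slightly blunter).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .vrml import read_vrml

logger = logging.getLogger(__name__)

__all__ = [
    "TriMesh",
    "OrientedMesh",
    "MeshFormatError",
    "MeshContentError",
    "read_mesh",
    "orient_artifact",
    "resample_mesh",
    "rescale_mesh",
]


class MeshFormatError(ValueError):
    """The file could not be parsed in the stated format."""


class MeshContentError(ValueError):
    """The file parsed but contains no usable mesh."""


@dataclass
class TriMesh:
    """A cleaned triangle mesh: vertices, faces, and where it came from.

    Invariants enforced by :func:`read_mesh` / :meth:`validate`: all face
    indices valid, no zero-area faces, a single connected component, and at
    least 4 vertices.
    """

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    provenance: dict = field(default_factory=dict)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def extents(self) -> np.ndarray:
        return self.vertices.max(axis=0) - self.vertices.min(axis=0)

    def validate(self) -> None:
        if self.n_vertices < 4:
            raise MeshContentError("mesh has fewer than 4 vertices")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise MeshContentError("face index out of range")
        areas = _face_areas(self.vertices, self.faces)
        if np.any(areas <= 0):
            raise MeshContentError("zero-area face present after cleanup")

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(), self.faces.copy(), dict(self.provenance)
        )


@dataclass
class OrientedMesh:
    """A TriMesh in the analysis convention plus the rotation that got it there.

    Convention: length axis y (tip at max y), plan view x-y, thickness z.
    ``ambiguous`` is set when the principal axes were too close to equal for
    the automatic orientation to be meaningful.
    """

    mesh: TriMesh
    rotation: np.ndarray  # the 3x3 orthonormal matrix that was applied
    ambiguous: bool = False
    convention: str = "length=y,plan=xy,thickness=z,tip=+y"

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def faces(self) -> np.ndarray:
        return self.mesh.faces

    def extents(self) -> np.ndarray:
        return self.mesh.extents()


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def _cleanup(
    vertices: np.ndarray, faces: np.ndarray, provenance: dict
) -> TriMesh:
    """Merge duplicate vertices, drop degenerate faces, keep largest component."""
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    n_v0, n_f0 = len(tm.vertices), len(tm.faces)
    tm.merge_vertices()
    # drop zero-area and duplicate faces
    areas = _face_areas(tm.vertices, tm.faces)
    tm.update_faces(areas > 0)
    tm.update_faces(tm.unique_faces())
    if len(tm.faces) == 0:
        raise MeshContentError("no valid faces remain after cleanup")
    components = trimesh.graph.connected_components(
        tm.face_adjacency, nodes=np.arange(len(tm.faces))
    )
    if len(components) > 1:
        largest = max(components, key=len)
        mask = np.zeros(len(tm.faces), dtype=bool)
        mask[largest] = True
        tm.update_faces(mask)
    tm.remove_unreferenced_vertices()
    dropped_v = n_v0 - len(tm.vertices)
    dropped_f = n_f0 - len(tm.faces)
    if dropped_v or dropped_f:
        logger.info(
            "cleanup dropped %d vertices / %d faces", dropped_v, dropped_f
        )
    provenance = dict(provenance)
    provenance["dropped_vertices"] = int(dropped_v)
    provenance["dropped_faces"] = int(dropped_f)
    out = TriMesh(
        np.asarray(tm.vertices, dtype=float),
        np.asarray(tm.faces, dtype=np.int64),
        provenance,
    )
    out.validate()
    return out


def read_mesh(path: str | Path, format: str = "auto") -> TriMesh:
    """Read a triangle mesh from OBJ / PLY / STL / VRML97 and clean it.

    Cleanup merges duplicate vertices, drops degenerate and duplicate
    faces, and keeps the largest connected component; counts of dropped
    elements are recorded in the provenance and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format
    if fmt == "auto":
        fmt = path.suffix.lower().lstrip(".")
        if fmt == "vrml":
            fmt = "wrl"
    if fmt not in {"obj", "ply", "stl", "wrl"}:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    if fmt == "wrl":
        vertices, faces = read_vrml(path)
    else:
        try:
            loaded = trimesh.load(str(path), file_type=fmt, force="mesh")
        except Exception as exc:  # parse failures vary by backend
            raise MeshFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
        if loaded is None or len(loaded.faces) == 0:
            raise MeshContentError(f"{path} contains no faces")
        vertices, faces = loaded.vertices, loaded.faces
    return _cleanup(
        np.asarray(vertices, dtype=float),
        np.asarray(faces, dtype=np.int64),
        {"source": str(path), "format": fmt},
    )


# --------------------------------------------------------------------------
# orientation


def _principal_frame(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-frame of the vertex covariance, eigenvalues descending."""
    centered = vertices - vertices.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # canonical sign: largest-magnitude component positive, so repeated
    # orientation of an already-oriented mesh is exactly idempotent
    for i in range(3):
        j = int(np.argmax(np.abs(evecs[:, i])))
        if evecs[j, i] < 0:
            evecs[:, i] = -evecs[:, i]
    return evals, evecs


def orient_artifact(
    mesh: TriMesh, rotation: np.ndarray | None = None
) -> OrientedMesh:
    """Center the mesh and rotate it into the analysis convention.

    With an explicit ``rotation`` (3x3 orthonormal) that matrix is applied
    verbatim after centering — the path for reproducing externally oriented
    datasets. Otherwise principal axes are used: the longest axis becomes y,
    the second x, the shortest z, and the y sign is chosen so the narrower
    half (smaller mean plan half-width) points to +y, i.e. the tip.

    Near-isotropic meshes (consecutive principal-value ratio below 1.01)
    are still oriented but flagged ``ambiguous``.
    """
    vertices = mesh.vertices - mesh.vertices.mean(axis=0)
    ambiguous = False
    user_given = rotation is not None
    if rotation is not None:
        rotation = np.asarray(rotation, dtype=float)
        if rotation.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (determinant +1)")
        new_vertices = vertices @ rotation.T
    else:
        evals, evecs = _principal_frame(vertices)
        safe = np.sqrt(np.maximum(evals, 1e-30))
        if safe[0] / safe[1] < 1.01 or safe[1] / safe[2] < 1.01:
            ambiguous = True
            warnings.warn(
                "near-isotropic mesh: automatic orientation is ambiguous",
                stacklevel=2,
            )
        # columns of evecs map to (y, x, z); build proper rotation rows (x,y,z)
        y_axis = evecs[:, 0]
        x_axis = evecs[:, 1]
        z_axis = np.cross(x_axis, y_axis)
        rot = np.stack([x_axis, y_axis, z_axis])  # world -> convention
        new_vertices = vertices @ rot.T
        # tip disambiguation: narrower half at +y
        upper = new_vertices[:, 1] > 0
        if upper.any() and (~upper).any():
            width_up = np.abs(new_vertices[upper, 0]).mean()
            width_down = np.abs(new_vertices[~upper, 0]).mean()
            if width_up > width_down:
                flip = np.diag([-1.0, -1.0, 1.0])  # 180 deg about z
                new_vertices = new_vertices @ flip
                rot = flip @ rot
        rotation = rot
    new_vertices = new_vertices - new_vertices.mean(axis=0)
    out = TriMesh(new_vertices, mesh.faces.copy(), dict(mesh.provenance))
    out.provenance["orientation"] = "user" if user_given else "auto"
    if ambiguous:
        out.provenance["orientation_ambiguous"] = True
    return OrientedMesh(out, rotation=rotation, ambiguous=ambiguous)


# --------------------------------------------------------------------------
# resolution normalization


def _vertex_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted plane quadrics accumulated per vertex (n, 4, 4)."""
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(cross, axis=1)
    normal = cross / np.maximum(area2, 1e-300)[:, None]
    d = -np.einsum("ij,ij->i", normal, tri[:, 0])
    p = np.column_stack([normal, d])  # (m, 4)
    face_q = (0.5 * area2)[:, None, None] * p[:, :, None] * p[:, None, :]
    quadrics = np.zeros((len(vertices), 4, 4))
    for corner in range(3):
        np.add.at(quadrics, faces[:, corner], face_q)
    return quadrics


def _feature_vertices(
    vertices: np.ndarray, faces: np.ndarray, max_dev_deg: float = 12.0
) -> np.ndarray:
    """Vertices where some incident face normal deviates from the mean
    vertex normal by more than ``max_dev_deg`` — ridge/rim vertices."""
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(cross, axis=1)
    fn = cross / np.maximum(norm, 1e-300)[:, None]
    vn = np.zeros_like(vertices)
    for corner in range(3):
        np.add.at(vn, faces[:, corner], cross)  # area-weighted
    vn /= np.maximum(np.linalg.norm(vn, axis=1), 1e-300)[:, None]
    min_dot = np.ones(len(vertices))
    for corner in range(3):
        dots = np.einsum("ij,ij->i", fn, vn[faces[:, corner]])
        np.minimum.at(min_dot, faces[:, corner], dots)
    return min_dot < np.cos(np.radians(max_dev_deg))


def _collapse_veto(
    vertices: np.ndarray,
    faces: np.ndarray,
    src: np.ndarray,
    dst: np.ndarray,
    min_quality: float = 0.25,
) -> np.ndarray:
    """True for candidate collapses whose surviving triangles would be
    flipped or of quality (~area / longest edge squared, 1 = equilateral)
    below ``min_quality``."""
    order_v = np.argsort(faces.flatten(), kind="stable")
    inc_face = np.repeat(np.arange(len(faces)), 3)[order_v]
    inc_corner = np.tile(np.arange(3), len(faces))[order_v]
    sorted_v = faces.flatten()[order_v]
    offsets = np.searchsorted(sorted_v, np.arange(len(vertices) + 1))

    deg = offsets[src + 1] - offsets[src]
    cand = np.repeat(np.arange(len(src)), deg)
    first_in_group = np.cumsum(deg) - deg
    within = np.arange(int(deg.sum())) - np.repeat(first_in_group, deg)
    flat_pos = np.repeat(offsets[src], deg) + within
    f_idx = inc_face[flat_pos]
    corner = inc_corner[flat_pos]

    tri = faces[f_idx].copy()
    # skip faces that also contain dst: they collapse away entirely
    contains_dst = (tri == dst[cand][:, None]).any(axis=1)
    tri[np.arange(len(tri)), corner] = dst[cand]

    p = vertices[tri]
    new_cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    old = vertices[faces[f_idx]]
    old_cross = np.cross(old[:, 1] - old[:, 0], old[:, 2] - old[:, 0])
    flipped = np.einsum("ij,ij->i", new_cross, old_cross) <= 0

    edge_len2 = np.maximum.reduce(
        [
            np.einsum("ij,ij->i", p[:, 1] - p[:, 0], p[:, 1] - p[:, 0]),
            np.einsum("ij,ij->i", p[:, 2] - p[:, 1], p[:, 2] - p[:, 1]),
            np.einsum("ij,ij->i", p[:, 0] - p[:, 2], p[:, 0] - p[:, 2]),
        ]
    )
    area2 = np.linalg.norm(new_cross, axis=1)
    quality = (2.0 / np.sqrt(3.0)) * area2 / np.maximum(edge_len2, 1e-300)
    bad_face = (~contains_dst) & (flipped | (quality < min_quality))
    veto = np.zeros(len(src), dtype=bool)
    np.logical_or.at(veto, cand[bad_face], True)
    return veto


def _qem_decimate(
    vertices: np.ndarray, faces: np.ndarray, target: int
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy pass-wise edge-collapse decimation with subset placement.

    Each pass ranks all edges by quadric error, collapses an independent
    set of the cheapest ones (each collapse moves a vertex onto its
    neighbor, so surviving vertices stay exactly on the scanned surface),
    and rebuilds. Flat regions collapse for near-zero cost while sharp
    rims and ridges carry a high cost and are preserved until nothing
    cheaper remains — the behavior a resolution-normalization step needs
    on edged artifacts.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    while len(vertices) > target:
        need = len(vertices) - target
        quadrics = _vertex_quadrics(vertices, faces)
        edges = np.unique(
            np.sort(
                np.concatenate(
                    [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]
                ),
                axis=1,
            ),
            axis=0,
        )
        u, v = edges[:, 0], edges[:, 1]
        hu = np.column_stack([vertices[u], np.ones(len(u))])
        hv = np.column_stack([vertices[v], np.ones(len(v))])
        q_sum = quadrics[u] + quadrics[v]
        cost_to_v = np.einsum("ij,ijk,ik->i", hv, q_sum, hv)
        cost_to_u = np.einsum("ij,ijk,ik->i", hu, q_sum, hu)
        keep_v = cost_to_v <= cost_to_u
        cost = np.where(keep_v, cost_to_v, cost_to_u)
        src = np.where(keep_v, u, v)
        dst = np.where(keep_v, v, u)

        # veto collapses that would create degenerate/flipped triangles:
        # such slivers punch holes in the downstream alpha complex
        bad = _collapse_veto(vertices, faces, src, dst)
        # never remove feature (ridge) vertices: coarsening a sharp rim
        # opens gaps the alpha-shape boundary cannot bridge
        bad |= _feature_vertices(vertices, faces)[src]
        cost = np.where(bad, np.inf, cost)

        order = np.argsort(cost, kind="stable")
        touched = np.zeros(len(vertices), dtype=bool)
        remap = np.arange(len(vertices))
        removed = 0
        for i in order:
            if not np.isfinite(cost[i]):
                break  # only vetoed collapses remain
            s, t = src[i], dst[i]
            if touched[s] or touched[t]:
                continue
            touched[s] = touched[t] = True
            remap[s] = t
            removed += 1
            if removed >= need:
                break
        if removed == 0:
            break
        new_faces = remap[faces]
        good = (
            (new_faces[:, 0] != new_faces[:, 1])
            & (new_faces[:, 1] != new_faces[:, 2])
            & (new_faces[:, 0] != new_faces[:, 2])
        )
        new_faces = new_faces[good]
        key = np.sort(new_faces, axis=1)
        _, first = np.unique(key, axis=0, return_index=True)
        new_faces = new_faces[np.sort(first)]
        used = np.unique(new_faces)
        index_map = np.full(len(vertices), -1, dtype=np.int64)
        index_map[used] = np.arange(len(used))
        vertices = vertices[used]
        faces = index_map[new_faces]
    return vertices, faces


def resample_mesh(mesh: TriMesh, target_vertices: int = 50_000) -> TriMesh:
    """Normalize mesh resolution to ``target_vertices`` (within 2%).

    Meshes below target are midpoint-subdivided first (which preserves the
    surface exactly), then decimated by quadric edge collapse onto original
    vertices. Total surface area is preserved to well under 1% at realistic
    densities.
    """
    if target_vertices < 100:
        raise ValueError("target_vertices must be at least 100")
    tol = 0.02
    vertices, faces = mesh.vertices, mesh.faces
    while len(vertices) < target_vertices:
        vertices, faces = trimesh.remesh.subdivide(vertices, faces)
    n = len(vertices)
    if abs(n - target_vertices) <= tol * target_vertices:
        out = TriMesh(
            np.asarray(vertices, float), np.asarray(faces, np.int64),
            dict(mesh.provenance),
        )
        out.provenance["resampled_to"] = int(len(vertices))
        return out

    nv, nf = _qem_decimate(vertices, faces, target_vertices)
    result = _cleanup(nv, nf, dict(mesh.provenance))
    result.provenance["resampled_to"] = int(len(result.vertices))
    if abs(len(result.vertices) - target_vertices) > 2 * tol * target_vertices:
        warnings.warn(
            f"resample reached {len(result.vertices)} vertices "
            f"(target {target_vertices})",
            stacklevel=2,
        )
    return result


def rescale_mesh(oriented: OrientedMesh) -> OrientedMesh:
    """Isotropically rescale so the length (y extent) equals 1."""
    extent_y = float(
        oriented.vertices[:, 1].max() - oriented.vertices[:, 1].min()
    )
    if extent_y <= 0:
        raise ValueError("mesh has zero length (y extent)")
    scaled = oriented.mesh.copy()
    scaled.vertices = scaled.vertices / extent_y
    scaled.provenance["scale_factor"] = 1.0 / extent_y
    return OrientedMesh(
        scaled,
        rotation=oriented.rotation,
        ambiguous=oriented.ambiguous,
        convention=oriented.convention,
    )
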