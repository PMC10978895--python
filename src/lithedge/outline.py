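"""Automatic detection of the 3D perimeter dividing an artifact's two faces.

The perimeter is found in plan view: the alpha-shape boundary of the
vertices projected to the x-y plane picks out the most extreme coordinates,
which are then lifted back to 3D using the z of their source vertices.
Over blunt stretches the projection is unreliable — a near-vertical surface
puts many vertices at the same plan position and the lifted z fluctuates
wildly — so wherever nearby face normals lie close to the x-y plane the
outline z is replaced by a local mean of surrounding surface heights.
Finally the outline is resampled to a fixed number of coordinates at
uniform arc-length spacing, starting at the tip and running
counter-clockwise in plan view.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon

from .mesh_core import OrientedMesh

logger = logging.getLogger(__name__)

__all__ = [
    "Outline3D",
    "RawOutline",
    "GeometryError",
    "project_boundary",
    "lift_boundary",
    "correct_blunt_regions",
    "resample_outline",
    "outline_perimeter",
    "detect_outline",
]


class GeometryError(ValueError):
    pass


@dataclass
class RawOutline:
    """Ordered closed 3D outline before resampling.

    ``vertex_index`` maps each coordinate back to its source mesh vertex;
    ``blunt_flag`` marks coordinates whose z was replaced by the local
    surface mean.
    """

    coords: np.ndarray  # (n, 3)
    vertex_index: np.ndarray  # (n,) int
    blunt_flag: np.ndarray | None = None


@dataclass
class Outline3D:
    """The detected perimeter: 1000 ordered, closed, evenly spaced coordinates.

    ``arc_pos`` is the cumulative 3D arc length at each coordinate, starting
    at the tip (maximum y); ``blunt_flag`` marks z-corrected coordinates;
    ``plan_centroid`` is the centroid of the x-y outline polygon.
    """

    coords: np.ndarray  # (n, 3)
    arc_pos: np.ndarray  # (n,)
    blunt_flag: np.ndarray  # (n,) bool
    plan_centroid: np.ndarray  # (2,)

    @property
    def n(self) -> int:
        return len(self.coords)

    def perimeter(self) -> float:
        return outline_perimeter(self)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "index": np.arange(self.n),
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "arc_pos": self.arc_pos,
                "blunt_flag": self.blunt_flag,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.9g")

    def to_obj(self, path) -> None:
        """Closed 3D polyline as OBJ line elements, for inspection."""
        lines = [f"v {x:.9g} {y:.9g} {z:.9g}" for x, y, z in self.coords]
        order = " ".join(str(i + 1) for i in range(self.n))
        lines.append(f"l {order} 1")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# alpha-shape boundary


def _alpha_boundary_edges(
    tri: Delaunay, circumradius: np.ndarray, alpha: float
) -> np.ndarray:
    """Boundary edges (pairs of point indices) of the alpha complex."""
    keep = circumradius <= alpha
    simplices = tri.simplices[keep]
    if len(simplices) == 0:
        return np.empty((0, 2), dtype=np.int64)
    edges = np.concatenate(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [2, 0]]]
    )
    key = np.sort(edges, axis=1)
    uniq, inverse, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    return uniq[counts == 1]


def _edges_to_loops(edges: np.ndarray) -> list[np.ndarray]:
    """Assemble undirected boundary edges into closed vertex loops.

    Returns [] if any vertex has degree other than 2 (non-simple boundary).
    """
    if len(edges) == 0:
        return []
    neighbors: dict[int, list[int]] = {}
    for u, v in edges:
        neighbors.setdefault(int(u), []).append(int(v))
        neighbors.setdefault(int(v), []).append(int(u))
    if any(len(adj) != 2 for adj in neighbors.values()):
        return []
    loops = []
    visited: set[int] = set()
    for start in neighbors:
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = start, neighbors[start][0]
        while cur != start:
            loop.append(cur)
            visited.add(cur)
            nxt = neighbors[cur][0] if neighbors[cur][0] != prev else neighbors[cur][1]
            prev, cur = cur, nxt
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Effective alpha radius per Delaunay triangle.

    The circumradius, capped at the longest edge: near-degenerate slivers
    (common where a scanned wall projects onto its own rim) have unbounded
    circumradius and would otherwise punch permanent holes into the alpha
    complex; capping admits them once their actual extent fits alpha.
    """
    pa, pb, pc = (points[simplices[:, i]] for i in range(3))
    la = np.linalg.norm(pb - pc, axis=1)
    lb = np.linalg.norm(pa - pc, axis=1)
    lc = np.linalg.norm(pa - pb, axis=1)
    ab = pb - pa
    ac = pc - pa
    area2 = np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])  # 2 * area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    longest = np.maximum.reduce([la, lb, lc])
    r = np.where(np.isfinite(r), np.minimum(r, longest), longest)
    return r


def project_boundary(
    mesh: OrientedMesh,
    alpha: float | None = None,
    alpha_grid_factor: float = 1.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered boundary of the alpha shape of the plan-view vertex cloud.

    Returns ``(polygon, vertex_index)``: the 2D boundary coordinates in loop
    order and, for each, the index of the source mesh vertex. With
    ``alpha=None`` the smallest alpha on a geometric grid (steps of
    ``alpha_grid_factor`` starting from the mean projected nearest-neighbor
    spacing) that yields a single simple loop enclosing every projected
    point is used. If several loops arise at the chosen alpha the largest
    by area is returned with a warning.
    """
    points3d = mesh.vertices
    points = points3d[:, :2]
    spread = points.max(axis=0) - points.min(axis=0)
    if min(spread) <= 0:
        raise GeometryError("degenerate plan-view projection (collinear points)")

    # exact 2D duplicates break Delaunay neighbor structure; keep the first
    _, unique_first = np.unique(
        np.round(points, 12), axis=0, return_index=True
    )
    unique_first.sort()
    pts = points[unique_first]

    tri = Delaunay(pts)
    radii = _circumradii(pts, tri.simplices)

    tree = cKDTree(pts)
    nn, _ = tree.query(pts[:: max(1, len(pts) // 2000)], k=2)
    base_alpha = float(np.mean(nn[:, 1]))

    candidates = (
        [alpha]
        if alpha is not None
        else [
            base_alpha * alpha_grid_factor**i
            for i in range(
                1 + math.ceil(
                    math.log(max(np.max(spread) / base_alpha, 2.0))
                    / math.log(alpha_grid_factor)
                )
            )
        ]
    )

    chosen = None
    for cand in candidates:
        edges = _alpha_boundary_edges(tri, radii, cand)
        loops = _edges_to_loops(edges)
        if not loops:
            continue
        polys = []
        for loop in loops:
            if len(loop) < 3:
                continue
            poly = Polygon(pts[loop])
            if poly.is_valid:
                polys.append((loop, poly))
        if not polys:
            continue
        loop, poly = max(polys, key=lambda lp: lp[1].area)
        if alpha is None:
            if len(polys) > 1:
                continue
            inside = shapely.contains_xy(
                poly.buffer(1e-9 * max(spread)), pts[:, 0], pts[:, 1]
            )
            if not inside.all():
                continue
        elif len(polys) > 1:
            logger.warning(
                "alpha=%g yields %d boundary loops; keeping largest",
                cand,
                len(polys),
            )
        chosen = (cand, loop)
        break
    if chosen is None:
        raise GeometryError("no alpha value produced a usable boundary loop")
    alpha_used, loop = chosen
    logger.debug("alpha shape boundary: alpha=%g, %d vertices", alpha_used, len(loop))
    vertex_index = unique_first[loop]
    return points[vertex_index], vertex_index


def lift_boundary(
    mesh: OrientedMesh, boundary: np.ndarray, vertex_index: np.ndarray
) -> RawOutline:
    """Attach to each boundary coordinate the z of its source mesh vertex."""
    if len(boundary) != len(vertex_index):
        raise GeometryError("boundary and vertex_index length mismatch")
    src = mesh.vertices[vertex_index]
    if not np.allclose(src[:, :2], boundary, atol=1e-9):
        raise GeometryError("boundary vertices do not map back to mesh vertices")
    coords = np.column_stack([boundary, src[:, 2]])
    return RawOutline(coords=coords, vertex_index=vertex_index)


def correct_blunt_regions(
    mesh: OrientedMesh,
    outline: RawOutline,
    parallel_threshold_deg: float = 15.0,
    blunt_k: int = 50,
    blunt_face_k: int = 30,
) -> RawOutline:
    """Fix the outline z over blunt (near-vertical) perimeter stretches.

    For each outline coordinate the mean inclination of nearby face normals
    is examined; where the normals lie within ``parallel_threshold_deg`` of
    the x-y plane the coordinate is flagged blunt and its z replaced by the
    mean z of the ``blunt_k`` nearest mesh vertices. x and y never change.

    Neighborhoods are taken by plan-view (x-y) distance: a blunt surface is
    by definition near-vertical, so a plan-view disk samples the wall over
    its full height, whereas a 3D ball around the provisional (unreliable)
    z would see only one end of it.
    """
    if blunt_k > len(mesh.vertices):
        raise ValueError("blunt_k exceeds mesh vertex count")
    tm = mesh.mesh.as_trimesh()
    face_normals = tm.face_normals
    face_centers = tm.triangles_center
    # angle between face normal and z axis: 90 deg = wall parallel to x-y plane
    normal_tilt = np.degrees(np.arccos(np.clip(np.abs(face_normals[:, 2]), 0, 1)))

    k_faces = min(blunt_face_k, len(face_centers))
    face_tree = cKDTree(face_centers[:, :2])
    _, face_idx = face_tree.query(outline.coords[:, :2], k=k_faces)
    mean_tilt = normal_tilt[face_idx].mean(axis=1)
    blunt = mean_tilt > (90.0 - parallel_threshold_deg)

    coords = outline.coords.copy()
    if blunt.any():
        vertex_tree = cKDTree(mesh.vertices[:, :2])
        _, vert_idx = vertex_tree.query(outline.coords[blunt, :2], k=blunt_k)
        coords[blunt, 2] = mesh.vertices[vert_idx, 2].mean(axis=1)
    return RawOutline(
        coords=coords,
        vertex_index=outline.vertex_index,
        blunt_flag=blunt,
    )


# --------------------------------------------------------------------------
# resampling


def _close_loop(coords: np.ndarray) -> np.ndarray:
    return np.vstack([coords, coords[:1]])


def resample_outline(
    outline: RawOutline, outline_points: int = 1000
) -> Outline3D:
    """Uniform arc-length resampling to a fixed number of coordinates.

    The resampled sequence starts at the tip (maximum y), runs
    counter-clockwise in plan view, and is closed (the last coordinate
    connects back to the first). Per-coordinate blunt flags are carried
    over from the nearest source coordinate.
    """
    coords = outline.coords
    if len(coords) < 4:
        raise GeometryError("outline must have at least 4 coordinates")
    plan = Polygon(coords[:, :2])
    if not plan.is_valid:
        raise GeometryError("outline projection is self-intersecting")

    # counter-clockwise in plan view (shoelace sign)
    x, y = coords[:, 0], coords[:, 1]
    area2 = float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if area2 < 0:
        coords = coords[::-1]
        blunt_in = (
            outline.blunt_flag[::-1]
            if outline.blunt_flag is not None
            else np.zeros(len(coords), bool)
        )
    else:
        blunt_in = (
            outline.blunt_flag
            if outline.blunt_flag is not None
            else np.zeros(len(coords), bool)
        )

    tip = int(np.argmax(coords[:, 1]))
    coords = np.roll(coords, -tip, axis=0)
    blunt_in = np.roll(blunt_in, -tip)

    closed = _close_loop(coords)
    gaps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(gaps)])
    total = cum[-1]
    if total <= 0:
        raise GeometryError("outline has zero length")
    targets = total * np.arange(outline_points) / outline_points
    new = np.column_stack(
        [np.interp(targets, cum, closed[:, i]) for i in range(3)]
    )

    # nearest source coordinate supplies the blunt flag
    src_idx = np.searchsorted(cum, targets, side="right") - 1
    src_idx = np.clip(src_idx, 0, len(coords) - 1)
    frac = (targets - cum[src_idx]) / np.maximum(gaps[src_idx], 1e-300)
    nearest = np.where(frac > 0.5, (src_idx + 1) % len(coords), src_idx)
    blunt = blunt_in[nearest]

    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(new, axis=0), axis=1))]
    )[: outline_points]
    centroid = Polygon(new[:, :2]).centroid
    return Outline3D(
        coords=new,
        arc_pos=arc,
        blunt_flag=blunt,
        plan_centroid=np.array([centroid.x, centroid.y]),
    )


def outline_perimeter(outline: Outline3D) -> float:
    """Total 3D perimeter, including the closing gap."""
    closed = _close_loop(outline.coords)
    return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def detect_outline(
    mesh: OrientedMesh,
    alpha: float | None = None,
    alpha_grid_factor: float = 1.3,
    outline_points: int = 1000,
    parallel_threshold_deg: float = 15.0,
    blunt_k: int = 50,
    blunt_face_k: int = 30,
) -> Outline3D:
    """Full outline stage: project, lift, blunt-correct, resample."""
    boundary, vertex_index = project_boundary(
        mesh, alpha=alpha, alpha_grid_factor=alpha_grid_factor
    )
    raw = lift_boundary(mesh, boundary, vertex_index)
    corrected = correct_blunt_regions(
        mesh,
        raw,
        parallel_threshold_deg=parallel_threshold_deg,
        blunt_k=blunt_k,
        blunt_face_k=blunt_face_k,
    )
    return resample_outline(corrected, outline_points=outline_points)
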