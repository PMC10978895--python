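"""Per-segment and per-artifact edge measurements.

Once the perimeter is segmented, each discrete edge gets: its 3D arc
length; its mean angle and a sharp/blunt label against a threshold (120
degrees by default, or derived per assemblage from the trough of the
pooled bimodal angle distribution); its transverse asymmetry (ratio of the
two half-angles either side of the horizontal direction toward the
plan-view center — near 1 for symmetric bifacial edges, near 0 for
plano-convex ones); and the surface concavity of both adjacent faces, on a
0 (concave) to 1 (convex) scale with categorical labels. The artifact
summary adds percent of sharp perimeter and refinement (width/thickness).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._kde import kde_mode_rows, kde_on_grid, silverman_bandwidth
from .ceam import (
    EdgeAngleProfile,
    FaceLabels,
    VertexAngles,
    _nearest_on_polyline,
)
from .mesh_core import OrientedMesh
from .outline import GeometryError, Outline3D, outline_perimeter
from .segmentation import SegmentationResult

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdResult",
    "EdgeSegment",
    "ArtifactReport",
    "sharp_threshold",
    "classify_segments",
    "percent_sharp",
    "transverse_asymmetry_profile",
    "vertex_concavity",
    "face_concavity_profile",
    "concavity_label",
    "refinement",
    "build_report",
]


# --------------------------------------------------------------------------
# assemblage-level sharp/blunt threshold


@dataclass
class ThresholdResult:
    """Trough of the pooled segment-angle distribution, if bimodal."""

    trough_deg: float | None
    rounded_deg: float
    mode_degs: tuple[float, ...] = ()
    unimodal: bool = False


def sharp_threshold(
    segment_mean_angles: np.ndarray,
    threshold_kde_floor_deg: float = 2.0,
    kde_grid_step_deg: float = 0.1,
    min_mode_separation_deg: float = 15.0,
    default_deg: float = 120.0,
) -> ThresholdResult:
    """Data-driven sharp/blunt cut from pooled segment mean angles.

    A Gaussian KDE of the pooled values typically shows two peaks — common
    sharp angles and common blunt angles. The threshold is the density
    minimum between the two highest peaks at least
    ``min_mode_separation_deg`` apart, also reported floored to the nearest
    multiple of 10 for cross-assemblage comparability. A unimodal
    distribution falls back to the default threshold.
    """
    values = np.asarray(segment_mean_angles, dtype=float)
    if values.size < 30:
        raise ValueError(
            "need at least 30 pooled segment angles for a data-driven "
            f"threshold (got {values.size}); use the default "
            f"{default_deg:g} deg"
        )
    grid = np.arange(0.0, 180.0 + 0.5 * kde_grid_step_deg, kde_grid_step_deg)
    bw = silverman_bandwidth(values, threshold_kde_floor_deg)
    dens = kde_on_grid(values, grid, bw)

    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if len(peaks) >= 2:
        order = peaks[np.argsort(dens[peaks])[::-1]]
        first = order[0]
        second = None
        for cand in order[1:]:
            if abs(grid[cand] - grid[first]) >= min_mode_separation_deg:
                second = cand
                break
    else:
        second = None
        first = peaks[0] if len(peaks) else None
    if second is None:
        return ThresholdResult(
            trough_deg=None,
            rounded_deg=default_deg,
            mode_degs=tuple(float(grid[p]) for p in ([first] if first is not None else [])),
            unimodal=True,
        )
    lo, hi = sorted((first, second))
    trough_idx = lo + int(np.argmin(dens[lo : hi + 1]))
    trough = float(grid[trough_idx])
    return ThresholdResult(
        trough_deg=trough,
        rounded_deg=float(math.floor(trough / 10.0) * 10.0),
        mode_degs=(float(grid[first]), float(grid[second])),
        unimodal=False,
    )


# --------------------------------------------------------------------------
# per-segment classification and lengths


def segment_arc_lengths(
    outline: Outline3D, seg: SegmentationResult
) -> np.ndarray:
    """3D arc length of each segment; sums exactly to the perimeter."""
    closed = np.vstack([outline.coords, outline.coords[:1]])
    gaps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    lengths = []
    for a, b in seg.segment_slices():
        lengths.append(gaps[a:b].sum())
    return np.asarray(lengths)


def classify_segments(
    seg: SegmentationResult, sharp_threshold_deg: float = 120.0
) -> np.ndarray:
    """Sharp (True) / blunt (False) per segment: mean strictly below the
    threshold is sharp; a mean exactly at the threshold is blunt."""
    means = np.asarray(seg.segment_means)
    return means < sharp_threshold_deg


def percent_sharp(
    outline: Outline3D, seg: SegmentationResult, is_sharp: np.ndarray
) -> float:
    """Percent of the 3D perimeter covered by sharp segments."""
    lengths = segment_arc_lengths(outline, seg)
    return float(100.0 * lengths[is_sharp].sum() / lengths.sum())


# --------------------------------------------------------------------------
# transverse asymmetry


def transverse_asymmetry_profile(
    mesh: OrientedMesh,
    outline: Outline3D,
    vertex_angles: VertexAngles,
    band_mask: np.ndarray,
    knn_profile: int = 50,
    kde_bw_floor_unit: float = 0.01,
    kde_grid_step_unit: float = 0.001,
) -> np.ndarray:
    """Per-outline-coordinate ratio of the two half-angles of the edge.

    At each band vertex ``v`` (with opposing partner ``o`` and outline
    foot ``e``) the edge angle is split by the horizontal unit vector
    ``h`` from ``e`` toward the plan-view centroid: the upper half-angle
    is between ``v - e`` and ``h``, the lower between ``o - e`` and ``h``.
    The per-vertex ratio min/max lies in (0, 1] — 1 is a perfectly
    symmetric section, plano-convex edges approach 0. Ratios are
    aggregated onto outline coordinates by the same k-nearest KDE-mode
    estimator as the angle profile.
    """
    vertices = mesh.vertices
    valid = (
        band_mask
        & (vertex_angles.opposing >= 0)
        & np.isfinite(vertex_angles.angle)
    )
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        raise GeometryError("no band vertices available for asymmetry")

    v = vertices[idx]
    o = vertices[vertex_angles.opposing[idx]]
    e = _nearest_on_polyline(outline.coords, v)
    h = np.zeros_like(e)
    h[:, :2] = outline.plan_centroid[None, :] - e[:, :2]
    norm = np.linalg.norm(h, axis=1)
    usable = norm > 1e-12
    if not usable.all():
        logger.warning(
            "%d vertices at the plan centroid skipped", (~usable).sum()
        )
    h[usable] /= norm[usable, None]

    def half_angle(p: np.ndarray) -> np.ndarray:
        u = p - e
        cross = np.linalg.norm(np.cross(u, h), axis=1)
        dot = np.einsum("ij,ij->i", u, h)
        return np.degrees(np.arctan2(cross, dot))

    up = half_angle(v)
    down = half_angle(o)
    hi = np.maximum(up, down)
    lo = np.minimum(up, down)
    ratio = np.where(hi > 1e-12, lo / np.maximum(hi, 1e-12), 1.0)
    idx = idx[usable]
    ratio = ratio[usable]

    k = min(knn_profile, idx.size)
    tree = cKDTree(vertices[idx])
    _, j = tree.query(outline.coords, k=k)
    if k == 1:
        j = j[:, None]
    samples = ratio[j]
    if k < 5:
        return np.median(samples, axis=1)
    return kde_mode_rows(
        samples,
        lo=0.0,
        hi=1.0,
        step=kde_grid_step_unit,
        bw_floor=kde_bw_floor_unit,
    )


# --------------------------------------------------------------------------
# surface concavity


def vertex_concavity(
    mesh: OrientedMesh,
    concavity_k: int = 60,
    concavity_outer_m: int = 20,
    planar_eps: float = 5e-3,
) -> np.ndarray:
    """Per-vertex surface concavity in [0, 1].

    Each vertex is compared with the outermost ``concavity_outer_m`` of
    its ``concavity_k`` nearest neighbors: with ``s`` the projection of
    the normal difference ``n_j - n_i`` onto the unit separation
    direction, normals tilting away from each other (s > eps) vote
    convex, toward each other (s < -eps) concave, and near-parallel
    normals planar. The unit-direction projection makes the test exactly
    invariant under uniform scaling (normals do not scale). The score is
    (convex votes + half the planar votes) / m: 0 on a bowl interior,
    0.5 on a plane, 1 on a sphere.
    """
    vertices = mesh.vertices
    k = min(concavity_k, len(vertices) - 1)
    m = min(concavity_outer_m, k)
    tm = mesh.mesh.as_trimesh()
    normals = np.asarray(tm.vertex_normals)
    if not np.isfinite(normals).all():
        raise GeometryError("mesh normals are not orientable")

    tree = cKDTree(vertices)
    _, neigh = tree.query(vertices, k=k + 1)
    outer = neigh[:, -m:]  # query returns sorted distances; farthest last
    dp = vertices[outer] - vertices[:, None, :]
    dp = dp / np.maximum(np.linalg.norm(dp, axis=2), 1e-300)[:, :, None]
    dn = normals[outer] - normals[:, None, :]
    s = np.einsum("ijk,ijk->ij", dp, dn)
    away = (s > planar_eps).sum(axis=1)
    planar = (np.abs(s) <= planar_eps).sum(axis=1)
    return (away + 0.5 * planar) / m


def face_concavity_profile(
    mesh: OrientedMesh,
    outline: Outline3D,
    faces: FaceLabels,
    band_mask: np.ndarray,
    concavity: np.ndarray,
    knn_profile: int = 50,
    kde_bw_floor_unit: float = 0.01,
    kde_grid_step_unit: float = 0.001,
) -> np.ndarray:
    """(upper, lower) concavity at each outline coordinate.

    KDE-mode aggregation of per-vertex concavity over the k nearest band
    vertices of each face separately; NaN where a face has no band
    vertices (logged).
    """
    out = np.full((outline.n, 2), np.nan)
    for col, label_mask in enumerate((faces.upper, faces.lower)):
        idx = np.flatnonzero(band_mask & label_mask)
        if idx.size == 0:
            logger.warning(
                "no band vertices on %s face; concavity undefined",
                "upper" if col == 0 else "lower",
            )
            continue
        k = min(knn_profile, idx.size)
        tree = cKDTree(mesh.vertices[idx])
        _, j = tree.query(outline.coords, k=k)
        if k == 1:
            j = j[:, None]
        samples = concavity[idx[j]]
        if k < 5:
            out[:, col] = np.median(samples, axis=1)
        else:
            out[:, col] = kde_mode_rows(
                samples,
                lo=0.0,
                hi=1.0,
                step=kde_grid_step_unit,
                bw_floor=kde_bw_floor_unit,
            )
    return out


_CATEGORY_ORDER = {"concave": 0, "planar": 1, "convex": 2}


def concavity_label(
    pair: tuple[float, float],
    concavity_low: float = 0.4,
    concavity_high: float = 0.6,
) -> str:
    """Categorical label for a (face, face) concavity pair, sorted so the
    label does not depend on face order (e.g. always 'concave-planar')."""
    cats = []
    for value in pair:
        if np.isnan(value):
            cats.append("undefined")
        elif value < concavity_low:
            cats.append("concave")
        elif value > concavity_high:
            cats.append("convex")
        else:
            cats.append("planar")
    cats.sort(key=lambda c: _CATEGORY_ORDER.get(c, 3))
    return "-".join(cats)


# --------------------------------------------------------------------------
# whole-artifact measures


def refinement(mesh: OrientedMesh) -> float:
    """Width over thickness (x extent / z extent) of the oriented mesh."""
    extents = mesh.extents()
    if extents[2] <= 0:
        raise GeometryError("zero thickness")
    return float(extents[0] / extents[2])


# --------------------------------------------------------------------------
# report assembly


@dataclass
class EdgeSegment:
    """One discrete edge segment and its measurements."""

    index_range: tuple[int, int]
    arc_length: float
    mean_angle: float
    is_sharp: bool
    asymmetry: float
    concavity_upper: float
    concavity_lower: float
    concavity_label: str


@dataclass
class ArtifactReport:
    """Full per-artifact result row."""

    artifact_id: str
    n_segments: int
    n_sharp_edges: int
    percent_sharp_perimeter: float
    perimeter: float
    refinement: float
    threshold_used: float
    segments: list[EdgeSegment] = field(default_factory=list)
    terminal_means_close: bool = False
    provenance: dict = field(default_factory=dict)

    def segment_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.segments):
            rows.append(
                {
                    "artifact_id": self.artifact_id,
                    "segment_index": i,
                    "start_coord": s.index_range[0],
                    "end_coord": s.index_range[1],
                    "arc_length": s.arc_length,
                    "mean_angle": s.mean_angle,
                    "is_sharp": s.is_sharp,
                    "asymmetry": s.asymmetry,
                    "concavity_upper": s.concavity_upper,
                    "concavity_lower": s.concavity_lower,
                    "concavity_label": s.concavity_label,
                }
            )
        return pd.DataFrame(rows)

    def summary_row(self) -> dict:
        return {
            "artifact_id": self.artifact_id,
            "n_segments": self.n_segments,
            "n_sharp_edges": self.n_sharp_edges,
            "percent_sharp": self.percent_sharp_perimeter,
            "perimeter": self.perimeter,
            "refinement": self.refinement,
            "threshold_used": self.threshold_used,
            "terminal_means_close": self.terminal_means_close,
        }


def build_report(
    artifact_id: str,
    mesh: OrientedMesh,
    outline: Outline3D,
    profile: EdgeAngleProfile,
    seg: SegmentationResult,
    asymmetry_profile: np.ndarray,
    concavity_profile: np.ndarray,
    sharp_threshold_deg: float = 120.0,
    concavity_low: float = 0.4,
    concavity_high: float = 0.6,
    provenance: dict | None = None,
) -> ArtifactReport:
    """Assemble per-segment metrics and whole-artifact summaries.

    Segment-level asymmetry and concavity are the means of the
    per-coordinate profiles over the segment's coordinates.
    """
    for name, value in (
        ("outline", outline),
        ("profile", profile),
        ("segmentation", seg),
        ("asymmetry profile", asymmetry_profile),
        ("concavity profile", concavity_profile),
    ):
        if value is None:
            raise ValueError(f"cannot assemble report: missing {name} stage")
    lengths = segment_arc_lengths(outline, seg)
    sharp = classify_segments(seg, sharp_threshold_deg)
    segments = []
    for i, (a, b) in enumerate(seg.segment_slices()):
        pair = (
            float(np.nanmean(concavity_profile[a:b, 0])),
            float(np.nanmean(concavity_profile[a:b, 1])),
        )
        segments.append(
            EdgeSegment(
                index_range=(a, b),
                arc_length=float(lengths[i]),
                mean_angle=float(seg.segment_means[i]),
                is_sharp=bool(sharp[i]),
                asymmetry=float(np.nanmean(asymmetry_profile[a:b])),
                concavity_upper=pair[0],
                concavity_lower=pair[1],
                concavity_label=concavity_label(
                    pair, concavity_low, concavity_high
                ),
            )
        )
    return ArtifactReport(
        artifact_id=artifact_id,
        n_segments=len(segments),
        n_sharp_edges=int(sharp.sum()),
        percent_sharp_perimeter=percent_sharp(outline, seg, sharp),
        perimeter=outline_perimeter(outline),
        refinement=refinement(mesh),
        threshold_used=sharp_threshold_deg,
        segments=segments,
        terminal_means_close=seg.terminal_means_close,
        provenance=provenance or {},
    )
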