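"""End-to-end analysis of a single artifact mesh.

Stages: read/clean -> orient -> rescale to unit length -> resample to the
common vertex count -> detect the 3D perimeter outline -> continuous edge
angle profile -> change-point segmentation -> per-segment metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ceam import (
    EdgeAngleProfile,
    FaceLabels,
    VertexAngles,
    assign_faces,
    ceam_profile,
    outer_band,
    vertex_edge_angles,
)
from .config import RunConfig
from .mesh_core import (
    OrientedMesh,
    TriMesh,
    orient_artifact,
    read_mesh,
    resample_mesh,
    rescale_mesh,
)
from .metrics import (
    ArtifactReport,
    build_report,
    face_concavity_profile,
    transverse_asymmetry_profile,
    vertex_concavity,
)
from .outline import Outline3D, detect_outline
from .segmentation import SegmentationResult, segment_profile

logger = logging.getLogger(__name__)

__all__ = ["ArtifactAnalysis", "analyze_mesh", "analyze_path"]


@dataclass
class ArtifactAnalysis:
    """Everything the pipeline computed for one artifact."""

    report: ArtifactReport
    mesh: OrientedMesh
    outline: Outline3D
    profile: EdgeAngleProfile
    segmentation: SegmentationResult
    faces: FaceLabels
    vertex_angles: VertexAngles
    band_mask: np.ndarray
    asymmetry_profile: np.ndarray
    concavity_profile: np.ndarray


def analyze_mesh(
    mesh: TriMesh,
    config: RunConfig | None = None,
    artifact_id: str = "artifact",
    rotation: np.ndarray | None = None,
) -> ArtifactAnalysis:
    """Run the full edge-analysis pipeline on an in-memory mesh."""
    cfg = config or RunConfig()
    oriented = orient_artifact(mesh, rotation=rotation)
    resampled = resample_mesh(oriented.mesh, cfg.target_vertices)
    oriented = OrientedMesh(
        resampled, rotation=oriented.rotation, ambiguous=oriented.ambiguous
    )
    oriented = rescale_mesh(oriented)

    outline = detect_outline(
        oriented,
        alpha=cfg.alpha,
        alpha_grid_factor=cfg.alpha_grid_factor,
        outline_points=cfg.outline_points,
        parallel_threshold_deg=cfg.parallel_threshold_deg,
        blunt_k=cfg.blunt_k,
        blunt_face_k=cfg.blunt_face_k,
    )
    faces = assign_faces(oriented, outline)
    vangles = vertex_edge_angles(oriented, outline, faces)
    band = outer_band(oriented, outline, cfg.band_fraction)
    profile = ceam_profile(
        vangles,
        outline,
        band,
        oriented,
        knn_profile=cfg.knn_profile,
        kde_bw_floor_deg=cfg.kde_bw_floor_deg,
        kde_grid_step_deg=cfg.kde_grid_step_deg,
        band_fraction=cfg.band_fraction,
    )
    seg = segment_profile(
        profile.angle,
        kmax=cfg.kmax,
        min_seg=cfg.min_seg,
        elbow_min_drop=cfg.elbow_min_drop,
    )
    asym = transverse_asymmetry_profile(
        oriented,
        outline,
        vangles,
        band,
        knn_profile=cfg.knn_profile,
        kde_bw_floor_unit=cfg.kde_bw_floor_unit,
        kde_grid_step_unit=cfg.kde_grid_step_unit,
    )
    concavity = vertex_concavity(
        oriented,
        concavity_k=cfg.concavity_k,
        concavity_outer_m=cfg.concavity_outer_m,
        planar_eps=cfg.planar_eps,
    )
    conc_profile = face_concavity_profile(
        oriented,
        outline,
        faces,
        band,
        concavity,
        knn_profile=cfg.knn_profile,
        kde_bw_floor_unit=cfg.kde_bw_floor_unit,
        kde_grid_step_unit=cfg.kde_grid_step_unit,
    )
    provenance = {
        "config": cfg.to_dict(),
        "mesh": dict(resampled.provenance),
        "orientation_ambiguous": bool(oriented.ambiguous),
    }
    report = build_report(
        artifact_id,
        oriented,
        outline,
        profile,
        seg,
        asym,
        conc_profile,
        sharp_threshold_deg=cfg.sharp_threshold_deg,
        concavity_low=cfg.concavity_low,
        concavity_high=cfg.concavity_high,
        provenance=provenance,
    )
    return ArtifactAnalysis(
        report=report,
        mesh=oriented,
        outline=outline,
        profile=profile,
        segmentation=seg,
        faces=faces,
        vertex_angles=vangles,
        band_mask=band,
        asymmetry_profile=asym,
        concavity_profile=conc_profile,
    )


def _sidecar_rotation(path: Path, rotation_dir: str | None) -> np.ndarray | None:
    """Load a 3x3 rotation for an artifact from a 9-number JSON sidecar."""
    candidates = [path.with_suffix(".rotation.json")]
    if rotation_dir:
        candidates.append(Path(rotation_dir) / (path.stem + ".rotation.json"))
    for cand in candidates:
        if cand.exists():
            data = json.loads(cand.read_text())
            matrix = np.asarray(data, dtype=float).reshape(3, 3)
            logger.info("using rotation sidecar %s", cand)
            return matrix
    return None


def analyze_path(
    path: str | Path,
    config: RunConfig | None = None,
    rotation: np.ndarray | None = None,
) -> ArtifactAnalysis:
    """Read a mesh file and analyze it; rotation sidecars are honored."""
    path = Path(path)
    cfg = config or RunConfig()
    if rotation is None:
        rotation = _sidecar_rotation(path, cfg.rotation_dir)
    mesh = read_mesh(path)
    return analyze_mesh(
        mesh, config=cfg, artifact_id=path.stem, rotation=rotation
    )
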