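"""Run configuration: every tunable of the pipeline in one serializable place.

Defaults reproduce the standard analysis conditions: meshes normalized to
50,000 vertices and unit length, outlines to 1000 coordinates, angles taken
from the outer 20% of surface area, and a 120-degree sharp/blunt threshold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunables of the edge-analysis pipeline.

    Attributes
    ----------
    target_vertices:
        Mesh resolution every artifact is resampled to before analysis.
    outline_points:
        Number of coordinates of the resampled perimeter outline.
    band_fraction:
        Fraction of total surface area nearest the outline used for angle,
        asymmetry and concavity aggregation (the "outer band").
    knn_profile:
        Neighborhood size k when aggregating per-vertex values onto each
        outline coordinate by KDE mode.
    alpha:
        Alpha-shape radius for outline detection; ``None`` selects the
        smallest value on a geometric grid that yields a single simple loop.
    alpha_grid_factor:
        Multiplicative step of the automatic alpha search grid.
    parallel_threshold_deg:
        A perimeter region counts as blunt when nearby face normals are
        within this many degrees of the x-y plane.
    blunt_face_k:
        Number of nearest faces averaged when testing normal parallelism.
    blunt_k:
        Number of nearest mesh vertices whose mean z replaces the outline z
        over blunt regions.
    kmax:
        Largest change-point count scanned during segmentation.
    min_seg:
        Minimum segment length in outline coordinates.
    elbow_min_drop:
        Minimum relative residual drop over the whole curve for any change
        point to be accepted (below it the profile counts as one segment).
    sharp_threshold_deg:
        Segment-mean angle at or above which a segment is labeled blunt.
    concavity_k:
        Neighborhood size for per-vertex surface concavity.
    concavity_outer_m:
        Of the ``concavity_k`` neighbors, only the farthest m take part in
        the normal-direction comparison.
    planar_eps:
        |(dp . dn)| below this counts as planar in the concavity sign test.
    concavity_low, concavity_high:
        Category cutoffs: below low = concave, above high = convex.
    kde_bw_floor_deg:
        Bandwidth floor (degrees) for angle-valued KDE modes.
    kde_grid_step_deg:
        Grid resolution (degrees) for angle-valued KDE modes.
    kde_bw_floor_unit:
        Bandwidth floor for unit-interval values (asymmetry, concavity).
    kde_grid_step_unit:
        Grid resolution for unit-interval values.
    threshold_kde_floor_deg:
        Bandwidth floor for the pooled assemblage angle distribution.
    seed:
        Seed forwarded to any stochastic step (synthetic jitter only; the
        measurement pipeline itself is deterministic).
    """

    target_vertices: int = 50_000
    outline_points: int = 1000
    band_fraction: float = 0.20
    knn_profile: int = 50
    alpha: float | None = None
    alpha_grid_factor: float = 1.3
    parallel_threshold_deg: float = 15.0
    blunt_face_k: int = 30
    blunt_k: int = 50
    kmax: int = 10
    min_seg: int = 25
    elbow_min_drop: float = 0.15
    sharp_threshold_deg: float = 120.0
    concavity_k: int = 60
    concavity_outer_m: int = 20
    planar_eps: float = 5e-3
    concavity_low: float = 0.4
    concavity_high: float = 0.6
    kde_bw_floor_deg: float = 0.5
    kde_grid_step_deg: float = 0.1
    kde_bw_floor_unit: float = 0.01
    kde_grid_step_unit: float = 0.001
    threshold_kde_floor_deg: float = 2.0
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None
    rotation_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from JSON or TOML, by extension."""
        path = Path(path)
        if path.suffix.lower() == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls.from_dict(data)

    # Fields that parametrize the science (as opposed to I/O plumbing);
    # the config-coverage test checks pipeline signatures against this set.
    TUNABLES = (
        "target_vertices",
        "outline_points",
        "band_fraction",
        "knn_profile",
        "alpha",
        "alpha_grid_factor",
        "parallel_threshold_deg",
        "blunt_face_k",
        "blunt_k",
        "kmax",
        "min_seg",
        "elbow_min_drop",
        "sharp_threshold_deg",
        "concavity_k",
        "concavity_outer_m",
        "planar_eps",
        "concavity_low",
        "concavity_high",
        "kde_bw_floor_deg",
        "kde_grid_step_deg",
        "kde_bw_floor_unit",
        "kde_grid_step_unit",
        "threshold_kde_floor_deg",
        "seed",
    )
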