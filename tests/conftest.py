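"""Shared fixtures: analyzed synthetic shapes, built once per session.

The heavy fixtures run the full pipeline at the standard 50,000-vertex
resolution; unit tests that only need a mesh topology use much smaller
shapes built inline.
"""

from __future__ import annotations

import numpy as np
import pytest

from lithedge.config import RunConfig
from lithedge.mesh_core import (
    orient_artifact,
    rescale_mesh,
    resample_mesh,
)
from lithedge.outline import detect_outline
from lithedge.ceam import compute_profile
from lithedge.pipeline import analyze_mesh
from lithedge.shapes import (
    lens_radius_for_cr,
    make_blunt_lens,
    make_lens,
    make_octahedron,
)

IDENTITY = np.eye(3)


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def octa_profile():
    """Full outline+CEAM pipeline on a ~50k-vertex regular octahedron."""
    mesh = resample_mesh(make_octahedron(7), 50_000)
    oriented = rescale_mesh(orient_artifact(mesh, rotation=IDENTITY))
    outline = detect_outline(oriented)
    profile, vangles, band = compute_profile(oriented, outline)
    return {
        "mesh": oriented,
        "outline": outline,
        "profile": profile,
        "vertex_angles": vangles,
        "band": band,
    }


@pytest.fixture(scope="session", params=[0.3, 0.5, 0.7, 0.9])
def lens_profile(request):
    """Equal-cap lens pipelines across the cap-shallowness range."""
    c_over_r = request.param
    R = lens_radius_for_cr(c_over_r, 0.4)
    mesh, oracle = make_lens(R, R, 0.4, n=50_000)
    resampled = resample_mesh(mesh, 50_000)
    oriented = rescale_mesh(orient_artifact(resampled, rotation=IDENTITY))
    outline = detect_outline(oriented)
    profile, vangles, band = compute_profile(oriented, outline)
    return {
        "c_over_r": c_over_r,
        "oracle": oracle,
        "mesh": oriented,
        "outline": outline,
        "profile": profile,
    }


@pytest.fixture(scope="session")
def blunt_lens_analysis():
    """Full analysis of the standard blunt-banded lens (f = 0.25)."""
    R = lens_radius_for_cr(0.7, 0.4)
    mesh, oracle = make_blunt_lens(R, R, 0.4, f=0.25, n=50_000)
    analysis = analyze_mesh(mesh, RunConfig(), "blunt_lens", rotation=IDENTITY)
    return {"oracle": oracle, "analysis": analysis}


@pytest.fixture(scope="session")
def asymmetric_lens_analysis():
    """Full analysis of the asymmetric lens (a=0.32, R_up=0.4, R_down=0.8)."""
    mesh, oracle = make_lens(0.4, 0.8, 0.32, n=50_000)
    analysis = analyze_mesh(mesh, RunConfig(), "asym_lens", rotation=IDENTITY)
    return {"oracle": oracle, "analysis": analysis}


@pytest.fixture(scope="session")
def small_lens():
    """A quick ~8k-vertex symmetric lens for structural tests."""
    R = lens_radius_for_cr(0.5, 0.4)
    mesh, oracle = make_lens(R, R, 0.4, n=8_000)
    return mesh, oracle
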