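"""Parametric test solids with closed-form edge geometry.

Real handaxe scans have no ground truth, so every stage of the pipeline is
validated on shapes whose edge properties are known exactly:

* a regular octahedron, whose equatorial dihedral is ``arccos(-1/3)``
  (109.4712 degrees) along every edge;
* biconvex "lenses" — two spherical caps sharing a rim circle — whose edge
  angle is ``arcsin(a/R_up) + arcsin(a/R_down)`` everywhere on the rim, and
  whose transverse asymmetry is the ratio of those two arcsines;
* lenses with a vertical blunt band over a known fraction of the rim;
* plano-convex and dished-top ("bowl") variants for asymmetry and
  concavity checks;
* a closed cylinder (every perimeter point blunt);
* piecewise-constant noisy signals for the change-point machinery.

All generators are deterministic given their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh_core import TriMesh, _cleanup

__all__ = [
    "ShapeOracle",
    "make_octahedron",
    "make_lens",
    "lens_radius_for_cr",
    "make_blunt_lens",
    "make_plano_convex",
    "make_bowl_top",
    "make_cylinder",
    "make_piecewise_signal",
]

OCTAHEDRON_DIHEDRAL_DEG = math.degrees(math.acos(-1.0 / 3.0))


@dataclass
class ShapeOracle:
    """Closed-form ground truth attached to a generated shape."""

    edge_angle_deg: float | None = None
    half_angle_up_deg: float | None = None
    half_angle_down_deg: float | None = None
    asymmetry: float | None = None
    blunt_fraction: float | None = None
    band_height: float | None = None
    band_center_phi_deg: float | None = None
    params: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# octahedron


def make_octahedron(subdivision: int = 0) -> TriMesh:
    """Regular octahedron, equatorial square in the x-y plane.

    Midpoint subdivision WITHOUT reprojection keeps every face coplanar
    with the original eight, so the equatorial dihedral stays exactly
    ``arccos(-1/3)`` at any level. Level k has ``8 * 4**k`` faces.
    """
    if subdivision < 0:
        raise ValueError("subdivision must be >= 0")
    vertices = np.array(
        [
            [1.0, 0.0, 0.0],
            [-1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, -1.0, 0.0],
            [0.0, 0.0, 1.0],
            [0.0, 0.0, -1.0],
        ]
    )
    faces = np.array(
        [
            [0, 2, 4],
            [2, 1, 4],
            [1, 3, 4],
            [3, 0, 4],
            [2, 0, 5],
            [1, 2, 5],
            [3, 1, 5],
            [0, 3, 5],
        ],
        dtype=np.int64,
    )
    for _ in range(subdivision):
        vertices, faces = trimesh.remesh.subdivide(vertices, faces)
    return _finish(vertices, faces, {"shape": "octahedron", "level": subdivision})


# --------------------------------------------------------------------------
# revolved solids (lens family, cylinder, bowl)


def _ring_radii(a: float, z_of_r, h: float) -> np.ndarray:
    """Radii from rim inward with ~h spacing measured along the meridian."""
    radii = [a]
    r = a
    while r > 0.75 * h:
        dr = 1e-4 * a
        rp = max(r - dr, 0.0)
        slope = (z_of_r(r) - z_of_r(rp)) / dr
        step = h / math.sqrt(1.0 + slope * slope)
        r = r - min(step, h)
        if r <= 0.75 * h:
            break
        radii.append(r)
    return np.asarray(radii)


def _build_surface(
    radii: np.ndarray,
    phi: np.ndarray,
    z_fn,
    apex_z: float,
    flip: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Quad-grid triangulation of one revolved surface, rim ring first."""
    m = len(phi)
    rings = []
    for r in radii:
        x = r * np.cos(phi)
        y = r * np.sin(phi)
        z = z_fn(np.full(m, r), phi)
        rings.append(np.column_stack([x, y, z]))
    vertices = np.vstack(rings + [np.array([[0.0, 0.0, apex_z]])])
    apex = len(vertices) - 1
    faces = []
    for j in range(len(radii) - 1):
        base0 = j * m
        base1 = (j + 1) * m
        for i in range(m):
            i2 = (i + 1) % m
            faces.append([base0 + i, base0 + i2, base1 + i])
            faces.append([base0 + i2, base1 + i2, base1 + i])
    base = (len(radii) - 1) * m
    for i in range(m):
        i2 = (i + 1) % m
        faces.append([base + i, base + i2, apex])
    faces = np.asarray(faces, dtype=np.int64)
    if flip:
        faces = faces[:, ::-1]
    return vertices, faces


def _revolved_solid(
    a: float,
    z_up,
    z_low,
    n_target: int,
    seed: int,
    provenance: dict,
    wall_jitter: float = 0.0,
) -> TriMesh:
    """Closed solid of revolution-like mesh from two surface height fields.

    ``z_up(r, phi)`` and ``z_low(r, phi)`` give the two faces over the plan
    disk of radius ``a``; where they disagree at the rim a vertical wall of
    quad strips closes the solid. ``wall_jitter`` adds a tiny seeded radial
    perturbation to interior wall rows so projected wall points are not
    exact 2D duplicates (as in a real scan).
    """
    rng = np.random.default_rng(seed)

    # estimate area to pick the sampling step; two passes to hit n_target.
    # overshoot slightly: downstream resolution normalization decimates
    # gracefully, whereas a shortfall forces subdivide-then-deep-decimate
    n_target = int(n_target * 1.04)
    h = a / math.sqrt(max(n_target, 16) / 14.0)
    for _ in range(2):
        phi_probe = np.array([0.0])
        up_of_r = lambda r: float(z_up(np.array([r]), phi_probe)[0])
        low_of_r = lambda r: float(z_low(np.array([r]), phi_probe)[0])
        radii_up = _ring_radii(a, up_of_r, h)
        radii_low = _ring_radii(a, low_of_r, h)
        m = max(12, int(round(2.0 * math.pi * a / h)))
        count = m * (len(radii_up) + len(radii_low))
        h = h * math.sqrt(count / n_target)
    phi = 2.0 * math.pi * np.arange(m) / m

    v_up, f_up = _build_surface(
        radii_up, phi, z_up, float(z_up(np.zeros(1), np.zeros(1))[0]), flip=False
    )
    v_low, f_low = _build_surface(
        radii_low, phi, z_low, float(z_low(np.zeros(1), np.zeros(1))[0]), flip=True
    )

    parts_v = [v_up, v_low]
    parts_f = [f_up, f_low + len(v_up)]
    offset = len(v_up) + len(v_low)

    # wall between the two rim rings where they are separated
    rim_top = z_up(np.full(m, a), phi)
    rim_bot = z_low(np.full(m, a), phi)
    gap = rim_top - rim_bot
    if np.any(gap > 1e-12):
        n_rows = max(1, int(math.ceil(float(gap.max()) / h)))
        rows = [v_up[:m]]  # top rim ring of the upper surface
        open_col = gap > 1e-9  # collapsed columns must merge with the rim
        for l in range(1, n_rows):
            t = l / n_rows
            z = rim_top + t * (rim_bot - rim_top)
            r = a + wall_jitter * rng.uniform(-1.0, 1.0, size=m) * open_col
            rows.append(
                np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
            )
        rows.append(v_low[:m])  # bottom rim ring of the lower surface
        row_index = []
        for row_id, row in enumerate(rows):
            if row_id == 0:
                row_index.append(np.arange(m))
            elif row_id == len(rows) - 1:
                row_index.append(np.arange(m) + len(v_up))
            else:
                parts_v.append(row)
                row_index.append(np.arange(m) + offset)
                offset += m
        wall_faces = []
        for row_id in range(len(rows) - 1):
            top, bot = row_index[row_id], row_index[row_id + 1]
            for i in range(m):
                i2 = (i + 1) % m
                wall_faces.append([top[i], bot[i], top[i2]])
                wall_faces.append([top[i2], bot[i], bot[i2]])
        parts_f.append(np.asarray(wall_faces, dtype=np.int64))

    vertices = np.vstack(parts_v)
    faces = np.vstack(parts_f)
    return _finish(vertices, faces, provenance)


def _finish(vertices: np.ndarray, faces: np.ndarray, provenance: dict) -> TriMesh:
    mesh = _cleanup(vertices, faces, provenance)
    tm = mesh.as_trimesh()
    trimesh.repair.fix_normals(tm)
    if tm.volume < 0:
        tm.invert()
    return TriMesh(
        np.asarray(tm.vertices, float),
        np.asarray(tm.faces, np.int64),
        mesh.provenance,
    )


def lens_radius_for_cr(c_over_r: float, a: float) -> float:
    """Cap sphere radius giving ``c/R = c_over_r`` for rim radius ``a``.

    With cap offset ``c = sqrt(R^2 - a^2)``, the half-angle of each face at
    the rim is ``arccos(c/R) = arcsin(a/R)``; the edge angle of an equal-cap
    lens is ``2 * arccos(c/R)``.
    """
    if not 0.0 < c_over_r < 1.0:
        raise ValueError("c/R must lie in (0, 1)")
    return a / math.sqrt(1.0 - c_over_r * c_over_r)


def _cap_fn(R: float, a: float, sign: float):
    c = math.sqrt(R * R - a * a)

    def z(r: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return sign * (np.sqrt(np.maximum(R * R - r * r, 0.0)) - c)

    return z


def _lens_oracle(R_up: float, R_down: float, a: float) -> ShapeOracle:
    half_up = math.degrees(math.asin(a / R_up))
    half_down = math.degrees(math.asin(a / R_down))
    return ShapeOracle(
        edge_angle_deg=half_up + half_down,
        half_angle_up_deg=half_up,
        half_angle_down_deg=half_down,
        asymmetry=min(half_up, half_down) / max(half_up, half_down),
        params={"R_up": R_up, "R_down": R_down, "a": a},
    )


def make_lens(
    R_up: float,
    R_down: float,
    a: float = 0.4,
    n: int = 50_000,
    seed: int = 0,
) -> tuple[TriMesh, ShapeOracle]:
    """Biconvex lens: two spherical caps sharing the rim circle r = a, z = 0.

    The sharp rim forms an edge of angle ``arcsin(a/R_up) +
    arcsin(a/R_down)`` everywhere, with transverse half-angles given by the
    two arcsines individually.
    """
    if a >= min(R_up, R_down):
        raise ValueError("rim radius must be smaller than both cap radii")
    mesh = _revolved_solid(
        a,
        _cap_fn(R_up, a, +1.0),
        _cap_fn(R_down, a, -1.0),
        n,
        seed,
        {"shape": "lens", "R_up": R_up, "R_down": R_down, "a": a},
    )
    return mesh, _lens_oracle(R_up, R_down, a)


def make_blunt_lens(
    R_up: float,
    R_down: float,
    a: float = 0.4,
    f: float = 0.25,
    band_height: float = 0.08,
    n: int = 50_000,
    seed: int = 0,
    taper: float = 0.005,
) -> tuple[TriMesh, ShapeOracle]:
    """Lens whose rim is replaced by a vertical band over arc fraction ``f``.

    The band is a cylindrical wall of the given height, symmetric about
    z = 0, centered on the -y side of the rim (opposite the tip) and blended
    into the sharp rim by a linear taper spanning ``taper`` of the perimeter
    at each end. The sharp remainder keeps the closed-form lens edge angle.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("blunt fraction must lie in (0, 1)")
    if band_height <= 0:
        raise ValueError("band height must be positive")
    if a >= min(R_up, R_down):
        raise ValueError("rim radius must be smaller than both cap radii")

    center = 1.5 * math.pi  # -y side; outline phase starts at the tip (+y)
    half_width = f * math.pi  # half the band arc, in radians

    def weight(phi: np.ndarray) -> np.ndarray:
        d = np.abs((phi - center + math.pi) % (2.0 * math.pi) - math.pi)
        ramp = taper * 2.0 * math.pi
        return np.clip((half_width - d) / ramp + 1.0, 0.0, 1.0) * (
            d < half_width + ramp
        )

    up_cap = _cap_fn(R_up, a, +1.0)
    low_cap = _cap_fn(R_down, a, -1.0)

    def z_up(r: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return up_cap(r, phi) + 0.5 * band_height * weight(phi) * (r / a) ** 6

    def z_low(r: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return low_cap(r, phi) - 0.5 * band_height * weight(phi) * (r / a) ** 6

    mesh = _revolved_solid(
        a,
        z_up,
        z_low,
        n,
        seed,
        {
            "shape": "blunt_lens",
            "R_up": R_up,
            "R_down": R_down,
            "a": a,
            "f": f,
            "band_height": band_height,
        },
        wall_jitter=2e-4 * a,
    )
    oracle = _lens_oracle(R_up, R_down, a)
    oracle.blunt_fraction = f
    oracle.band_height = band_height
    oracle.band_center_phi_deg = math.degrees(center)
    return mesh, oracle


def make_plano_convex(
    R_down: float,
    a: float = 0.4,
    cone_angle_deg: float = 2.0,
    n: int = 50_000,
    seed: int = 0,
) -> tuple[TriMesh, ShapeOracle]:
    """Near-flat-topped lens: a shallow cone over a convex lower cap.

    The upper face is a cone of ``cone_angle_deg`` rising from the rim —
    flat enough to behave as the planar face of a plano-convex tool (the
    exact-plane limit would coincide with the rim plane and leave no upper
    face), yet meeting the lower cap directly at the rim with no wall. The
    upper transverse half-angle equals the cone angle, so the edge is
    maximally asymmetric; the upper surface is planar along the meridian
    and only negligibly curved azimuthally.
    """
    lift = a * math.tan(math.radians(cone_angle_deg))

    def z_up(r: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return lift * (1.0 - r / a)

    mesh = _revolved_solid(
        a,
        z_up,
        _cap_fn(R_down, a, -1.0),
        n,
        seed,
        {
            "shape": "plano_convex",
            "R_down": R_down,
            "a": a,
            "cone_angle_deg": cone_angle_deg,
        },
    )
    half_up = cone_angle_deg
    half_down = math.degrees(math.asin(a / R_down))
    return mesh, ShapeOracle(
        edge_angle_deg=half_up + half_down,
        half_angle_up_deg=half_up,
        half_angle_down_deg=half_down,
        asymmetry=min(half_up, half_down) / max(half_up, half_down),
        params={"R_down": R_down, "a": a, "cone_angle_deg": cone_angle_deg},
    )


def make_bowl_top(
    R_down: float,
    R_bowl: float = 2.0,
    a: float = 0.4,
    lift: float = 0.005,
    n: int = 50_000,
    seed: int = 0,
) -> tuple[TriMesh, ShapeOracle]:
    """Lens with a concave (dished) upper face and convex lower cap.

    The upper surface is a shallow spherical bowl (curvature center above
    the solid), raised so the whole dish stays above the rim plane; a short
    wall joins its rim to the lower cap. Upper-face concavity is uniformly
    concave, the lower face uniformly convex.
    """
    if R_bowl <= a:
        raise ValueError("bowl radius must exceed rim radius")
    cb = math.sqrt(R_bowl * R_bowl - a * a)

    def z_up(r: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return lift + (R_bowl - np.sqrt(np.maximum(R_bowl * R_bowl - r * r, 0.0)))

    mesh = _revolved_solid(
        a,
        z_up,
        _cap_fn(R_down, a, -1.0),
        n,
        seed,
        {"shape": "bowl_top", "R_down": R_down, "R_bowl": R_bowl, "a": a},
        wall_jitter=2e-4 * a,
    )
    return mesh, ShapeOracle(
        params={
            "R_down": R_down,
            "R_bowl": R_bowl,
            "a": a,
            "lift": lift,
            "bowl_depth": R_bowl - cb,
        }
    )


def make_cylinder(
    radius: float = 0.4,
    height: float = 0.3,
    n: int = 30_000,
    seed: int = 0,
) -> tuple[TriMesh, ShapeOracle]:
    """Closed vertical cylinder: the entire perimeter surface is blunt."""

    def z_up(r: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return np.full_like(r, 0.5 * height, dtype=float)

    def z_low(r: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return np.full_like(r, -0.5 * height, dtype=float)

    mesh = _revolved_solid(
        radius,
        z_up,
        z_low,
        n,
        seed,
        {"shape": "cylinder", "radius": radius, "height": height},
        wall_jitter=2e-4 * radius,
    )
    return mesh, ShapeOracle(
        blunt_fraction=1.0,
        band_height=height,
        params={"radius": radius, "height": height},
    )


# --------------------------------------------------------------------------
# signals


def make_piecewise_signal(
    means: list[float],
    lengths: list[int],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Concatenated Gaussian-noised constant blocks plus the ground truth.

    Returns ``(signal, truth)`` where ``truth`` holds the true breakpoint
    indices (block starts, excluding 0) and block means.
    """
    if len(means) != len(lengths):
        raise ValueError("means and lengths must have equal length")
    if any(l < 1 for l in lengths):
        raise ValueError("all block lengths must be >= 1")
    rng = np.random.default_rng(seed)
    blocks = [
        np.full(l, mu, dtype=float) for mu, l in zip(means, lengths)
    ]
    signal = np.concatenate(blocks)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.size)
    breakpoints = np.cumsum(lengths)[:-1].tolist()
    return signal, {"breakpoints": breakpoints, "means": list(means)}
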