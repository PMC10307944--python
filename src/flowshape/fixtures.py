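"""Seeded synthetic test geometries.

Every generator emits a valid closed genus-0 triangle mesh and is fully
deterministic given its parameters and seed.  The protrusion sphere is the
stress-test geometry for conformal-map area distortion (a sphere with one
or more finger-like protrusions of controlled length relative to the sphere
radius); the band-limited random shapes emulate a population of smooth
cell-like blobs with spectral power decaying as l^-2, mirroring the
empirically front-loaded power spectra of real cell meshes.
"""

from __future__ import annotations

import numpy as np
import trimesh as _trimesh

from .harmonics import SHCoefficients, sh_evaluate
from .mesh import TriangleMesh

__all__ = [
    "make_icosphere",
    "make_ellipsoid",
    "make_protrusion_sphere",
    "make_random_shape",
    "random_coefficients",
]


def make_icosphere(subdiv: int = 3, radius: float = 1.0) -> TriangleMesh:
    """Regular icosahedron subdivided ``subdiv`` times, projected to radius.

    Vertex count is 10 * 4**subdiv + 2 (2562 at the default reconstruction
    level of 4).
    """
    if subdiv < 0:
        raise ValueError("subdiv must be >= 0")
    tm = _trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    v = np.asarray(tm.vertices, float)
    v = v / np.linalg.norm(v, axis=1, keepdims=True) * radius
    return TriangleMesh(v, np.asarray(tm.faces))


def make_ellipsoid(a: float, b: float, c: float, subdiv: int = 3) -> TriangleMesh:
    """Icosphere scaled anisotropically to semi-axes (a, b, c)."""
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    s = make_icosphere(subdiv)
    return s.with_vertices(s.vertices * np.array([a, b, c]))


def _smooth_bump(t: np.ndarray) -> np.ndarray:
    """C1 radial profile: 1 at the apex (t=0), 0 with zero slope at t=1."""
    t = np.clip(t, 0.0, 1.0)
    return (1.0 - t * t) ** 2


def make_protrusion_sphere(
    length_ratio: float,
    width: float = 0.3,
    subdiv: int = 3,
    n_protrusions: int = 1,
    seed: int = 0,
    radius: float = 1.0,
) -> tuple[TriangleMesh, np.ndarray]:
    """Sphere with radial finger-like protrusions; returns (mesh, labels).

    Each protrusion displaces the vertices inside an angular cap of radius
    ``width`` outward along the radial direction, by a smooth C1 bump whose
    apex reaches ``length_ratio * radius`` above the sphere.  Cap centers are
    existing vertex directions chosen by the seeded RNG (so the apex height
    is exact) and are rejected if caps would overlap.  ``labels`` flags the
    vertices belonging to any protrusion cap.
    """
    if length_ratio < 0:
        raise ValueError("length_ratio must be >= 0")
    if not 0 < width < np.pi / 4:
        raise ValueError("width must be in (0, pi/4)")
    sphere = make_icosphere(subdiv, radius=radius)
    v = sphere.vertices.copy()
    n = len(v)
    labels = np.zeros(n, dtype=bool)
    if length_ratio == 0 or n_protrusions == 0:
        return sphere, labels
    rng = np.random.default_rng(seed)
    dirs = v / radius
    centers: list[np.ndarray] = []
    order = rng.permutation(n)
    for idx in order:
        c = dirs[idx]
        if all(np.arccos(np.clip(c @ p, -1, 1)) >= 2.5 * width for p in centers):
            centers.append(c)
        if len(centers) == n_protrusions:
            break
    if len(centers) < n_protrusions:
        raise ValueError(
            f"cannot place {n_protrusions} non-overlapping caps of width {width}"
        )
    disp = np.zeros(n)
    for c in centers:
        ang = np.arccos(np.clip(dirs @ c, -1.0, 1.0))
        cap = ang < width
        labels |= cap
        disp[cap] += length_ratio * radius * _smooth_bump(ang[cap] / width)
    v = v + disp[:, None] * dirs
    return TriangleMesh(v, sphere.faces), labels


def random_coefficients(
    lmax_gen: int = 12, amplitude: float = 0.15, seed: int = 0
) -> SHCoefficients:
    """Seeded Gaussian SH coefficients of a radial displacement field.

    Degrees 2..lmax_gen carry power decaying as l^-2 (degree 0 and 1 are
    zero: no net inflation, no first-order translation mode); within a
    degree the per-order variance is split evenly.
    """
    rng = np.random.default_rng(seed)
    coeffs = np.zeros((lmax_gen + 1) ** 2)
    for l in range(2, lmax_gen + 1):
        sigma = amplitude / l  # power S_l ~ amplitude^2 / l^2
        sl = slice(l * l, (l + 1) * (l + 1))
        coeffs[sl] = rng.normal(0.0, sigma / np.sqrt(2 * l + 1), size=2 * l + 1)
    return SHCoefficients(lmax_gen, coeffs)


def make_random_shape(
    lmax_gen: int = 12,
    amplitude: float = 0.15,
    seed: int = 0,
    subdiv: int = 3,
) -> TriangleMesh:
    """Unit icosphere with a seeded band-limited radial displacement field."""
    sphere = make_icosphere(subdiv)
    coeffs = random_coefficients(lmax_gen, amplitude, seed)
    u = sh_evaluate(coeffs, sphere.vertices)
    if u.min() <= -0.9:
        raise ValueError(
            f"self-intersecting displacement for seed {seed}: min 1+u = {1 + u.min():.3f}"
        )
    return sphere.with_vertices(sphere.vertices * (1.0 + u)[:, None])
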