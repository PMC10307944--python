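"""Conformal spherical parameterization and the curvature function.

A genus-0 surface is flowed to the unit sphere with conformalized mean
curvature flow (cMCF): implicit-Euler mean curvature flow whose stiffness
matrix is frozen at the initial cotangent Laplacian while the mass matrix is
rebuilt every step.  Freezing the stiffness is what makes the limit map
conformal and removes the neck-pinch singularities of plain MCF.

Because the limit map preserves angles, the original shape is fully encoded
(up to similarity) by a single scalar field on the sphere:

    rho = H * |df| / |df'|

the mean curvature times the local length ratio between the surface and its
spherical image.  Squaring the ratio gives the area distortion, so rho is
sampled per vertex as ``H_i * sqrt(A_i / A'_i)`` from barycentric vertex
areas on the (area-4*pi normalized) input and on the sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import (
    TriangleMesh,
    cotangent_laplacian,
    enclosed_volume,
    face_areas,
    face_normals,
    mean_curvature,
    normalize_mesh,
    require_valid,
    surface_area,
    vertex_areas,
)

__all__ = [
    "SphericalMap",
    "CurvatureFunction",
    "FlowDiagnostics",
    "sphericity",
    "cmcf",
    "curvature_function",
    "quasi_conformal_error",
    "count_flipped_faces",
]


@dataclass(frozen=True)
class SphericalMap:
    """Unit-sphere vertex positions sharing the source mesh's connectivity."""

    sphere_positions: np.ndarray
    source: TriangleMesh

    def __post_init__(self):
        p = np.asarray(self.sphere_positions, dtype=np.float64)
        if p.shape != self.source.vertices.shape:
            raise ValueError("spherical map must have one position per source vertex")
        object.__setattr__(self, "sphere_positions", p)

    @property
    def sphere_mesh(self) -> TriangleMesh:
        return TriangleMesh(self.sphere_positions, self.source.faces)


@dataclass(frozen=True)
class CurvatureFunction:
    """Per-vertex samples of rho on a spherical map (dimensionless after
    area normalization)."""

    values: np.ndarray
    map: SphericalMap

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (self.map.source.n_vertices,):
            raise ValueError("one rho sample per vertex required")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite curvature samples")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class FlowDiagnostics:
    iterations: int
    sphericity_trace: np.ndarray
    converged: bool


def sphericity(mesh: TriangleMesh) -> float:
    """Dimensionless sphericity 36*pi*V^2/A^3; equals 1 only for a round sphere."""
    a = surface_area(mesh)
    v = enclosed_volume(mesh)
    return float(36.0 * np.pi * v * v / a**3)


def relative_sphericity(mesh: TriangleMesh) -> float:
    """Sphericity of a mesh relative to the same connectivity radially
    projected onto the unit sphere about its area-weighted centroid.

    A discrete polyhedron can never reach sphericity 1 (chordal faces cut
    both volume and area), so convergence of the flow is judged against the
    best value the connectivity itself can attain; the ratio tends to 1
    exactly when all vertices approach a common sphere.
    """
    va = vertex_areas(mesh)
    c = (mesh.vertices * va[:, None]).sum(axis=0) / va.sum()
    x = mesh.vertices - c
    r = np.linalg.norm(x, axis=1, keepdims=True)
    proj = TriangleMesh(x / r, mesh.faces)
    return sphericity(TriangleMesh(x, mesh.faces)) / sphericity(proj)


def count_flipped_faces(smap: SphericalMap) -> int:
    """Number of spherical triangles whose normal points inward (inverted
    orientation on the sphere)."""
    m = smap.sphere_mesh
    fn = face_normals(m)
    cen = m.vertices[m.faces].mean(axis=1)
    return int(np.sum(np.einsum("ij,ij->i", fn, cen) <= 0))


def cmcf(
    mesh: TriangleMesh,
    step: float = 0.05,
    tol: float = 5e-4,
    max_iter: int = 1500,
    patience: int = 30,
) -> tuple[SphericalMap, FlowDiagnostics]:
    """Conformalized mean curvature flow to the unit sphere.

    Implicit Euler steps ``(M_t + step * L_0) x' = M_t x`` with the stiffness
    ``L_0`` fixed at the initial cotangent Laplacian and the lumped
    barycentric mass ``M_t`` rebuilt from the evolving positions.  After each
    step the surface is recentered on its area-weighted centroid and rescaled
    to unit RMS radius.

    Convergence is judged on the *relative* sphericity (the ratio to the
    best value the connectivity can attain, :func:`relative_sphericity`): at
    the default ``tol`` of 5e-4 the vertex radii agree with a common sphere
    to about 1% before the final hard projection.  Very high area distortion
    (long protrusions) makes the flow plateau and eventually degrade
    numerically as triangles collapse on the sphere, so the best map seen is
    tracked and returned, and the loop stops early once ``patience``
    iterations pass without improvement.
    """
    if step <= 0 or tol <= 0:
        raise ValueError("step and tol must be positive")
    require_valid(mesh, "cmcf input")

    x = mesh.vertices.copy()
    work = mesh
    L0 = cotangent_laplacian(mesh)
    trace = []
    converged = False
    steps_taken = 0
    best_s, best_x, since_best = -np.inf, x, 0
    while True:
        s = relative_sphericity(work)
        trace.append(s)
        if s > best_s:
            best_s, best_x, since_best = s, x, 0
        else:
            since_best += 1
        if s >= 1.0 - tol:
            converged = True
            break
        if steps_taken >= max_iter or since_best >= patience:
            break
        M = sp.diags(vertex_areas(work))
        x = splu((M + step * L0).tocsc()).solve(M @ x)
        # recenter and rescale to unit RMS radius to remove drift
        work = TriangleMesh(x, mesh.faces)
        va = vertex_areas(work)
        c = (x * va[:, None]).sum(axis=0) / va.sum()
        x = (x - c) / np.sqrt(np.mean(np.sum((x - c) ** 2, axis=1)))
        work = TriangleMesh(x, mesh.faces)
        steps_taken += 1

    if not converged:
        warnings.warn(
            f"cMCF did not reach relative sphericity {1 - tol:.6f} in "
            f"{steps_taken} iterations (best {best_s:.6f}); returning best map"
        )
    va = vertex_areas(TriangleMesh(best_x, mesh.faces))
    c = (best_x * va[:, None]).sum(axis=0) / va.sum()
    y = best_x - c
    r = np.linalg.norm(y, axis=1, keepdims=True)
    smap = SphericalMap(y / r, mesh)
    return smap, FlowDiagnostics(
        iterations=steps_taken, sphericity_trace=np.asarray(trace), converged=converged
    )


def curvature_function(mesh: TriangleMesh, smap: SphericalMap) -> CurvatureFunction:
    """Sample rho = H * sqrt(A / A') per vertex.

    H and A are the mean curvature and barycentric vertex area of the
    area-4*pi normalized source mesh; A' the vertex area on the spherical
    image.  The square root converts the area ratio into the length-distortion
    ratio of the conformal map.
    """
    if smap.source.faces.shape != mesh.faces.shape or np.any(
        smap.source.faces != mesh.faces
    ):
        raise ValueError("spherical map does not share the mesh's connectivity")
    norm = normalize_mesh(mesh)
    h = mean_curvature(norm)
    a_src = vertex_areas(norm)
    a_img = vertex_areas(smap.sphere_mesh)
    if np.any(a_img <= 0):
        raise ValueError("collapsed spherical map: zero image vertex area")
    rho = h * np.sqrt(a_src / a_img)
    return CurvatureFunction(rho, smap)


def quasi_conformal_error(
    mesh: TriangleMesh, smap: SphericalMap
) -> tuple[np.ndarray, dict]:
    """Per-face quasi-conformal error Q and a (mean, max) summary.

    Q is the ratio of the largest to smallest singular value of the 2D linear
    map taking each source triangle (in its intrinsic plane) to its spherical
    image; Q >= 1 with equality for a perfectly conformal map.  Q is invariant
    to uniform scaling of either mesh.  Degenerate image triangles report
    Q = +inf.
    """
    if smap.source.faces.shape != mesh.faces.shape or np.any(
        smap.source.faces != mesh.faces
    ):
        raise ValueError("connectivity mismatch")
    q = np.empty(mesh.n_faces)
    src = _face_frames(mesh)
    img = _face_frames(smap.sphere_mesh)
    for i in range(mesh.n_faces):
        a, b = src[i], img[i]
        try:
            j = b @ np.linalg.inv(a)
        except np.linalg.LinAlgError:
            q[i] = np.inf
            continue
        s = np.linalg.svd(j, compute_uv=False)
        q[i] = np.inf if s[-1] <= 0 else s[0] / s[-1]
    finite = q[np.isfinite(q)]
    summary = {
        "mean": float(finite.mean()) if finite.size else np.inf,
        "max": float(q.max()),
        "n_degenerate": int(np.sum(~np.isfinite(q))),
    }
    return q, summary


def _face_frames(mesh: TriangleMesh) -> np.ndarray:
    """Per-face 2x2 matrices of edge vectors expressed in an intrinsic
    orthonormal frame of the face plane."""
    v, f = mesh.vertices, mesh.faces
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    u = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
    n = np.cross(e1, e2)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    w = np.cross(n, u)
    out = np.empty((len(f), 2, 2))
    out[:, 0, 0] = np.einsum("ij,ij->i", e1, u)
    out[:, 1, 0] = np.einsum("ij,ij->i", e1, w)
    out[:, 0, 1] = np.einsum("ij,ij->i", e2, u)
    out[:, 1, 1] = np.einsum("ij,ij->i", e2, w)
    return out
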