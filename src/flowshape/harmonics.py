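"""Real spherical harmonics: basis, fitting, spectra and spectral filters.

Conventions (used consistently by fitting, rotation and correlation code):

* real, fully normalized (orthonormal) harmonics without the Condon–Shortley
  phase;
* coefficients stored flat in (l ascending, m from -l to +l) order, so a band
  limit ``lmax`` holds ``(lmax + 1)**2`` numbers;
* ``theta`` is colatitude from +z, ``phi`` azimuth in [0, 2*pi).

The sum of squared coefficients of the curvature function equals (by
Parseval) the integral of rho^2 over the sphere, which for an area-normalized
mesh is its Willmore energy — 4*pi exactly for a round sphere, larger for
everything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from .mesh import TriangleMesh, vertex_areas
from .spheremap import CurvatureFunction, SphericalMap

__all__ = [
    "SHCoefficients",
    "PowerSpectrum",
    "ProtrusionResult",
    "lm_order",
    "sh_basis",
    "sh_evaluate",
    "irf_fit",
    "fit_curvature",
    "power_spectrum",
    "willmore_energy",
    "gaussian_filter",
    "log_filter",
    "detect_protrusions",
    "auto_threshold",
    "real_to_complex",
    "complex_to_real",
    "write_coefficients_csv",
    "read_coefficients_csv",
]

DEFAULT_LMAX = 24  # captures cell-scale detail; diminishing returns beyond
DEFAULT_K = 0.005  # Gaussian width parameter; spatial SD = sqrt(k) radians


@dataclass(frozen=True)
class SHCoefficients:
    """Real SH coefficients up to degree ``lmax`` in canonical flat order."""

    lmax: int
    coeffs: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coeffs, dtype=np.float64).ravel()
        if len(c) != (self.lmax + 1) ** 2:
            raise ValueError(
                f"expected {(self.lmax + 1) ** 2} coefficients for lmax={self.lmax}, "
                f"got {len(c)}"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite coefficients")
        object.__setattr__(self, "coeffs", c)

    def degree_slice(self, l: int) -> np.ndarray:
        """View of the 2l+1 coefficients of degree l (m = -l..l)."""
        return self.coeffs[l * l : (l + 1) * (l + 1)]

    def __getitem__(self, lm: tuple[int, int]) -> float:
        l, m = lm
        if not (0 <= l <= self.lmax and -l <= m <= l):
            raise IndexError(f"(l, m) = {lm} out of range")
        return float(self.coeffs[l * l + l + m])

    def truncated(self, lmax: int) -> "SHCoefficients":
        if lmax >= self.lmax:
            out = np.zeros((lmax + 1) ** 2)
            out[: len(self.coeffs)] = self.coeffs
            return SHCoefficients(lmax, out)
        return SHCoefficients(lmax, self.coeffs[: (lmax + 1) ** 2].copy())

    def copy(self) -> "SHCoefficients":
        return SHCoefficients(self.lmax, self.coeffs.copy())


@dataclass(frozen=True)
class PowerSpectrum:
    """Per-degree energies S_l = sum_m c_lm^2."""

    energies: np.ndarray

    @property
    def lmax(self) -> int:
        return len(self.energies) - 1

    def total(self) -> float:
        return float(self.energies.sum())


@dataclass(frozen=True)
class ProtrusionResult:
    """Outcome of the blob (protrusion) detector."""

    score: float  # total original-surface area above threshold
    mask: np.ndarray  # per-vertex flag: filtered response > threshold
    filtered: np.ndarray  # per-vertex LoG response
    threshold: float


def lm_order(lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """The canonical (l, m) sequence as two integer arrays."""
    ls = np.concatenate([np.full(2 * l + 1, l) for l in range(lmax + 1)])
    ms = np.concatenate([np.arange(-l, l + 1) for l in range(lmax + 1)])
    return ls, ms


def _check_unit(points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    r = np.linalg.norm(pts, axis=1)
    if np.any(np.abs(r - 1.0) > tol):
        raise ValueError("points must lie on the unit sphere")
    return pts


def sh_basis(lmax: int, points: np.ndarray) -> np.ndarray:
    """Matrix of real orthonormal SH values; rows = points, columns = (l, m).

    Built from the complex harmonics Y_l^m(theta, phi):

        R_{l,0}  = Y_l^0
        R_{l,m}  = sqrt(2) (-1)^m Re Y_l^m      (m > 0)
        R_{l,-m} = sqrt(2) (-1)^m Im Y_l^m      (m > 0)

    The (-1)^m cancels the Condon–Shortley phase of the associated Legendre
    functions, so e.g. R_{1,1} = sqrt(3/4pi) * x is positive on +x.
    """
    pts = _check_unit(points)
    theta = np.arccos(np.clip(pts[:, 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2.0 * np.pi)
    return sh_basis_angles(lmax, theta, phi)


def sh_basis_angles(lmax: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, float).ravel()
    phi = np.asarray(phi, float).ravel()
    n = len(theta)
    out = np.empty((n, (lmax + 1) ** 2))
    for l in range(lmax + 1):
        base = l * l + l
        out[:, base] = sph_harm_y(l, 0, theta, phi).real
        for m in range(1, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            sign = -1.0 if m % 2 else 1.0
            out[:, base + m] = np.sqrt(2.0) * sign * y.real
            out[:, base - m] = np.sqrt(2.0) * sign * y.imag
    return out


def sh_evaluate(coeffs: SHCoefficients, points: np.ndarray) -> np.ndarray:
    """Synthesize the band-limited function at unit-sphere points."""
    return sh_basis(coeffs.lmax, points) @ coeffs.coeffs


def irf_fit(
    curv: CurvatureFunction | np.ndarray,
    lmax: int = DEFAULT_LMAX,
    passes: int = 3,
    tol: float = 1e-6,
    points: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> SHCoefficients:
    """Iterative residual fitting of real SH coefficients.

    One degree at a time, lowest first, an area-weighted least-squares
    problem is solved against the running residual; full sweeps are repeated
    until the largest coefficient change drops below ``tol`` or ``passes``
    sweeps are exhausted.  Weights default to the spherical vertex areas so
    the discrete normal equations approximate the L2 inner product on the
    sphere (which is what makes Parseval hold for the fitted coefficients).
    """
    if isinstance(curv, CurvatureFunction):
        samples = curv.values
        points = curv.map.sphere_positions
        if weights is None:
            weights = vertex_areas(curv.map.sphere_mesh)
    else:
        samples = np.asarray(curv, float).ravel()
        if points is None:
            raise ValueError("points required when fitting raw samples")
    if len(samples) < (lmax + 1) ** 2:
        raise ValueError(
            f"{len(samples)} samples cannot determine {(lmax + 1) ** 2} coefficients"
        )
    if weights is None:
        weights = np.full(len(samples), 4.0 * np.pi / len(samples))
    basis = sh_basis(lmax, points)
    w = np.asarray(weights, float)

    coeffs = np.zeros((lmax + 1) ** 2)
    residual = samples.copy()
    for _ in range(max(1, passes)):
        max_change = 0.0
        for l in range(lmax + 1):
            sl = slice(l * l, (l + 1) * (l + 1))
            b = basis[:, sl]
            bw = b * w[:, None]
            gram = b.T @ bw
            rhs = bw.T @ (residual + b @ coeffs[sl])
            new = np.linalg.solve(gram, rhs)
            delta = new - coeffs[sl]
            residual -= b @ delta
            coeffs[sl] = new
            max_change = max(max_change, float(np.abs(delta).max(initial=0.0)))
        if max_change < tol:
            break
    return SHCoefficients(lmax, coeffs)


def fit_curvature(
    mesh: TriangleMesh,
    lmax: int = DEFAULT_LMAX,
    step: float = 0.01,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[SHCoefficients, SphericalMap, CurvatureFunction]:
    """Convenience pipeline: cMCF map -> rho -> IRF fit."""
    from .spheremap import cmcf, curvature_function

    smap, _ = cmcf(mesh, step=step, tol=tol, max_iter=max_iter)
    rho = curvature_function(mesh, smap)
    return irf_fit(rho, lmax=lmax), smap, rho


def power_spectrum(coeffs: SHCoefficients) -> PowerSpectrum:
    """Rotation-invariant per-degree energies S_l = sum_m c_lm^2."""
    s = np.array(
        [float(np.sum(coeffs.degree_slice(l) ** 2)) for l in range(coeffs.lmax + 1)]
    )
    return PowerSpectrum(s)


def willmore_energy(coeffs: SHCoefficients) -> float:
    """Total Willmore energy W~ = sum of squared coefficients.

    For rho fitted from an area-normalized mesh this equals the surface
    integral of H^2 dA (band-limited); it measures deviation from a round
    sphere, whose value is 4*pi.  The l=0 (constant) term is included; the
    pure deviation reading is W~ - 4*pi.
    """
    return float(np.sum(coeffs.coeffs**2))


def gaussian_filter(coeffs: SHCoefficients, k: float) -> SHCoefficients:
    """Spectral Gaussian smoothing: c_lm *= exp(-l(l+1) k / 2).

    The heat-kernel convention makes the realized spatial kernel's angular
    standard deviation sqrt(k) radians in the small-angle regime, so the
    default k = 0.005 corresponds to about 4 degrees on the sphere.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    ls, _ = lm_order(coeffs.lmax)
    factor = np.exp(-ls * (ls + 1) * k / 2.0)
    return SHCoefficients(coeffs.lmax, coeffs.coeffs * factor)


def log_filter(coeffs: SHCoefficients, k: float) -> SHCoefficients:
    """Laplacian-of-Gaussian blob filter in the SH domain.

    Each degree is multiplied by its (negated) Laplace–Beltrami eigenvalue
    times the Gaussian transfer function, then globally sign-flipped so that
    the response at the center of a positive curvature blob is positive.
    The realized spatial kernel is axially symmetric.  The constant (l=0)
    component is annihilated.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    ls, _ = lm_order(coeffs.lmax)
    factor = ls * (ls + 1.0) * np.exp(-ls * (ls + 1) * k / 2.0)
    return SHCoefficients(coeffs.lmax, coeffs.coeffs * factor)


def gaussian_kernel_angular_sd(
    k: float, lmax: int = 192, cap_radius: float = np.radians(1.0)
) -> float:
    """Angular standard deviation (radians) of the realized smoothing kernel.

    A narrow spherical cap (an approximate delta at the north pole) is
    projected onto the zonal (m = 0) harmonics, the Gaussian transfer
    function is applied, and a Gaussian in colatitude is least-squares
    fitted to the resulting spatial profile.  For the heat-kernel convention
    used here the result is sqrt(k) radians in the small-angle limit
    (~4 degrees at k = 0.005).
    """
    from scipy.integrate import quad
    from scipy.optimize import curve_fit
    from scipy.special import eval_legendre

    ls = np.arange(lmax + 1)
    # zonal coefficients of the unit-mass cap: c_l = 2*pi*N * int Y_l0 sin(t) dt
    cap = np.empty(lmax + 1)
    for l in ls:
        val, _ = quad(
            lambda t, l=l: np.sqrt((2 * l + 1) / (4 * np.pi))
            * eval_legendre(l, np.cos(t))
            * np.sin(t),
            0.0,
            cap_radius,
        )
        cap[l] = 2 * np.pi * val
    cap /= 2 * np.pi * (1 - np.cos(cap_radius))  # unit height -> unit mass
    filt = cap * np.exp(-ls * (ls + 1) * k / 2.0)
    theta = np.linspace(0.0, min(np.pi, 8 * np.sqrt(max(k, 1e-6))), 400)
    profile = np.zeros_like(theta)
    for l in ls:
        profile += filt[l] * np.sqrt((2 * l + 1) / (4 * np.pi)) * eval_legendre(
            l, np.cos(theta)
        )
    p0 = (profile[0], np.sqrt(max(k, 1e-6)))
    popt, _ = curve_fit(
        lambda t, a, s: a * np.exp(-(t**2) / (2 * s**2)), theta, profile, p0=p0
    )
    return float(abs(popt[1]))


def auto_threshold(filtered: np.ndarray, n_sigmas: float = 3.0) -> float:
    """Robust default threshold: n_sigmas times 1.4826*MAD of the response."""
    med = np.median(filtered)
    mad = np.median(np.abs(filtered - med))
    return float(n_sigmas * 1.4826 * mad)


def detect_protrusions(
    mesh: TriangleMesh,
    smap: SphericalMap,
    coeffs: SHCoefficients,
    k: float = DEFAULT_K,
    threshold: float | None = None,
) -> ProtrusionResult:
    """Threshold the LoG response of the curvature function.

    The filtered field is evaluated at the spherical vertex positions; the
    total *original-mesh* area of the vertices whose response exceeds the
    threshold is the protrusion score (area in physical units is the
    meaningful proxy for how much of the cell surface protrudes).  With
    ``threshold=None`` the robust 3-sigma auto threshold is used.
    """
    if smap.source.faces.shape != mesh.faces.shape or np.any(
        smap.source.faces != mesh.faces
    ):
        raise ValueError("mesh/map connectivity mismatch")
    filtered = sh_evaluate(log_filter(coeffs, k), smap.sphere_positions)
    if threshold is None:
        threshold = auto_threshold(filtered)
    mask = filtered > threshold
    areas = vertex_areas(mesh)
    return ProtrusionResult(
        score=float(areas[mask].sum()),
        mask=mask,
        filtered=filtered,
        threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# real <-> complex coefficient conversion (shared with rotation/correlation)


def real_to_complex(coeffs: SHCoefficients) -> list[np.ndarray]:
    """Per-degree complex coefficient vectors a_{lm} (m = -l..l) such that
    sum_m a_lm Y_l^m (complex, Condon–Shortley) equals the real expansion."""
    out = []
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    for l in range(coeffs.lmax + 1):
        c = coeffs.degree_slice(l)
        a = np.zeros(2 * l + 1, dtype=complex)
        a[l] = c[l]  # m = 0
        for m in range(1, l + 1):
            cp, cm = c[l + m], c[l - m]
            sign = -1.0 if m % 2 else 1.0
            a[l + m] = sign * (cp - 1j * cm) * inv_sqrt2
            a[l - m] = (cp + 1j * cm) * inv_sqrt2
        out.append(a)
    return out


def complex_to_real(blocks: list[np.ndarray]) -> SHCoefficients:
    """Inverse of :func:`real_to_complex` (imaginary residue discarded)."""
    lmax = len(blocks) - 1
    coeffs = np.zeros((lmax + 1) ** 2)
    sqrt2 = np.sqrt(2.0)
    for l, a in enumerate(blocks):
        base = l * l + l
        coeffs[base] = a[l].real
        for m in range(1, l + 1):
            sign = -1.0 if m % 2 else 1.0
            coeffs[base + m] = (sign * a[l + m] + a[l - m]).real / sqrt2
            coeffs[base - m] = ((a[l - m] - sign * a[l + m]) / (1j * sqrt2)).real
    return SHCoefficients(lmax, coeffs)


# ---------------------------------------------------------------------------
# CSV round trip (canonical l,m,coeff rows)


def write_coefficients_csv(coeffs: SHCoefficients, path) -> None:
    ls, ms = lm_order(coeffs.lmax)
    with open(path, "w") as fh:
        fh.write("l,m,coeff\n")
        for l, m, c in zip(ls, ms, coeffs.coeffs):
            fh.write(f"{l},{m},{float(c)!r}\n")


def read_coefficients_csv(path) -> SHCoefficients:
    data = np.genfromtxt(path, delimiter=",", names=True, dtype=None, encoding=None)
    ls = np.asarray(data["l"], int)
    ms = np.asarray(data["m"], int)
    cs = np.asarray(data["coeff"], float)
    lmax = int(ls.max())
    out = np.zeros((lmax + 1) ** 2)
    out[ls * ls + ls + ms] = cs
    return SHCoefficients(lmax, out)
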