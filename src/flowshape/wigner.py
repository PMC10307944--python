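"""Wigner rotation matrices for (real) spherical harmonics.

The small Wigner d-matrix is evaluated with the explicit factorial sum in
log-space (stable for the moderate degrees used here, l <= ~64).  Full
rotations use the ZYZ Euler convention: R = Rz(alpha) @ Ry(beta) @ Rz(gamma),
with the complex Wigner matrix

    D^l_{m'm}(alpha, beta, gamma) = exp(-i m' alpha) d^l_{m'm}(beta) exp(-i m gamma)

acting on complex coefficient vectors so that the rotated function f' obeys
f'(x) = f(R^T x).  Real rotation blocks are obtained by conjugating with the
real<->complex change of basis; they are orthogonal and block-diagonal per
degree, which is why rotations preserve the per-degree power spectrum.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln


def wigner_d(l: int, beta: np.ndarray) -> np.ndarray:
    """Small Wigner d^l(beta) for an array of angles.

    Returns an array of shape (len(beta), 2l+1, 2l+1) indexed [b, l+m', l+m].
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
    n = 2 * l + 1
    m = np.arange(-l, l + 1)
    mp = m[:, None]  # m'
    mm = m[None, :]  # m
    # log prefactor sqrt((l+m')!(l-m')!(l+m)!(l-m)!)
    logpre = 0.5 * (
        gammaln(l + mp + 1)
        + gammaln(l - mp + 1)
        + gammaln(l + mm + 1)
        + gammaln(l - mm + 1)
    )
    cb = np.cos(beta / 2.0)[:, None, None]
    sb = np.sin(beta / 2.0)[:, None, None]
    # guard logs of zero: handled by masking the power terms
    out = np.zeros((len(beta), n, n))
    smin = np.maximum(0, mm - mp)  # (n, n)
    smax = np.minimum(l + mm, l - mp)
    for s in range(0, 2 * l + 1):
        valid = (s >= smin) & (s <= smax)
        if not np.any(valid):
            continue
        k_cos = 2 * l + mm - mp - 2 * s  # exponent of cos(beta/2)
        k_sin = mp - mm + 2 * s  # exponent of sin(beta/2)
        logden = (
            gammaln(np.where(valid, l + mm - s, 0) + 1)
            + gammaln(s + 1)
            + gammaln(np.where(valid, mp - mm + s, 0) + 1)
            + gammaln(np.where(valid, l - mp - s, 0) + 1)
        )
        coef = np.where(valid, np.exp(logpre - logden), 0.0)
        sign = np.where((mp - mm + s) % 2 == 0, 1.0, -1.0)
        term = coef * sign
        # powers with 0^0 = 1 semantics
        pc = np.where(k_cos == 0, 1.0, cb ** np.maximum(k_cos, 0))
        ps = np.where(k_sin == 0, 1.0, sb ** np.maximum(k_sin, 0))
        out += term[None, :, :] * pc * ps
    return out


def wigner_D(l: int, alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Complex Wigner matrix D^l(alpha, beta, gamma), shape (2l+1, 2l+1)."""
    d = wigner_d(l, np.array([beta]))[0]
    m = np.arange(-l, l + 1)
    return np.exp(-1j * m[:, None] * alpha) * d * np.exp(-1j * m[None, :] * gamma)


def euler_zyz(rotation: np.ndarray) -> tuple[float, float, float]:
    """Extract ZYZ Euler angles (alpha, beta, gamma) with beta in [0, pi]."""
    r = np.asarray(rotation, dtype=np.float64)
    if r.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(r @ r.T, np.eye(3), atol=1e-6) or np.linalg.det(r) < 0:
        raise ValueError("not a proper rotation matrix")
    beta = np.arccos(np.clip(r[2, 2], -1.0, 1.0))
    if np.sin(beta) > 1e-9:
        alpha = np.arctan2(r[1, 2], r[0, 2])
        gamma = np.arctan2(r[2, 1], -r[2, 0])
    else:
        # gimbal: fold everything into alpha
        alpha = np.arctan2(r[1, 0], r[0, 0]) if r[2, 2] > 0 else np.arctan2(-r[1, 0], -r[0, 0])
        gamma = 0.0
        if r[2, 2] < 0:
            beta = np.pi
    return float(alpha), float(beta), float(gamma)


def rotation_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix Rz(alpha) @ Ry(beta) @ Rz(gamma)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    rz_a = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    ry_b = np.array([[cb, 0, sb], [0, 1.0, 0], [-sb, 0, cb]])
    rz_g = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1.0]])
    return rz_a @ ry_b @ rz_g


@lru_cache(maxsize=8)
def _real_to_complex_matrix(l: int) -> np.ndarray:
    """Unitary T with a = T c mapping real coefficients to complex ones."""
    n = 2 * l + 1
    t = np.zeros((n, n), dtype=complex)
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    t[l, l] = 1.0
    for m in range(1, l + 1):
        sign = -1.0 if m % 2 else 1.0
        t[l + m, l + m] = sign * inv_sqrt2
        t[l + m, l - m] = -1j * sign * inv_sqrt2
        t[l - m, l + m] = inv_sqrt2
        t[l - m, l - m] = 1j * inv_sqrt2
    return t


def real_wigner_block(l: int, rotation: np.ndarray) -> np.ndarray:
    """Orthogonal (2l+1)x(2l+1) block rotating real degree-l coefficients."""
    alpha, beta, gamma = euler_zyz(rotation)
    t = _real_to_complex_matrix(l)
    d = wigner_D(l, alpha, beta, gamma)
    block = t.conj().T @ d @ t
    return block.real
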