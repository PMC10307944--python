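"""Minimal vectorized quaternion arithmetic (w, x, y, z convention).

Quaternions encode conformal (rotate + scale) actions on edge vectors in the
spin-transformation reconstruction; arrays hold one quaternion per row.
"""

from __future__ import annotations

import numpy as np

__all__ = ["qmul", "qconj", "pure", "vec", "left_matrix"]


def qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product, broadcasting over leading axes."""
    aw, ax, ay, az = np.moveaxis(np.asarray(a, float), -1, 0)
    bw, bx, by, bz = np.moveaxis(np.asarray(b, float), -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def qconj(a: np.ndarray) -> np.ndarray:
    out = np.array(a, dtype=float, copy=True)
    out[..., 1:] *= -1.0
    return out


def pure(v: np.ndarray) -> np.ndarray:
    """Imaginary quaternion (0, v) from 3-vectors."""
    v = np.asarray(v, float)
    out = np.zeros(v.shape[:-1] + (4,))
    out[..., 1:] = v
    return out


def vec(q: np.ndarray) -> np.ndarray:
    """Vector (imaginary) part."""
    return np.asarray(q, float)[..., 1:]


def left_matrix(q: np.ndarray) -> np.ndarray:
    """Real 4x4 matrix of left multiplication: left_matrix(q) @ p == q * p.

    For arrays of quaternions returns shape (..., 4, 4).  The transpose is
    left multiplication by the conjugate, which is what makes quaternionic
    Hermitian matrices real-symmetric in this encoding.
    """
    q = np.asarray(q, float)
    w, x, y, z = np.moveaxis(q, -1, 0)
    rows = [
        np.stack([w, -x, -y, -z], axis=-1),
        np.stack([x, w, -z, y], axis=-1),
        np.stack([y, z, w, -x], axis=-1),
        np.stack([z, -y, x, w], axis=-1),
    ]
    return np.stack(rows, axis=-2)
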