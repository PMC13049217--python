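"""Minimal scalar-first unit-quaternion helpers.

All quaternions are ``[w, x, y, z]`` arrays. Only the operations the
simulator and the angular-path metric need are provided.
"""

from __future__ import annotations

import numpy as np

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def qmul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 ⊗ q2 (both scalar-first)."""
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Unit quaternion rotating by ``angle`` radians about unit ``axis``."""
    half = 0.5 * angle
    q = np.empty(4)
    q[0] = np.cos(half)
    q[1:] = np.sin(half) * axis
    return q


def normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)


def geodesic_angles(quat: np.ndarray) -> np.ndarray:
    """Rotation angle (radians) between consecutive rows of an (n, 4) array.

    Uses the chord construction ``4 * arcsin(min(|q2-q1|, |q2+q1|) / 2)``
    which is sign-convention invariant and numerically accurate for small
    steps (unlike ``2 * arccos(|dot|)``).
    """
    d_minus = np.linalg.norm(np.diff(quat, axis=0), axis=1)
    d_plus = np.linalg.norm(quat[1:] + quat[:-1], axis=1)
    chord = np.minimum(d_minus, d_plus)
    return 4.0 * np.arcsin(np.clip(0.5 * chord, 0.0, 1.0))
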