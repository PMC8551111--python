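"""Parameter-free extrapolators of target position.

The linear (L) extrapolator continues the latest displacement; the
curvilinear (C) extrapolator continues at the same speed and turn rate
along a circular arc. For collinear inputs the two coincide.
"""
from __future__ import annotations

import math

import numpy as np


def linear_extrapolate(p_prev: np.ndarray, p_curr: np.ndarray) -> np.ndarray:
    """Predict the next position assuming constant velocity."""
    p_prev = np.asarray(p_prev, dtype=float)
    p_curr = np.asarray(p_curr, dtype=float)
    return p_curr + (p_curr - p_prev)


def rotate(v: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate a 2-vector counterclockwise by ``angle_rad``."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    v = np.asarray(v, dtype=float)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def turn_angle(d_prev: np.ndarray, d_curr: np.ndarray) -> float:
    """Signed angle (rad, CCW positive) from ``d_prev`` to ``d_curr``.

    Defined as 0 when either displacement is zero.
    """
    if np.hypot(*d_prev) == 0 or np.hypot(*d_curr) == 0:
        return 0.0
    cross = d_prev[0] * d_curr[1] - d_prev[1] * d_curr[0]
    dot = d_prev[0] * d_curr[0] + d_prev[1] * d_curr[1]
    return math.atan2(cross, dot)


def curvilinear_extrapolate(
    p_2: np.ndarray, p_1: np.ndarray, p_0: np.ndarray
) -> np.ndarray:
    """Predict the next position continuing the current turn rate.

    ``p_2, p_1, p_0`` are three consecutive positions (oldest first).
    The latest displacement is rotated by the angle between the two
    observed displacements and added to ``p_0``. Degenerate cases: a
    zero latest displacement returns ``p_0``; a zero previous
    displacement implies a zero turn angle (= linear extrapolation).
    """
    p_2 = np.asarray(p_2, dtype=float)
    p_1 = np.asarray(p_1, dtype=float)
    p_0 = np.asarray(p_0, dtype=float)
    d_prev = p_1 - p_2
    d_curr = p_0 - p_1
    if np.hypot(*d_curr) == 0:
        return p_0.copy()
    dtheta = turn_angle(d_prev, d_curr)
    return p_0 + rotate(d_curr, dtheta)
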