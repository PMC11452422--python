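"""Quasi-uniform sphere sampling and rotation helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["fibonacci_sphere", "random_rotation", "perpendicular_directions"]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors from the Fibonacci (golden-angle) lattice."""
    if n < 1:
        raise ValueError("n must be positive")
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed 3×3 rotation matrix (uniform quaternion)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def perpendicular_directions(axis: np.ndarray, n: int = 36) -> np.ndarray:
    """n unit vectors evenly spaced in the plane perpendicular to ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    theta = np.linspace(0.0, np.pi, n, endpoint=False)  # line-angles: half turn
    return np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2
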