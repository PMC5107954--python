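"""Small vector-geometry helpers (point-to-segment distances, unit vectors)."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize ``v``; raises on the zero vector."""
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def point_segment_distance(p, a, b) -> float:
    """Euclidean distance from point ``p`` to segment ``a``–``b``."""
    d, _t, _q = point_segment_closest(p, a, b)
    return d


def point_segment_closest(p, a, b):
    """Distance, segment parameter t in [0,1], and closest point on a-b."""
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        t = 0.0
    else:
        t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    q = a + t * ab
    return float(np.linalg.norm(p - q)), t, q


def point_segments_distance(p, A, B):
    """Vectorized distances from point ``p`` to segments ``A[i]``–``B[i]``.

    Parameters
    ----------
    p : (3,) array
    A, B : (n, 3) arrays of segment endpoints

    Returns
    -------
    dist : (n,) distances
    t : (n,) clamped segment parameters of the closest points
    """
    p = np.asarray(p, dtype=float)
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    AB = B - A
    denom = np.einsum("ij,ij->i", AB, AB)
    num = np.einsum("ij,ij->i", p[None, :] - A, AB)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0.0, num / np.where(denom > 0.0, denom, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    Q = A + t[:, None] * AB
    dist = np.linalg.norm(p[None, :] - Q, axis=1)
    return dist, t


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle in [0, pi] between two (not necessarily unit) vectors."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    c = float(np.clip((u @ v) / (nu * nv), -1.0, 1.0))
    return float(np.arccos(c))
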