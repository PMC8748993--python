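"""Small vector-geometry helpers shared by structure building and analysis.

All coordinates are numpy float64 arrays of shape (3,) in Angstroms; angles
are in degrees unless a function name says otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "distance",
    "angle_at",
    "dihedral",
    "unit",
    "place_atom",
    "perpendicular",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return v normalized to unit length."""
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def angle_at(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle a-vertex-b in degrees, in [0, 180]."""
    u = np.asarray(a, float) - np.asarray(vertex, float)
    v = np.asarray(b, float) - np.asarray(vertex, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, length: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms c-b-a.

    D is at `length` from `a`, with angle D-a-b equal to `angle` and
    torsion D-a-b-c equal to `torsion` (NeRF construction).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    # local frame at a, x pointing from b to a
    bc = unit(b - c)
    n = unit(np.cross(bc, a - b))
    ba = unit(a - b)
    m = np.cross(n, ba)
    d_local = length * np.array(
        [np.cos(np.pi - ang), np.sin(np.pi - ang) * np.cos(tor), np.sin(np.pi - ang) * np.sin(tor)]
    )
    return a + d_local[0] * ba + d_local[1] * m + d_local[2] * n


def perpendicular(v: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to v (deterministic choice)."""
    v = unit(np.asarray(v, float))
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, ref))
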