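"""Small 3D geometry helpers shared across the package.

Angles are in degrees everywhere.  These are the only places where raw
vector math happens; everything above works in terms of named quantities
(chi, psi, twist, tilt, groove distance).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "fit_plane",
    "point_plane_distance",
    "signed_angle",
    "place_atom",
    "unit",
]


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle of four points, IUPAC sign, in (-180, 180].

    Looking from p1 toward p2, the angle from the half-plane holding p0 to
    the half-plane holding p3; clockwise positive.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), unit(b2)))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through >= 3 points: (centroid, unit normal)."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def point_plane_distance(point, centroid, normal) -> float:
    return float(abs(np.dot(np.asarray(point, float) - centroid, unit(np.asarray(normal, float)))))


def signed_angle(v1, v2, axis) -> float:
    """Signed angle from v1 to v2 about ``axis`` (right-hand rule), degrees.

    v1 and v2 are projected onto the plane normal to the axis first.
    """
    a = unit(np.asarray(axis, float))
    u1 = np.asarray(v1, float) - np.dot(v1, a) * a
    u2 = np.asarray(v2, float) - np.dot(v2, a) * a
    x = float(np.dot(u1, u2))
    y = float(np.dot(a, np.cross(u1, u2)))
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given atoms A, B, C with |CD| = bond, angle(B,C,D) and
    torsion(A,B,C,D) prescribed (NeRF construction).  Degrees in, position out.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
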