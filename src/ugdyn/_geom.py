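"""Small geometric primitives shared across modules."""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError

#: Average atomic masses for mass-weighted centroids (Da).  Anything not
#: listed falls back to carbon, which is adequate for pseudo-atom fixtures.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "CA": 40.078,
    "MG": 24.305, "MN": 54.938,
}


def mass_of(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), 12.011)


def angle_deg(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    """Angle at ``vertex`` formed by points a-vertex-c, in degrees [0, 180]."""
    u = np.asarray(a, float) - vertex
    v = np.asarray(c, float) - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("coincident centers: angle undefined")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_deg(p1, p2, p3, p4) -> float:
    """Signed torsion of four points in (-180, 180], IUPAC convention:
    looking down p2->p3, positive is clockwise rotation of p4 relative to
    p1; the cis (eclipsed) arrangement is 0."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise DegenerateGeometryError("central atoms coincide: torsion undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear atoms: torsion undefined")
    m1 = np.cross(n1, b2 / nb2)
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def wrap_angle(deg: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR-based)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
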