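"""Low-level vector geometry shared by every module.

All coordinates are Cartesian, in ångströms, as numpy float64 arrays of
shape (3,).  All angles cross module boundaries in degrees on the
interval (-180, +180]; conversion to radians is internal.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "as_vec3",
    "wrap_angle",
    "dihedral",
    "bond_angle",
    "place_atom",
    "rotation_about_axis",
]


class DegenerateGeometryError(ValueError):
    """Raised when colinear or coincident points make an angle undefined."""


def as_vec3(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("coordinates must be finite")
    return v


def wrap_angle(deg):
    """Wrap an angle (or array) in degrees onto (-180, +180]."""
    w = -((-np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0)
    return w if np.ndim(deg) else float(w)


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees, in [0, 180]."""
    u = as_vec3(a) - as_vec3(b)
    v = as_vec3(c) - as_vec3(b)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("coincident points in bond angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion p1-p2-p3-p4 in degrees on (-180, +180].

    IUPAC sign convention: looking from p2 toward p3, a positive angle
    is a clockwise rotation of the p3->p4 bond relative to the p2->p1
    bond.  cis (eclipsed) is 0, trans is 180.
    """
    b1 = as_vec3(p2) - as_vec3(p1)
    b2 = as_vec3(p3) - as_vec3(p2)
    b3 = as_vec3(p4) - as_vec3(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("colinear triplet: torsion undefined")
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0:
        raise DegenerateGeometryError("coincident central atoms")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / nb2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang == -180.0 else float(ang)


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d bonded to c from internal coordinates (NeRF).

    Returns the unique point with |d-c| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees).
    """
    a, b, c = as_vec3(a), as_vec3(b), as_vec3(c)
    th = np.radians(angle)
    ph = np.radians(torsion)
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc == 0.0:
        raise DegenerateGeometryError("coincident b and c")
    bc_u = bc / nbc
    n = np.cross(b - a, bc_u)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise DegenerateGeometryError("colinear a, b, c: frame undefined")
    n_u = n / nn
    m_u = np.cross(n_u, bc_u)
    d_local = np.array(
        [
            -bond * np.cos(th),
            bond * np.sin(th) * np.cos(ph),
            bond * np.sin(th) * np.sin(ph),
        ]
    )
    return c + d_local[0] * bc_u + d_local[1] * m_u + d_local[2] * n_u


def rotation_about_axis(axis, deg: float) -> np.ndarray:
    """3x3 rotation matrix for a right-handed rotation about *axis*."""
    u = as_vec3(axis)
    nu = np.linalg.norm(u)
    if nu == 0.0:
        raise ValueError("zero rotation axis")
    u = u / nu
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    k = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * k + (1.0 - c) * np.outer(u, u)
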