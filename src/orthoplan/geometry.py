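"""Rigid-body mathematics shared by every pipeline stage.

All public interfaces use millimetres for lengths and degrees for angles;
radians are used only internally.  The coordinate frame is right-handed with
+x toward the patient's left (left-right), +y anterior (advance-setback) and
+z superior (impaction-elongation).

Euler convention
----------------
Fixed (extrinsic) axes, ``R = Rz(yaw) @ Ry(roll) @ Rx(pitch)``: pitch about
x, roll about y, yaw about z.  At the small angles typical of orthognathic
plans (< 13 deg) the axis orders agree to first order; this convention is
used everywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "EulerAngles",
    "Plane",
    "RigidTransform",
    "euler_compose",
    "euler_decompose",
    "rotation_about_center",
    "superpose_rigid",
]

_ORTHO_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when point configurations are too degenerate to define a pose."""


def _check_rotation(r: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {r.shape}")
    if not np.allclose(r.T @ r, np.eye(3), atol=tol):
        raise ValueError("rotation matrix is not orthonormal")
    if abs(np.linalg.det(r) - 1.0) > tol:
        raise ValueError("rotation matrix determinant is not +1 (reflection?)")
    return r


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array (or a single 3-vector) of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 representation."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``b`` first, then ``a``."""
    return a.compose(b)


@dataclass(frozen=True)
class EulerAngles:
    """Pitch/roll/yaw in degrees about the fixed x/y/z axes.

    ``gimbal_lock`` flags a decomposition at |roll| = 90 deg where yaw was
    tie-broken to zero and the remaining angle folded into pitch.
    """

    pitch: float
    roll: float
    yaw: float
    gimbal_lock: bool = field(default=False, compare=False)

    def as_array(self) -> np.ndarray:
        return np.array([self.pitch, self.roll, self.yaw])


def _rx(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_compose(e: EulerAngles | tuple) -> np.ndarray:
    """Rotation matrix ``Rz(yaw) @ Ry(roll) @ Rx(pitch)`` (angles in degrees)."""
    if not isinstance(e, EulerAngles):
        e = EulerAngles(*e)
    p, r, y = (math.radians(v) for v in (e.pitch, e.roll, e.yaw))
    return _rz(y) @ _ry(r) @ _rx(p)


def euler_decompose(r: np.ndarray) -> EulerAngles:
    """Decompose a rotation into pitch/roll/yaw degrees.

    For ``R = Rz(c) Ry(b) Rx(a)`` the closed form is ``b = asin(-R[2,0])``,
    ``a = atan2(R[2,1], R[2,2])``, ``c = atan2(R[1,0], R[0,0])``.  At gimbal
    lock (|b| = 90 deg) only a +/- c is determined: yaw is set to zero and the
    whole angle folded into pitch, with ``gimbal_lock=True``.
    """
    r = _check_rotation(r)
    s = -r[2, 0]
    s = min(1.0, max(-1.0, s))
    roll = math.asin(s)
    if 1.0 - abs(s) < 1e-12:
        sign = 1.0 if s > 0 else -1.0
        # R[0,1] = sign*sin(a -/+ c), R[1,1] = cos(a -/+ c); with c := 0
        pitch = math.atan2(sign * r[0, 1], r[1, 1])
        return EulerAngles(math.degrees(pitch), math.degrees(roll), 0.0, gimbal_lock=True)
    pitch = math.atan2(r[2, 1], r[2, 2])
    yaw = math.atan2(r[1, 0], r[0, 0])
    return EulerAngles(math.degrees(pitch), math.degrees(roll), math.degrees(yaw))


def superpose_rigid(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition (Kabsch/Horn, SVD closed form).

    Returns the proper rigid transform minimising ``sum ||T(s_i) - t_i||^2``
    over paired points.  Reflections are excluded by flipping the sign of the
    smallest singular direction when ``det < 0``.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 pairs or a (near-)collinear source configuration,
        where the rotation is not uniquely determined.
    """
    s = np.asarray(source, dtype=float)
    t = np.asarray(target, dtype=float)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 3:
        raise ValueError("source and target must be matching (N, 3) arrays")
    if len(s) < 3:
        raise DegenerateGeometryError("at least 3 point pairs are required")
    sc = s - s.mean(axis=0)
    tc = t - t.mean(axis=0)
    sv = np.linalg.svd(sc, compute_uv=False)
    # two significant singular values needed for a unique rotation
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("source points are (near-)collinear")
    h = sc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = t.mean(axis=0) - rot @ s.mean(axis=0)
    return RigidTransform(rot, trans)


def rotation_about_center(center: np.ndarray, axis: np.ndarray, angle_deg: float) -> RigidTransform:
    """Rotation by ``angle_deg`` about ``axis`` through ``center`` (a fixed point)."""
    axis = np.asarray(axis, dtype=float).reshape(3)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis must be non-zero")
    axis = axis / n
    center = np.asarray(center, dtype=float).reshape(3)
    a = math.radians(angle_deg)
    # Rodrigues formula
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    rot = np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)
    return RigidTransform(rot, center - rot @ center)


@dataclass(frozen=True)
class Plane:
    """Plane through ``origin`` with unit ``normal``."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError("plane normal must be non-zero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.origin) @ self.normal

    @classmethod
    def from_points(cls, p0, p1, p2) -> "Plane":
        p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
        n = np.cross(p1 - p0, p2 - p0)
        if np.linalg.norm(n) < 1e-12:
            raise DegenerateGeometryError("plane points are collinear")
        return cls(p0, n)
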