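"""Virtual surgical planning: plane-cut osteotomy, segment displacement and
the maxillary occlusal plane.

A surgical plan is an ordered list of steps applied to a bone segment (or
the whole maxillomandibular complex, MMC): linear translations along the
left-right (x), advance-setback (y) and impaction-elongation (z) axes in mm,
and rotations specified clinically as a rotation *center* plus a *target*
point and the *goal* point it should move toward.  The rotation is the
minimal one aligning the center-to-target direction with the center-to-goal
direction: axis = unit cross product of the two center-relative vectors,
angle = the angle between them.  The goal sets a direction only — distances
to the center are preserved.

The six-component summary of a plan (three translations, pitch/roll/yaw of
the net rotation) is the quantity reported per patient in planning tables.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

from .geometry import (
    DegenerateGeometryError,
    EulerAngles,
    Plane,
    RigidTransform,
    euler_decompose,
    rotation_about_center,
)
from .io import LandmarkSet

__all__ = [
    "Displacement6",
    "PlanStep",
    "SurgicalPlan",
    "apply_plan",
    "cut_mesh_by_plane",
    "occlusal_plane",
    "rotate_segment_to_goal",
    "translate_segment",
]


@dataclass(frozen=True)
class Displacement6:
    """Net displacement summary: translations in mm, rotations in degrees."""

    left_right: float
    advance_setback: float
    impaction_elongation: float
    pitch: float
    roll: float
    yaw: float

    def as_array(self) -> np.ndarray:
        return np.array([self.left_right, self.advance_setback, self.impaction_elongation,
                         self.pitch, self.roll, self.yaw])

    @classmethod
    def from_transform(cls, transform: RigidTransform) -> "Displacement6":
        e = euler_decompose(transform.rotation)
        t = transform.translation
        return cls(float(t[0]), float(t[1]), float(t[2]), e.pitch, e.roll, e.yaw)


@dataclass(frozen=True)
class PlanStep:
    """One plan step: either a translation or a center/target/goal rotation."""

    translation: np.ndarray | None = None
    center: np.ndarray | None = None
    target: np.ndarray | None = None
    goal: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.translation is None) == (self.center is None):
            raise ValueError("a step is either a translation or a rotation, not both")
        if self.translation is not None:
            object.__setattr__(self, "translation",
                               np.asarray(self.translation, dtype=float).reshape(3))
        else:
            for name in ("center", "target", "goal"):
                v = getattr(self, name)
                if v is None:
                    raise ValueError(f"rotation step requires {name!r}")
                object.__setattr__(self, name, np.asarray(v, dtype=float).reshape(3))

    @property
    def is_translation(self) -> bool:
        return self.translation is not None

    def to_transform(self) -> RigidTransform:
        if self.is_translation:
            return RigidTransform(np.eye(3), self.translation)
        return _goal_rotation(self.center, self.target, self.goal)


@dataclass(frozen=True)
class SurgicalPlan:
    steps: tuple

    def __init__(self, steps) -> None:
        object.__setattr__(self, "steps", tuple(steps))

    def net_transform(self) -> RigidTransform:
        net = RigidTransform.identity()
        for step in self.steps:
            net = step.to_transform().compose(net)
        return net

    def summary(self) -> Displacement6:
        return Displacement6.from_transform(self.net_transform())

    def to_dict(self) -> dict:
        out = []
        for s in self.steps:
            if s.is_translation:
                out.append({"translate": list(s.translation)})
            else:
                out.append({"rotate": {"center": list(s.center),
                                       "target": list(s.target),
                                       "goal": list(s.goal)}})
        return {"steps": out}

    @classmethod
    def from_dict(cls, d: dict) -> "SurgicalPlan":
        steps = []
        for raw in d["steps"]:
            if "translate" in raw:
                steps.append(PlanStep(translation=raw["translate"]))
            elif "rotate" in raw:
                r = raw["rotate"]
                steps.append(PlanStep(center=r["center"], target=r["target"], goal=r["goal"]))
            else:
                raise ValueError(f"unrecognised plan step {raw!r}")
        return cls(steps)

    @classmethod
    def load(cls, path) -> "SurgicalPlan":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def cut_mesh_by_plane(mesh: trimesh.Trimesh, plane: Plane):
    """Split a mesh by a plane into (positive-side, negative-side) pieces.

    Triangles crossing the plane are split along the intersection; the cut
    boundaries are left open (uncapped), so the two pieces' surface areas sum
    to the input area.  If the plane misses the mesh entirely one piece is
    empty and a warning is issued.
    """
    lo, hi = mesh.bounds
    d_corners = plane.signed_distance(trimesh.bounds.corners(mesh.bounds))
    if np.all(d_corners > 0) or np.all(d_corners < 0):
        warnings.warn("cut plane misses the mesh bounding box; one piece is empty")
    pos = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=plane.normal, plane_origin=plane.origin, cap=False)
    neg = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=-plane.normal, plane_origin=plane.origin, cap=False)
    return pos, neg


def translate_segment(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                      dx: float, dy: float, dz: float):
    """Translate a bone segment and its landmarks by (dx, dy, dz) mm."""
    t = RigidTransform(np.eye(3), [dx, dy, dz])
    return _apply_transform(mesh, landmarks, t) + (t,)


def _goal_rotation(center, target, goal) -> RigidTransform:
    center = np.asarray(center, dtype=float)
    u = np.asarray(target, dtype=float) - center
    v = np.asarray(goal, dtype=float) - center
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("target and goal must differ from the rotation center")
    u, v = u / nu, v / nv
    c = float(np.clip(u @ v, -1.0, 1.0))
    axis = np.cross(u, v)
    n_axis = np.linalg.norm(axis)
    if n_axis < 1e-12:
        if c > 0:
            return RigidTransform.identity()
        raise DegenerateGeometryError(
            "target and goal directions are anti-parallel; the rotation axis is ambiguous")
    angle = math.degrees(math.atan2(n_axis, c))
    return rotation_about_center(center, axis / n_axis, angle)


def rotate_segment_to_goal(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                           center, target, goal):
    """Rotate a segment about ``center`` so the target direction meets the goal.

    The rotation maps the direction (target - center) onto (goal - center);
    every distance to the center — including |target - center| — is
    preserved, so the goal fixes a direction, not a radius.
    """
    t = _goal_rotation(center, target, goal)
    return _apply_transform(mesh, landmarks, t) + (t,)


def _apply_transform(mesh, landmarks, transform):
    out_mesh = mesh.copy()
    out_mesh.vertices = transform.apply(np.asarray(mesh.vertices))
    return out_mesh, landmarks.transformed(transform)


def apply_plan(mmc_mesh: trimesh.Trimesh, landmarks: LandmarkSet, plan: SurgicalPlan):
    """Apply a surgical plan's steps in order to the MMC model and landmarks.

    Returns ``(simulation_mesh, displaced_landmarks, net_transform)``; the
    plan's :class:`Displacement6` summary is the Euler decomposition of the
    net transform.
    """
    net = plan.net_transform()
    out_mesh, out_lm = _apply_transform(mmc_mesh, landmarks, net)
    return out_mesh, out_lm, net


def occlusal_plane(landmarks: LandmarkSet):
    """Maxillary occlusal plane and its orthonormal frame.

    The plane passes through the mesiobuccal cusps of the right and left
    first upper molars and the central-incisor midpoint (taken from the
    landmark of that name, or computed from the right/left incisor landmarks
    if absent).  The frame's x-axis points from the right to the left molar
    cusp, the z-axis is the plane normal oriented into the +z hemisphere
    (tie-break: +y), and y completes the right-handed triad.

    Returns ``(Plane, frame)`` where ``frame`` is a rotation matrix whose
    columns are the x/y/z axes of the occlusal frame.
    """
    right = landmarks.get("mesiobuccal cusp right 1st molar")
    left = landmarks.get("mesiobuccal cusp left 1st molar")
    if right is None or left is None:
        raise KeyError("both first-molar mesiobuccal cusp landmarks are required")
    incisor = landmarks.get("central-incisor midpoint")
    if incisor is None:
        try:
            incisor = 0.5 * (landmarks["right incisor"] + landmarks["left incisor"])
        except KeyError as exc:
            raise KeyError(
                "need 'central-incisor midpoint' or both incisor landmarks") from exc

    x = left - right
    nx = np.linalg.norm(x)
    n = np.cross(x, incisor - right)
    nn = np.linalg.norm(n)
    if nx < 1e-12 or nn < 1e-12:
        raise DegenerateGeometryError("occlusal landmarks are collinear")
    x = x / nx
    z = n / nn
    if z[2] < 0 or (z[2] == 0 and z[1] < 0):
        z = -z
    y = np.cross(z, x)
    y /= np.linalg.norm(y)
    # x lies in the plane and z is its normal, so (x, y, z) is orthonormal
    frame = np.column_stack([x, y, z])
    origin = (right + left + incisor) / 3.0
    return Plane(origin, z), frame
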