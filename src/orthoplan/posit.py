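"""Natural-head-position (NHP) reproduction from a single photograph.

Head orientation in a clinical photograph is recovered with POSIT ("pose
from orthography and scaling with iterations"): given >= 4 non-coplanar 3D
facial landmarks on the CT model and their 2D pixel positions in the
photograph, POSIT solves the scaled-orthographic pose from the model-point
pseudo-inverse and iteratively applies perspective corrections until the
pose converges.  Applying the recovered rotation (the translation is
discarded — NHP is an orientation) re-poses the CT skeletal model into the
upright natural head position that the photograph records.

The camera model is a simple pinhole: focal length in pixels and principal
point, with the camera looking down +z so a point ``(X, Y, Z)`` projects to
``u = f*X/Z + u0``, ``v = f*Y/Z + v0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DegenerateGeometryError, RigidTransform
from .io import LandmarkSet

__all__ = ["FRONTAL_VIEW", "CameraModel", "PoseEstimate", "posit_pose",
           "project_points", "reproduce_nhp"]

# Fixed rotation from the head/CT frame (+x patient-left, +y anterior,
# +z superior) into the camera frame of a frontal facial photograph: the
# camera looks at the face along the anterior axis, so image u spans
# left-right, image v spans inferior-superior, and depth decreases as the
# face approaches the camera.
FRONTAL_VIEW = np.array([
    [1.0, 0.0, 0.0],   # cam x = head x
    [0.0, 0.0, 1.0],   # cam y = head z
    [0.0, -1.0, 0.0],  # cam z = head -y (into the scene)
])


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics: focal length and principal point, both in pixels."""

    focal: float = 2000.0
    principal_point: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.focal <= 0:
            raise ValueError("focal length must be positive")


@dataclass(frozen=True)
class PoseEstimate:
    rotation: np.ndarray
    translation: np.ndarray
    iterations: int
    residual_px: float


def project_points(points: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Perspective-project camera-frame points; all must be in front (Z > 0)."""
    pts = np.asarray(points, dtype=float)
    if np.any(pts[:, 2] <= 0):
        raise ValueError("point behind the camera (Z <= 0)")
    u0, v0 = camera.principal_point
    return np.column_stack([
        camera.focal * pts[:, 0] / pts[:, 2] + u0,
        camera.focal * pts[:, 1] / pts[:, 2] + v0,
    ])


def _matched_arrays(image_points, model_points):
    if isinstance(image_points, dict):
        if not isinstance(model_points, dict):
            raise TypeError("pass both landmark sets as mappings, or both as arrays")
        names = [n for n in model_points if n in image_points]
        missing = set(image_points) ^ set(model_points)
        if len(names) < 4:
            raise ValueError(
                f"need >= 4 corresponding named points, found {len(names)} "
                f"(unmatched: {sorted(missing)})"
            )
        img = np.array([np.asarray(image_points[n], dtype=float) for n in names])
        mod = np.array([np.asarray(model_points[n], dtype=float) for n in names])
        return img, mod, names
    img = np.asarray(image_points, dtype=float)
    mod = np.asarray(model_points, dtype=float)
    if len(img) != len(mod) or len(img) < 4:
        raise ValueError("need >= 4 corresponding points with equal counts")
    return img, mod, None


def posit_pose(image_points, model_points, camera: CameraModel | None = None,
               tol: float = 1e-8, max_iterations: int = 50) -> PoseEstimate:
    """Classic POSIT: pose of a rigid landmark set from one photograph.

    Parameters
    ----------
    image_points
        Mapping ``name -> (u, v)`` pixels, or an (N, 2) array.
    model_points
        Mapping ``name -> (x, y, z)`` mm in the model frame, or an (N, 3)
        array in corresponding order.
    camera
        Pinhole intrinsics; defaults to a 2000 px focal length with the
        principal point at the image origin.

    Returns the rotation and translation taking model coordinates into the
    camera frame, with the final image-space residual in pixels.

    Raises
    ------
    DegenerateGeometryError
        If the centered model points are coplanar/collinear (condition
        number above 1e6) so the pseudo-inverse is unreliable.
    """
    camera = camera or CameraModel()
    img, mod, _ = _matched_arrays(image_points, model_points)

    # object vectors relative to the reference (first) landmark
    a = mod - mod[0]
    sv = np.linalg.svd(a[1:], compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > 1e6:
        raise DegenerateGeometryError(
            "model landmarks are coplanar or collinear; POSIT needs a 3D spread"
        )
    b = np.linalg.pinv(a)  # (3, N) pseudo-inverse of the object matrix

    u0, v0 = camera.principal_point
    uv = img - np.array([u0, v0])
    f = camera.focal

    eps = np.zeros(len(mod))
    rot = np.eye(3)
    tz = None
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        x = uv[:, 0] * (1 + eps) - uv[0, 0]
        y = uv[:, 1] * (1 + eps) - uv[0, 1]
        i_vec = b @ x
        j_vec = b @ y
        s1, s2 = np.linalg.norm(i_vec), np.linalg.norm(j_vec)
        if s1 < 1e-300 or s2 < 1e-300:
            raise DegenerateGeometryError("degenerate POSIT system (zero scale)")
        s = (s1 + s2) / 2.0
        r1 = i_vec / s1
        r2 = j_vec / s2
        # orthonormalise the first two rows, complete with the cross product
        r2 = r2 - (r2 @ r1) * r1
        r2 /= np.linalg.norm(r2)
        r3 = np.cross(r1, r2)
        rot = np.vstack([r1, r2, r3])
        tz = f / s
        eps_new = (a @ r3) / tz
        if np.max(np.abs(eps_new - eps)) < tol:
            eps = eps_new
            break
        eps = eps_new

    # camera coordinates of the reference landmark, then shift to the model origin
    p0 = np.array([uv[0, 0] / f * tz, uv[0, 1] / f * tz, tz])
    trans = p0 - rot @ mod[0]
    cam_pts = mod @ rot.T + trans
    residual = float(np.sqrt(np.mean(np.sum((project_points(cam_pts, camera) - img) ** 2, axis=1))))
    return PoseEstimate(rot, trans, iterations, residual)


def reproduce_nhp(model, model_landmarks: LandmarkSet, photo_landmarks,
                  camera: CameraModel | None = None):
    """Re-pose a CT skeletal model into the photograph's natural head position.

    Estimates the head pose with :func:`posit_pose`, removes the fixed
    frontal-view camera orientation (:data:`FRONTAL_VIEW`) to express the
    pose in the CT/global frame, and applies only the rotation to the model
    and landmarks — the natural head position is an orientation, so the
    translation is discarded.

    Returns ``(nhp_model, nhp_landmarks, rotation)``.
    """
    pose = posit_pose(photo_landmarks, model_landmarks, camera)
    rotation = FRONTAL_VIEW.T @ pose.rotation
    transform = RigidTransform(rotation, np.zeros(3))
    nhp_model = model.copy()
    nhp_model.vertices = transform.apply(np.asarray(model.vertices))
    return nhp_model, model_landmarks.transformed(transform), rotation
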