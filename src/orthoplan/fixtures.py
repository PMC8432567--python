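"""Synthetic phantom inputs with known ground truth.

Patient CT and scan data for this workflow are not shareable, so every input
the pipeline consumes can be generated here as a stylised phantom: an
ellipsoidal cranium with a parabolic dental-arch "maxilla" carrying all
vocabulary landmarks, noisy partially-overlapping dentition scans displaced
by a known rigid transform, perspective-projected facial landmarks under a
known head rotation, and "postoperative" models built from a simulation
model by a known maxillary displacement under a known global re-pose.

The geometry is deliberately non-anatomical: the registration, pose and
evaluation algorithms only require region structure, landmark placement and
realistic length scales (mm), not anatomy.  All generators are
deterministic per seed, and each generator draws from its own seeded
stream, so adding one never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import RigidTransform, euler_compose, rotation_about_center
from .io import FACIAL_LANDMARKS, LandmarkSet
from .planning import Displacement6, occlusal_plane
from .posit import CameraModel, project_points

__all__ = [
    "PhantomSpec",
    "SkullPhantom",
    "make_dentition_scan",
    "make_photo_projection",
    "make_postop_case",
    "make_skull_phantom",
]

# per-generator RNG stream ids (namespaced so streams never collide)
_STREAM_PHANTOM, _STREAM_SCAN, _STREAM_PHOTO, _STREAM_POSTOP = range(4)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class PhantomSpec:
    seed: int = 0
    target_vertices: int = 800       # approximate phantom resolution
    noise_sigma: float = 0.0         # surface jitter, mm
    overlap: float = 1.0             # scan overlap fraction

    def __post_init__(self) -> None:
        if self.target_vertices < 100:
            raise ValueError("resolution below 100 vertices is too degenerate")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not 0 < self.overlap <= 1:
            raise ValueError("overlap must lie in (0, 1]")


@dataclass(frozen=True)
class SkullPhantom:
    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    cranial_indices: np.ndarray      # cranium vertices (non-surgically exposed)
    maxilla_indices: np.ndarray      # dental-arch vertices (surgical region)
    spec: PhantomSpec = field(default_factory=PhantomSpec)


# canonical landmark template, mm; +x patient-left, +y anterior, +z superior.
# The cranium ellipsoid occupies z in [-15, 95]; the dental arch hangs below
# it (occlusal level z = -40) so the two regions are spatially separate.
_ARCH_RADIUS = 28.0
_ARCH_CENTER_Y = 25.0
_ARCH_Z = -40.0


def _arch_point(theta_deg: float, radius: float = _ARCH_RADIUS, z: float = _ARCH_Z):
    t = np.radians(theta_deg)
    return np.array([radius * np.sin(t), _ARCH_CENTER_Y + radius * np.cos(t), z])


def _landmark_template() -> LandmarkSet:
    lm = LandmarkSet()
    # tooth landmarks around the arch; patient-right is -x (negative angles)
    for side, sign in (("right", -1.0), ("left", 1.0)):
        lm[f"{side} incisor"] = _arch_point(sign * 8)
        lm[f"{side} canine"] = _arch_point(sign * 30)
        lm[f"{side} 1st molar"] = _arch_point(sign * 60)
        lm[f"{side} 2nd molar"] = _arch_point(sign * 78)
        lm[f"mesiobuccal cusp {side} 1st molar"] = _arch_point(sign * 58, radius=29.5)
    lm["central-incisor midpoint"] = 0.5 * (lm["right incisor"] + lm["left incisor"])
    # facial landmarks; pronasale offset anteriorly so the set is non-coplanar
    lm["pronasale"] = np.array([0.0, 68.0, -12.0])
    for side, sign in (("right", -1.0), ("left", 1.0)):
        lm[f"{side} exocanthion"] = np.array([sign * 45.0, 42.0, 15.0])
        lm[f"{side} endocanthion"] = np.array([sign * 15.0, 52.0, 15.0])
        lm[f"{side} cheilion"] = np.array([sign * 22.0, 54.0, -34.0])
    return lm


def _make_cranium(subdivisions: int) -> trimesh.Trimesh:
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    unit = np.asarray(sphere.vertices)
    # distinct semi-axes plus low-frequency bumps: a plain ellipsoid is too
    # close to rotationally symmetric for surface registration to lock onto
    bump = 1.0 + 0.04 * np.sin(3.1 * unit[:, 0] + 1.0) * np.cos(2.3 * unit[:, 1]) \
        + 0.03 * np.sin(2.7 * unit[:, 2] - 0.5)
    verts = unit * bump[:, None] * np.array([52.0, 66.0, 58.0]) + np.array([0.0, 0.0, 40.0])
    return trimesh.Trimesh(vertices=verts, faces=sphere.faces, process=False)


def _make_arch(n_segments: int) -> trimesh.Trimesh:
    """Swept-rectangle dental arch with sinusoidal cusp bumps."""
    thetas = np.linspace(-np.radians(85), np.radians(85), n_segments)
    # rectangular cross-section offsets: (radial, z)
    section = [(-3.0, 0.0), (3.0, 0.0), (3.0, 14.0), (-3.0, 14.0)]
    verts = []
    for t in thetas:
        bump = 0.8 * np.cos(8 * t)  # stylised cusps
        for dr, dz in section:
            r = _ARCH_RADIUS + dr + bump
            verts.append([r * np.sin(t), _ARCH_CENTER_Y + r * np.cos(t), _ARCH_Z - 2 + dz])
    verts = np.array(verts)
    faces = []
    k = len(section)
    for i in range(n_segments - 1):
        for j in range(k):
            a = i * k + j
            b = i * k + (j + 1) % k
            c = (i + 1) * k + j
            d = (i + 1) * k + (j + 1) % k
            faces.append([a, b, d])
            faces.append([a, d, c])
    # end caps
    for base, order in ((0, (0, 1, 2, 0, 2, 3)), ((n_segments - 1) * k, (0, 2, 1, 0, 3, 2))):
        idx = [base + o for o in order]
        faces.append(idx[:3])
        faces.append(idx[3:])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def make_skull_phantom(spec: PhantomSpec | None = None) -> SkullPhantom:
    """Stylised skull phantom: ellipsoid cranium plus dental arch.

    Returns the combined mesh, the full landmark vocabulary, and index sets
    for the cranial (registration) and maxillary (surgical) vertex regions.
    Deterministic per ``spec.seed``.
    """
    spec = spec or PhantomSpec()
    # icosphere sizes: subdiv 2 -> 162 verts, 3 -> 642, 4 -> 2562
    subdiv = 2 if spec.target_vertices < 500 else (3 if spec.target_vertices < 2000 else 4)
    n_segments = max(12, spec.target_vertices // 16)
    cranium = _make_cranium(subdiv)
    arch = _make_arch(n_segments)
    n_cranium = len(cranium.vertices)
    mesh = trimesh.util.concatenate([cranium, arch])
    if spec.noise_sigma > 0:
        rng = _rng(spec.seed, _STREAM_PHANTOM)
        mesh.vertices = mesh.vertices + rng.normal(0, spec.noise_sigma, mesh.vertices.shape)
    landmarks = _landmark_template()
    cranial = np.arange(n_cranium)
    maxilla = np.arange(n_cranium, len(mesh.vertices))
    return SkullPhantom(mesh, landmarks, cranial, maxilla, spec)


def make_dentition_scan(model: trimesh.Trimesh, region, true_transform: RigidTransform,
                        sigma: float = 0.0, overlap: float = 1.0, seed: int = 0):
    """Emulate an optical dentition scan of a model region.

    Extracts the submesh spanned by the ``region`` vertex indices, randomly
    drops ``1 - overlap`` of its faces, jitters vertices with Gaussian noise
    of ``sigma`` mm, and moves the result by the *inverse* of
    ``true_transform`` — so fusing the scan back onto the model must recover
    ``true_transform``.

    Returns ``(scan_mesh, true_transform)``.
    """
    region = np.asarray(list(region), dtype=int)
    if len(region) == 0:
        raise ValueError("region is empty")
    in_region = np.zeros(len(model.vertices), dtype=bool)
    in_region[region] = True
    face_mask = in_region[model.faces].all(axis=1)
    sub = model.submesh([np.flatnonzero(face_mask)], append=True)
    rng = _rng(seed, _STREAM_SCAN)
    if overlap < 1.0:
        n_keep = int(round(len(sub.faces) * overlap))
        keep = rng.choice(len(sub.faces), size=max(n_keep, 1), replace=False)
        sub = sub.submesh([np.sort(keep)], append=True)
    if len(sub.vertices) < 50:
        raise ValueError(
            f"scan would have only {len(sub.vertices)} vertices; overlap too low")
    verts = np.asarray(sub.vertices, dtype=float)
    if sigma > 0:
        verts = verts + rng.normal(0, sigma, verts.shape)
    verts = true_transform.inverse().apply(verts)
    scan = trimesh.Trimesh(vertices=verts, faces=sub.faces, process=False)
    return scan, true_transform


def make_photo_projection(landmarks: LandmarkSet, true_rotation: np.ndarray,
                          camera: CameraModel | None = None, distance: float = 1500.0,
                          pixel_noise: float = 0.0, seed: int = 0,
                          names=FACIAL_LANDMARKS):
    """Emulate a frontal clinical photograph's 2D facial landmarks.

    The named model landmarks are rotated by ``true_rotation`` about their
    centroid, viewed through the fixed frontal camera orientation
    (:data:`~orthoplan.posit.FRONTAL_VIEW`, looking at the face along the
    anterior axis) at ``distance`` mm, and perspective-projected; seeded
    Gaussian pixel noise is added.

    Returns ``(photo_landmarks, true_rotation)`` where photo landmarks map
    names to (u, v) pixel coordinates.
    """
    from .posit import FRONTAL_VIEW

    if distance <= 0:
        raise ValueError("camera distance must be positive")
    camera = camera or CameraModel()
    names = [n for n in names if n in landmarks]
    pts = landmarks.as_array(names)
    centroid = pts.mean(axis=0)
    cam_pts = (pts - centroid) @ (FRONTAL_VIEW @ np.asarray(true_rotation, dtype=float)).T
    cam_pts = cam_pts + np.array([0.0, 0.0, distance])
    uv = project_points(cam_pts, camera)
    if pixel_noise > 0:
        uv = uv + _rng(seed, _STREAM_PHOTO).normal(0, pixel_noise, uv.shape)
    return {n: uv[i] for i, n in enumerate(names)}, np.asarray(true_rotation, dtype=float)


@dataclass(frozen=True)
class PostopCase:
    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    cranial_indices: np.ndarray
    applied: Displacement6
    landmark_displacement: dict      # name -> true displacement vector (sim frame)
    global_pose: RigidTransform


def _maxilla_transform(applied: Displacement6, center: np.ndarray) -> RigidTransform:
    rot = euler_compose((applied.pitch, applied.roll, applied.yaw))
    about = RigidTransform(rot, center - rot @ center)
    shift = RigidTransform(np.eye(3), [applied.left_right, applied.advance_setback,
                                       applied.impaction_elongation])
    return shift.compose(about)


def make_postop_case(sim_mesh: trimesh.Trimesh, sim_landmarks: LandmarkSet,
                     maxilla_region, applied: Displacement6,
                     global_pose: RigidTransform | None = None,
                     cranial_sigma: float = 0.0, seed: int = 0,
                     cranial_indices=None) -> PostopCase:
    """Emulate a postoperative CT model from a simulation model.

    The maxillary region (vertices in ``maxilla_region``) and the tooth and
    occlusal landmarks are displaced by ``applied`` — the rotation taken
    about the occlusal-frame origin, then the translation.  Gaussian noise
    of ``cranial_sigma`` mm is added to the cranial vertices, and the whole
    model is re-posed by ``global_pose`` (emulating a different scanner
    pose).  The ground truth stored in the returned case is ``applied`` plus
    the exact per-landmark displacement vectors in the simulation frame.
    """
    maxilla_region = np.asarray(list(maxilla_region), dtype=int)
    if len(maxilla_region) == 0:
        raise ValueError("maxilla region is empty")
    global_pose = global_pose or RigidTransform.identity()
    plane, _ = occlusal_plane(sim_landmarks)
    t_app = _maxilla_transform(applied, plane.origin)

    verts = np.asarray(sim_mesh.vertices, dtype=float).copy()
    verts[maxilla_region] = t_app.apply(verts[maxilla_region])
    if cranial_indices is None:
        in_max = np.zeros(len(verts), dtype=bool)
        in_max[maxilla_region] = True
        cranial_indices = np.flatnonzero(~in_max)
    cranial_indices = np.asarray(list(cranial_indices), dtype=int)
    if cranial_sigma > 0:
        rng = _rng(seed, _STREAM_POSTOP)
        verts[cranial_indices] = verts[cranial_indices] + rng.normal(
            0, cranial_sigma, (len(cranial_indices), 3))

    moved = LandmarkSet()
    displacement = {}
    for name, p in sim_landmarks.items():
        if name in FACIAL_LANDMARKS:
            q = p.copy()
        else:
            q = t_app.apply(p)
        displacement[name] = q - p
        moved[name] = q

    verts = global_pose.apply(verts)
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(sim_mesh.faces), process=False)
    return PostopCase(mesh, moved.transformed(global_pose), cranial_indices,
                      applied, displacement, global_pose)
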