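"""Rigid surface registration: trimmed k-d-tree ICP and rigid coherent point
drift (CPD), plus the dentition-fusion and cranial-base pipelines built on
them.

The fusion pipeline aligns an optical dentition scan to a CT-derived skeletal
surface: trimmed ICP provides the coarse alignment, then rigid CPD — an EM
fit of a Gaussian-mixture correspondence model with an explicit uniform
outlier component — refines it.  The same trimmed ICP, restricted to a
cranial-base vertex mask, registers postoperative to simulation models for
the accuracy evaluation.

"ICP" here means point-to-point iterative closest point with two
modifications, each of which can be switched off: correspondences farther
than ``max_distance`` are rejected, and the worst ``trim_fraction`` of the
surviving pairs is discarded before the least-squares fit.  With
``trim_fraction=0`` and ``max_distance=inf`` it reduces to classic ICP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .geometry import RigidTransform, superpose_rigid

__all__ = [
    "CPDParams",
    "ICPParams",
    "NoOverlapError",
    "RegistrationResult",
    "cpd_rigid_register",
    "fuse_dentition",
    "icp_register",
    "nearest_neighbors",
    "register_cranial_base",
]


class NoOverlapError(RuntimeError):
    """All correspondences were rejected; the surfaces do not overlap."""


@dataclass(frozen=True)
class ICPParams:
    max_iterations: int = 100
    tolerance: float = 1e-6          # convergence threshold on RMS change, mm
    max_distance: float = np.inf     # correspondence rejection radius, mm
    trim_fraction: float = 0.1       # worst fraction of pairs discarded

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim_fraction <= 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class CPDParams:
    outlier_weight: float = 0.1      # w: mass of the uniform outlier component
    max_iterations: int = 150
    tolerance: float = 1e-8          # convergence threshold on objective change
    estimate_scale: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.outlier_weight < 1.0:
            raise ValueError("outlier_weight must lie in [0, 1)")


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    rms: float
    iterations: int
    converged: bool
    scale: float = 1.0
    history: tuple = ()      # per-iteration RMS (ICP) or objective (CPD)


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, trimesh.Trimesh):
        return np.asarray(obj.vertices, dtype=float)
    pts = np.asarray(obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (N, 3) points, got shape {pts.shape}")
    return pts


def nearest_neighbors(query, reference):
    """Exact nearest reference point for each query point.

    Returns ``(indices, distances)``; backed by a k-d tree, so exact but far
    cheaper than the quadratic scan for surface-sized point sets.
    """
    ref = _as_points(reference)
    if len(ref) == 0:
        raise ValueError("reference point set is empty")
    q = _as_points(query)
    dist, idx = cKDTree(ref).query(q, k=1)
    return np.asarray(idx), np.asarray(dist)


def icp_register(source, target, params: ICPParams | None = None,
                 init: RigidTransform | None = None) -> RegistrationResult:
    """Trimmed point-to-point ICP from ``source`` onto ``target``.

    Each iteration corresponds transformed source points to their nearest
    target points, rejects pairs beyond ``max_distance`` and the worst
    ``trim_fraction`` of the rest, and re-solves the rigid superposition on
    the survivors.  Stops when the kept-pair RMS changes by less than
    ``tolerance`` or at ``max_iterations``.
    """
    params = params or ICPParams()
    transform = init or RigidTransform.identity()
    src = _as_points(source)
    if len(src) < 3:
        raise ValueError("at least 3 source points are required")
    tgt = _as_points(target)
    tree = cKDTree(tgt)

    rms_prev = np.inf
    rms = np.inf
    iterations = 0
    converged = False
    history = []
    for iterations in range(1, params.max_iterations + 1):
        moved = transform.apply(src)
        dist, idx = tree.query(moved, k=1)
        keep = dist <= params.max_distance
        if keep.sum() < 3:
            raise NoOverlapError(
                f"only {int(keep.sum())} correspondences within "
                f"{params.max_distance} mm; surfaces do not overlap"
            )
        kept_idx = np.flatnonzero(keep)
        if params.trim_fraction > 0 and len(kept_idx) > 3:
            n_keep = max(3, int(np.ceil(len(kept_idx) * (1 - params.trim_fraction))))
            order = np.argsort(dist[kept_idx], kind="stable")
            kept_idx = kept_idx[order[:n_keep]]
        transform = superpose_rigid(src[kept_idx], tgt[idx[kept_idx]])
        resid = transform.apply(src[kept_idx]) - tgt[idx[kept_idx]]
        rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
        history.append(rms)
        if abs(rms_prev - rms) < params.tolerance:
            converged = True
            break
        rms_prev = rms
    return RegistrationResult(transform, rms, iterations, converged, history=tuple(history))


def _cpd_objective(dist2, sigma2, w, n_dim, n_target, volume):
    """Negative log-likelihood of the GMM-plus-uniform-outlier model."""
    m = dist2.shape[0]
    gauss = np.exp(-dist2 / (2 * sigma2)) / ((2 * np.pi * sigma2) ** (n_dim / 2) * m)
    mixture = (1 - w) * gauss.sum(axis=0) + w / volume
    return -float(np.sum(np.log(np.maximum(mixture, 1e-300)))), gauss, mixture


def cpd_rigid_register(source, target, params: CPDParams | None = None,
                       init: RigidTransform | None = None) -> RegistrationResult:
    """Rigid coherent-point-drift registration of ``source`` onto ``target``.

    The transformed source points act as centroids of an isotropic Gaussian
    mixture generating the target points, with a uniform component of weight
    ``outlier_weight`` absorbing clutter.  EM alternates soft correspondence
    (E-step) with the closed-form weighted rigid fit and variance update
    (M-step); the negative log-likelihood is non-increasing.
    """
    params = params or CPDParams()
    transform = init or RigidTransform.identity()
    y = _as_points(source)   # moving: mixture centroids
    x = _as_points(target)   # fixed: data
    if len(y) == 0 or len(x) == 0:
        raise ValueError("point sets must be non-empty")
    m, n = len(y), len(x)
    d = 3

    span = x.max(axis=0) - x.min(axis=0)
    volume = float(np.prod(np.maximum(span, 1e-6)))
    w = params.outlier_weight

    ty = transform.apply(y)
    dist2 = ((x[None, :, :] - ty[:, None, :]) ** 2).sum(axis=2)
    sigma2 = dist2.sum() / (d * m * n)
    scale = 1.0

    obj_prev = np.inf
    iterations = 0
    converged = False
    degenerate = False
    history = []
    for iterations in range(1, params.max_iterations + 1):
        obj, gauss, mixture = _cpd_objective(dist2, sigma2, w, d, n, volume)
        history.append(obj)
        if abs(obj_prev - obj) < params.tolerance * max(1.0, abs(obj_prev)) \
                and np.isfinite(obj_prev):
            converged = True
            break
        obj_prev = obj
        # E-step: posterior responsibility of centroid m for target point n
        p = (1 - w) * gauss / np.maximum(mixture[None, :], 1e-300)
        np_ = p.sum()
        if np_ < 1e-12:
            raise NoOverlapError("all target points explained by the outlier component")
        # M-step: weighted rigid (optionally scaled) closed form
        p1 = p.sum(axis=1)          # (M,)
        pt1 = p.sum(axis=0)         # (N,)
        mu_x = (pt1 @ x) / np_
        mu_y = (p1 @ y) / np_
        xc = x - mu_x
        yc = y - mu_y
        a = xc.T @ p.T @ yc
        u, sv, vt = np.linalg.svd(a)
        c = np.diag([1.0, 1.0, np.sign(np.linalg.det(u @ vt))])
        rot = u @ c @ vt
        if params.estimate_scale:
            denom = float(p1 @ np.sum(yc**2, axis=1))
            scale = float(np.trace(np.diag(sv) @ c)) / max(denom, 1e-300)
        trans = mu_x - scale * rot @ mu_y
        rot_full = rot
        transform = RigidTransform(rot_full, trans)
        ty = scale * (y @ rot_full.T) + trans
        dist2 = ((x[None, :, :] - ty[:, None, :]) ** 2).sum(axis=2)
        # variance from the responsibility-weighted residuals
        sigma2_new = float((p * dist2).sum()) / (np_ * d)
        if sigma2_new < 1e-12:
            degenerate = True
            converged = True
            sigma2 = max(sigma2_new, 1e-12)
            break
        sigma2 = sigma2_new

    resid2 = dist2.min(axis=1)
    rms = float(np.sqrt(np.mean(resid2)))
    if degenerate:
        import warnings

        warnings.warn("CPD variance collapsed below 1e-12; treating as converged")
    return RegistrationResult(transform, rms, iterations, converged, scale=scale,
                              history=tuple(history))


def fuse_dentition(scan: trimesh.Trimesh, ct_model: trimesh.Trimesh,
                   icp: ICPParams | None = None,
                   cpd: CPDParams | None = None,
                   max_cpd_points: int = 600,
                   overlap_radius: float = 10.0,
                   seed: int = 0) -> RegistrationResult:
    """Fuse an optical dentition scan onto a CT skeletal model.

    Runs trimmed ICP of the scan vertices onto the CT surface, then refines
    with rigid CPD seeded by the ICP result.  The scan covers only the
    dentition, so the CPD target is cropped to CT vertices within
    ``overlap_radius`` mm of the ICP-aligned scan; the rest of the skeleton
    would otherwise bias the mixture fit.  Point sets larger than
    ``max_cpd_points`` are subsampled (deterministically per ``seed``) for
    the quadratic CPD stage.
    """
    if len(getattr(scan, "faces", [])) == 0 or len(getattr(ct_model, "faces", [])) == 0:
        raise ValueError("both meshes must be non-empty")
    icp_result = icp_register(scan.vertices, ct_model.vertices, icp)

    rng = np.random.default_rng(seed)
    src = np.asarray(scan.vertices, dtype=float)
    tgt = np.asarray(ct_model.vertices, dtype=float)
    _, dist_to_scan = nearest_neighbors(tgt, icp_result.transform.apply(src))
    near = dist_to_scan <= overlap_radius
    if near.sum() >= 50:
        tgt = tgt[near]
    if len(src) > max_cpd_points:
        src = src[rng.choice(len(src), max_cpd_points, replace=False)]
    if len(tgt) > max_cpd_points:
        tgt = tgt[rng.choice(len(tgt), max_cpd_points, replace=False)]
    cpd_result = cpd_rigid_register(src, tgt, cpd, init=icp_result.transform)
    return RegistrationResult(
        cpd_result.transform,
        cpd_result.rms,
        icp_result.iterations + cpd_result.iterations,
        cpd_result.converged,
        scale=cpd_result.scale,
        history=icp_result.history + cpd_result.history,
    )


def _principal_frame(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    frame = vt.T
    if np.linalg.det(frame) < 0:
        frame[:, 2] = -frame[:, 2]
    return centroid, frame


def _pca_inits(moving_pts: np.ndarray, fixed_pts: np.ndarray):
    """Candidate coarse alignments from principal axes.

    The principal frame of a point cloud is determined only up to axis
    flips; the four proper-rotation sign combinations are all returned (plus
    the identity is tried by the caller) and ICP disambiguates by residual.
    """
    mc, mf = _principal_frame(moving_pts)
    fc, ff = _principal_frame(fixed_pts)
    inits = []
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        flip = np.diag([sx, sy, sx * sy])
        rot = ff @ flip @ mf.T
        inits.append(RigidTransform(rot, fc - rot @ mc))
    return inits


def register_cranial_base(moving: trimesh.Trimesh, fixed: trimesh.Trimesh,
                          mask, params: ICPParams | None = None,
                          min_vertices: int = 100,
                          fixed_mask=None) -> RegistrationResult:
    """Register ``moving`` onto ``fixed`` on the cranial-base
    (non-surgically-exposed) regions.

    ``mask`` selects the cranial-base vertices of the moving mesh;
    ``fixed_mask`` those of the fixed mesh, defaulting to the same indices —
    valid whenever the two models share vertex ordering, as they do when a
    postoperative model is produced from the same segmentation pipeline or
    a synthetic perturbation.  The pose difference between the two scans is
    arbitrary, so ICP is restarted from the identity and from the four
    principal-axes alignments of the two cranial clouds; the restart with
    the lowest kept-pair RMS wins.  The returned transform is meant to be
    applied to the whole moving model and its landmarks downstream.
    """
    mask = np.asarray(list(mask), dtype=int)
    if len(mask) < min_vertices:
        raise ValueError(
            f"cranial-base mask selects {len(mask)} vertices; at least {min_vertices} required"
        )
    fixed_mask = mask if fixed_mask is None else np.asarray(list(fixed_mask), dtype=int)
    moving_pts = np.asarray(moving.vertices, dtype=float)[mask]
    fixed_pts = np.asarray(fixed.vertices, dtype=float)[fixed_mask]
    best = None
    for init in [None, *_pca_inits(moving_pts, fixed_pts)]:
        try:
            result = icp_register(moving_pts, fixed_pts, params, init)
        except NoOverlapError:
            continue
        if best is None or result.rms < best.rms:
            best = result
    if best is None:
        raise NoOverlapError("cranial-base registration failed from every restart")
    return best
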