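"""Rigid registration: closed-form best fit (Kabsch/SVD) and ICP.

ICP here is the classic point-to-surface-correspondence variant: seeded
uniform subsampling of source vertices, closest points on the target
surface as correspondences, optional trimming of the worst correspondences
(guards partial overlap, e.g. a scan covering only part of a bone), and
the closed-form rigid update. Initialization is centroid + principal-axes
alignment with the proper-rotation sign combination that minimizes RMS;
the capture range is therefore limited (documented at roughly 15 deg /
10 mm beyond what the axes disambiguate) — no global search is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh import SurfaceQuery
from .transforms import RigidTransform

__all__ = ["ICPParams", "ICPResult", "best_fit_transform", "icp_register"]


@dataclass(frozen=True)
class ICPParams:
    max_iterations: int = 400
    convergence_tol: float = 1e-7  # mm change in RMS between iterations
    subsample_size: int = 600
    correspondence: str = "point_to_point"
    outlier_rejection: float = 100.0  # distance percentile kept (100 = no trimming)
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.correspondence != "point_to_point":
            raise ValueError("only point_to_point correspondence is implemented")


@dataclass(frozen=True)
class ICPResult:
    transform: RigidTransform
    rms: float
    iterations_used: int
    converged: bool
    rms_trace: tuple = field(default=(), repr=False)


def best_fit_transform(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping source points onto target points.

    Kabsch/SVD solution of ``argmin_{R,t} sum ||R s_i + t - d_i||^2`` over
    proper rotations; a reflection in the SVD solution is corrected by
    flipping the smallest singular direction.
    """
    src = np.asarray(source_points, float).reshape(-1, 3)
    dst = np.asarray(target_points, float).reshape(-1, 3)
    if len(src) != len(dst):
        raise ValueError("source and target must pair up one-to-one")
    if len(src) < 3:
        raise ValueError("need at least 3 point pairs")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 means the points are collinear: rotation about the line is free
    if np.sum(S > S[0] * 1e-9) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    return RigidTransform(rotation=R, translation=dc - R @ sc)


def _principal_axes_candidates(src_pts: np.ndarray, dst_pts: np.ndarray):
    """Proper-rotation initializations aligning source principal axes to
    target principal axes, over the four sign disambiguations."""
    sc, dc = src_pts.mean(axis=0), dst_pts.mean(axis=0)
    _, _, Vs = np.linalg.svd(src_pts - sc, full_matrices=False)
    _, _, Vd = np.linalg.svd(dst_pts - dc, full_matrices=False)
    if np.linalg.det(Vs) < 0:
        Vs[2] *= -1
    if np.linalg.det(Vd) < 0:
        Vd[2] *= -1
    out = []
    for flips in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        R = Vd.T @ np.diag(flips) @ Vs
        out.append(RigidTransform(rotation=R, translation=dc - R @ sc))
    return out


def _rms(query: SurfaceQuery, pts: np.ndarray) -> float:
    _, d, _ = query.closest(pts)
    return float(np.sqrt(np.mean(d**2)))


def icp_register(
    source: trimesh.Trimesh,
    target: trimesh.Trimesh,
    params: ICPParams = ICPParams(),
    initial: RigidTransform | None = None,
) -> ICPResult:
    """Register ``source`` onto ``target`` with point-to-point ICP.

    Returns the transform mapping source coordinates into the target frame,
    the final correspondence RMS (mm), and the per-iteration RMS trace
    (monotone non-increasing up to trimming effects).
    """
    if len(source.vertices) == 0 or len(target.vertices) == 0:
        raise ValueError("cannot register empty meshes")
    query = SurfaceQuery(target)
    src_all = source.vertices.view(np.ndarray)
    rng = np.random.default_rng(params.seed)
    if params.subsample_size and len(src_all) > params.subsample_size:
        idx = rng.choice(len(src_all), size=params.subsample_size, replace=False)
        src = src_all[idx]
    else:
        src = src_all.copy()

    if initial is not None:
        starts = [initial]
    else:
        # multi-start: refine every axis-sign candidate for a few iterations
        # before committing - on near-symmetric shapes (a near-circular bone
        # shaft has an approximate 180-degree symmetry) the raw initial RMS
        # can prefer a candidate that converges into a pseudo-symmetric
        # local minimum
        probe = src[:: max(1, len(src) // 300)]
        refined = []
        for cand in _principal_axes_candidates(src, target.vertices.view(np.ndarray)):
            for _ in range(20):
                moved = cand.apply(probe)
                cp, _, _ = query.closest(moved)
                cand = best_fit_transform(moved, cp).compose(cand)
            refined.append((_rms(query, cand.apply(probe)), cand))
        refined.sort(key=lambda c: c[0])
        starts = [refined[0][1]]
        # if the best start is not decisively better than the runner-up,
        # run the full loop from both and keep the better end state
        if len(refined) > 1 and refined[0][0] > 0.6 * refined[1][0]:
            starts.append(refined[1][1])

    best = None
    for T in starts:
        run = _icp_loop(query, src, T, params)
        if best is None or run.rms < best.rms:
            best = run
    return best


def _trim(d, moved, cp, params):
    if (
        params.outlier_rejection < 100.0
        and np.percentile(d, params.outlier_rejection) > 3.5 * np.median(d)
    ):
        # heavy far tail: correspondences falling off unmatched regions of a
        # partial scan; trim the whole tail. When the tail is consistent
        # with the bulk, nothing is trimmed - trimming there merely discards
        # the correspondences that pin the weak modes and stalls convergence.
        keep = d <= 3.5 * np.median(d)
        return moved[keep], cp[keep], d[keep]
    return moved, cp, d


def _icp_loop(
    query: SurfaceQuery, src: np.ndarray, T: RigidTransform, params: ICPParams
) -> ICPResult:
    """Inner ICP iteration with Besl-McKay-style step extrapolation.

    Plain ICP converges only linearly, painfully so along weakly
    constrained modes (azimuthal rotation of a near-circular bone shaft).
    When successive incremental updates point the same way, the geometric
    series they form is extrapolated in one jump; the jump is kept only if
    it does not increase the RMS, so the monotone-descent property of ICP
    is preserved.
    """
    from scipy.spatial.transform import Rotation

    trace = []
    prev_rms = np.inf
    converged = False
    iterations = 0
    prev_v = None
    cached = None  # correspondence reuse after an accepted extrapolation
    for iterations in range(1, params.max_iterations + 1):
        if cached is not None:
            moved, cp, d = cached
            cached = None
        else:
            moved = T.apply(src)
            cp, d, _ = query.closest(moved)
        moved_k, cp_k, d_k = _trim(d, moved, cp, params)
        rms = float(np.sqrt(np.mean(d_k**2)))
        trace.append(rms)
        if abs(prev_rms - rms) < params.convergence_tol:
            converged = True
            break
        prev_rms = rms
        T_plain = best_fit_transform(moved_k, cp_k).compose(T)
        delta = T_plain.compose(T.inverse())
        v = np.concatenate(
            [Rotation.from_matrix(delta.rotation).as_rotvec(), delta.translation]
        )
        T_next = T_plain
        if prev_v is not None:
            n_v, n_p = np.linalg.norm(v), np.linalg.norm(prev_v)
            if n_v > 0 and n_p > 0:
                cos = float(v @ prev_v) / (n_v * n_p)
                ratio = n_v / n_p
                if cos > 0.9 and ratio < 1.0:
                    factor = min(25.0, 1.0 / (1.0 - ratio))
                    if factor > 1.5:
                        big = RigidTransform(
                            rotation=Rotation.from_rotvec(factor * v[:3]).as_matrix(),
                            translation=factor * v[3:],
                        )
                        T_cand = big.compose(T)
                        moved_c = T_cand.apply(src)
                        cp_c, d_c, _ = query.closest(moved_c)
                        _, _, d_ck = _trim(d_c, moved_c, cp_c, params)
                        if float(np.sqrt(np.mean(d_ck**2))) <= rms:
                            T_next = T_cand
                            cached = (moved_c, cp_c, d_c)
                            v = factor * v
        T = T_next
        prev_v = v
    return ICPResult(
        transform=T,
        rms=trace[-1],
        iterations_used=iterations,
        converged=converged,
        rms_trace=tuple(trace),
    )
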