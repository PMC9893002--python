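"""Two-view rigid registration: sphere-marker initialization then
curvature-gated iterative-closest-point (ICP) refinement.

The coarse stage extracts the centers of three spherical target balls in
each view (algebraic least-squares sphere fit), matches the two center
triangles by side-length congruence, and solves the orthogonal Procrustes
problem for the initial motion.  The fine stage runs point-to-point ICP
in which candidate correspondences must agree both in distance (within a
cutoff) and in local surface variation — a curvature proxy computed from
the eigenvalues of each point's k-neighborhood covariance.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .transform import RigidTransform

log = logging.getLogger(__name__)


@dataclass
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float


@dataclass
class IcpParams:
    curvature_k: int = 20
    curvature_tol: float = 0.05       # absolute, on the [0, 1/3] surface-variation scale
    max_iterations: int = 50
    rmse_tolerance: float = 1e-6      # cm, convergence on RMSE change
    max_correspondence: float = 5.0   # cm
    #: require correspondences to be reciprocal (mutual nearest neighbors).
    #: Opposite-side views see complementary halves of every branch; plain
    #: nearest-neighbor pairing then locks back-surface points onto
    #: front-surface points and biases the translation by roughly the
    #: branch diameter.  A back-surface point is never the mutual nearest
    #: neighbor of a front-surface point when any genuinely shared point
    #: is nearby, so the reciprocity test rejects exactly the bias pairs.
    reciprocal: bool = True
    #: additionally keep only the closest ``trim_quantile`` fraction of
    #: surviving pairs each iteration (trimmed ICP).
    trim_quantile: float = 0.5

    def __post_init__(self) -> None:
        for name in ("curvature_k", "curvature_tol", "max_iterations",
                     "rmse_tolerance", "max_correspondence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.trim_quantile <= 1:
            raise ValueError("trim_quantile must be in (0, 1]")


class RegistrationError(RuntimeError):
    pass


def fit_sphere(points) -> SphereFit:
    """Algebraic least-squares sphere through >= 4 non-coplanar points.

    Linearizes ``|x - c|^2 = r^2`` into ``2 c . x + (r^2 - |c|^2) = |x|^2``
    and solves the overdetermined linear system.
    """
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, float)
    if len(pts) < 4:
        raise RegistrationError("sphere fit needs at least 4 points")
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = (pts ** 2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise RegistrationError("degenerate (coplanar) points: sphere is not determined")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise RegistrationError("sphere fit collapsed to non-positive radius")
    radius = float(np.sqrt(r2))
    res = np.linalg.norm(pts - center, axis=1) - radius
    return SphereFit(center=center, radius=radius, rms_residual=float(np.sqrt(np.mean(res ** 2))))


def match_markers(centers_F: np.ndarray, centers_B: np.ndarray, tol: float = 0.5) -> np.ndarray:
    """Correspondence between two marker-center triples by triangle congruence.

    Returns the permutation ``perm`` such that ``centers_B[perm[i]]``
    corresponds to ``centers_F[i]``.  Each vertex is keyed by the length of
    its opposite side; a near-equilateral triangle (side spread below
    ``2 * tol``) is ambiguous and rejected.
    """
    cF = np.asarray(centers_F, float).reshape(3, 3)
    cB = np.asarray(centers_B, float).reshape(3, 3)

    def opposite_sides(c):
        # side opposite vertex i connects the other two vertices
        return np.array([np.linalg.norm(c[(i + 1) % 3] - c[(i + 2) % 3]) for i in range(3)])

    sF, sB = opposite_sides(cF), opposite_sides(cB)
    if sF.max() - sF.min() < 2 * tol:
        raise RegistrationError("near-equilateral marker triangle: correspondence ambiguous")
    best, best_err = None, np.inf
    for perm in itertools.permutations(range(3)):
        err = np.abs(sF - sB[list(perm)]).max()
        if err < best_err:
            best, best_err = np.array(perm), err
    if best_err > tol:
        raise RegistrationError(
            f"marker triangles are not congruent within {tol} cm (best residual {best_err:.3g})")
    return best


def rigid_from_pairs(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid motion mapping ``src`` onto ``dst`` (Kabsch/SVD
    orthogonal Procrustes with reflection guard)."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if len(src) != len(dst) or len(src) < 3:
        raise ValueError("need >= 3 matched pairs")
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, S, Vt = np.linalg.svd(H)
    # collinear inputs leave the rotation about the line undetermined
    if S[1] < 1e-9 * max(S[0], 1.0):
        raise RegistrationError("collinear points: rigid motion is not determined")
    D = np.eye(3)
    if np.linalg.det(Vt.T @ U.T) < 0:
        D[2, 2] = -1.0
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cd - R @ cs)


def surface_variation(cloud, k: int = 20) -> np.ndarray:
    """Per-point surface variation: lambda0 / (lambda0+lambda1+lambda2) of
    the k-nearest-neighbor covariance eigenvalues (sorted ascending).

    0 on a perfect plane, up to 1/3 for a fully isotropic neighborhood.
    Degenerate (zero total variance) neighborhoods return 0.
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, float)
    if len(pts) <= k:
        raise ValueError(f"cloud size {len(pts)} must exceed k={k}")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)
    nb = pts[idx]  # (n, k+1, 3) includes the point itself
    nb = nb - nb.mean(axis=1, keepdims=True)
    cov = np.einsum("nij,nik->njk", nb, nb) / (k + 1)
    ev = np.linalg.eigvalsh(cov)  # ascending
    total = ev.sum(axis=1)
    out = np.zeros(len(pts))
    ok = total > 1e-18
    out[ok] = ev[ok, 0] / total[ok]
    return out


def icp_refine(
    source: PointCloud,
    target: PointCloud,
    init: RigidTransform,
    params: IcpParams = IcpParams(),
) -> Tuple[RigidTransform, List[float]]:
    """Point-to-point ICP with a curvature-similarity correspondence gate.

    Returns the composed transform (initialization included) and the RMSE
    trace over iterations; the trace is non-increasing because a step that
    fails to improve the RMSE is rejected and iteration stops.
    """
    if len(source) == 0 or len(target) == 0:
        raise RegistrationError("empty cloud")
    curv_s = surface_variation(source, params.curvature_k)
    curv_t = surface_variation(target, params.curvature_k)
    tree = cKDTree(target.points)

    current = init
    previous = init
    trace: List[float] = []
    for it in range(params.max_iterations):
        moved = current.apply(source.points)
        d, j = tree.query(moved)
        keep = (d <= params.max_correspondence) & \
               (np.abs(curv_s - curv_t[j]) <= params.curvature_tol)
        if params.reciprocal and keep.any():
            _, back = cKDTree(moved).query(target.points)
            keep &= back[j] == np.arange(len(moved))
        if params.trim_quantile < 1 and keep.any():
            keep &= d <= np.quantile(d[keep], params.trim_quantile)
        if not keep.any():
            raise RegistrationError(
                f"ICP iteration {it}: no correspondences within "
                f"{params.max_correspondence} cm and curvature tol {params.curvature_tol}")
        rmse = float(np.sqrt(np.mean(d[keep] ** 2)))
        if trace and rmse > trace[-1]:
            current = previous  # reject the non-improving step
            break
        trace.append(rmse)
        if len(trace) > 1 and trace[-2] - trace[-1] < params.rmse_tolerance:
            break
        step = rigid_from_pairs(moved[keep], target.points[j[keep]])
        previous = current
        current = step.compose(current)
    else:
        log.info("ICP hit the iteration cap (%d)", params.max_iterations)
    log.info("ICP finished after %d evaluations, final RMSE %.4g cm", len(trace), trace[-1])
    return current, trace


def registration_error(
    cloud_F: PointCloud,
    cloud_B: PointCloud,
    transform: RigidTransform,
    max_correspondence: float = 5.0,
) -> float:
    """RMS nearest-neighbor distance from the transformed back view to the
    front view, over the overlap (pairs within ``max_correspondence``)."""
    moved = transform.apply(cloud_B.points)
    d, _ = cKDTree(cloud_F.points).query(moved)
    overlap = d <= max_correspondence
    if not overlap.any():
        raise RegistrationError("no overlap between the views under this transform")
    return float(np.sqrt(np.mean(d[overlap] ** 2)))
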