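"""Seeded generator of ground-truth open-center trees and sampled point clouds.

Open-center (vase) training keeps a short vertical trunk that splits into
three or four outward-leaning scaffold ("primary") branches, each carrying
higher-order lateral branches.  Trees here are 1.5-1.9 m tall dwarf orchard
stock.  Every downstream stage — denoising, registration, skeletonization,
branch labeling, pruning-point placement — is tested against the exact
centerlines, per-point branch labels, rigid transforms and pruning points
this module fabricates.

Geometry is piecewise-linear centerlines (default 4 cm segments) with mild
random curvature; clouds are points sampled on cylinder surfaces around the
centerlines with Gaussian radial noise plus uniform box outliers.  All
randomness flows through one ``numpy.random.Generator`` derived from the
seed; identical seeds give bitwise-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .cloud import PointCloud
from .constants import BranchClass
from .transform import RigidTransform, rotation_about_axis

PRUNE_FRACTION = 2.0 / 3.0

# Default branch radii (cm) used when sampling cylinder surfaces.  The
# taper is roughly pipe-model consistent (trunk^2 ~ sum of primaries^2).
# Radii stay below R*tan(theta) ~ 3.4 cm so that a skeleton node near a
# branch axis always finds surface points inside its growth sector within
# the 8.2 cm search radius; dwarf stock is slender above the root collar.
CLASS_RADIUS = {
    BranchClass.TRUNK: 2.5,
    BranchClass.PRIMARY: 1.5,
    BranchClass.LATERAL: 0.8,
}


@dataclass
class GroundTruthTree:
    """Exact centerline model of one open-center tree.

    ``polylines[i]`` is an ``(k_i, 3)`` ordered centerline; ``parents[i]``
    is ``None`` for the trunk or ``(parent_polyline, parent_vertex)`` for
    the attachment of branch ``i``.
    """

    polylines: List[np.ndarray]
    branch_class: List[BranchClass]
    parents: List[Optional[Tuple[int, int]]]
    true_pruning_points: np.ndarray  # (n_primary, 3)
    root_radius: float
    radii: List[float] = field(default_factory=list)

    def arc_length(self, i: int) -> float:
        seg = np.diff(self.polylines[i], axis=0)
        return float(np.linalg.norm(seg, axis=1).sum())

    @property
    def height(self) -> float:
        return float(max(p[:, 2].max() for p in self.polylines))


@dataclass
class SceneSample:
    """A sampled cloud with its provenance: branch id/class per point,
    outward surface normals, and which points are planted outliers."""

    cloud: PointCloud
    branch_id: np.ndarray
    branch_class: np.ndarray
    normals: np.ndarray
    outlier_mask: np.ndarray
    seed: int
    tree: GroundTruthTree


@dataclass
class TwoViewSample:
    """Two partially occluded views of one scene, related by a known rigid
    motion, each carrying three spherical registration markers."""

    view_F: PointCloud
    view_B: PointCloud
    true_transform: RigidTransform  # maps view_B coordinates onto view_F's frame
    marker_centers_F: np.ndarray  # (3, 3) exact centers, view_F frame
    marker_centers_B: np.ndarray  # (3, 3) exact centers, view_B frame
    marker_clouds_F: List[PointCloud]
    marker_clouds_B: List[PointCloud]
    tree_mask_F: np.ndarray  # True where the view point belongs to the tree (not a marker)
    tree_mask_B: np.ndarray
    world_index_F: np.ndarray  # index into the source sample for each tree point
    world_index_B: np.ndarray


# ----------------------------------------------------------------------
# centerline construction


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _wiggly_polyline(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    rng: np.random.Generator,
    segment: float = 4.0,
    wiggle: float = 0.06,
) -> np.ndarray:
    """Piecewise-linear path of exact arc length ``length`` whose segment
    directions jitter around ``direction`` (fractional sigma ``wiggle``)."""
    d_nom = _unit(np.asarray(direction, float))
    pts = [np.asarray(start, float)]
    remaining = float(length)
    while remaining > 1e-9:
        step = min(segment, remaining)
        d = _unit(d_nom + rng.normal(0.0, wiggle, 3))
        pts.append(pts[-1] + step * d)
        remaining -= step
    return np.array(pts)


def _point_at_arc_fraction(poly: np.ndarray, fraction: float) -> np.ndarray:
    seg = np.diff(poly, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    target = fraction * lens.sum()
    cum = 0.0
    for i, L in enumerate(lens):
        if cum + L >= target - 1e-12:
            t = (target - cum) / L if L > 0 else 0.0
            return poly[i] + t * seg[i]
        cum += L
    return poly[-1].copy()


def generate_tree(
    trunk_height: float = 45.0,
    n_primary: int = 3,
    height: float = 170.0,
    seed: int = 0,
    segment: float = 4.0,
    n_lateral_per_primary: Tuple[int, int] = (1, 3),
    lateral_length: Tuple[float, float] = (25.0, 45.0),
    primary_elevation: Tuple[float, float] = (40.0, 55.0),
    root_radius: float = 4.1,
) -> GroundTruthTree:
    """Build one ground-truth open-center tree.

    ``height`` is the target total tree height in cm (dwarf orchard stock
    runs 150-190 cm); ``primary_elevation`` is the take-off angle of the
    scaffold branches above the horizontal, in degrees.  Vase training has
    no central leader: two scaffolds split from the trunk top and the rest
    attach along the upper trunk, all leaning well away from vertical.
    """
    if trunk_height <= 0:
        raise ValueError("trunk height must be positive")
    if not 3 <= n_primary <= 4:
        raise ValueError("open-center form carries 3 or 4 primary branches")
    if height <= trunk_height:
        raise ValueError("total height must exceed trunk height")
    rng = np.random.default_rng(seed)

    polylines: List[np.ndarray] = []
    classes: List[BranchClass] = []
    parents: List[Optional[Tuple[int, int]]] = []
    radii: List[float] = []

    trunk = _wiggly_polyline(np.zeros(3), np.array([0.0, 0.0, 1.0]), trunk_height, rng,
                             segment=segment, wiggle=0.02)
    polylines.append(trunk)
    classes.append(BranchClass.TRUNK)
    parents.append(None)
    radii.append(CLASS_RADIUS[BranchClass.TRUNK])

    # two scaffolds split at the trunk top; the others attach along the
    # upper trunk
    n_inner = n_primary - 2
    top_idx = len(trunk) - 1
    inner_idx = np.unique(
        np.clip(np.round(np.linspace(0.55, 0.85, n_inner) * top_idx).astype(int),
                1, top_idx - 1)
    )
    attach = list(inner_idx) + [top_idx, top_idx]

    azimuths = rng.uniform(0, 360) + np.arange(n_primary) * (360.0 / n_primary) \
        + rng.uniform(-15, 15, n_primary)
    pruning_points = []
    primary_ids = []
    for j, (vi, az) in enumerate(zip(attach, azimuths)):
        # the last-listed scaffold is the tallest: it fixes the tree height
        is_leader = j == n_primary - 1
        elev = rng.uniform(max(primary_elevation[0], primary_elevation[1] - 7.0),
                           primary_elevation[1]) if is_leader \
            else rng.uniform(*primary_elevation)
        d = np.array([
            np.cos(np.radians(elev)) * np.cos(np.radians(az)),
            np.cos(np.radians(elev)) * np.sin(np.radians(az)),
            np.sin(np.radians(elev)),
        ])
        start = trunk[vi]
        rise = height - start[2]
        L = rise / d[2]
        if not is_leader:
            L *= rng.uniform(0.7, 0.95)
        L = max(L, 60.0)
        poly = _wiggly_polyline(start, d, L, rng, segment=segment, wiggle=0.04)
        pid = len(polylines)
        polylines.append(poly)
        classes.append(BranchClass.PRIMARY)
        parents.append((0, vi))
        radii.append(CLASS_RADIUS[BranchClass.PRIMARY])
        primary_ids.append(pid)
        pruning_points.append(_point_at_arc_fraction(poly, PRUNE_FRACTION))

        n_lat = rng.integers(n_lateral_per_primary[0], n_lateral_per_primary[1] + 1)
        for _ in range(n_lat):
            frac = rng.uniform(0.25, 0.85)
            ai = max(1, min(len(poly) - 2, int(round(frac * (len(poly) - 1)))))
            lat_az = rng.uniform(0, 360)
            # laterals splay off the primary: rotate the primary direction
            # away by 35-65 degrees about a random perpendicular axis
            perp = _unit(np.cross(d, rotation_about_axis([0, 0, 1], lat_az) @ np.array([1.0, 0, 0]))
                         + 1e-12)
            lat_dir = rotation_about_axis(perp, rng.uniform(35, 65)) @ d
            # keep laterals between gently rising and moderately steep so
            # they neither dive into the ground nor overtop the scaffold
            lat_dir[2] = np.clip(abs(lat_dir[2]), 0.05, 0.6)
            lat_dir = _unit(lat_dir)
            lat_len = rng.uniform(*lateral_length)
            lat = _wiggly_polyline(poly[ai], lat_dir, lat_len, rng, segment=segment, wiggle=0.05)
            polylines.append(lat)
            classes.append(BranchClass.LATERAL)
            parents.append((pid, ai))
            radii.append(CLASS_RADIUS[BranchClass.LATERAL])

    return GroundTruthTree(
        polylines=polylines,
        branch_class=classes,
        parents=parents,
        true_pruning_points=np.array(pruning_points),
        root_radius=root_radius,
        radii=radii,
    )


# ----------------------------------------------------------------------
# cloud sampling


def sample_cloud(
    tree: GroundTruthTree,
    density: float = 1.5,
    noise_sigma: float = 0.15,
    outlier_frac: float = 0.02,
    seed: int = 0,
) -> SceneSample:
    """Sample points on cylinder surfaces around every centerline.

    ``density`` is points per cm^2 of branch surface; radial Gaussian noise
    of ``noise_sigma`` cm is added along the outward normal.  Outliers are
    drawn uniformly in the bounding box inflated by 20 cm so that the
    requested fraction of the final cloud is outliers (to rounding).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if not 0 <= outlier_frac < 0.2:
        raise ValueError("outlier fraction must be in [0, 0.2)")
    rng = np.random.default_rng(seed)

    pts, normals, bid, bcls = [], [], [], []
    for i, poly in enumerate(tree.polylines):
        r = tree.radii[i]
        seg = np.diff(poly, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        for s in range(len(seg)):
            if lens[s] <= 0:
                continue
            area = 2.0 * np.pi * r * lens[s]
            n = int(area * density)
            if rng.random() < area * density - n:
                n += 1
            if n == 0:
                continue
            axis = seg[s] / lens[s]
            # orthonormal frame around the segment axis
            a = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
            u = _unit(np.cross(axis, a))
            v = np.cross(axis, u)
            t = rng.uniform(0, lens[s], n)
            phi = rng.uniform(0, 2 * np.pi, n)
            nrm = np.outer(np.cos(phi), u) + np.outer(np.sin(phi), v)
            rad = r + rng.normal(0.0, noise_sigma, n)
            p = poly[s] + np.outer(t, axis) + nrm * rad[:, None]
            pts.append(p)
            normals.append(nrm)
            bid.append(np.full(n, i))
            bcls.append(np.full(n, int(tree.branch_class[i])))

    surface = np.vstack(pts)
    normals = np.vstack(normals)
    bid = np.concatenate(bid)
    bcls = np.concatenate(bcls)

    n_out = int(round(len(surface) * outlier_frac / (1.0 - outlier_frac)))
    lo = surface.min(axis=0) - 20.0
    hi = surface.max(axis=0) + 20.0
    out_pts = rng.uniform(lo, hi, (n_out, 3))
    out_nrm = rng.normal(size=(n_out, 3))
    out_nrm /= np.linalg.norm(out_nrm, axis=1, keepdims=True)

    all_pts = np.vstack([surface, out_pts])
    mask = np.zeros(len(all_pts), dtype=bool)
    mask[len(surface):] = True
    order = rng.permutation(len(all_pts))

    return SceneSample(
        cloud=PointCloud(all_pts[order], labels=np.concatenate([bid, np.full(n_out, -1)])[order]),
        branch_id=np.concatenate([bid, np.full(n_out, -1)])[order],
        branch_class=np.concatenate([bcls, np.full(n_out, -1)])[order],
        normals=np.vstack([normals, out_nrm])[order],
        outlier_mask=mask[order],
        seed=seed,
    tree=tree,
    )


# ----------------------------------------------------------------------
# two-view scenes with spherical markers

DEFAULT_MARKER_CENTERS = np.array([
    [70.0, 45.0, 12.0],
    [-65.0, 40.0, 30.0],
    [5.0, -75.0, 20.0],
])
MARKER_RADIUS = 3.5
MARKER_LABEL_BASE = 1000


def _sample_sphere(center, radius, n, noise_sigma, rng):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius + rng.normal(0.0, noise_sigma, n)
    return center + v * r[:, None]


def make_two_views(
    sample: SceneSample,
    transform: Optional[RigidTransform] = None,
    marker_centers: Optional[np.ndarray] = None,
    marker_radius: float = MARKER_RADIUS,
    marker_points: int = 400,
    noise_sigma: float = 0.0,
    see_through: float = 0.1,
    seed: int = 0,
) -> TwoViewSample:
    """Split a scene into front/back camera views with shared markers.

    The front camera looks along -y, the back camera (platform rotated
    half a turn) along +y.  A surface point survives in a view when its
    outward normal faces that camera, or with probability ``see_through``
    (thin branches are porous to a depth sensor).  ``transform`` is the
    rigid motion that carries back-view coordinates onto the front frame;
    the default is the platform's 180-degree yaw about the tree axis plus
    a small translation.
    """
    rng = np.random.default_rng(seed)
    if transform is None:
        transform = RigidTransform(rotation_about_axis([0, 0, 1], 180.0),
                                   np.array([8.0, -5.0, 1.5]))
    if marker_centers is None:
        marker_centers = DEFAULT_MARKER_CENTERS.copy()
    marker_centers = np.asarray(marker_centers, float).reshape(3, 3)
    sides = np.linalg.norm(marker_centers - np.roll(marker_centers, 1, axis=0), axis=1)
    area2 = np.linalg.norm(np.cross(marker_centers[1] - marker_centers[0],
                                    marker_centers[2] - marker_centers[0]))
    if area2 < 1e-6 * sides.max() ** 2:
        raise ValueError("marker centers are collinear")

    cam_F = np.array([0.0, 1.0, 0.0])   # direction from scene toward front camera
    cam_B = np.array([0.0, -1.0, 0.0])

    def visible(cam):
        facing = sample.normals @ cam > 0
        lucky = rng.random(len(sample.normals)) < see_through
        return (facing | lucky) & ~sample.outlier_mask

    idx_F = np.flatnonzero(visible(cam_F))
    idx_B = np.flatnonzero(visible(cam_B))

    inv = transform.inverse()

    def build_view(idx, to_view):
        tree_pts = sample.cloud.points[idx]
        tree_lbl = sample.branch_id[idx]
        marker_clouds = []
        m_pts, m_lbl = [], []
        for k, c in enumerate(marker_centers):
            sp = _sample_sphere(c, marker_radius, marker_points, noise_sigma, rng)
            sp_v = to_view(sp)
            marker_clouds.append(PointCloud(sp_v))
            m_pts.append(sp_v)
            m_lbl.append(np.full(len(sp), MARKER_LABEL_BASE + k))
        pts = np.vstack([to_view(tree_pts)] + m_pts)
        lbl = np.concatenate([tree_lbl] + m_lbl)
        tree_mask = np.zeros(len(pts), dtype=bool)
        tree_mask[: len(tree_pts)] = True
        return PointCloud(pts, labels=lbl), marker_clouds, tree_mask

    view_F, markers_F, mask_F = build_view(idx_F, lambda p: p)
    view_B, markers_B, mask_B = build_view(idx_B, inv.apply)

    return TwoViewSample(
        view_F=view_F,
        view_B=view_B,
        true_transform=transform,
        marker_centers_F=marker_centers.copy(),
        marker_centers_B=inv.apply(marker_centers),
        marker_clouds_F=markers_F,
        marker_clouds_B=markers_B,
        tree_mask_F=mask_F,
        tree_mask_B=mask_B,
        world_index_F=idx_F,
        world_index_B=idx_B,
    )
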