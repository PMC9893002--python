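"""Space colonization skeletonization.

The skeleton grows from a seed node by competing for "attraction" points
(the input cloud).  Each iteration:

1.  every attraction within the search radius ``R`` of its *nearest*
    skeleton node is assigned to that node's influence set ``S(p)``;
2.  each influenced node computes the neighborhood direction ``V_p``, the
    normalized sum of unit vectors toward its attractions;
3.  attractions outside the sector of half-angle ``theta`` around ``V_p``
    are discarded for this node;
4.  the growth direction ``f`` is the normalized sum of unit vectors
    toward the surviving sector attractions;
5.  a child node is spawned at distance ``Ds`` from its parent along ``f``
    (one child per influenced node per iteration);
6.  attractions within the deletion threshold ``Rd`` of any newly spawned
    node are consumed.

The loop ends when no attraction influences any node, or after
``max_iterations``, or after ``stall_limit`` consecutive iterations in
which nothing was spawned and nothing was consumed (isolated attraction
clusters can otherwise hold the loop open forever).  Defaults follow the
orchard-tree setting R = 8.2 cm, theta = 22.5 deg, Ds = 4.0 cm,
Rd = 6.0 cm.

Sign convention: direction vectors point from the skeleton node toward
the attraction points, so growth advances into unclaimed space.  The
``legacy_sign`` switch flips both sums to the opposite orientation for
side-by-side comparison; it is not useful for skeletonization.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .skeleton import Skeleton

log = logging.getLogger(__name__)

_TIE_EPS = 1e-12
_DUP_EPS = 1e-6


@dataclass
class ColonizationParams:
    R: float = 8.2          # search radius, cm
    theta: float = 22.5     # sector half-angle, degrees
    Ds: float = 4.0         # node spacing, cm
    Rd: float = 6.0         # attraction deletion threshold, cm
    max_iterations: int = 500
    stall_limit: int = 10
    legacy_sign: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.Ds <= self.Rd <= self.R):
            raise ValueError("parameters must satisfy 0 < Ds <= Rd <= R")
        if not (0 < self.theta < 90):
            raise ValueError("theta must lie in (0, 90) degrees")


class AttractionSet:
    """The shrinking set of space points still competing for the skeleton."""

    def __init__(self, points: np.ndarray):
        self.points = np.asarray(points, float).reshape(-1, 3)
        self.alive = np.ones(len(self.points), dtype=bool)

    def alive_points(self) -> np.ndarray:
        return self.points[self.alive]

    def alive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())


def assign_attractions(
    skeleton: Skeleton, attractions: AttractionSet, R: float
) -> Dict[int, np.ndarray]:
    """Map node id -> indices of attractions it influences.

    An attraction belongs to the influence set of its nearest skeleton
    node, and only if that distance is strictly below ``R``; ties on the
    nearest node go to the smaller node id.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    ids = skeleton.node_ids
    pos = skeleton.positions_array()
    pts = attractions.alive_points()
    idx = attractions.alive_indices()
    if len(pts) == 0 or len(ids) == 0:
        return {}
    tree = cKDTree(pos)
    k = min(2, len(ids))
    d, j = tree.query(pts, k=k)
    if k == 1:
        d = d[:, None]
        j = j[:, None]
    nearest = j[:, 0].copy()
    if k == 2:  # deterministic tie-break: lower node id wins
        tied = d[:, 1] - d[:, 0] < _TIE_EPS
        nearest[tied] = np.minimum(j[tied, 0], j[tied, 1])
    within = d[:, 0] < R
    out: Dict[int, np.ndarray] = {}
    id_arr = np.asarray(ids)
    for row in np.flatnonzero(within):
        nid = int(id_arr[nearest[row]])
        out.setdefault(nid, []).append(idx[row])
    return {nid: np.asarray(v) for nid, v in out.items()}


def _unit_sum(p: np.ndarray, targets: np.ndarray, legacy_sign: bool) -> np.ndarray:
    vecs = targets - p
    norms = np.linalg.norm(vecs, axis=1)
    ok = norms > 0
    s = (vecs[ok] / norms[ok, None]).sum(axis=0)
    return -s if legacy_sign else s


def neighborhood_direction(
    p: np.ndarray, attractions: np.ndarray, legacy_sign: bool = False
) -> Optional[np.ndarray]:
    """Unit vector V_p toward the influence set; None when the unit
    vectors cancel (symmetric surroundings)."""
    if len(attractions) == 0:
        raise ValueError("influence set is empty")
    s = _unit_sum(np.asarray(p, float), np.asarray(attractions, float), legacy_sign)
    n = np.linalg.norm(s)
    if n < 1e-12:
        return None
    return s / n


def growth_set(
    p: np.ndarray, V_p: np.ndarray, attractions: np.ndarray, theta: float
) -> np.ndarray:
    """Boolean mask of attractions inside the sector of half-angle
    ``theta`` (degrees, inclusive) around ``V_p``."""
    vecs = np.asarray(attractions, float) - np.asarray(p, float)
    norms = np.linalg.norm(vecs, axis=1)
    mask = norms > 0
    cosang = np.full(len(vecs), -1.0)
    cosang[mask] = vecs[mask] @ np.asarray(V_p, float) / norms[mask]
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) <= theta + 1e-12


def growth_direction(
    p: np.ndarray, subset: np.ndarray, legacy_sign: bool = False
) -> Optional[np.ndarray]:
    """Normalized growth vector f over the sector subset; None when the
    sum cancels."""
    if len(subset) == 0:
        raise ValueError("growth subset is empty")
    F = _unit_sum(np.asarray(p, float), np.asarray(subset, float), legacy_sign)
    n = np.linalg.norm(F)
    if n < 1e-12:
        return None
    return F / n


def spawn_node(skeleton: Skeleton, parent: int, f: np.ndarray, Ds: float) -> Optional[int]:
    """Append a child at ``parent_position + Ds * f``; returns None (no
    node) when the position duplicates an existing node."""
    f = np.asarray(f, float)
    if abs(np.linalg.norm(f) - 1.0) > 1e-6:
        raise ValueError("growth direction must be a unit vector")
    pos = skeleton.position(parent) + Ds * f
    existing = skeleton.positions_array()
    if len(existing) and np.min(np.linalg.norm(existing - pos, axis=1)) < _DUP_EPS:
        return None
    return skeleton.add_node(pos, parent=parent)


def kill_attractions(
    new_positions: np.ndarray, attractions: AttractionSet, Rd: float
) -> int:
    """Consume attractions within ``Rd`` (inclusive) of any new node;
    returns how many were removed."""
    if Rd <= 0:
        raise ValueError("Rd must be positive")
    new_positions = np.asarray(new_positions, float).reshape(-1, 3)
    if len(new_positions) == 0 or attractions.n_alive == 0:
        return 0
    idx = attractions.alive_indices()
    d, _ = cKDTree(new_positions).query(attractions.points[idx])
    dead = d <= Rd
    attractions.alive[idx[dead]] = False
    return int(dead.sum())


def default_seed_position(points: np.ndarray, slab: float = 2.0) -> np.ndarray:
    """Default root seed: the centroid of the lowest ``slab`` cm of the
    cloud, dropped to the floor of that slab.

    Horizontally this is the trunk axis; vertically it sits at the very
    bottom of the capture, so the base ring of trunk-surface points is
    azimuthally symmetric around the seed, the first neighborhood
    direction points straight up, and the chain starts along the trunk
    axis instead of jagging across the shell.
    """
    z = points[:, 2]
    sel = z <= z.min() + slab
    seed = points[sel].mean(axis=0)
    seed[2] = z.min()
    return seed


def colonize(
    cloud: PointCloud,
    seed_position: Optional[np.ndarray] = None,
    params: ColonizationParams = ColonizationParams(),
) -> Skeleton:
    """Grow a rooted skeleton through ``cloud`` by space colonization."""
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, float)
    if len(pts) == 0:
        raise ValueError("empty cloud")
    if seed_position is None:
        seed_position = default_seed_position(pts)
    seed_position = np.asarray(seed_position, float).reshape(3)
    lo, hi = pts.min(axis=0) - params.R, pts.max(axis=0) + params.R
    if np.any(seed_position < lo) or np.any(seed_position > hi):
        log.warning("seed position lies outside the cloud bounding box (inflated by R)")

    skeleton = Skeleton()
    skeleton.add_node(seed_position)
    attractions = AttractionSet(pts)
    stall = 0
    cause = "iteration cap"
    for it in range(params.max_iterations):
        influence = assign_attractions(skeleton, attractions, params.R)
        if not influence:
            cause = "no attraction influences any node"
            if it == 0:
                raise ValueError("seed not within search radius of any point")
            break
        new_ids: List[int] = []
        for nid in sorted(influence):
            att = attractions.points[influence[nid]]
            p = skeleton.position(nid)
            V_p = neighborhood_direction(p, att, params.legacy_sign)
            if V_p is None:
                continue
            sector = att[growth_set(p, V_p, att, params.theta)]
            if len(sector) == 0:
                # Degenerate sector: the influence set straddles diverging
                # branches (or surrounds the node) and no attraction falls
                # inside the cone.  Grow along V_p itself so the frontier
                # never freezes; the next node's Voronoi split separates
                # the branches.
                f = V_p
            else:
                f = growth_direction(p, sector, params.legacy_sign)
                if f is None:
                    continue
            child = spawn_node(skeleton, nid, f, params.Ds)
            if child is not None:
                new_ids.append(child)
        killed = 0
        if new_ids:
            killed = kill_attractions(
                np.array([skeleton.position(i) for i in new_ids]), attractions, params.Rd)
        log.debug("iteration %d: %d nodes spawned, %d attractions killed, %d alive",
                  it, len(new_ids), killed, attractions.n_alive)
        if not new_ids and killed == 0:
            stall += 1
            if stall >= params.stall_limit:
                cause = f"stalled for {params.stall_limit} iterations"
                break
        else:
            stall = 0
    log.info("colonization finished: %d nodes, %d attractions left (%s)",
             len(skeleton), attractions.n_alive, cause)
    return skeleton
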