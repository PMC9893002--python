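"""Pruned-tree cylinder modeling.

After the pruning plan is fixed, each cut removes the distal part of its
primary branch: a new vertex is inserted at the pruning position and the
entire subtree beyond it is deleted.  Branch radii then follow the pipe
model, ``r_parent^n = sum_i r_child_i^n`` with ``n = 2`` (cross-sectional
area is conserved across a junction, as if the stem were a bundle of
unit pipes each feeding a leaf).  The split among siblings is weighted by
the total edge length of each child subtree, a standard proxy for the
amount of foliage a limb supports.  Finally every skeleton edge becomes a
conical frustum, giving a watertight multi-segment cylinder model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import trimesh

from .analyze import PruningPlan
from .skeleton import Skeleton

log = logging.getLogger(__name__)


@dataclass
class RadiusMap:
    radii: Dict[int, float]     # node id -> beginning radius, cm
    exponent: float
    root_radius: float
    floored: Tuple[int, ...] = ()  # leaf ids clamped to the tip floor


@dataclass
class TreeMesh:
    vertices: np.ndarray
    faces: np.ndarray
    face_branch: np.ndarray     # per-face id of the child node of the host edge

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


def prune_skeleton(skeleton: Skeleton, plan: PruningPlan) -> Skeleton:
    """Apply every cut in the plan; returns a new skeleton.

    Each pruning point lies on a host edge (u, v): a vertex is inserted
    at the cut position as a new leaf child of ``u`` and the distal
    vertex ``v`` with all its descendants is removed.
    """
    pruned = skeleton.copy()
    for pt in plan.points:
        u, v = pt.host_edge
        if u not in pruned or v not in pruned or pruned.parent[v] != u:
            raise ValueError(f"pruning point host edge {pt.host_edge} is not in the skeleton")
        pu, pv = pruned.position(u), pruned.position(v)
        seg = pv - pu
        L2 = float(seg @ seg)
        t = float((np.asarray(pt.position) - pu) @ seg) / L2 if L2 > 0 else 0.0
        resid = np.linalg.norm(np.asarray(pt.position) - (pu + t * seg))
        if not (-1e-6 <= t <= 1 + 1e-6) or resid > 1e-6:
            raise ValueError(f"pruning point for branch {pt.branch_id} is not on its host edge")
        removed = pruned.remove_subtree(v)
        pruned.add_node(np.asarray(pt.position, float), parent=u)
        log.debug("cut branch %d: removed %d nodes", pt.branch_id, len(removed))
    return pruned


def _subtree_edge_length(skeleton: Skeleton, node: int) -> float:
    total = 0.0
    for n in skeleton.subtree(node):
        p = skeleton.parent[n]
        if p is not None:
            total += skeleton.edge_length(p, n)
    return total


def assign_radii(
    skeleton: Skeleton,
    root_radius: float = 4.1,
    exponent: float = 2.0,
    min_tip_radius: float = 0.2,
) -> RadiusMap:
    """Pipe-model radius allocation from the measured root radius.

    Along unbranched runs the radius is carried unchanged; at a junction
    with children of subtree weights ``w_i`` each child receives
    ``r_parent * (w_i / sum w)^(1/n)``, so ``sum r_child^n = r_parent^n``
    exactly.  Leaf radii are floored at ``min_tip_radius`` (logged).
    """
    if root_radius <= 0:
        raise ValueError("root radius must be positive")
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    skeleton.validate()
    radii: Dict[int, float] = {skeleton.root: float(root_radius)}
    floored: List[int] = []
    stack = [skeleton.root]
    while stack:
        n = stack.pop()
        kids = skeleton.children[n]
        r = radii[n]
        if len(kids) == 1:
            radii[kids[0]] = r
        elif len(kids) > 1:
            w = np.array([_subtree_edge_length(skeleton, c) + skeleton.edge_length(n, c)
                          for c in kids])
            if w.sum() <= 0:
                w = np.ones(len(kids))
            frac = w / w.sum()
            for c, fr in zip(kids, frac):
                radii[c] = r * fr ** (1.0 / exponent)
        stack.extend(kids)
    for leaf in skeleton.leaves():
        if radii[leaf] < min_tip_radius:
            radii[leaf] = min_tip_radius
            floored.append(leaf)
    if floored:
        log.info("tip radius floor %.2g cm applied to %d leaves", min_tip_radius, len(floored))
    return RadiusMap(radii=radii, exponent=exponent, root_radius=root_radius,
                     floored=tuple(floored))


def _ring(center: np.ndarray, axis: np.ndarray, radius: float, sides: int) -> np.ndarray:
    a = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, a)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    ang = 2 * np.pi * np.arange(sides) / sides
    return center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


def build_mesh(skeleton: Skeleton, radii: RadiusMap, sides: int = 16) -> TreeMesh:
    """One capped conical frustum per edge: base radius at the parent,
    top radius at the child, the edge as the axis."""
    if sides < 3:
        raise ValueError("need at least 3 sides per ring")
    verts: List[np.ndarray] = []
    faces: List[Tuple[int, int, int]] = []
    branch: List[int] = []

    for p, c in skeleton.edges():
        pp, pc = skeleton.position(p), skeleton.position(c)
        axis = pc - pp
        L = np.linalg.norm(axis)
        if L < 1e-12:
            log.warning("zero-length edge (%d, %d) skipped", p, c)
            continue
        axis = axis / L
        base = _ring(pp, axis, radii.radii[p], sides)
        top = _ring(pc, axis, radii.radii[c], sides)
        i0 = len(verts)
        verts.extend(base)
        verts.extend(top)
        verts.append(pp)  # base cap center
        verts.append(pc)  # top cap center
        ib, it_, cb, ct = i0, i0 + sides, i0 + 2 * sides, i0 + 2 * sides + 1
        for s in range(sides):
            s2 = (s + 1) % sides
            faces.append((ib + s, ib + s2, it_ + s))      # side lower tri
            faces.append((ib + s2, it_ + s2, it_ + s))    # side upper tri
            faces.append((cb, ib + s2, ib + s))           # base cap (faces down)
            faces.append((ct, it_ + s, it_ + s2))         # top cap (faces up)
            branch.extend([c, c, c, c])

    return TreeMesh(
        vertices=np.array(verts).reshape(-1, 3),
        faces=np.array(faces, dtype=np.int64).reshape(-1, 3),
        face_branch=np.array(branch, dtype=np.int64),
    )


def total_axis_length(skeleton: Skeleton) -> float:
    """Sum of all edge lengths — the total woody axis the mesh models."""
    return float(sum(skeleton.edge_length(p, c) for p, c in skeleton.edges()))
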