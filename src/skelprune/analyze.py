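"""Branch labeling and pruning-point placement on the skeleton graph.

The skeleton's parent->child links form a directed graph G(C, E).  The
trunk is traced greedily from the lowest node: at each junction the
successor edge with the smallest turn angle psi relative to the incoming
edge is taken, and tracing stops once even the best successor turns by
more than ``psi_max`` (open-center trunks are short and near-vertical, so
a hard turn marks the scaffold split).  Primary (scaffold) branches start
at trunk vertices with off-trunk successors and at the trunk top; within
each candidate subtree the origin-to-leaf path with the greatest
cumulative Euclidean length L_i wins, and candidates shorter than
``min_length`` (default 50 cm) are rejected as false branches and remain
lateral.  The pruning point of each primary branch sits at arc-length
fraction 2/3 of L_i from the branch origin: dormant pruning removes the
distal third of each scaffold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np

from .constants import BranchClass
from .skeleton import Skeleton

log = logging.getLogger(__name__)


@dataclass
class TrunkResult:
    vertices: List[int]          # ordered root-up
    edges: List[Tuple[int, int]]
    psi_max: float               # degrees


@dataclass
class PrimaryBranch:
    branch_id: int
    origin: int                  # PB_start trunk vertex
    path: List[int]              # origin ... leaf
    length: float                # L_i, cm


@dataclass
class PruningPoint:
    branch_id: int
    position: np.ndarray
    host_edge: Tuple[int, int]
    fraction: float              # arc-length fraction from the branch origin


@dataclass
class PruningPlan:
    points: List[PruningPoint] = field(default_factory=list)


@dataclass
class LabeledSkeleton:
    skeleton: Skeleton
    digraph: nx.DiGraph
    trunk: TrunkResult
    branches: List[PrimaryBranch]
    edge_class: Dict[Tuple[int, int], BranchClass]
    plan: Optional[PruningPlan] = None


def build_digraph(skeleton: Skeleton) -> nx.DiGraph:
    """Directed graph with one vertex per node and one parent->child edge
    per link; vertex attribute ``pos`` holds the 3D position."""
    skeleton.validate()
    G = nx.DiGraph()
    for nid in skeleton.node_ids:
        G.add_node(nid, pos=skeleton.position(nid))
    for p, c in skeleton.edges():
        G.add_edge(p, c)
    return G


def _edge_vec(G: nx.DiGraph, e: Tuple[int, int]) -> np.ndarray:
    return G.nodes[e[1]]["pos"] - G.nodes[e[0]]["pos"]


def turn_angle(G: nx.DiGraph, e_prev: Tuple[int, int], e_next: Tuple[int, int]) -> float:
    """psi: the angle (degrees) between two consecutive directed edges."""
    a, b = _edge_vec(G, e_prev), _edge_vec(G, e_next)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.degrees(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0))))


def _root_of(G: nx.DiGraph) -> int:
    roots = [n for n in G.nodes if G.in_degree(n) == 0]
    if len(roots) != 1:
        raise ValueError(f"graph has {len(roots)} roots; expected exactly one")
    return roots[0]


def identify_trunk(G: nx.DiGraph, psi_max: float = 30.0) -> TrunkResult:
    """Greedy minimum-turn trunk trace from the lowest-z vertex.

    The first trunk edge is the root's most vertical out-edge (smallest
    angle to +z); ties anywhere break toward the smaller child id.
    """
    root = _root_of(G)
    zs = {n: G.nodes[n]["pos"][2] for n in G.nodes}
    lowest = min(G.nodes, key=lambda n: (zs[n], n))
    if lowest != root:
        log.warning("lowest vertex %d is not the graph root %d; starting at the root", lowest, root)
    verts = [root]
    edges: List[Tuple[int, int]] = []
    succ = sorted(G.successors(root))
    if not succ:
        return TrunkResult(vertices=verts, edges=edges, psi_max=psi_max)

    def vertical_angle(c):
        v = _edge_vec(G, (root, c))
        n = np.linalg.norm(v)
        cosz = v[2] / n if n > 0 else -1.0
        return float(np.degrees(np.arccos(np.clip(cosz, -1.0, 1.0))))

    first_child = min(succ, key=lambda c: (round(vertical_angle(c), 9), c))
    e_s = (root, first_child)
    edges.append(e_s)
    verts.append(first_child)
    while True:
        cur = verts[-1]
        succ = sorted(G.successors(cur))
        if not succ:
            break
        best = min(succ, key=lambda c: (round(turn_angle(G, e_s, (cur, c)), 9), c))
        psi = turn_angle(G, e_s, (cur, best))
        if psi > psi_max:
            break
        e_s = (cur, best)
        edges.append(e_s)
        verts.append(best)
    return TrunkResult(vertices=verts, edges=edges, psi_max=psi_max)


def find_branch_origins(G: nx.DiGraph, trunk: TrunkResult) -> List[int]:
    """Trunk vertices with at least one off-trunk successor, plus the
    trunk top, ordered root-up."""
    trunk_edges = set(trunk.edges)
    origins = []
    for v in trunk.vertices:
        off = [c for c in G.successors(v) if (v, c) not in trunk_edges]
        if off or v == trunk.vertices[-1]:
            origins.append(v)
    return origins


def _path_length(G: nx.DiGraph, path: List[int]) -> float:
    pos = [G.nodes[n]["pos"] for n in path]
    return float(sum(np.linalg.norm(b - a) for a, b in zip(pos, pos[1:])))


def identify_primary_branches(
    G: nx.DiGraph,
    trunk: TrunkResult,
    min_length: float = 50.0,
) -> List[PrimaryBranch]:
    """Per origin and per off-trunk child subtree: depth-first search to
    every endpoint, backtrack, and keep the maximal-L_i path; candidates
    below ``min_length`` are rejected (false branches stay lateral)."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    trunk_edges = set(trunk.edges)
    branches: List[PrimaryBranch] = []
    bid = 0
    for origin in find_branch_origins(G, trunk):
        for child in sorted(G.successors(origin)):
            if (origin, child) in trunk_edges:
                continue
            # enumerate every origin->leaf path through this child
            best_path, best_len = None, -1.0
            stack = [[origin, child]]
            while stack:
                path = stack.pop()
                succ = sorted(G.successors(path[-1]), reverse=True)
                if not succ:
                    L = _path_length(G, path)
                    # ties in L_i break toward the lexicographically
                    # smaller vertex sequence
                    if L > best_len + 1e-12 or (
                        abs(L - best_len) <= 1e-12 and best_path is not None and path < best_path
                    ):
                        best_path, best_len = path, L
                    continue
                for s in succ:
                    stack.append(path + [s])
            # inclusive threshold, robust to float accumulation in L_i
            if best_path is not None and best_len >= min_length - 1e-9:
                branches.append(PrimaryBranch(
                    branch_id=bid, origin=origin, path=best_path, length=best_len))
                bid += 1
    if not branches:
        log.info("no primary branch reached the %.1f cm minimum length", min_length)
    return branches


def locate_pruning_points(
    G: nx.DiGraph,
    branches: List[PrimaryBranch],
    fraction: float = 2.0 / 3.0,
) -> PruningPlan:
    """Interpolate each branch polyline at arc-length ``fraction * L_i``."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    plan = PruningPlan()
    for br in branches:
        if br.length <= 0:
            log.warning("branch %d has zero length; skipped", br.branch_id)
            continue
        target = fraction * br.length
        cum = 0.0
        for a, b in zip(br.path, br.path[1:]):
            pa, pb = G.nodes[a]["pos"], G.nodes[b]["pos"]
            L = float(np.linalg.norm(pb - pa))
            if cum + L >= target - 1e-12:
                t = (target - cum) / L if L > 0 else 0.0
                plan.points.append(PruningPoint(
                    branch_id=br.branch_id,
                    position=pa + t * (pb - pa),
                    host_edge=(a, b),
                    fraction=fraction,
                ))
                break
            cum += L
    return plan


def label_edges(
    G: nx.DiGraph,
    trunk: TrunkResult,
    branches: List[PrimaryBranch],
) -> Dict[Tuple[int, int], BranchClass]:
    """Partition E into TRUNK / PRIMARY / LATERAL."""
    classes = {e: BranchClass.LATERAL for e in G.edges}
    for br in branches:
        for e in zip(br.path, br.path[1:]):
            classes[e] = BranchClass.PRIMARY
    for e in trunk.edges:
        classes[e] = BranchClass.TRUNK
    return classes


def analyze_skeleton(
    skeleton: Skeleton,
    psi_max: float = 30.0,
    min_length: float = 50.0,
    fraction: float = 2.0 / 3.0,
) -> LabeledSkeleton:
    """Full analysis pass: digraph, trunk, primaries, labels, plan."""
    G = build_digraph(skeleton)
    trunk = identify_trunk(G, psi_max)
    branches = identify_primary_branches(G, trunk, min_length)
    classes = label_edges(G, trunk, branches)
    plan = locate_pruning_points(G, branches, fraction)
    log.info("analysis: trunk %d edges, %d primary branches, %d pruning points",
             len(trunk.edges), len(branches), len(plan.points))
    return LabeledSkeleton(skeleton=skeleton, digraph=G, trunk=trunk,
                           branches=branches, edge_class=classes, plan=plan)
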