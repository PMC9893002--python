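"""Independent reference implementations used as test oracles.

Everything here is written as plain loops over the definitions, with no
spatial indexing and no code shared with the package implementations.
"""
from __future__ import annotations

import numpy as np

from skelprune.skeleton import Skeleton


def brute_knn_mean_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Mean distance to the k nearest neighbors, self excluded, by full
    pairwise distances."""
    n = len(points)
    out = np.zeros(n)
    for i in range(n):
        d = np.sort(np.linalg.norm(points - points[i], axis=1))
        out[i] = d[1 : k + 1].mean()  # d[0] == 0 is the point itself
    return out


def brute_assign(node_ids, node_pos, attractions, R):
    """Eq-by-eq attraction assignment: nearest node, strictly within R,
    ties to the lower node id."""
    result = {}
    for qi, q in enumerate(attractions):
        best, best_d = None, np.inf
        for nid, p in zip(node_ids, node_pos):
            d = np.linalg.norm(q - p)
            if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and (best is None or nid < best)):
                best, best_d = nid, d
        if best_d < R:
            result.setdefault(best, []).append(qi)
    return {k: np.array(v) for k, v in result.items()}


def nearest_segment_distance(point, polylines):
    """Distance from a point to the nearest centerline segment."""
    best = np.inf
    for poly in polylines:
        for a, b in zip(poly[:-1], poly[1:]):
            ab = b - a
            t = np.clip(np.dot(point - a, ab) / np.dot(ab, ab), 0.0, 1.0)
            best = min(best, np.linalg.norm(point - (a + t * ab)))
    return best


def naive_colonize(points, seed_position, R, theta, Ds, Rd,
                   max_iterations=500, stall_limit=10):
    """Direct-loop space colonization: same rules as the package
    (toward-attraction sums, inclusive sector, empty-sector fallback along
    V_p, duplicate guard, lower-id tie-breaks), no spatial index."""
    skel = Skeleton()
    skel.add_node(np.asarray(seed_position, float))
    pts = [np.asarray(p, float) for p in points]
    alive = list(range(len(pts)))
    stall = 0
    for _ in range(max_iterations):
        ids = skel.node_ids
        pos = {i: skel.position(i) for i in ids}
        influence = brute_assign(ids, [pos[i] for i in ids],
                                 [pts[a] for a in alive], R)
        if not influence:
            break
        new_nodes = []
        for nid in sorted(influence):
            att = np.array([pts[alive[a]] for a in influence[nid]])
            p = pos[nid]
            units = []
            for q in att:
                v = q - p
                n = np.linalg.norm(v)
                if n > 0:
                    units.append(v / n)
            s = np.sum(units, axis=0)
            if np.linalg.norm(s) < 1e-12:
                continue
            V = s / np.linalg.norm(s)
            sector = []
            for q in att:
                v = q - p
                n = np.linalg.norm(v)
                if n == 0:
                    continue
                ang = np.degrees(np.arccos(np.clip(np.dot(v / n, V), -1, 1)))
                if ang <= theta + 1e-12:
                    sector.append(v / n)
            if sector:
                F = np.sum(sector, axis=0)
                if np.linalg.norm(F) < 1e-12:
                    continue
                f = F / np.linalg.norm(F)
            else:
                f = V
            new_pos = p + Ds * f
            dup = any(np.linalg.norm(skel.position(i) - new_pos) < 1e-6
                      for i in skel.node_ids)
            if not dup:
                new_nodes.append(skel.add_node(new_pos, parent=nid))
        killed = 0
        if new_nodes:
            survivors = []
            for a in alive:
                dmin = min(np.linalg.norm(pts[a] - skel.position(i)) for i in new_nodes)
                if dmin <= Rd:
                    killed += 1
                else:
                    survivors.append(a)
            alive = survivors
        if not new_nodes and killed == 0:
            stall += 1
            if stall >= stall_limit:
                break
        else:
            stall = 0
    return skel


def greedy_trunk_reference(G, psi_max):
    """Step-by-step trunk trace re-implemented over explicit path
    enumeration: at each vertex enumerate all successor edges, compute
    their turn angles directly, and take the minimum."""
    import numpy as np
    root = [n for n in G.nodes if G.in_degree(n) == 0][0]

    def vec(a, b):
        return G.nodes[b]["pos"] - G.nodes[a]["pos"]

    def ang(u, v):
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return np.degrees(np.arccos(np.clip(c, -1, 1)))

    succ = sorted(G.successors(root))
    if not succ:
        return [root]
    up = np.array([0.0, 0.0, 1.0])
    scored = sorted((round(ang(vec(root, c), up), 9), c) for c in succ)
    path = [root, scored[0][1]]
    while True:
        cur = path[-1]
        options = sorted(G.successors(cur))
        if not options:
            break
        e_s = vec(path[-2], path[-1])
        scored = sorted((round(ang(e_s, vec(cur, c)), 9), c) for c in options)
        psi, best = scored[0]
        if psi > psi_max:
            break
        path.append(best)
    return path


def all_paths_longest(G, origin, through_child):
    """Brute-force: every origin->leaf path via ``through_child``; return
    (best_path, best_length) by cumulative Euclidean length."""
    import itertools
    import numpy as np

    def length(path):
        pos = [G.nodes[n]["pos"] for n in path]
        return sum(np.linalg.norm(b - a) for a, b in zip(pos, pos[1:]))

    paths = []

    def rec(path):
        succ = sorted(G.successors(path[-1]))
        if not succ:
            paths.append(list(path))
            return
        for s in succ:
            rec(path + [s])

    rec([origin, through_child])
    best = max(paths, key=lambda p: (round(length(p), 12), [-x for x in p]))
    # tie-break toward the lexicographically smaller sequence
    best_len = length(best)
    ties = [p for p in paths if abs(length(p) - best_len) <= 1e-12]
    best = min(ties)
    return best, best_len


def geometric_sphere_fit(points):
    """Iterative nonlinear least-squares sphere fit (oracle for the
    algebraic fit)."""
    from scipy.optimize import least_squares

    points = np.asarray(points, float)
    c0 = points.mean(axis=0)
    r0 = np.linalg.norm(points - c0, axis=1).mean()

    def resid(x):
        return np.linalg.norm(points - x[:3], axis=1) - x[3]

    sol = least_squares(resid, np.r_[c0, r0])
    return sol.x[:3], sol.x[3]


def brute_registration_error(cloud_F, cloud_B, transform, max_corr=5.0):
    moved = transform.apply(cloud_B.points)
    dists = []
    for p in moved:
        d = np.min(np.linalg.norm(cloud_F.points - p, axis=1))
        if d <= max_corr:
            dists.append(d)
    return float(np.sqrt(np.mean(np.square(dists))))
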