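"""Skeleton-graph analysis: trunk trace, branch selection, pruning points."""
import numpy as np
import pytest

from skelprune import analyze
from skelprune.analyze import (analyze_skeleton, build_digraph,
                               find_branch_origins, identify_primary_branches,
                               identify_trunk, label_edges,
                               locate_pruning_points)
from skelprune.constants import BranchClass
from skelprune.skeleton import Skeleton

from conftest import random_tree_skeleton, straight_branch_skeleton
from oracles import all_paths_longest, greedy_trunk_reference


def chain_skeleton(positions):
    sk = Skeleton()
    prev = None
    for p in positions:
        prev = sk.add_node(p, parent=prev)
    return sk


class TestBuildDigraph:
    def test_chain_orientation(self):
        sk = chain_skeleton([[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        G = build_digraph(sk)
        assert sorted(G.edges) == [(0, 1), (1, 2)]

    def test_edge_count_is_n_minus_one(self, rng):
        sk = random_tree_skeleton(rng, n_nodes=17)
        G = build_digraph(sk)
        assert G.number_of_edges() == len(sk) - 1

    def test_json_round_trip_preserves_graph(self, rng):
        sk = random_tree_skeleton(rng, n_nodes=12)
        G1 = build_digraph(sk)
        G2 = build_digraph(Skeleton.from_dict(sk.to_dict()))
        assert sorted(G1.edges) == sorted(G2.edges)
        for n in G1.nodes:
            assert np.allclose(G1.nodes[n]["pos"], G2.nodes[n]["pos"])


class TestIdentifyTrunk:
    def test_straight_chain_entirely_trunk(self):
        sk = chain_skeleton([[0, 0, z] for z in range(0, 40, 4)])
        trunk = identify_trunk(build_digraph(sk), psi_max=30.0)
        assert len(trunk.edges) == len(sk) - 1

    def test_bend_terminates_trunk(self):
        """Vertical chain of 5 nodes, then a 40-degree bend: with a
        30-degree limit the trunk is exactly the first 5 nodes."""
        up = [[0, 0, 4.0 * i] for i in range(5)]
        bend = np.array([np.sin(np.radians(40)), 0, np.cos(np.radians(40))])
        more = [up[-1] + bend * 4.0 * (i + 1) for i in range(4)]
        sk = chain_skeleton(up + more)
        trunk = identify_trunk(build_digraph(sk), psi_max=30.0)
        assert trunk.vertices == [0, 1, 2, 3, 4]

    def test_most_vertical_first_edge(self):
        sk = Skeleton()
        sk.add_node([0, 0, 0])
        sk.add_node([3.0, 0, 1.0], parent=0)   # oblique
        sk.add_node([0.2, 0, 4.0], parent=0)   # near-vertical
        trunk = identify_trunk(build_digraph(sk), psi_max=45.0)
        assert trunk.vertices[1] == 2

    def test_matches_greedy_reference_on_random_trees(self, rng):
        for _ in range(25):
            sk = random_tree_skeleton(rng, n_nodes=int(rng.integers(5, 21)))
            G = build_digraph(sk)
            psi = float(rng.uniform(15, 60))
            assert identify_trunk(G, psi).vertices == greedy_trunk_reference(G, psi)


class TestBranchOrigins:
    def test_midway_side_branch_gives_two_origins(self):
        sk = straight_branch_skeleton()
        # trunk is 0-1-2 then the branch bends off; origin = bend + top
        G = build_digraph(sk)
        trunk = identify_trunk(G, psi_max=30.0)
        origins = find_branch_origins(G, trunk)
        assert origins[-1] == trunk.vertices[-1]

    def test_three_inner_plus_top(self):
        """A trunk with three side branches and a top yields four origins."""
        sk = chain_skeleton([[0, 0, 4.0 * i] for i in range(11)])
        side = np.array([1.0, 0, 0.2])
        side /= np.linalg.norm(side)
        for v in (3, 5, 7):
            prev = v
            pos = np.asarray(sk.position(v))
            for i in range(3):
                pos = pos + side * 4.0
                prev = sk.add_node(pos, parent=prev)
        G = build_digraph(sk)
        trunk = identify_trunk(G, psi_max=30.0)
        origins = find_branch_origins(G, trunk)
        assert origins == [3, 5, 7, 10]

    def test_matches_direct_scan(self, rng):
        sk = random_tree_skeleton(rng, n_nodes=25)
        G = build_digraph(sk)
        trunk = identify_trunk(G, 30.0)
        origins = find_branch_origins(G, trunk)
        trunk_edges = set(trunk.edges)
        expect = [v for v in trunk.vertices
                  if any((v, c) not in trunk_edges for c in G.successors(v))
                  or v == trunk.vertices[-1]]
        assert origins == expect


class TestPrimaryBranches:
    def test_single_branch_length(self):
        sk = straight_branch_skeleton(step=10.0, n=6)  # 60 cm branch
        G = build_digraph(sk)
        trunk = identify_trunk(G, 30.0)
        branches = identify_primary_branches(G, trunk, min_length=50.0)
        assert len(branches) == 1
        assert branches[0].length == pytest.approx(60.0)

    def test_longest_path_wins_shorter_is_lateral(self):
        sk = straight_branch_skeleton(step=10.0, n=0)
        # two arms from the trunk top: 80 cm and 55 cm
        top = 2
        d1 = np.array([1.0, 0, 0.2]); d1 /= np.linalg.norm(d1)
        d2 = np.array([0, 1.0, 0.2]); d2 /= np.linalg.norm(d2)
        prev, pos = top, np.asarray(sk.position(top))
        first_d1 = None
        for i in range(8):
            pos = pos + d1 * 10
            prev = sk.add_node(pos, parent=prev)
            if first_d1 is None:
                first_d1 = prev
        # the 55-cm arm forks off the first d1 node
        prev, pos = first_d1, np.asarray(sk.position(first_d1))
        for i in range(5):
            pos = pos + d2 * 9
            prev = sk.add_node(pos, parent=prev)
        G = build_digraph(sk)
        trunk = identify_trunk(G, 30.0)
        branches = identify_primary_branches(G, trunk, min_length=50.0)
        assert len(branches) == 1
        assert branches[0].length == pytest.approx(80.0)
        classes = label_edges(G, trunk, branches)
        lateral = [e for e, c in classes.items() if c == BranchClass.LATERAL]
        assert len(lateral) == 5  # the divergent 45-cm tail

    def test_min_length_inclusive(self):
        sk = straight_branch_skeleton(step=10.0, n=5)  # exactly 50 cm
        G = build_digraph(sk)
        trunk = identify_trunk(G, 30.0)
        assert len(identify_primary_branches(G, trunk, min_length=50.0)) == 1

    def test_matches_all_paths_oracle(self, rng):
        for _ in range(15):
            sk = random_tree_skeleton(rng, n_nodes=int(rng.integers(8, 26)))
            G = build_digraph(sk)
            trunk = identify_trunk(G, 30.0)
            branches = identify_primary_branches(G, trunk, min_length=0.0)
            got = {(b.origin, b.path[1]): (tuple(b.path), b.length) for b in branches}
            trunk_edges = set(trunk.edges)
            for origin in find_branch_origins(G, trunk):
                for child in sorted(G.successors(origin)):
                    if (origin, child) in trunk_edges:
                        continue
                    path, length = all_paths_longest(G, origin, child)
                    assert got[(origin, child)][0] == tuple(path)
                    assert got[(origin, child)][1] == pytest.approx(length)


class TestPruningPoints:
    def test_straight_branch_two_thirds(self):
        sk = straight_branch_skeleton(step=10.0, n=9)  # nodes at 0..90 cm
        G = build_digraph(sk)
        trunk = identify_trunk(G, 30.0)
        branches = identify_primary_branches(G, trunk, min_length=50.0)
        plan = locate_pruning_points(G, branches)
        assert len(plan.points) == 1
        p = plan.points[0]
        start = G.nodes[branches[0].path[0]]["pos"]
        assert np.linalg.norm(p.position - start) == pytest.approx(60.0)

    def test_fraction_near_one_returns_tip(self):
        sk = straight_branch_skeleton(step=10.0, n=6)
        G = build_digraph(sk)
        trunk = identify_trunk(G, 30.0)
        branches = identify_primary_branches(G, trunk, min_length=0.0)
        plan = locate_pruning_points(G, branches, fraction=1 - 1e-12)
        tip = G.nodes[branches[0].path[-1]]["pos"]
        assert np.allclose(plan.points[0].position, tip, atol=1e-6)

    def test_arc_length_oracle_on_random_polylines(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 12))
            steps = rng.uniform(2, 9, n)
            dirs = rng.normal(0, 1, (n, 3))
            dirs[:, 2] = np.abs(dirs[:, 2]) + 0.5
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            pts = np.vstack([[0, 0, 0], np.cumsum(dirs * steps[:, None], axis=0)])
            sk = chain_skeleton([[0, 0, -10.0]] + pts.tolist())
            G = build_digraph(sk)
            trunk = analyze.TrunkResult(vertices=[0], edges=[], psi_max=30.0)
            br = analyze.PrimaryBranch(branch_id=0, origin=1,
                                       path=list(range(1, len(sk))),
                                       length=float(steps.sum()))
            frac = float(rng.uniform(0.2, 0.9))
            plan = locate_pruning_points(G, [br], fraction=frac)
            p = plan.points[0]
            # brute-force arc-length integration up to the returned point
            cum = 0.0
            for a, b in zip(br.path, br.path[1:]):
                pa, pb = G.nodes[a]["pos"], G.nodes[b]["pos"]
                if (a, b) == p.host_edge:
                    cum += np.linalg.norm(p.position - pa)
                    break
                cum += np.linalg.norm(pb - pa)
            assert cum == pytest.approx(frac * br.length, abs=1e-9)
            # collinearity with the host edge
            a, b = p.host_edge
            pa, pb = G.nodes[a]["pos"], G.nodes[b]["pos"]
            t = np.dot(p.position - pa, pb - pa) / np.dot(pb - pa, pb - pa)
            assert np.linalg.norm(p.position - (pa + t * (pb - pa))) < 1e-9
            assert -1e-9 <= t <= 1 + 1e-9


class TestLabelEdges:
    def test_pure_chain_all_trunk(self):
        sk = chain_skeleton([[0, 0, 4.0 * i] for i in range(8)])
        G = build_digraph(sk)
        trunk = identify_trunk(G, 30.0)
        classes = label_edges(G, trunk, [])
        assert all(c == BranchClass.TRUNK for c in classes.values())

    def test_classes_partition_edges(self, colonized):
        lab = analyze_skeleton(colonized)
        assert len(lab.edge_class) == len(colonized) - 1
        trunk = {e for e, c in lab.edge_class.items() if c == BranchClass.TRUNK}
        prim = {e for e, c in lab.edge_class.items() if c == BranchClass.PRIMARY}
        assert not trunk & prim

    def test_ground_truth_skeleton_macro_accuracy(self):
        """Labeling an exact ground-truth centerline skeleton recovers the
        true per-edge classes with macro accuracy >= 0.9."""
        from skelprune import synthetic

        scores = []
        for seed in (1, 2, 5):
            t = synthetic.generate_tree(seed=seed)
            sk = Skeleton()
            node_of = {}
            sk.add_node(t.polylines[0][0])
            node_of[(0, 0)] = 0
            truth = {}
            for i, poly in enumerate(t.polylines):
                if t.parents[i] is None:
                    prev = node_of[(0, 0)]
                    start = 1
                else:
                    prev = node_of[t.parents[i]]
                    start = 1
                    node_of[(i, 0)] = prev
                for vi in range(start, len(poly)):
                    nid = sk.add_node(poly[vi], parent=prev)
                    truth[(prev, nid)] = int(t.branch_class[i])
                    node_of[(i, vi)] = nid
                    prev = nid
            lab = analyze_skeleton(sk)
            per_class = []
            for cls in BranchClass:
                edges = [e for e, c in truth.items() if c == cls]
                if edges:
                    ok = np.mean([lab.edge_class[e] == cls for e in edges])
                    per_class.append(ok)
            scores.append(np.mean(per_class))
        assert np.mean(scores) >= 0.9

    def test_rejected_short_candidates_stay_lateral(self):
        sk = straight_branch_skeleton(step=10.0, n=4)  # 40 cm < 50 cm
        G = build_digraph(sk)
        trunk = identify_trunk(G, 30.0)
        branches = identify_primary_branches(G, trunk, min_length=50.0)
        assert branches == []
        classes = label_edges(G, trunk, branches)
        assert sum(1 for c in classes.values() if c == BranchClass.LATERAL) == 4
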