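"""Rooted skeleton tree: node positions plus parent/child links.

The skeleton is produced by the space colonization pass and consumed by
the branch-labeling and modeling stages.  Node ids are dense integers in
insertion order; the root is always id 0 of a freshly grown skeleton,
but any single-rooted structure is accepted.
"""
from __future__ import annotations

from typing import Dict, Iterator, List, Optional

import numpy as np


class Skeleton:
    """Rooted tree of 3D skeleton nodes (cm)."""

    def __init__(self) -> None:
        self._positions: Dict[int, np.ndarray] = {}
        self.parent: Dict[int, Optional[int]] = {}
        self.children: Dict[int, List[int]] = {}
        self.root: Optional[int] = None
        self._next_id = 0

    # -- construction -------------------------------------------------
    def add_node(self, position, parent: Optional[int] = None, node_id: Optional[int] = None) -> int:
        pos = np.asarray(position, dtype=np.float64).reshape(3)
        if node_id is None:
            node_id = self._next_id
        if node_id in self._positions:
            raise ValueError(f"duplicate node id {node_id}")
        self._next_id = max(self._next_id, node_id + 1)
        if parent is None:
            if self.root is not None:
                raise ValueError("skeleton already has a root")
            self.root = node_id
        else:
            if parent not in self._positions:
                raise KeyError(f"unknown parent id {parent}")
            self.children[parent].append(node_id)
        self._positions[node_id] = pos
        self.parent[node_id] = parent
        self.children[node_id] = []
        return node_id

    # -- queries ------------------------------------------------------
    def __len__(self) -> int:
        return len(self._positions)

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._positions

    def position(self, node_id: int) -> np.ndarray:
        return self._positions[node_id]

    @property
    def node_ids(self) -> List[int]:
        return sorted(self._positions)

    def positions_array(self) -> np.ndarray:
        """``(n, 3)`` positions ordered by node id."""
        return np.array([self._positions[i] for i in self.node_ids])

    def edges(self) -> Iterator[tuple]:
        """Yield (parent, child) pairs, parent-first order by child id."""
        for nid in self.node_ids:
            p = self.parent[nid]
            if p is not None:
                yield (p, nid)

    def edge_length(self, parent: int, child: int) -> float:
        return float(np.linalg.norm(self._positions[child] - self._positions[parent]))

    def subtree(self, node_id: int) -> List[int]:
        """All descendants of ``node_id`` including itself (DFS preorder, children by id)."""
        out, stack = [], [node_id]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(sorted(self.children[n], reverse=True))
        return out

    def leaves(self) -> List[int]:
        return [n for n in self.node_ids if not self.children[n]]

    def validate(self) -> None:
        """Raise if the structure is not a single rooted tree."""
        if self.root is None:
            raise ValueError("skeleton has no root")
        seen = self.subtree(self.root)
        if len(seen) != len(self._positions) or len(set(seen)) != len(seen):
            raise ValueError("skeleton is not a single connected tree")
        for nid, p in self.parent.items():
            if p is not None and nid not in self.children[p]:
                raise ValueError("inconsistent parent/child links")

    def remove_subtree(self, node_id: int) -> List[int]:
        """Delete ``node_id`` and all its descendants; return the removed ids."""
        removed = self.subtree(node_id)
        p = self.parent[node_id]
        if p is not None:
            self.children[p].remove(node_id)
        elif node_id == self.root:
            self.root = None
        for n in removed:
            del self._positions[n], self.parent[n], self.children[n]
        return removed

    def copy(self) -> "Skeleton":
        s = Skeleton()
        s._positions = {k: v.copy() for k, v in self._positions.items()}
        s.parent = dict(self.parent)
        s.children = {k: list(v) for k, v in self.children.items()}
        s.root = self.root
        s._next_id = self._next_id
        return s

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": 1,
            "root": self.root,
            "nodes": [{"id": i, "xyz": self._positions[i].tolist()} for i in self.node_ids],
            "edges": [[p, c] for p, c in self.edges()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Skeleton":
        s = cls()
        pos = {n["id"]: n["xyz"] for n in d["nodes"]}
        parent = {c: p for p, c in d["edges"]}
        # insert root first, then repeatedly attach children
        s.add_node(pos[d["root"]], None, d["root"])
        pending = [nid for nid in pos if nid != d["root"]]
        while pending:
            progressed = []
            for nid in sorted(pending):
                if parent.get(nid) in s._positions:
                    s.add_node(pos[nid], parent[nid], nid)
                    progressed.append(nid)
            if not progressed:
                raise ValueError("skeleton JSON is not a connected rooted tree")
            pending = [n for n in pending if n not in progressed]
        return s
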