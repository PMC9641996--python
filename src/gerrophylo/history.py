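"""Explicit character histories along a tree.

Shared between the trait simulator (true histories) and stochastic
character mapping (sampled histories): both emit per-branch ordered
``(state, duration)`` segments in parent-to-child direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree import Tree

__all__ = ["CharacterHistory"]


@dataclass
class CharacterHistory:
    """One explicit realisation of a discrete character on a tree.

    ``segments[node]`` lists ``(state, duration)`` pieces along the
    branch above ``node``, ordered from the parent end; durations sum to
    the branch length and adjacent segments differ in state.
    """

    tree: Tree
    root_state: int
    segments: dict[int, list[tuple[int, float]]] = field(default_factory=dict)

    def node_states(self) -> dict[int, int]:
        """State at every node (end of its branch; root state at root)."""
        out = {self.tree.root: self.root_state}
        for v in self.tree.preorder():
            if v == self.tree.root:
                continue
            segs = self.segments.get(v)
            out[v] = segs[-1][0] if segs else out[self.tree.parent[v]]
        return out

    def tip_states(self) -> dict[str, int]:
        states = self.node_states()
        return {self.tree.labels[i]: states[i] for i in self.tree.tip_indices}

    def n_changes(self) -> int:
        """Total number of state-change points across all branches."""
        total = 0
        for segs in self.segments.values():
            total += max(len(segs) - 1, 0)
        return total

    def change_points(self) -> list[tuple[int, int, int]]:
        """All changes as ``(node, from_state, to_state)`` triples."""
        out = []
        for v, segs in self.segments.items():
            for (s0, _), (s1, _) in zip(segs, segs[1:]):
                out.append((int(v), int(s0), int(s1)))
        return out

    def entries_into(self, state: int) -> list[int]:
        """Branches (node indices) on which the history enters ``state``."""
        return [v for v, s0, s1 in self.change_points() if s1 == state and s0 != state]

    def exits_from(self, state: int) -> list[int]:
        return [v for v, s0, s1 in self.change_points() if s0 == state and s1 != state]

    def validate(self, atol: float = 1e-9) -> None:
        states = self.node_states()
        for v in self.tree.preorder():
            if v == self.tree.root:
                continue
            segs = self.segments.get(v, [])
            if not segs:
                raise ValueError(f"branch above node {v} has no segments")
            if segs[0][0] != states[self.tree.parent[v]]:
                raise ValueError(f"branch {v}: first segment != parent state")
            if abs(sum(d for _, d in segs) - self.tree.blen[v]) > atol * max(
                1.0, self.tree.blen[v]
            ):
                raise ValueError(f"branch {v}: durations do not sum to branch length")
            for (a, _), (b, _) in zip(segs, segs[1:]):
                if a == b:
                    raise ValueError(f"branch {v}: adjacent segments share a state")

    def dwell_times(self, k: int) -> np.ndarray:
        dwell = np.zeros(k)
        for segs in self.segments.values():
            for s, d in segs:
                dwell[s] += d
        return dwell
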