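"""State-transition graphs, branch partitions, and descendant counts.

One synchronous update sends every state to a unique successor, so the
transition graph is a functional graph: out-degree 1 everywhere, with
attracting fixed points and period-2 cycles.  Following the field's
inverted-tree vocabulary, a state's "parent" is its successor, and the
states that eventually flow into a node are its "descendants".

After a basin-size jump, the newly acquired states decompose into
head-rooted branches: a branch head is a new state whose successor is not
itself new (it already belonged to the basin before the jump), and a
branch comprises the head plus every new state whose forward path reaches
it without leaving the new set.  One boundary case arises at the very
first jump of a run: the target itself is newly acquired and is its own
successor, so it is treated as a branch head (it roots the tree).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BranchPartition",
    "build_transition_map",
    "descendant_counts",
    "new_states_after_jump",
    "partition_branches",
    "transition_edge_table",
]


def build_transition_map(W: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Successor index of every row of ``states`` under one synchronous update.

    ``states`` must be the full enumeration from
    :func:`~hopbasin.basins.enumerate_states` (or an index-closed subset in
    that order); the returned array maps row i to the row index of its
    successor.
    """
    from .basins import pattern_index

    Wf = W.astype(np.float64)
    nxt = np.where(states.astype(np.float64) @ Wf >= 0.0, 1, -1)
    return pattern_index(nxt)


def new_states_after_jump(basin_before, basin_after) -> np.ndarray:
    """States in the basin after a jump but not before (set difference).

    Accepts boolean masks over the enumerated state space (returns indices)
    or integer index arrays/sets.
    """
    before = np.asarray(basin_before)
    after = np.asarray(basin_after)
    if before.dtype == bool and after.dtype == bool:
        return np.flatnonzero(after & ~before)
    return np.setdiff1d(after, before, assume_unique=False)


@dataclass(frozen=True)
class BranchPartition:
    """Decomposition of newly acquired basin states into branches.

    ``branches`` lists (head index, branch size); sizes count the head
    itself, and they sum to ``new_state_count`` — every new state belongs
    to exactly one branch.
    """

    branches: list[tuple[int, int]]
    new_state_count: int

    @property
    def sizes(self) -> np.ndarray:
        return np.array([s for _, s in self.branches], dtype=np.int64)


def partition_branches(new_states, tmap: np.ndarray) -> BranchPartition:
    """Partition new states into head-rooted branches of the transition graph.

    A head is a new state whose successor is not new, or which is its own
    successor (the target attractor when the basin was empty before the
    jump).  Every other new state is assigned to the head its forward path
    reaches while staying inside the new set.
    """
    new_idx = np.asarray(sorted(set(int(i) for i in np.asarray(list(new_states)))))
    if new_idx.size == 0:
        return BranchPartition([], 0)
    new_set = set(new_idx.tolist())
    heads = {i for i in new_idx if int(tmap[i]) not in new_set or int(tmap[i]) == i}

    assigned_head: dict[int, int] = {}

    def head_of(s: int) -> int:
        path = []
        cur = s
        while cur not in assigned_head:
            if cur in heads:
                assigned_head[cur] = cur
                break
            path.append(cur)
            nxt = int(tmap[cur])
            if nxt not in new_set or len(path) > len(new_set):
                raise AssertionError(
                    "malformed basin: forward path left the new set without a head"
                )
            cur = nxt
        h = assigned_head[cur]
        for p in path:
            assigned_head[p] = h
        return h

    counts: dict[int, int] = {h: 0 for h in heads}
    for s in new_idx:
        counts[head_of(int(s))] += 1

    branches = sorted(counts.items())
    assert sum(s for _, s in branches) == len(new_set)
    return BranchPartition([(int(h), int(s)) for h, s in branches], len(new_set))


def descendant_counts(tmap: np.ndarray) -> np.ndarray:
    """For every state, the number of states whose forward orbit visits it.

    Counts include the state itself ("branch size" of a node network-wide).
    A forward orbit runs until it repeats, so it includes the full terminal
    cycle: both members of a period-2 cycle count each other, and every
    state feeding a cycle contributes to both cycle members.

    Implemented by reverse-topological accumulation over the tree part of
    the functional graph, then distributing each cycle's total inflow to
    its members.
    """
    tmap = np.asarray(tmap, dtype=np.int64)
    m = tmap.shape[0]
    on_cycle = tmap[tmap] == np.arange(m)  # period 1 or 2

    counts = np.ones(m, dtype=np.int64)
    indeg = np.bincount(tmap, minlength=m)
    # Kahn-style peel of the in-trees: leaves inward toward the cycles.
    stack = [int(v) for v in np.flatnonzero((indeg == 0) & ~on_cycle)]
    inflow = np.zeros(m, dtype=np.int64)  # tree mass entering each cycle node
    while stack:
        u = stack.pop()
        w = int(tmap[u])
        if on_cycle[w]:
            inflow[w] += counts[u]
        else:
            counts[w] += counts[u]
        indeg[w] -= 1
        if indeg[w] == 0 and not on_cycle[w]:
            stack.append(w)

    done = np.zeros(m, dtype=bool)
    for v in np.flatnonzero(on_cycle):
        v = int(v)
        if done[v]:
            continue
        w = int(tmap[v])
        comp = [v] if w == v else [v, w]
        total = len(comp) + sum(int(inflow[c]) for c in comp)
        for c in comp:
            counts[c] = total
            done[c] = True
    return counts


def transition_edge_table(tmap: np.ndarray) -> np.ndarray:
    """Two-column (source index, successor index) edge list of the graph."""
    tmap = np.asarray(tmap, dtype=np.int64)
    return np.column_stack([np.arange(tmap.shape[0], dtype=np.int64), tmap])
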