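"""Exhaustive state-space enumeration and the repeated-presentation protocol.

For small networks (n <= 20) the full set of 2**n states can be enumerated
and the attractor basin of a target pattern measured exactly: the basin is
the set of initial states whose synchronous dynamics converge to the target
as a fixed point.  States ending in a period-2 limit cycle belong to no
basin.

The repeated-presentation experiment pretrains a network on ``p`` random
stimuli (each scaled by a multiplier) and then appends Hebbian copies of a
random target one at a time, j = 1..J, recording the exhaustive basin size
after every presentation.  Positive changes in the size trajectory are the
"jumps" whose distribution the analysis modules characterise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    DEFAULT_MAX_ITERS,
    WeightedPatternSet,
    add_target_copies,
    build_weight_matrix,
    evolve_batch,
    random_pattern,
    random_patterns,
)

__all__ = [
    "BasinTrajectory",
    "JumpRecord",
    "PresentationRun",
    "enumerate_states",
    "extract_jumps",
    "pattern_index",
    "run_presentation_experiment",
    "target_basin",
    "target_basin_mask",
]

_MAX_ENUM_N = 20


def enumerate_states(n: int) -> np.ndarray:
    """All 2**n states as a (2**n, n) array of +/-1 integers.

    Ordering convention: state ``i`` is the n-bit binary expansion of ``i``,
    most significant bit first, with bit 0 -> -1 and bit 1 -> +1.  So index
    0 is all-(-1), index 2**n - 1 is all-(+1), and the order is
    lexicographic with -1 < +1.
    """
    if n < 1:
        raise ValueError(f"invalid dimension: n must be >= 1, got {n}")
    if n > _MAX_ENUM_N:
        raise ValueError(
            f"state space too large: 2**{n} states exceeds the n <= {_MAX_ENUM_N} "
            "enumeration guard; use sampled-state experiments instead"
        )
    idx = np.arange(2**n, dtype=np.int64)
    bits = (idx[:, None] >> np.arange(n - 1, -1, -1)) & 1
    return (2 * bits - 1).astype(np.int64)


def pattern_index(patterns: np.ndarray) -> np.ndarray:
    """Map +/-1 patterns (rows) to their :func:`enumerate_states` indices."""
    pats = np.atleast_2d(patterns)
    n = pats.shape[1]
    weights = 1 << np.arange(n - 1, -1, -1, dtype=np.int64)
    return ((pats > 0) @ weights).astype(np.int64)


def target_basin_mask(
    W: np.ndarray,
    target: np.ndarray,
    states: np.ndarray,
    max_iters: int = DEFAULT_MAX_ITERS,
) -> np.ndarray:
    """Boolean mask over ``states``: which initial states converge to target.

    Membership requires exact fixed-point convergence onto the target
    pattern itself; the negated target's basin and limit-cycle states never
    count.  The target is a member iff it is a fixed point.
    """
    target = np.asarray(target, dtype=np.int64)
    if target.shape[0] != W.shape[0]:
        raise ValueError("target length must match network size")
    finals, fixed, _ = evolve_batch(W, states, max_iters=max_iters)
    return fixed & (finals == target).all(axis=1)


def target_basin(W: np.ndarray, target, states: np.ndarray) -> np.ndarray:
    """The basin of ``target`` as an array of states (rows of ``states``)."""
    return states[target_basin_mask(W, np.asarray(target), states)]


@dataclass(frozen=True)
class BasinTrajectory:
    """Exhaustive target-basin size after j = 0..J presentations."""

    sizes: np.ndarray  # (J+1,) nonnegative ints; sizes[0] = pretraining only
    target: np.ndarray
    run_id: int
    J: int

    def __post_init__(self):
        if len(self.sizes) != self.J + 1:
            raise ValueError("trajectory must have J + 1 entries (j = 0..J)")


@dataclass(frozen=True)
class JumpRecord:
    """A positive basin-size change at presentation ``j`` (size >= 1 states)."""

    j: int
    size: int


def extract_jumps(traj) -> list[JumpRecord]:
    """Positive basin-size changes of a trajectory, one record per jump.

    A jump at presentation j is ``sizes[j] - sizes[j-1] > 0``.  Zero and
    negative changes produce no record (negative changes are retained in the
    trajectory itself for diagnostics).
    """
    sizes = np.asarray(traj.sizes if isinstance(traj, BasinTrajectory) else traj)
    if len(sizes) < 2:
        raise ValueError("trajectory must have at least 2 entries")
    diffs = np.diff(sizes)
    return [JumpRecord(j=int(j + 1), size=int(d)) for j, d in enumerate(diffs) if d > 0]


@dataclass
class PresentationRun:
    """Full record of one repeated-presentation run.

    ``branch_sizes``/``branch_jumps`` are populated only when branch
    collection was requested: for every jump, the sizes of the head-rooted
    branches that the newly acquired states form in the post-jump
    transition graph, and the presentation index of the jump each branch
    belongs to.
    """

    trajectory: BasinTrajectory
    jumps: list[JumpRecord]
    negative_changes: list[tuple[int, int]] = field(default_factory=list)  # (j, change<0)
    branch_sizes: list[int] = field(default_factory=list)
    branch_jumps: list[int] = field(default_factory=list)
    seed: int | None = None


def run_presentation_experiment(
    n: int = 10,
    pretrain_count: int = 50,
    pretrain_multiplier: int = 10,
    J: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    run_id: int = 0,
    collect_branches: bool = False,
    verify_at: tuple[int, ...] = (),
) -> PresentationRun:
    """Run the repeated-presentation protocol with exhaustive basins.

    Pretrains an ``n``-unit network with ``pretrain_count`` random stimuli
    (each scaled by ``pretrain_multiplier``), draws a fresh random target,
    then appends one Hebbian copy of the target per presentation
    j = 1..``J``, measuring the exhaustive basin size each time
    (``sizes[0]`` is the pretraining-only basin).  Weights are updated
    incrementally; ``verify_at`` lists presentation indices at which the
    incremental matrix is checked (exactly, in integer arithmetic) against
    a batch rebuild from the concatenated pattern set.
    """
    from .graph import build_transition_map, partition_branches  # cycle-free import

    rng = np.random.default_rng(seed)
    states = enumerate_states(n)
    target = random_pattern(n, rng)

    if pretrain_count > 0:
        pretrain = random_patterns(pretrain_count, n, rng)
        pset = WeightedPatternSet(
            pretrain, np.full(pretrain_count, pretrain_multiplier, dtype=np.int64)
        )
        W = build_weight_matrix(pset)
    else:
        pretrain = np.empty((0, n), dtype=np.int64)
        W = np.zeros((n, n), dtype=np.int64)

    sizes = np.zeros(J + 1, dtype=np.int64)
    mask = target_basin_mask(W, target, states)
    sizes[0] = mask.sum()

    run = PresentationRun(
        trajectory=BasinTrajectory(sizes, target, run_id, J),
        jumps=[],
    )

    for j in range(1, J + 1):
        W = add_target_copies(W, target, 1)
        if j in verify_at:
            full = np.concatenate([pretrain, np.tile(target, (j, 1))])
            mults = np.concatenate(
                [
                    np.full(len(pretrain), pretrain_multiplier, dtype=np.int64),
                    np.ones(j, dtype=np.int64),
                ]
            )
            W_batch = build_weight_matrix(WeightedPatternSet(full, mults))
            if not np.array_equal(W, W_batch):
                raise AssertionError(
                    f"incremental weights diverged from batch rebuild at j={j}"
                )
        new_mask = target_basin_mask(W, target, states)
        sizes[j] = new_mask.sum()
        change = int(sizes[j] - sizes[j - 1])
        if change > 0:
            run.jumps.append(JumpRecord(j=j, size=change))
            if collect_branches:
                tmap = build_transition_map(W, states)
                new_idx = np.flatnonzero(new_mask & ~mask)
                part = partition_branches(new_idx, tmap)
                run.branch_sizes.extend(int(s) for _, s in part.branches)
                run.branch_jumps.extend(j for _ in part.branches)
        elif change < 0:
            run.negative_changes.append((j, change))
        mask = new_mask

    return run
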