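"""Binary patterns, Hebbian weights, and synchronous Amari-Hopfield dynamics.

The model is the classical Amari-Hopfield network: ``n`` fully connected
binary units with states in {-1, +1}, a symmetric zero-diagonal weight
matrix built by the batch Hebbian (outer-product) rule, and deterministic
synchronous updates

    s(t+1) = sign(W s(t)),   sign(0) = +1.

Weights are kept in integer arithmetic so that incrementally adding stored
patterns is bit-exact against rebuilding the matrix from scratch.  Under
symmetric zero-diagonal weights the synchronous map admits only fixed
points and period-2 orbits, which is what :func:`evolve` detects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_MAX_ITERS",
    "FIXED_POINT",
    "LIMIT_CYCLE",
    "MAX_ITER_EXCEEDED",
    "EvolutionResult",
    "WeightedPatternSet",
    "add_target_copies",
    "build_weight_matrix",
    "evolve",
    "evolve_batch",
    "load_patterns_csv",
    "load_weights_csv",
    "random_pattern",
    "random_patterns",
    "save_patterns_csv",
    "save_weights_csv",
    "synchronous_update",
]

# Safety cap on synchronous updates.  Transients in these networks are far
# shorter (tens of steps even at n = 1000); the cap only guards against bugs.
DEFAULT_MAX_ITERS = 200

FIXED_POINT = "fixed_point"
LIMIT_CYCLE = "limit_cycle"
MAX_ITER_EXCEEDED = "max_iter_exceeded"


def _as_pattern(s, n: int | None = None) -> np.ndarray:
    """Validate and return a 1-D +/-1 integer pattern."""
    arr = np.asarray(s)
    if arr.ndim != 1:
        raise ValueError(f"pattern must be 1-D, got shape {arr.shape}")
    if not np.all(np.abs(arr) == 1):
        raise ValueError("pattern entries must be exactly -1 or +1")
    if n is not None and arr.shape[0] != n:
        raise ValueError(f"dimension mismatch: pattern length {arr.shape[0]} != {n}")
    return arr.astype(np.int64, copy=False)


def random_pattern(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a length-``n`` pattern with i.i.d. equiprobable +/-1 entries.

    Parameters
    ----------
    n
        Number of units; must be >= 1.
    rng
        A seeded :class:`numpy.random.Generator`; identical seeds give
        identical patterns.
    """
    if n < 1:
        raise ValueError(f"invalid dimension: n must be >= 1, got {n}")
    return rng.choice(np.array([-1, 1], dtype=np.int64), size=n)


def random_patterns(p: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``p`` independent random patterns as a (p, n) integer array."""
    if p < 0:
        raise ValueError(f"invalid count: p must be >= 0, got {p}")
    if n < 1:
        raise ValueError(f"invalid dimension: n must be >= 1, got {n}")
    return rng.choice(np.array([-1, 1], dtype=np.int64), size=(p, n))


@dataclass(frozen=True)
class WeightedPatternSet:
    """A set of stored patterns, each with a positive presentation multiplier.

    A row with multiplier ``m`` is the pattern scaled by ``m`` before the
    Hebbian outer product, so it contributes ``m**2 * x x^T`` to the weights.
    This is how "presenting a stimulus with weight m" enters the model.
    """

    patterns: np.ndarray  # (p, n), entries +/-1
    multipliers: np.ndarray  # (p,), positive

    def __post_init__(self):
        pats = np.asarray(self.patterns, dtype=np.int64)
        mults = np.asarray(self.multipliers, dtype=np.int64)
        if pats.ndim != 2:
            raise ValueError("patterns must be a (p, n) array")
        if not np.all(np.abs(pats) == 1):
            raise ValueError("pattern entries must be exactly -1 or +1")
        if mults.shape != (pats.shape[0],):
            raise ValueError("one multiplier per pattern required")
        if np.any(mults <= 0):
            raise ValueError("multipliers must be positive")
        object.__setattr__(self, "patterns", pats)
        object.__setattr__(self, "multipliers", mults)

    @property
    def n(self) -> int:
        return self.patterns.shape[1]

    def __len__(self) -> int:
        return self.patterns.shape[0]


def build_weight_matrix(pset: WeightedPatternSet) -> np.ndarray:
    """Batch Hebbian rule: W = X^T X with the diagonal zeroed.

    ``X`` stacks the patterns row-wise, each scaled by its multiplier, so
    ``W[i, j] = sum_mu m_mu**2 * x_mu[i] * x_mu[j]`` for ``i != j`` and
    ``W[i, i] = 0``.  Integer arithmetic throughout.
    """
    if len(pset) == 0:
        raise ValueError("pattern set must be nonempty")
    X = pset.patterns * pset.multipliers[:, None]
    W = X.T @ X
    np.fill_diagonal(W, 0)
    return W


def add_target_copies(W: np.ndarray, target, count: int = 1) -> np.ndarray:
    """Return W plus ``count`` additional Hebbian copies of ``target``.

    Exactly equivalent (in integer arithmetic) to rebuilding the weight
    matrix with ``count`` extra multiplier-1 rows of ``target`` appended.
    """
    if count < 1:
        raise ValueError(f"invalid count: must be >= 1, got {count}")
    t = _as_pattern(target, W.shape[0])
    delta = count * np.outer(t, t)
    np.fill_diagonal(delta, 0)
    return W + delta


def synchronous_update(W: np.ndarray, s) -> np.ndarray:
    """One synchronous step: s' = sign(W s), with sign(0) = +1.

    All units are recomputed simultaneously from the same input state.
    """
    s = _as_pattern(s, W.shape[0])
    field = W @ s
    return np.where(field >= 0, 1, -1).astype(np.int64)


def _update_batch(Wf: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Synchronous step applied to every row of S (float64 internally)."""
    return np.where(S @ Wf >= 0.0, 1.0, -1.0)


@dataclass(frozen=True)
class EvolutionResult:
    """Outcome of iterating the synchronous map from one initial state.

    ``steps`` counts the updates needed to first reach ``final`` (0 if the
    initial state is already a fixed point); the extra update used to detect
    convergence is not counted.
    """

    outcome: str
    final: np.ndarray
    steps: int


def evolve(W: np.ndarray, s0, max_iters: int = DEFAULT_MAX_ITERS) -> EvolutionResult:
    """Iterate synchronous updates until a fixed point or 2-cycle is found.

    A fixed point is declared when s(t+1) = s(t); a limit cycle when
    s(t+2) = s(t) but s(t+1) != s(t) (symmetric zero-diagonal synchronous
    dynamics admit no longer periods).  If neither occurs within
    ``max_iters`` updates the outcome is ``max_iter_exceeded``.
    """
    if max_iters < 1:
        raise ValueError(f"invalid count: max_iters must be >= 1, got {max_iters}")
    s = _as_pattern(s0, W.shape[0])
    prev = None
    for t in range(max_iters):
        nxt = synchronous_update(W, s)
        if np.array_equal(nxt, s):
            return EvolutionResult(FIXED_POINT, s, t)
        if prev is not None and np.array_equal(nxt, prev):
            return EvolutionResult(LIMIT_CYCLE, s, t)
        prev = s
        s = nxt
    return EvolutionResult(MAX_ITER_EXCEEDED, s, max_iters)


def evolve_batch(
    W: np.ndarray, S0: np.ndarray, max_iters: int = DEFAULT_MAX_ITERS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evolve every row of ``S0`` simultaneously to its asymptotic orbit.

    Returns ``(finals, fixed, converged)`` where ``finals`` holds, per row,
    the fixed point (if any) or the current cycle state, ``fixed`` marks rows
    that reached a fixed point, and ``converged`` marks rows whose orbit
    settled (period <= 2) within ``max_iters``.

    All rows are advanced together until every row satisfies
    ``s(t+2) = s(t)``, i.e. is inside its period-1 or period-2 orbit; weight
    magnitudes here are far below 2**53, so float64 matmuls are exact.
    """
    if max_iters < 1:
        raise ValueError(f"invalid count: max_iters must be >= 1, got {max_iters}")
    Wf = W.astype(np.float64)
    S = S0.astype(np.float64)
    prev = None
    converged = np.zeros(S.shape[0], dtype=bool)
    for _ in range(max_iters):
        nxt = _update_batch(Wf, S)
        if prev is not None:
            converged = (nxt == prev).all(axis=1)
            if converged.all():
                prev, S = S, nxt
                break
        prev, S = S, nxt
    # One more step distinguishes fixed points from 2-cycles row-wise.
    nxt = _update_batch(Wf, S)
    fixed = (nxt == S).all(axis=1) & converged
    return S.astype(np.int64), fixed, converged


# -- plain-text serialization -------------------------------------------------

def save_patterns_csv(path, patterns: np.ndarray) -> None:
    """Write patterns (one per row) as comma-separated +1/-1 integers."""
    np.savetxt(path, np.atleast_2d(patterns), fmt="%d", delimiter=",")


def load_patterns_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, dtype=np.int64, delimiter=","))


def save_weights_csv(path, W: np.ndarray) -> None:
    """Write a weight matrix as a square integer CSV (exact round-trip)."""
    np.savetxt(path, W, fmt="%d", delimiter=",")


def load_weights_csv(path) -> np.ndarray:
    W = np.loadtxt(path, dtype=np.int64, delimiter=",")
    return np.atleast_2d(W)
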