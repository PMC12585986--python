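"""Sampled-initial-state experiments for networks too large to enumerate.

At n = 100 or n = 1000 the basin of a target cannot be measured
exhaustively, so convergence is probed on fixed samples of initial states
drawn from Hamming shells around the target: ``m`` states at each distance
``k`` (all entries equal to the target except exactly ``k`` flipped
units).  The same sampled states are reused across all presentations of a
run, so the per-presentation in-basin proportion changes only when the
basin itself changes — the accuracy trajectories are step functions.

Two condition sweeps characterise jump variability at n = 100:

* stimulus degradation — probe distance k in {5, 10, 15, 20, 25} with a
  single pretraining stimulus (weight 20);
* memory interference — k fixed at 20 with 1..5 pretraining stimuli
  (weight 20 each).

Per run, the coefficient of variation (CV) of the positive jump sizes in
the sampled in-basin count summarises dispersion; condition effects are
assessed with Welch's unequal-variance one-way ANOVA.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import (
    WeightedPatternSet,
    add_target_copies,
    build_weight_matrix,
    evolve_batch,
    random_pattern,
    random_patterns,
)

__all__ = [
    "DEGRADATION_KS",
    "INTERFERENCE_COUNTS",
    "WelchAnovaResult",
    "jump_cv",
    "run_condition_sweep",
    "sample_states_at_distance",
    "sampled_accuracy_experiment",
    "welch_anova",
]

DEGRADATION_KS = (5, 10, 15, 20, 25)
INTERFERENCE_COUNTS = (1, 2, 3, 4, 5)

# Above this shell size, distinct flip-sets are drawn by rejection instead
# of enumerating the whole shell.
_ENUM_SHELL_LIMIT = 200_000


def sample_states_at_distance(
    target, k: int, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``m`` states at Hamming distance exactly ``k`` from ``target``.

    States are pairwise distinct whenever the shell holds at least ``m``
    states (C(n, k) >= m); otherwise sampling falls back to drawing with
    replacement.  Returns an (m, n) array.
    """
    target = np.asarray(target, dtype=np.int64)
    n = target.shape[0]
    if not 0 <= k <= n:
        raise ValueError(f"invalid distance: k must be in [0, {n}], got {k}")
    if m < 1:
        raise ValueError(f"invalid count: m must be >= 1, got {m}")

    shell = math.comb(n, k)
    out = np.tile(target, (m, 1))
    if k == 0:
        return out
    if shell < m:
        flips = np.array([rng.choice(n, size=k, replace=False) for _ in range(m)])
    elif shell <= _ENUM_SHELL_LIMIT:
        combos = np.array(list(itertools.combinations(range(n), k)), dtype=np.int64)
        flips = combos[rng.choice(shell, size=m, replace=False)]
    else:
        # Shell too large to enumerate: draw uniform k-subsets in bulk
        # (k smallest ranks of a random row) and deduplicate.
        rows: list[np.ndarray] = []
        have = 0
        while have < m:
            draws = np.argpartition(
                rng.random((m - have + 4, n)), k - 1, axis=1
            )[:, :k]
            draws = np.unique(np.sort(draws, axis=1), axis=0)
            rows.append(draws)
            stacked = np.unique(np.concatenate(rows), axis=0)
            rows, have = [stacked], stacked.shape[0]
        flips = rng.permutation(rows[0])[:m]
    out[np.arange(m)[:, None], flips] *= -1
    return out


def _in_basin_counts(W: np.ndarray, S: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Boolean membership of each sampled row in the target's basin."""
    finals, fixed, _ = evolve_batch(W, S)
    return fixed & (finals == target).all(axis=1)


def sampled_accuracy_experiment(
    n: int = 100,
    k_list: tuple[int, ...] = (1, 2, 3, 5, 10, 20),
    m: int = 100,
    pretrain_count: int = 1,
    pretrain_multiplier: int = 30,
    J: int = 500,
    seed: int | np.random.SeedSequence = 0,
    run_id: int = 0,
) -> pd.DataFrame:
    """Accuracy-vs-presentations curves from frozen Hamming-shell samples.

    Pretrains an ``n``-unit network (default: one stimulus at weight 30,
    the n = 100 condition; use weight 100 for n = 1000), samples ``m``
    states at every distance in ``k_list`` once, then presents the target
    ``J`` times, recording for each j = 0..J the proportion of each shell's
    sample inside the target basin.  Returns a tidy frame with columns
    ``run_id, k, j, proportion``.
    """
    rng = np.random.default_rng(seed)
    target = random_pattern(n, rng)
    pretrain = random_patterns(pretrain_count, n, rng)
    W = build_weight_matrix(
        WeightedPatternSet(
            pretrain, np.full(pretrain_count, pretrain_multiplier, dtype=np.int64)
        )
    )

    samples = [sample_states_at_distance(target, k, m, rng) for k in k_list]
    sizes = [s.shape[0] for s in samples]
    S = np.concatenate(samples)
    bounds = np.cumsum([0] + sizes)

    records = []
    for j in range(J + 1):
        if j > 0:
            W = add_target_copies(W, target, 1)
        member = _in_basin_counts(W, S, target)
        for ki, k in enumerate(k_list):
            prop = member[bounds[ki] : bounds[ki + 1]].mean()
            records.append((run_id, k, j, float(prop)))
    return pd.DataFrame(records, columns=["run_id", "k", "j", "proportion"])


def jump_cv(jump_sizes) -> float:
    """Coefficient of variation (sample sd / mean) of positive jump sizes.

    Returns NaN when fewer than two jumps are available (the sample
    standard deviation, ddof = 1, is then undefined); such runs are
    excluded from downstream ANOVAs and their count reported.
    """
    sizes = np.asarray(jump_sizes, dtype=np.float64)
    if sizes.size < 2:
        return float("nan")
    return float(sizes.std(ddof=1) / sizes.mean())


def _sweep_run(
    n: int,
    k: int,
    m: int,
    pretrain_count: int,
    pretrain_multiplier: int,
    J: int,
    rng: np.random.Generator,
    resample: bool = True,
) -> list[int]:
    """One sweep run: positive jumps of the sampled in-basin count.

    With ``resample`` (the default for the condition sweeps) a fresh set of
    ``m`` shell states is drawn at every presentation, so the in-basin
    count is a fresh size-m probe of the current basin; with
    ``resample=False`` the j = 0 sample is frozen for the whole run.
    """
    target = random_pattern(n, rng)
    pretrain = random_patterns(pretrain_count, n, rng)
    W = build_weight_matrix(
        WeightedPatternSet(
            pretrain, np.full(pretrain_count, pretrain_multiplier, dtype=np.int64)
        )
    )
    S = sample_states_at_distance(target, k, m, rng)
    counts = np.zeros(J + 1, dtype=np.int64)
    counts[0] = _in_basin_counts(W, S, target).sum()
    for j in range(1, J + 1):
        W = add_target_copies(W, target, 1)
        if resample:
            S = sample_states_at_distance(target, k, m, rng)
        counts[j] = _in_basin_counts(W, S, target).sum()
    diffs = np.diff(counts)
    return [int(d) for d in diffs if d > 0]


def run_condition_sweep(
    sweep: str,
    n: int = 100,
    runs: int = 100,
    m: int = 100,
    J: int = 300,
    pretrain_multiplier: int = 20,
    seed: int | np.random.SeedSequence = 0,
    resample: bool = True,
) -> pd.DataFrame:
    """Jump-size CV across degradation or interference conditions.

    ``sweep`` is ``"degradation"`` (probe distance k varies over
    {5, 10, 15, 20, 25}, one pretraining stimulus) or ``"interference"``
    (k = 20, pretraining count varies over 1..5).  Each condition gets
    ``runs`` independent runs of ``J`` presentations; per run the CV of
    the positive jumps in the sampled in-basin count is recorded (NaN when
    fewer than two jumps occurred).  Returns a tidy frame with columns
    ``sweep, condition, run_id, n_jumps, cv``.

    The shell probe is redrawn at every presentation by default
    (``resample=True``): the jump statistic then reflects both basin growth
    and shell coverage, which is what makes its per-run CV sensitive to
    stimulus degradation and memory interference.  ``resample=False``
    freezes the j = 0 sample as in the accuracy experiment.
    """
    if sweep == "degradation":
        conditions = [(k, 1) for k in DEGRADATION_KS]
    elif sweep == "interference":
        conditions = [(20, p) for p in INTERFERENCE_COUNTS]
    else:
        raise ValueError(
            f"unknown sweep {sweep!r}: expected 'degradation' or 'interference'"
        )

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(len(conditions) * runs)
    records = []
    ci = 0
    for k, pretrain_count in conditions:
        condition = k if sweep == "degradation" else pretrain_count
        for r in range(runs):
            rng = np.random.default_rng(children[ci])
            ci += 1
            jumps = _sweep_run(
                n, k, m, pretrain_count, pretrain_multiplier, J, rng, resample=resample
            )
            records.append((sweep, condition, r, len(jumps), jump_cv(jumps)))
    return pd.DataFrame(
        records, columns=["sweep", "condition", "run_id", "n_jumps", "cv"]
    )


@dataclass(frozen=True)
class WelchAnovaResult:
    F: float
    df1: float
    df2: float
    p: float


def welch_anova(groups) -> WelchAnovaResult:
    """Welch's unequal-variance one-way ANOVA.

    Groups are weighted by n_i / s_i**2; the statistic is the weighted
    between-group mean square over Welch's correction term, with
    Satterthwaite-style denominator degrees of freedom, and the p-value
    comes from the F distribution.  Requires >= 2 groups, each with >= 2
    finite values and positive variance.
    """
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise ValueError("welch_anova requires at least 2 groups")
    for g in arrays:
        g = g[np.isfinite(g)]
        if g.size < 2:
            raise ValueError("degenerate group: fewer than 2 finite values")
        if g.var(ddof=1) <= 0:
            raise ValueError("degenerate group: zero variance")
    arrays = [g[np.isfinite(g)] for g in arrays]

    g = len(arrays)
    n = np.array([a.size for a in arrays], dtype=np.float64)
    means = np.array([a.mean() for a in arrays])
    var = np.array([a.var(ddof=1) for a in arrays])
    w = n / var
    sw = w.sum()
    grand = (w * means).sum() / sw
    numer = (w * (means - grand) ** 2).sum() / (g - 1)
    lam = 3.0 * ((1.0 - w / sw) ** 2 / (n - 1)).sum() / (g**2 - 1)
    F = numer / (1.0 + 2.0 * lam * (g - 2) / 3.0)
    df1 = g - 1.0
    df2 = 1.0 / lam
    p = float(stats.f.sf(F, df1, df2))
    return WelchAnovaResult(float(F), df1, df2, p)
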