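# Methods

## Model

The package simulates a classical Amari-Hopfield network: `n` binary units
with states `s_i ∈ {−1, +1}`, fully connected through a symmetric,
zero-diagonal weight matrix built by the batch Hebbian rule

    W = Xᵀ X,   W_ii = 0,

where the rows of `X` are the stored patterns, each scaled by its
presentation weight (a pattern stored with weight `m` therefore contributes
`m² x xᵀ` to `W`). Dynamics are deterministic synchronous updates

    s(t+1) = sign(W s(t)),   sign(0) = +1,

iterated until a fixed point (`s(t+1) = s(t)`) or a period-2 limit cycle
(`s(t+2) = s(t)`, `s(t+1) ≠ s(t)`). Symmetric zero-diagonal synchronous
dynamics admit no longer periods, so two-step comparison is a complete
convergence test; a `max_iters` cap (default 200, far above observed
transients of < 15 updates even at n = 1000) guards against bugs only.

The **attractor basin** of a target pattern is the set of initial states
whose dynamics converge to the target as an exact fixed point. Limit-cycle
states belong to no basin, and the negated target's basin is never
counted. The target itself is a member iff it is a fixed point.

## The repeated-presentation study

Each run (a) pretrains the network with `p` fresh random ±1 stimuli at
weight `w` — establishing a crowded attractor landscape the target must
compete against — and (b) appends one weight-1 Hebbian copy of a fresh
random target per presentation, `j = 1..J`, measuring the target basin
after every presentation. Defaults are the study conditions:

| experiment | n | pretraining | J | runs |
|---|---|---|---|---|
| exp1/exp2 (exhaustive) | 10 | 50 stimuli × weight 10 | 1000 | 100 |
| exp3 accuracy (sampled) | 100 / 1000 | 1 stimulus × weight 30 / 100 | 500 | 1 per curve |
| exp4 sweeps (sampled) | 100 | 1–5 stimuli × weight 20 | 300 | 100 per condition |

At n = 10 the basin is measured exhaustively over all 2¹⁰ = 1024 states
(all states advanced simultaneously; correctness anchored to a per-state
loop oracle in the tests). Weights are updated incrementally in integer
arithmetic, bit-identical to batch rebuilding (spot-verified inside the
run loop when `verify_at` is set).

A **jump** is a positive change in basin size between consecutive
presentations. Negative changes occur rarely (~0.1% of presentations);
they are logged but excluded from the jump distribution, which is the
distribution of positive changes only.

## Jump-distribution analysis

Pooled positive jump sizes (integers ≥ 1) are compared across four
candidates fitted by maximum likelihood on the same sample:

* lognormal: `meanlog = mean(log x)`, `sdlog = RMS deviation of log x`
  (divisor n);
* exponential: `rate = 1/mean(x)`;
* half-normal with location fixed at 1: `σ = sqrt(mean((x−1)²))`;
* power law with lower bound `x_min = 1`: by default the continuous Pareto
  MLE `α = 1 + n / Σ log x` — the scaling-exponent estimator used by the
  standard R fitting stack when the lower bound is fixed — with the
  discrete zeta-law MLE (`p(x) = x^{−α}/ζ(α, x_min)`, bounded 1-D
  likelihood maximization using scipy's Hurwitz zeta) available via
  `fit_powerlaw_discrete` / `discrete_powerlaw=True`.

Continuous likelihoods are applied to the integer data without continuity
correction, keeping all four AICs (`2k − 2 log L`) on a common footing.
Model preference stability is assessed by nonparametric bootstrap: 1000
resamples with replacement, refitting all four models and counting which
attains the lowest AIC. Excess kurtosis uses the moment ratio with the
`(1 − 1/n)²` small-sample factor (the default of the common R estimator);
at these sample sizes the convention shifts values well under 1%.

## Transition-graph branch analysis

One synchronous update defines a functional graph (out-degree 1); in the
field's inverted-tree vocabulary a state's *parent* is its successor and
the *branch size* of a node is the number of states whose forward orbit
reaches it, counting the node itself. After every jump the newly acquired
states (basin after minus basin before) are partitioned into head-rooted
branches: a **head** is a new state whose successor is not new — or which
is its own successor. The second clause handles a case the head rule alone
cannot: at the first jump of a run the target itself is newly acquired and
is its own successor, so it roots its branch. Branch sizes always sum to
the number of new states (asserted). Note that the new-state set can be
larger than the net jump: a presentation that grows the basin may
simultaneously evict other states, so branch totals bound the net change
from above.

Network-wide descendant counts are computed by reverse-topological
accumulation over the in-trees plus distribution of each terminal cycle's
inflow to its members; both members of a period-2 cycle count each other
(the forward orbit includes the full cycle). A per-state forward-orbit
oracle in the tests pins this convention down exactly. For the
network-wide heavy-tail comparison, counts ≥ 2 are pooled over all J + 1
presentation snapshots of a single run (`descendant_count_pool`,
`mode="snapshots"`); pooling each run's pretraining-only network across
runs is available as `mode="pretrained"` and gives a slightly lower
exponent (≈ 1.64 vs ≈ 1.67) because it omits the growing target attractor.

## Sampled-state experiments in large networks

For n ∈ {100, 1000}, basins are probed on Hamming shells: `m = 100` states
at exact distance `k` from the target, pairwise distinct whenever the
shell holds at least `m` states (sampling with replacement otherwise —
only reachable for tiny shells). Shells too large to enumerate are sampled
by drawing uniform `k`-subsets (the `k` smallest ranks of a random vector)
with deduplication.

In the **accuracy experiment** the shell samples are frozen at j = 0 and
reused for all presentations, so the per-shell in-basin proportion is a
pure step function of j (most consecutive differences are exactly zero).
In the **condition sweeps** the shell probe is redrawn at every
presentation: the per-run statistic is then the positive jumps of a fresh
size-`m` probe of the current basin, and its coefficient of variation
(sample sd / mean, ddof = 1) is what responds to the experimental
conditions. This distinction matters: with frozen probes the jump-size CV
is nearly invariant across degradation (k ∈ {5..25}) and interference
(1–5 pretraining stimuli) conditions (Welch F ≈ 1), whereas the
fresh-probe statistic falls monotonically with both, strongly
(Welch F ≈ 70+ at 20 runs/condition). Runs with fewer than two positive
jumps have no defined CV; they are recorded as missing, counted, and
excluded from the ANOVA.

Welch's unequal-variance one-way ANOVA is implemented from the standard
formulas (group weights `nᵢ/sᵢ²`, Satterthwaite-style denominator df) and
cross-checked against `pingouin.welch_anova` to 6 decimals in the tests.

## Seeding and reproducibility

Every experiment takes one base seed; run `r` uses
`SeedSequence(base).spawn(runs)[r]`, so runs never share a random stream
and are individually reproducible. Outputs are plain CSV/JSON with a
SHA-256 manifest; rerunning a config yields byte-identical tables.

## Numerical choices

* Integer weights throughout; batch evolution casts to float64 (fields are
  ≪ 2⁵³, so matmuls are exact).
* `sign(0) = +1`, deterministic — no stochastic tie-breaking.
* Zeta MLE: bounded search on α ∈ (1, 50], `xatol = 1e-10`; AIC ties break
  by model name.
* CDF/CCDF tables are tabulated at sorted unique values with
  `CDF + CCDF = 1`; the zero CCDF at the maximum is dropped before
  log-scale plotting.

## What the generator does and does not emulate

Inputs are internally generated i.i.d. equiprobable ±1 patterns — the
study is a self-contained simulation, so passing tests establish the
model's behaviour, not properties of any empirical data. The model omits
(deliberately) asynchronous or stochastic updates, graded/spiking units,
non-Hebbian plasticity, and sparse connectivity; conclusions about
discontinuous learning transfer to such settings only as qualitative
hypotheses.

## Known limitations

* Exhaustive basin measurement is capped at n ≤ 20 (the enumeration guard);
  beyond that only shell sampling is available.
* The four-model comparison assumes the strictest common support
  (all values ≥ 1) and refuses smaller samples than 4 values.
* The half-normal σ and the jump frequency are the statistics most
  sensitive to the far tail and to the smallest jumps respectively, and
  show the largest run-to-run variability of the reported quantities.
* The n = 1000 accuracy experiment is CPU-minutes scale and is not run by
  default (`exp3 --large`).
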