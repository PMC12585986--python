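# hopbasin

Attractor-basin dynamics of Hebbian Amari-Hopfield networks under repeated
stimulus presentation.

Individual learning curves — in conditioning, skill acquisition, memory —
often show sudden jumps rather than the smooth improvement seen in group
averages. `hopbasin` studies the simplest network model of associative
memory that reproduces this: a fully connected network of `n` binary ±1
units with symmetric Hebbian weights `W = XᵀX` (zero diagonal) and
deterministic synchronous dynamics `s(t+1) = sign(W s(t))`, `sign(0) = +1`.
A network is pretrained on random stimuli, then repeatedly presented with
one target stimulus, one Hebbian copy at a time. The package measures the
target's attractor basin after every presentation — exhaustively over all
2ⁿ states for small networks, by Hamming-shell sampling for n up to 1000 —
and characterises:

* the discrete **jumps** in basin size (most presentations change nothing;
  growth arrives in rare, heavy-tailed increments),
* the **jump-size distribution**, compared across lognormal, exponential,
  half-normal (location 1) and power-law (x_min = 1) models by
  maximum-likelihood AIC with bootstrap model-preference counts,
* the **transition-graph structure** of newly acquired states: head-rooted
  branches whose sizes follow a power law, and network-wide descendant
  counts,
* how stimulus degradation (probe Hamming distance) and memory
  interference (pretraining load) shape jump-size variability (CV), tested
  with Welch's ANOVA.

## Worked example

```python
import numpy as np
from hopbasin import (
    run_presentation_experiment, extract_jumps, compare_models_aic,
)

run = run_presentation_experiment(
    n=10, pretrain_count=50, pretrain_multiplier=10, J=1000, seed=42,
)
sizes = run.trajectory.sizes
print(f"basin size: {sizes[0]} -> {sizes[-1]} states "
      f"in {len(run.jumps)} jumps over 1000 presentations")
for rep in compare_models_aic([j.size for j in run.jumps]):
    print(f"{rep.model:>12}: AIC {rep.aic:8.1f}  {rep.params}")
```

Output (seed 42):

```
basin size: 0 -> 462 states in 7 jumps over 1000 presentations
    powerlaw: AIC     40.4  {'alpha': 1.7116899413861333}
   lognormal: AIC     53.8  {'meanlog': 1.405106271492801, 'sdlog': 2.082691007027185}
 exponential: AIC     74.7  {'rate': 0.015151515151515152}
  halfnormal: AIC     83.9  {'sigma': 167.84218778364396}
```

The basin stays flat for dozens of presentations, then gains tens or
hundreds of states at once: 7 jumps account for all 462 states gained.
(A single run is too small to rank models reliably — the study pools
jumps over 100 runs, where the lognormal wins decisively; see below.)

## Command line

```bash
hopbasin exp1 --runs 100 --seed 0 --out out/exp1   # exhaustive basin growth
hopbasin exp2 --runs 100 --seed 0 --out out/exp2   # branch decomposition
hopbasin exp3 --n 100   --seed 0 --out out/exp3    # sampled accuracy curves
hopbasin exp4 --sweep both --runs 100 --seed 0 --out out/exp4
hopbasin fit out/exp1/jumps.csv --bootstrap 1000   # four-model comparison
hopbasin report out/exp2
```

Outputs are tidy CSV tables and JSON fit reports with a SHA-256 manifest;
identical seeds give byte-identical files.

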