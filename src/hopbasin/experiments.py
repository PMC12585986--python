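"""Reproducible orchestration of the four experiments.

Each experiment is a pure function of an :class:`ExperimentConfig` whose
defaults are the study's protocol constants:

* ``exp1_basin``   — 10-unit exhaustive-basin growth: 100 runs, 50
  pretraining stimuli at weight 10, 1000 target presentations, pooled
  jump distribution and four-model AIC comparison with bootstrap.
* ``exp2_branches``— branch decomposition of newly acquired states over
  the same protocol, plus network-wide descendant counts of the
  pretrained networks.
* ``exp3_sampled`` — sampled Hamming-shell accuracy curves at n = 100
  (one pretraining stimulus at weight 30, 500 presentations); n = 1000
  uses weight 100 and shells up to k = 100.
* ``exp4_sweeps``  — degradation and interference sweeps at n = 100.

Every run gets a deterministic child seed spawned from the base seed
(`numpy` ``SeedSequence.spawn``), so runs are independently reproducible
and never share a random stream.  Outputs are plain CSV/JSON files listed,
with content hashes, in a ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import basins, fitting, graph, network, sampled

__all__ = [
    "EXPERIMENT_DEFAULTS",
    "ExperimentConfig",
    "aggregate_jump_pool",
    "child_seeds",
    "descendant_count_pool",
    "load_config",
    "run_experiment",
]

logger = logging.getLogger("hopbasin")

EXPERIMENT_DEFAULTS: dict[str, dict] = {
    "exp1_basin": dict(
        n=10, pretrain_count=50, pretrain_multiplier=10, J=1000, runs=100, B=1000
    ),
    "exp2_branches": dict(
        n=10, pretrain_count=50, pretrain_multiplier=10, J=1000, runs=100, B=1000
    ),
    "exp3_sampled": dict(
        n=100,
        pretrain_count=1,
        pretrain_multiplier=30,
        J=500,
        runs=1,
        k_list=(1, 2, 3, 5, 10, 20),
        m=100,
    ),
    "exp4_sweeps": dict(
        n=100, pretrain_count=1, pretrain_multiplier=20, J=300, runs=100, m=100
    ),
}

# The n = 1000 variant of exp3 (enabled by --large / n=1000).
_EXP3_LARGE = dict(
    n=1000, pretrain_multiplier=100, k_list=(1, 2, 3, 5, 10, 20, 50, 100)
)


@dataclass(frozen=True)
class ExperimentConfig:
    """A fully specified experiment; defaults are the study's settings."""

    experiment: str
    n: int = 10
    pretrain_count: int = 50
    pretrain_multiplier: int = 10
    J: int = 1000
    runs: int = 100
    k_list: tuple[int, ...] = ()
    m: int = 100
    B: int = 1000
    seed: int = 0
    out_dir: str | None = None
    x_min: int = 1
    collect_branches: bool = False
    sweeps: tuple[str, ...] = ("degradation", "interference")

    @classmethod
    def with_defaults(cls, experiment: str, **overrides) -> "ExperimentConfig":
        if experiment not in EXPERIMENT_DEFAULTS:
            raise ValueError(
                f"config error: unknown experiment {experiment!r}; "
                f"expected one of {sorted(EXPERIMENT_DEFAULTS)}"
            )
        params = dict(EXPERIMENT_DEFAULTS[experiment])
        if experiment == "exp3_sampled" and overrides.get("n") == 1000:
            params.update(_EXP3_LARGE)
        params.update({k: v for k, v in overrides.items() if v is not None})
        return cls(experiment=experiment, **params)

    def __post_init__(self):
        for name in ("n", "J", "runs", "m", "B"):
            if getattr(self, name) < 1:
                raise ValueError(f"config error: {name} must be positive")
        if self.pretrain_count < 0:
            raise ValueError("config error: pretrain_count must be >= 0")
        if self.pretrain_count > 0 and self.pretrain_multiplier < 1:
            raise ValueError("config error: pretrain_multiplier must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> dict:
    """Read a YAML/key-value config file into a flat override dict."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("config error: config file must hold a key-value mapping")
    if "k_list" in data and data["k_list"] is not None:
        data["k_list"] = tuple(data["k_list"])
    if "sweeps" in data and data["sweeps"] is not None:
        data["sweeps"] = tuple(data["sweeps"])
    return data


def child_seeds(base_seed: int, runs: int) -> list[np.random.SeedSequence]:
    """Deterministic, stream-independent per-run seeds.

    Run r receives ``SeedSequence(base_seed).spawn(runs)[r]``; spawned
    sequences have distinct spawn keys, so no two runs share a stream.
    """
    return np.random.SeedSequence(base_seed).spawn(runs)


def aggregate_jump_pool(
    runs: list[basins.PresentationRun],
) -> tuple[np.ndarray, float]:
    """Pool positive jump sizes across runs; proportion of presentations with one.

    Returns ``(pool, proportion)`` with proportion = total jumps / (runs * J).
    """
    if not runs:
        raise ValueError("at least one run required")
    pool = np.array(
        [j.size for run in runs for j in run.jumps], dtype=np.int64
    )
    total_presentations = sum(run.trajectory.J for run in runs)
    return pool, float(pool.size / total_presentations)


# -- output helpers -----------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out: Path, config: ExperimentConfig, files: list[Path]) -> Path:
    manifest = {
        "config": config.to_dict(),
        "files": {f.name: _sha256(f) for f in files},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def _runs_to_frames(
    runs: list[basins.PresentationRun],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    traj = pd.DataFrame(
        [
            (run.trajectory.run_id, j, int(s))
            for run in runs
            for j, s in enumerate(run.trajectory.sizes)
        ],
        columns=["run_id", "j", "basin_size"],
    )
    jumps = pd.DataFrame(
        [(run.trajectory.run_id, jr.j, jr.size) for run in runs for jr in run.jumps],
        columns=["run_id", "j", "jump_size"],
    )
    neg = pd.DataFrame(
        [
            (run.trajectory.run_id, j, c)
            for run in runs
            for j, c in run.negative_changes
        ],
        columns=["run_id", "j", "change"],
    )
    branches = pd.DataFrame(
        [
            (run.trajectory.run_id, jj, int(s))
            for run in runs
            for jj, s in zip(run.branch_jumps, run.branch_sizes)
        ],
        columns=["run_id", "j", "branch_size"],
    )
    return traj, jumps, neg, branches


def _run_basin_runs(config: ExperimentConfig) -> list[basins.PresentationRun]:
    runs = []
    for r, cs in enumerate(child_seeds(config.seed, config.runs)):
        t0 = time.time()
        run = basins.run_presentation_experiment(
            n=config.n,
            pretrain_count=config.pretrain_count,
            pretrain_multiplier=config.pretrain_multiplier,
            J=config.J,
            seed=cs,
            run_id=r,
            collect_branches=config.collect_branches,
        )
        logger.info(
            "run %d: %d jumps, %.1fs", r, len(run.jumps), time.time() - t0
        )
        runs.append(run)
    return runs


def _fit_summary(pool: np.ndarray, x_min: int, B: int, rng) -> dict:
    if pool.size < 4:  # too few values for a meaningful four-model comparison
        return {"n": int(pool.size), "aic_ranking": [], "bootstrap": None}
    ranking = fitting.compare_models_aic(pool, x_min=x_min)
    boot = fitting.bootstrap_model_preference(pool, B=B, rng=rng, x_min=x_min)
    return {
        "n": int(pool.size),
        "excess_kurtosis": fitting.excess_kurtosis(pool),
        "aic_ranking": [r.to_dict() for r in ranking],
        "bootstrap": {"B": boot.B, "counts": boot.counts, "skipped": boot.skipped},
    }


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Execute one experiment, write its output files, return the aggregate.

    The returned dict is also what ``report`` prints: pooled statistics,
    fit rankings, and (for exp4) the Welch ANOVA per sweep.  When an output
    directory is given (config.out_dir or ``out_dir``), tidy CSV tables,
    JSON reports, and a hash manifest are written there.
    """
    out = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def save_df(df: pd.DataFrame, name: str):
        if out is not None:
            path = out / name
            df.to_csv(path, index=False)
            files.append(path)

    def save_json(obj, name: str):
        if out is not None:
            path = out / name
            path.write_text(json.dumps(obj, indent=2, default=float) + "\n")
            files.append(path)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    result: dict = {"experiment": config.experiment}

    log_handler = None
    old_level = logger.level
    if out is not None:
        log_handler = logging.FileHandler(out / "run.log")
        log_handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        logger.addHandler(log_handler)
        logger.setLevel(logging.INFO)
        logger.info("start %s seed=%d runs=%d", config.experiment, config.seed,
                    config.runs)

    try:
        return _run_experiment_body(config, result, rng, save_df, save_json)
    finally:
        if log_handler is not None:
            logger.info("done %s", config.experiment)
            logger.removeHandler(log_handler)
            log_handler.close()
            logger.setLevel(old_level)
            files.append(out / "run.log")
            _write_manifest(out, config, files)


def _run_experiment_body(config, result, rng, save_df, save_json):

    if config.experiment in ("exp1_basin", "exp2_branches"):
        config = dataclasses.replace(
            config, collect_branches=config.experiment == "exp2_branches"
        )
        runs = _run_basin_runs(config)
        pool, proportion = aggregate_jump_pool(runs)
        traj, jumps, neg, branches = _runs_to_frames(runs)
        save_df(traj, "trajectories.csv")
        save_df(jumps, "jumps.csv")
        save_df(neg, "negative_changes.csv")
        result["proportion_increase"] = proportion
        result["n_negative_changes"] = int(len(neg))

        if config.experiment == "exp1_basin":
            result["jump_fits"] = _fit_summary(pool, config.x_min, config.B, rng)
            save_json(result["jump_fits"], "jump_fits.json")
            if pool.size:
                save_df(fitting.empirical_cdf_ccdf(pool), "jump_cdf.csv")
        else:
            save_df(branches, "branches.csv")
            bsizes = branches["branch_size"].to_numpy()
            result["n_branches"] = int(bsizes.size)
            result["proportion_singleton"] = (
                float((bsizes == 1).mean()) if bsizes.size else float("nan")
            )
            big = bsizes[bsizes >= 2]
            result["branch_fits"] = _fit_summary(big, config.x_min, config.B, rng)
            save_json(
                {
                    "proportion_singleton": result["proportion_singleton"],
                    "n_branches": result["n_branches"],
                    **result["branch_fits"],
                },
                "branch_fits.json",
            )
            # Network-wide descendant counts over one run's snapshots.
            counts = descendant_count_pool(config)
            big = counts[counts >= 2]
            result["descendant_fits"] = _fit_summary(big, config.x_min, config.B, rng)
            save_json(result["descendant_fits"], "descendant_fits.json")
            save_df(fitting.empirical_cdf_ccdf(big), "descendant_cdf.csv")
            # Before/after snapshot of one jump in a small (8-unit) network,
            # as edge lists rather than a rendered figure.
            example = jump_edge_example(n=8, seed=config.seed)
            if example is not None:
                before, after = example
                save_df(before, "example_edges_before.csv")
                save_df(after, "example_edges_after.csv")

    elif config.experiment == "exp3_sampled":
        frames = []
        for r, cs in enumerate(child_seeds(config.seed, config.runs)):
            frames.append(
                sampled.sampled_accuracy_experiment(
                    n=config.n,
                    k_list=config.k_list,
                    m=config.m,
                    pretrain_count=config.pretrain_count,
                    pretrain_multiplier=config.pretrain_multiplier,
                    J=config.J,
                    seed=cs,
                    run_id=r,
                )
            )
        acc = pd.concat(frames, ignore_index=True)
        save_df(acc, "accuracy.csv")
        steps = acc.sort_values(["run_id", "k", "j"]).groupby(["run_id", "k"])[
            "proportion"
        ]
        result["accuracy"] = acc
        result["fraction_nonzero_steps"] = float(
            steps.apply(lambda s: (np.diff(s) != 0).mean()).mean()
        )

    elif config.experiment == "exp4_sweeps":
        tables = []
        anova = {}
        sub_seeds = child_seeds(config.seed, len(config.sweeps))
        for sweep, cs in zip(config.sweeps, sub_seeds):
            df = sampled.run_condition_sweep(
                sweep,
                n=config.n,
                runs=config.runs,
                m=config.m,
                J=config.J,
                pretrain_multiplier=config.pretrain_multiplier,
                seed=cs,
            )
            tables.append(df)
            groups = [
                g["cv"].dropna().to_numpy() for _, g in df.groupby("condition")
            ]
            res = sampled.welch_anova(groups)
            anova[sweep] = {
                "F": res.F,
                "df1": res.df1,
                "df2": res.df2,
                "p": res.p,
                "mean_cv_by_condition": df.groupby("condition")["cv"]
                .mean()
                .to_dict(),
                "excluded_runs": int(df["cv"].isna().sum()),
            }
        sweeps_df = pd.concat(tables, ignore_index=True)
        save_df(sweeps_df, "sweeps.csv")
        save_json(anova, "welch_anova.json")
        result["sweeps"] = sweeps_df
        result["welch_anova"] = anova

    else:  # pragma: no cover - guarded by ExperimentConfig
        raise ValueError(f"config error: unknown experiment {config.experiment!r}")

    return result


def jump_edge_example(
    n: int = 8,
    pretrain_count: int = 50,
    pretrain_multiplier: int = 10,
    J: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame] | None:
    """Transition-graph edge lists immediately before and after one jump.

    Runs a small network until the first basin-size increase and returns
    two frames (source, successor, in_basin, is_new) — the data behind a
    before/after basin picture.  Returns None if no jump occurs within J
    presentations.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 8]))
    states = basins.enumerate_states(n)
    target = network.random_pattern(n, rng)
    pats = network.random_patterns(pretrain_count, n, rng)
    W = network.build_weight_matrix(
        network.WeightedPatternSet(
            pats, np.full(pretrain_count, pretrain_multiplier)
        )
    )
    prev_mask = basins.target_basin_mask(W, target, states)
    prev_W = W
    for _ in range(J):
        W = network.add_target_copies(W, target, 1)
        mask = basins.target_basin_mask(W, target, states)
        if mask.sum() > prev_mask.sum():
            frames = []
            for Wx, mx, new in (
                (prev_W, prev_mask, np.zeros(len(states), bool)),
                (W, mask, mask & ~prev_mask),
            ):
                tmap = graph.build_transition_map(Wx, states)
                edges = graph.transition_edge_table(tmap)
                frames.append(
                    pd.DataFrame(
                        {
                            "source": edges[:, 0],
                            "successor": edges[:, 1],
                            "in_basin": mx.astype(int),
                            "is_new": new.astype(int),
                        }
                    )
                )
            return frames[0], frames[1]
        prev_mask, prev_W = mask, W
    return None


def descendant_count_pool(
    config: ExperimentConfig, mode: str = "snapshots"
) -> np.ndarray:
    """Network-wide descendant counts for the branch-size comparison.

    ``mode="snapshots"`` (default) runs one repeated-presentation run with
    the config's first child seed and pools the descendant count of every
    enumerated state at every presentation count j = 0..J — the
    network-wide counterpart of the per-jump branch analysis.
    ``mode="pretrained"`` instead pools counts of each run's
    pretraining-only network across all runs.
    """
    states = basins.enumerate_states(config.n)
    pool: list[int] = []
    if mode == "snapshots":
        rng = np.random.default_rng(child_seeds(config.seed, 1)[0])
        target = network.random_pattern(config.n, rng)
        pats = network.random_patterns(config.pretrain_count, config.n, rng)
        W = network.build_weight_matrix(
            network.WeightedPatternSet(
                pats, np.full(config.pretrain_count, config.pretrain_multiplier)
            )
        )
        for j in range(config.J + 1):
            if j > 0:
                W = network.add_target_copies(W, target, 1)
            tmap = graph.build_transition_map(W, states)
            pool.extend(graph.descendant_counts(tmap).tolist())
    elif mode == "pretrained":
        for cs in child_seeds(config.seed, config.runs):
            rng = np.random.default_rng(cs)
            network.random_pattern(config.n, rng)  # keep stream aligned with runs
            pats = network.random_patterns(config.pretrain_count, config.n, rng)
            W = network.build_weight_matrix(
                network.WeightedPatternSet(
                    pats, np.full(config.pretrain_count, config.pretrain_multiplier)
                )
            )
            tmap = graph.build_transition_map(W, states)
            pool.extend(graph.descendant_counts(tmap).tolist())
    else:
        raise ValueError(f"unknown descendant pool mode {mode!r}")
    return np.array(pool, dtype=np.int64)
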