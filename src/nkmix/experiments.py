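"""Replicate experiments across landscapes and intermixing levels.

One *replicate* is one NK problem space plus the heuristics and initial
solutions drawn for it.  Every intermixing level of a replicate shares that
material — the runs are identical in every way except how diversity is
arranged on the ring — so level contrasts are paired within replicates.

Seed hierarchy (all derived deterministically from ``master_seed``):

* landscape seed     <- (master, replicate, 0)
* heuristic stream   <- (master, replicate, 1)
* initial states     <- (master, replicate, 2)
* level dynamics     <- (master, replicate, 10 + canonical level index)

Keying the per-level stream by the level's *canonical* index means running a
subset of levels reproduces exactly the same per-level results as the full
sweep under the same master seed.

Aggregation follows the cross-landscape convention: mean equilibrium score
and its standard error are computed across replicates; per-round
trajectories of unequal length are right-padded with each run's final value
("carry forward") before averaging; unique-knowledge curves are cumulative
counts of distinct solutions ever present, reported as marginals against a
reference level.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import sample_heuristic, sample_heuristic_pair
from .engine import (
    MAX_ROUNDS_DEFAULT,
    N_AGENTS_DEFAULT,
    SimulationTrace,
    build_population,
    initial_states_for,
    run_simulation,
)
from .landscape import generate_landscape
from .network import IntermixingScheme, Regime, TorusNetwork, levels_for


def derived_seed(*key: int) -> int:
    """A deterministic 31-bit seed derived from an integer key path."""
    ss = np.random.SeedSequence(list(key))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


@dataclass(frozen=True)
class ExperimentSpec:
    """A full intermixing sweep: regime, levels, replicate count, parameters."""

    regime: Regime
    levels: tuple[str, ...] | None = None  # None = all five canonical levels
    n_replicates: int = 200
    n_loci: int = 20
    k_epistasis: int = 5
    exponent: float = 10.0
    master_seed: int = 0
    max_rounds: int = MAX_ROUNDS_DEFAULT
    n_agents: int = N_AGENTS_DEFAULT

    def __post_init__(self) -> None:
        object.__setattr__(self, "regime", Regime(self.regime))
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(self.levels))
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def resolved_levels(self) -> tuple[str, ...]:
        return self.levels if self.levels is not None else levels_for(self.regime)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regime"] = self.regime.value
        d["levels"] = list(self.resolved_levels)
        return d


@dataclass
class AggregateResult:
    """Cross-replicate aggregates of one experiment sweep.

    Trajectory arrays share a common length (the longest run across all
    levels and replicates); shorter runs are carried forward at their final
    value.  Standard errors are across replicates (landscapes).
    """

    spec: ExperimentSpec
    levels: tuple[str, ...]
    eq_scores: np.ndarray  # (n_replicates, n_levels) final mean scores
    equilibrium_rounds: np.ndarray  # (n_replicates, n_levels); -1 = not reached
    mean_score_trajectory: dict[str, np.ndarray]  # level -> (T+1,)
    mean_cumulative_unique: dict[str, np.ndarray]  # level -> (T+1,)
    n_nonequilibrium: int

    @property
    def mean_eq_score(self) -> dict[str, float]:
        return {
            lvl: float(self.eq_scores[:, j].mean()) for j, lvl in enumerate(self.levels)
        }

    @property
    def se_eq_score(self) -> dict[str, float]:
        out = {}
        for j, lvl in enumerate(self.levels):
            col = self.eq_scores[:, j]
            if col.size < 2:
                out[lvl] = float("nan")  # undefined with a single replicate
            else:
                out[lvl] = float(col.std(ddof=1) / np.sqrt(col.size))
        return out

    def gap_se(self, level_a: str, level_b: str) -> float:
        """Cross-replicate standard error of the paired eq-score gap a - b."""
        ja, jb = self.levels.index(level_a), self.levels.index(level_b)
        diff = self.eq_scores[:, ja] - self.eq_scores[:, jb]
        if diff.size < 2:
            return float("nan")
        return float(diff.std(ddof=1) / np.sqrt(diff.size))

    def marginal_unique_knowledge(self, reference_level: str) -> dict[str, np.ndarray]:
        """Per-level mean cumulative-unique curves minus the reference level's.

        The reference level's own curve is identically zero.
        """
        if reference_level not in self.levels:
            raise ValueError(
                f"unknown reference level {reference_level!r}; have {self.levels}"
            )
        ref = self.mean_cumulative_unique[reference_level]
        return {lvl: c - ref for lvl, c in self.mean_cumulative_unique.items()}

    def summary_frame(self) -> pd.DataFrame:
        se = self.se_eq_score
        mean_rounds = {
            lvl: float(
                np.where(self.equilibrium_rounds[:, j] < 0,
                         np.nan, self.equilibrium_rounds[:, j]).mean()
            )
            for j, lvl in enumerate(self.levels)
        }
        return pd.DataFrame(
            {
                "level": list(self.levels),
                "mean_eq_score": [self.mean_eq_score[l] for l in self.levels],
                "se_eq_score": [se[l] for l in self.levels],
                "mean_equilibrium_round": [mean_rounds[l] for l in self.levels],
            }
        )

    def trajectory_frame(self) -> pd.DataFrame:
        rows = []
        for lvl in self.levels:
            traj = self.mean_score_trajectory[lvl]
            uniq = self.mean_cumulative_unique[lvl]
            for t in range(len(traj)):
                rows.append(
                    {
                        "level": lvl,
                        "round": t,
                        "mean_score": traj[t],
                        "mean_cumulative_unique": uniq[t],
                    }
                )
        return pd.DataFrame(rows)


def _pad_carry_forward(arr: np.ndarray, length: int) -> np.ndarray:
    """Right-pad a trajectory with its final value ("carry forward")."""
    if len(arr) >= length:
        return np.asarray(arr[:length], dtype=np.float64)
    out = np.full(length, float(arr[-1]))
    out[: len(arr)] = arr
    return out


def run_replicate(
    spec: ExperimentSpec, replicate: int, levels: tuple[str, ...] | None = None
) -> dict[str, SimulationTrace]:
    """Run one replicate (one landscape) over the requested levels."""
    levels = levels if levels is not None else spec.resolved_levels
    canonical = levels_for(spec.regime)
    network = TorusNetwork(spec.n_agents)
    land_seed = derived_seed(spec.master_seed, replicate, 0)
    landscape = generate_landscape(
        spec.n_loci, spec.k_epistasis, land_seed, exponent=spec.exponent
    )
    heur_rng = _rng(spec.master_seed, replicate, 1)
    init_rng = _rng(spec.master_seed, replicate, 2)
    if spec.regime is Regime.ABILITY:
        h_a, h_b = sample_heuristic_pair(spec.n_loci, heur_rng)
        heuristics = {"A": h_a, "B": h_b}
    else:
        heuristics = sample_heuristic(spec.n_loci, heur_rng)
    initial = initial_states_for(spec.regime, spec.n_loci, init_rng, spec.n_agents)
    traces: dict[str, SimulationTrace] = {}
    for level in levels:
        dyn_rng = _rng(spec.master_seed, replicate, 10 + canonical.index(level))
        scheme = IntermixingScheme.for_level(spec.regime, level)
        agents = build_population(
            landscape, network, scheme, heuristics, initial, dyn_rng
        )
        traces[level] = run_simulation(
            landscape, agents, network, dyn_rng, max_rounds=spec.max_rounds
        )
    landscape.free_tables()
    return traces


def run_experiment(spec: ExperimentSpec, progress: bool = False) -> AggregateResult:
    """Run all replicates of a sweep and aggregate across landscapes."""
    levels = spec.resolved_levels
    n_reps = spec.n_replicates
    eq_scores = np.empty((n_reps, len(levels)))
    eq_rounds = np.empty((n_reps, len(levels)), dtype=np.int64)
    score_trajs: dict[str, list[np.ndarray]] = {lvl: [] for lvl in levels}
    unique_trajs: dict[str, list[np.ndarray]] = {lvl: [] for lvl in levels}
    n_noneq = 0

    rep_iter = range(n_reps)
    if progress:
        try:
            from tqdm import tqdm

            rep_iter = tqdm(rep_iter, desc=f"{spec.regime.value} sweep")
        except ImportError:  # pragma: no cover
            pass
    for r in rep_iter:
        traces = run_replicate(spec, r, levels)
        for j, lvl in enumerate(levels):
            tr = traces[lvl]
            eq_scores[r, j] = tr.mean_score_by_round[-1]
            eq_rounds[r, j] = -1 if tr.equilibrium_round is None else tr.equilibrium_round
            n_noneq += not tr.reached_equilibrium
            score_trajs[lvl].append(tr.mean_score_by_round)
            unique_trajs[lvl].append(tr.cumulative_unique_by_round.astype(np.float64))

    length = max(len(t) for trs in score_trajs.values() for t in trs)
    mean_score = {
        lvl: np.mean([_pad_carry_forward(t, length) for t in trs], axis=0)
        for lvl, trs in score_trajs.items()
    }
    mean_unique = {
        lvl: np.mean([_pad_carry_forward(t, length) for t in trs], axis=0)
        for lvl, trs in unique_trajs.items()
    }
    return AggregateResult(
        spec=spec,
        levels=levels,
        eq_scores=eq_scores,
        equilibrium_rounds=eq_rounds,
        mean_score_trajectory=mean_score,
        mean_cumulative_unique=mean_unique,
        n_nonequilibrium=n_noneq,
    )


def write_result(result: AggregateResult, out_dir: str | os.PathLike) -> None:
    """Write summary/trajectory CSVs plus a JSON sidecar with spec and flags."""
    os.makedirs(out_dir, exist_ok=True)
    result.summary_frame().to_csv(os.path.join(out_dir, "summary.csv"), index=False)
    result.trajectory_frame().to_csv(
        os.path.join(out_dir, "trajectories.csv"), index=False
    )
    pd.DataFrame(
        result.eq_scores, columns=list(result.levels)
    ).to_csv(os.path.join(out_dir, "equilibrium_scores.csv"), index=False)
    sidecar = {
        "spec": result.spec.to_dict(),
        "n_nonequilibrium": result.n_nonequilibrium,
        "mean_eq_score": result.mean_eq_score,
        "se_eq_score": result.se_eq_score,
    }
    with open(os.path.join(out_dir, "experiment.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
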