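"""Simulation engine: synchronous exploit-else-explore rounds to equilibrium.

Each round, every agent decides from the same time-``t`` snapshot:

1. *Exploit*: if any neighbor's snapshot score strictly exceeds the agent's
   own, copy the full state of the best such neighbor (ties among equally
   good neighbors break toward the lowest ring distance, then the lowest
   position index);
2. otherwise *explore* via the shifted-mask heuristic, adopting the best of
   the N candidates only if it strictly improves the agent's score;
3. otherwise keep the current state.

All updates are applied at once.  Because every state change strictly
increases that agent's score and the solution space is finite, the dynamics
must reach an equilibrium round in which no agent changes; the population
mean score is non-decreasing throughout.

States are integer-encoded solutions (bit ``i`` = locus ``i``); scoring goes
through the landscape's precomputed normalized table, so a round costs a few
vectorized array operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import Heuristic, batch_candidate_states
from .landscape import NKLandscape
from .network import (
    IntermixingScheme,
    Regime,
    TorusNetwork,
    assign_seed_states,
    assign_species,
)

N_AGENTS_DEFAULT = 100
MAX_ROUNDS_DEFAULT = 1000


@dataclass
class Agent:
    """One network position: species label, heuristic, current state + score."""

    position: int
    species_label: str
    heuristic: Heuristic
    state: int
    score: float


@dataclass
class SimulationTrace:
    """Per-round record of one simulation (round 0 = initial population)."""

    mean_score_by_round: np.ndarray  # population mean normalized score
    unique_new_by_round: np.ndarray  # solutions first seen at each round
    n_changed_by_round: np.ndarray  # agents that changed state (0 at round 0)
    equilibrium_round: int | None  # first round with no state change
    reached_equilibrium: bool
    final_states: np.ndarray  # integer-encoded states, by position
    final_scores: np.ndarray

    @property
    def n_rounds(self) -> int:
        """Number of completed update rounds (excludes round 0)."""
        return len(self.mean_score_by_round) - 1

    @property
    def cumulative_unique_by_round(self) -> np.ndarray:
        """Distinct solutions ever present in the population up to each round."""
        return np.cumsum(self.unique_new_by_round)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": np.arange(len(self.mean_score_by_round)),
                "mean_score": self.mean_score_by_round,
                "unique_new": self.unique_new_by_round,
                "cumulative_unique": self.cumulative_unique_by_round,
                "n_changed": self.n_changed_by_round,
            }
        )


# ---------------------------------------------------------------------------
# population construction


def initial_states_for(
    regime: Regime,
    n_loci: int,
    rng: np.random.Generator,
    n_agents: int = N_AGENTS_DEFAULT,
) -> np.ndarray:
    """Draw the initial solutions a regime requires (integer-encoded, distinct).

    Ability regime: ``n_agents`` pairwise-distinct uniform solutions (one per
    agent).  Knowledge regime: 5 distinct uniform seed solutions, later
    expanded over positions by the intermixing scheme.
    """
    count = n_agents if Regime(regime) is Regime.ABILITY else 5
    space = 1 << n_loci
    if count > space:
        raise ValueError(f"cannot draw {count} distinct solutions from 2^{n_loci}")
    seen: set[int] = set()
    out = []
    while len(out) < count:
        v = int(rng.integers(space))
        if v not in seen:
            seen.add(v)
            out.append(v)
    return np.asarray(out, dtype=np.int64)


def build_population(
    landscape: NKLandscape,
    network: TorusNetwork,
    scheme: IntermixingScheme,
    heuristics,
    initial_states: np.ndarray,
    rng: np.random.Generator,
) -> list[Agent]:
    """Place species/seed solutions on the ring per the intermixing scheme.

    Ability regime: ``heuristics`` is a mapping ``{"A": .., "B": ..}`` and
    ``initial_states`` has one state per position.  Knowledge regime:
    ``heuristics`` is a single :class:`Heuristic` and ``initial_states`` are
    the 5 seed solutions (``rng`` drives the random bloc assignment).
    """
    table = landscape.normalized_table()
    regime = Regime(scheme.regime)
    initial_states = np.asarray(initial_states, dtype=np.int64)
    if regime is Regime.ABILITY:
        labels = assign_species(scheme, network)
        if initial_states.size != network.n_agents:
            raise ValueError("ability regime needs one initial state per agent")
        states = initial_states
        heur_by_label = dict(heuristics)
    else:
        idx = assign_seed_states(scheme, network, rng)
        if initial_states.size != 5:
            raise ValueError("knowledge regime needs exactly 5 seed states")
        states = initial_states[idx]
        labels = np.array(["A"] * network.n_agents)
        heur_by_label = {"A": heuristics}
    for h in heur_by_label.values():
        h.validate_for(landscape.n_loci)
    return [
        Agent(
            position=p,
            species_label=str(labels[p]),
            heuristic=heur_by_label[str(labels[p])],
            state=int(states[p]),
            score=float(table[states[p]]),
        )
        for p in range(network.n_agents)
    ]


# ---------------------------------------------------------------------------
# dynamics


def _heuristic_groups(agents: list[Agent]) -> list[tuple[Heuristic, np.ndarray]]:
    groups: dict[Heuristic, list[int]] = {}
    for a in agents:
        groups.setdefault(a.heuristic, []).append(a.position)
    return [(h, np.asarray(ps, dtype=np.int64)) for h, ps in groups.items()]


def _decide_round(
    states: np.ndarray,
    scores: np.ndarray,
    prio: np.ndarray,
    groups: list[tuple[Heuristic, np.ndarray]],
    table: np.ndarray,
    n_loci: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """New states for all agents from one synchronous snapshot."""
    # exploitation: copy the best strictly-better neighbor
    nbr_scores = scores[prio]  # (n, 4), columns in tie-break priority order
    best = nbr_scores.max(axis=1)
    exploit = best > scores
    first = np.argmax(nbr_scores == best[:, None], axis=1)
    new_states = states.copy()
    rows = np.nonzero(exploit)[0]
    new_states[rows] = states[prio[rows, first[rows]]]
    # exploration, batched per heuristic (fixed group order keeps runs reproducible)
    for heuristic, members in groups:
        idx = members[~exploit[members]]
        if idx.size == 0:
            continue  # no randomness consumed for empty groups
        cands = batch_candidate_states(states[idx], heuristic, n_loci, rng)
        cand_scores = table[cands]
        j = np.argmax(cand_scores, axis=1)  # first max == lowest shift
        rows_m = np.arange(idx.size)
        best_cand = cand_scores[rows_m, j]
        adopt = best_cand > scores[idx]
        new_states[idx[adopt]] = cands[rows_m, j][adopt]
    return new_states


def step_round(
    agents: list[Agent],
    network: TorusNetwork,
    landscape: NKLandscape,
    rng: np.random.Generator,
) -> dict:
    """Advance the population one synchronous round, in place.

    Returns per-round stats: ``n_changed``, ``n_exploited`` (agents that
    copied a neighbor), ``n_explored`` (agents that adopted an explored
    candidate).
    """
    table = landscape.normalized_table()
    states = np.array([a.state for a in agents], dtype=np.int64)
    scores = np.array([a.score for a in agents], dtype=np.float64)
    prio = network.neighbor_priority()
    new_states = _decide_round(
        states, scores, prio, _heuristic_groups(agents), table, landscape.n_loci, rng
    )
    changed = new_states != states
    nbr_best = scores[prio].max(axis=1)
    exploited = nbr_best > scores
    for a, s in zip(agents, new_states):
        a.state = int(s)
        a.score = float(table[a.state])
    return {
        "n_changed": int(changed.sum()),
        "n_exploited": int((changed & exploited).sum()),
        "n_explored": int((changed & ~exploited).sum()),
    }


def run_simulation(
    landscape: NKLandscape,
    agents: list[Agent],
    network: TorusNetwork,
    rng: np.random.Generator,
    max_rounds: int = MAX_ROUNDS_DEFAULT,
) -> SimulationTrace:
    """Iterate synchronous rounds until no agent changes state (equilibrium).

    Fully deterministic given the landscape, the initial population, and the
    generator state.  If ``max_rounds`` is hit first, the trace is flagged
    ``reached_equilibrium=False`` and a warning is emitted (no exception).
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    table = landscape.normalized_table()
    prio = network.neighbor_priority()
    groups = _heuristic_groups(agents)
    states = np.array([a.state for a in agents], dtype=np.int64)
    scores = table[states]

    mean_scores = [float(scores.mean())]
    seen = set(states.tolist())
    unique_new = [len(seen)]
    n_changed_hist = [0]
    equilibrium_round: int | None = None

    for t in range(1, max_rounds + 1):
        new_states = _decide_round(
            states, scores, prio, groups, table, landscape.n_loci, rng
        )
        n_changed = int((new_states != states).sum())
        states = new_states
        scores = table[states]
        fresh = set(states.tolist()) - seen
        seen |= fresh
        mean_scores.append(float(scores.mean()))
        unique_new.append(len(fresh))
        n_changed_hist.append(n_changed)
        if n_changed == 0:
            equilibrium_round = t
            break

    reached = equilibrium_round is not None
    if not reached:
        warnings.warn(
            f"simulation hit max_rounds={max_rounds} without reaching equilibrium",
            RuntimeWarning,
            stacklevel=2,
        )
    for a, s in zip(agents, states):
        a.state = int(s)
        a.score = float(table[a.state])
    return SimulationTrace(
        mean_score_by_round=np.asarray(mean_scores),
        unique_new_by_round=np.asarray(unique_new, dtype=np.int64),
        n_changed_by_round=np.asarray(n_changed_hist, dtype=np.int64),
        equilibrium_round=equilibrium_round,
        reached_equilibrium=reached,
        final_states=states.copy(),
        final_scores=scores.copy(),
    )
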