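"""Torus communication network and spatial intermixing schemes.

The population sits on a degree-4 circulant ring ("torus"): agent ``p`` is
connected to ``p±1`` and ``p±2`` (mod ``n_agents``), i.e. the two agents to
its immediate left and right on each side.  This gives every agent a small
local neighborhood while keeping the whole group connected.

An :class:`IntermixingScheme` controls how a fixed amount of diversity is
*arranged* on the ring:

* ability regime — two species A/B (different search heuristics) placed in
  alternating contiguous blocs of size 50, 25, 10, 5 or 1 (minimal → full
  intermixing), always 50 agents of each species;
* knowledge regime — five distinct seed solutions (one shared heuristic)
  placed in contiguous blocs of size 20, 4, 5 or 2, or fully at random,
  always 20 agents per seed solution.  Bloc-to-solution assignment is a
  uniformly random *balanced* assignment so each seed covers exactly
  ``n_agents / 5`` positions.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from enum import Enum

import numpy as np


class ConfigError(ValueError):
    """Inconsistent network / intermixing configuration."""


class Regime(Enum):
    ABILITY = "ability"
    KNOWLEDGE = "knowledge"


#: level -> contiguous bloc size (None = fully random placement)
ABILITY_BLOC_SIZES: dict[str, int] = {
    "minimal": 50,
    "low": 25,
    "moderate": 10,
    "high": 5,
    "full": 1,
}
KNOWLEDGE_BLOC_SIZES: dict[str, int | None] = {
    "minimal": 20,
    "low": 4,
    "moderate": 5,
    "high": 2,
    "random": None,
}

ABILITY_LEVELS: tuple[str, ...] = tuple(ABILITY_BLOC_SIZES)
KNOWLEDGE_LEVELS: tuple[str, ...] = tuple(KNOWLEDGE_BLOC_SIZES)

N_SEED_STATES = 5


def levels_for(regime: Regime) -> tuple[str, ...]:
    return ABILITY_LEVELS if Regime(regime) is Regime.ABILITY else KNOWLEDGE_LEVELS


@dataclass(frozen=True)
class TorusNetwork:
    """Degree-4 ring lattice: neighbors are offsets {-2, -1, +1, +2} mod n."""

    n_agents: int = 100
    rewire_prob: float = 0.0  # hook for small-world variants; 0 = pure ring

    def __post_init__(self) -> None:
        if self.n_agents < 5:
            raise ConfigError("torus needs at least 5 agents for 4 distinct neighbors")
        if self.rewire_prob != 0.0:
            raise NotImplementedError("rewired (small-world) networks are not implemented")

    def neighbors(self, position: int) -> list[int]:
        """The four ring neighbors of ``position``."""
        if not 0 <= position < self.n_agents:
            raise ConfigError(f"position {position} out of range")
        n = self.n_agents
        return [(position + d) % n for d in (-2, -1, 1, 2)]

    def neighbor_priority(self) -> np.ndarray:
        """(n, 4) neighbor positions ordered by (ring distance, position index).

        Row ``p`` lists p's neighbors in tie-break priority order for
        exploitation: distance-1 neighbors before distance-2, lower position
        index first within a distance.
        """
        return _neighbor_priority(self.n_agents)


@functools.lru_cache(maxsize=64)
def _neighbor_priority(n: int) -> np.ndarray:
    rows = []
    for p in range(n):
        d1 = sorted([(p - 1) % n, (p + 1) % n])
        d2 = sorted([(p - 2) % n, (p + 2) % n])
        rows.append(d1 + d2)
    out = np.asarray(rows, dtype=np.int64)
    out.setflags(write=False)
    return out


@dataclass(frozen=True)
class IntermixingScheme:
    """How diversity is arranged on the ring: regime + level (+ bloc size)."""

    regime: Regime
    level: str
    bloc_size: int | None = None

    @classmethod
    def for_level(
        cls, regime: Regime, level: str, bloc_size: int | None = None
    ) -> "IntermixingScheme":
        """Build a scheme from a named level, with an optional bloc-size override."""
        regime = Regime(regime)
        sizes = ABILITY_BLOC_SIZES if regime is Regime.ABILITY else KNOWLEDGE_BLOC_SIZES
        if level not in sizes:
            raise ConfigError(
                f"unknown {regime.value} level {level!r}; expected one of {list(sizes)}"
            )
        return cls(regime, level, sizes[level] if bloc_size is None else bloc_size)


def assign_species(scheme: IntermixingScheme, network: TorusNetwork) -> np.ndarray:
    """Species labels ('A'/'B') by position: alternating blocs, A at position 0.

    Deterministic: bloc boundaries start at position 0 (a rotation of the
    labeling is dynamics-irrelevant by ring symmetry).
    """
    if Regime(scheme.regime) is not Regime.ABILITY:
        raise ConfigError("assign_species requires the ability regime")
    n, bs = network.n_agents, scheme.bloc_size
    if bs is None or bs < 1 or n % bs != 0 or (n // bs) % 2 != 0:
        raise ConfigError(
            f"bloc size {bs} must divide {n} into an even number of blocs"
        )
    labels = np.where((np.arange(n) // bs) % 2 == 0, "A", "B")
    return labels


def assign_seed_states(
    scheme: IntermixingScheme,
    network: TorusNetwork,
    rng: np.random.Generator,
    n_states: int = N_SEED_STATES,
) -> np.ndarray:
    """Seed-state index (0..4) by position under a knowledge-regime scheme.

    Bloc levels: the ring is partitioned into contiguous blocs of
    ``bloc_size``; a uniformly random *balanced* assignment gives each state
    the same number of blocs (hence exactly ``n/n_states`` positions).  The
    ``random`` level is a uniformly random balanced permutation over all
    positions.
    """
    if Regime(scheme.regime) is not Regime.KNOWLEDGE:
        raise ConfigError("assign_seed_states requires the knowledge regime")
    n, bs = network.n_agents, scheme.bloc_size
    if n % n_states != 0:
        raise ConfigError(f"n_agents {n} not divisible by {n_states} seed states")
    if bs is None:  # random level
        return rng.permutation(np.repeat(np.arange(n_states), n // n_states))
    if bs < 1 or n % bs != 0 or (n // bs) % n_states != 0:
        raise ConfigError(
            f"bloc size {bs} must divide {n} into a multiple of {n_states} blocs"
        )
    n_blocs = n // bs
    bloc_states = rng.permutation(np.repeat(np.arange(n_states), n_blocs // n_states))
    return np.repeat(bloc_states, bs)
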