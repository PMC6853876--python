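"""Agent species: manipulation masks, manipulation behaviors, shifted-mask search.

A species' search capability (its *heuristic*) is a manipulation mask — the
subset of loci it can alter — plus one of four manipulation behaviors:

* ``SET_ONES``  — set every masked bit to 1;
* ``SET_ZEROS`` — set every masked bit to 0;
* ``JUMBLE``    — randomly shuffle the masked bits in place (conserves the
  number of 1s inside the mask);
* ``INVERT``    — flip every masked bit.

Exploration "shifts" the mask cyclically one locus at a time: for shifts
``s = 0 .. N-1`` the behavior is applied to the agent's *current* state under
the mask ``{(b + s) mod N}``, yielding exactly N candidate solutions per
call.  The agent adopts the best candidate only if it strictly beats its
current score (ties among candidates break toward the lowest shift).

Mask positions are 0-indexed internally; text interfaces (config files, the
examples in the docs) use 1-indexed positions, converted by
:func:`mask_from_one_indexed` / :func:`mask_to_one_indexed`.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .landscape import NKLandscape, ParameterError


class Behavior(Enum):
    SET_ONES = "set_ones"
    SET_ZEROS = "set_zeros"
    JUMBLE = "jumble"
    INVERT = "invert"


BEHAVIORS: tuple[Behavior, ...] = tuple(Behavior)
DETERMINISTIC_BEHAVIORS = frozenset(
    {Behavior.SET_ONES, Behavior.SET_ZEROS, Behavior.INVERT}
)


def mask_from_one_indexed(positions) -> tuple[int, ...]:
    """Convert 1-indexed bit positions (as used in prose/configs) to 0-indexed."""
    return tuple(sorted(int(p) - 1 for p in positions))


def mask_to_one_indexed(mask) -> tuple[int, ...]:
    return tuple(sorted(int(p) + 1 for p in mask))


@dataclass(frozen=True)
class Heuristic:
    """A species' search capability: manipulation mask + manipulation behavior."""

    mask: tuple[int, ...]
    behavior: Behavior

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", tuple(sorted(int(b) for b in self.mask)))
        object.__setattr__(self, "behavior", Behavior(self.behavior))
        if len(set(self.mask)) != len(self.mask):
            raise ParameterError(f"mask has duplicate positions: {self.mask}")

    def validate_for(self, n_loci: int) -> None:
        if not 2 <= len(self.mask) <= n_loci - 2:
            raise ParameterError(
                f"mask size {len(self.mask)} outside [2, {n_loci - 2}]"
            )
        if self.mask and (self.mask[0] < 0 or self.mask[-1] >= n_loci):
            raise ParameterError(f"mask positions out of [0, {n_loci}): {self.mask}")

    def shifted_positions(self, n_loci: int) -> np.ndarray:
        """(N, |mask|) array: row ``s`` is the mask shifted by ``s`` (mod N)."""
        return _shifted_masks(self.mask, n_loci)[0]

    def shifted_mask_ints(self, n_loci: int) -> np.ndarray:
        """(N,) int64 bitmasks of the shifted masks (bit i = locus i)."""
        return _shifted_masks(self.mask, n_loci)[1]


@functools.lru_cache(maxsize=4096)
def _shifted_masks(mask: tuple[int, ...], n_loci: int) -> tuple[np.ndarray, np.ndarray]:
    base = np.asarray(mask, dtype=np.int64)
    pos = (base[None, :] + np.arange(n_loci, dtype=np.int64)[:, None]) % n_loci
    ints = (np.int64(1) << pos).sum(axis=1)
    pos.setflags(write=False)
    ints.setflags(write=False)
    return pos, ints


# ---------------------------------------------------------------------------
# sampling


def sample_heuristic_pair(
    n_loci: int, rng: np.random.Generator
) -> tuple[Heuristic, Heuristic]:
    """Draw the two species' heuristics for one problem space.

    The A mask size is uniform on {3 .. N-2}; the B mask size is uniform on
    {2 .. min(|A|-1, N-|A|)} so B is strictly smaller and fits in the
    complement: masks are fully disjoint.  Behaviors are a uniformly random
    ordered pair of *distinct* behaviors.
    """
    if n_loci < 6:
        raise ParameterError("n_loci must be >= 6 to sample a disjoint heuristic pair")
    size_a = int(rng.integers(3, n_loci - 2, endpoint=True))
    mask_a = rng.choice(n_loci, size=size_a, replace=False)
    hi_b = min(size_a - 1, n_loci - size_a)
    size_b = int(rng.integers(2, hi_b, endpoint=True))
    complement = np.setdiff1d(np.arange(n_loci), mask_a)
    mask_b = rng.choice(complement, size=size_b, replace=False)
    ia, ib = rng.permutation(len(BEHAVIORS))[:2]
    return (
        Heuristic(tuple(mask_a.tolist()), BEHAVIORS[ia]),
        Heuristic(tuple(mask_b.tolist()), BEHAVIORS[ib]),
    )


def sample_heuristic(n_loci: int, rng: np.random.Generator) -> Heuristic:
    """Draw a single-species heuristic (knowledge-diversity regime)."""
    if n_loci < 4:
        raise ParameterError("n_loci must be >= 4 to sample a heuristic")
    size = int(rng.integers(2, n_loci - 2, endpoint=True))
    mask = rng.choice(n_loci, size=size, replace=False)
    behavior = BEHAVIORS[int(rng.integers(len(BEHAVIORS)))]
    return Heuristic(tuple(mask.tolist()), behavior)


# ---------------------------------------------------------------------------
# behavior application


def apply_behavior(state, mask, behavior: Behavior, rng: np.random.Generator | None = None):
    """Apply a manipulation behavior to a bit array under ``mask`` (0-indexed).

    Returns a new array; bits outside the mask are unchanged.  ``JUMBLE``
    requires ``rng`` and shuffles the masked bits in place (a uniformly
    random permutation of the multiset of masked values).
    """
    behavior = Behavior(behavior)
    bits = np.array(state, dtype=np.uint8, copy=True)
    m = np.asarray(sorted(mask), dtype=np.int64)
    if behavior is Behavior.SET_ONES:
        bits[m] = 1
    elif behavior is Behavior.SET_ZEROS:
        bits[m] = 0
    elif behavior is Behavior.INVERT:
        bits[m] = 1 - bits[m]
    elif behavior is Behavior.JUMBLE:
        if rng is None:
            raise ParameterError("JUMBLE requires a random generator")
        bits[m] = rng.permutation(bits[m])
    else:  # pragma: no cover - exhaustive enum
        raise ParameterError(f"unknown behavior: {behavior}")
    return bits


def batch_candidate_states(
    states: np.ndarray,
    heuristic: Heuristic,
    n_loci: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """All N shifted-mask candidates for each of ``m`` integer-encoded states.

    Returns an (m, N) int64 array; column ``s`` applies the mask shifted by
    ``s``.  For ``JUMBLE``, randomness is consumed shift by shift (one
    (m, |mask|) uniform block per shift), so runs are reproducible for a
    fixed generator state.
    """
    states = np.asarray(states, dtype=np.int64)
    pos, ints = _shifted_masks(heuristic.mask, n_loci)
    b = heuristic.behavior
    if b is Behavior.SET_ONES:
        return states[:, None] | ints[None, :]
    if b is Behavior.SET_ZEROS:
        return states[:, None] & ~ints[None, :]
    if b is Behavior.INVERT:
        return states[:, None] ^ ints[None, :]
    if rng is None:
        raise ParameterError("JUMBLE requires a random generator")
    m = states.size
    out = np.empty((m, n_loci), dtype=np.int64)
    for s in range(n_loci):
        p = pos[s]
        bits = (states[:, None] >> p[None, :]) & 1
        order = np.argsort(rng.random((m, p.size)), axis=1)
        shuffled = np.take_along_axis(bits, order, axis=1)
        out[:, s] = (states & ~ints[s]) | (shuffled << p[None, :]).sum(axis=1)
    return out


def candidate_states(
    state: int,
    heuristic: Heuristic,
    n_loci: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """The N exploration candidates for one integer-encoded state."""
    return batch_candidate_states(np.array([state]), heuristic, n_loci, rng)[0]


def explore(
    state: int,
    current_score: float,
    heuristic: Heuristic,
    landscape: NKLandscape,
    rng: np.random.Generator | None = None,
) -> int:
    """Shifted-mask exploration from ``state``; returns the adopted state.

    Evaluates exactly N candidates and returns the best-scoring one if it
    *strictly* beats ``current_score``, else returns ``state`` unchanged.
    Candidate ties break toward the lowest shift index.
    """
    cands = candidate_states(state, heuristic, landscape.n_loci, rng)
    scores = landscape.normalized_from_index(cands)
    j = int(np.argmax(scores))
    if scores[j] > current_score:
        return int(cands[j])
    return state
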