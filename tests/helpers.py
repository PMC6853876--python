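"""Independent oracles used by the test suite.

Everything here recomputes model quantities by naive scalar definitions
(per-locus loops, explicit enumeration, literal tie-break scans) and stays
independent of the package's vectorized/tabled code paths.
"""

from __future__ import annotations

import numpy as np

from nkmix import Behavior, index_to_bits


def naive_component_score(land, bits, locus) -> float:
    """Table lookup by the documented convention, written as a scalar loop."""
    idx = int(bits[locus]) << land.k_epistasis
    for j, p in enumerate(land.partners[locus]):
        idx |= int(bits[p]) << (land.k_epistasis - 1 - j)
    return float(land.payoff_tables[locus][idx])


def naive_raw_score(land, bits) -> float:
    return sum(naive_component_score(land, bits, i) for i in range(land.n_loci)) / land.n_loci


def naive_global_max(land) -> tuple[int, float]:
    """Exhaustive argmax by per-solution loops; ties -> lowest integer encoding."""
    best_idx, best_val = 0, -1.0
    for s in range(1 << land.n_loci):
        v = naive_raw_score(land, index_to_bits(s, land.n_loci))
        if v > best_val:
            best_idx, best_val = s, v
    return best_idx, best_val


def naive_apply(bits, mask, behavior):
    """Deterministic behaviors only, applied position by position."""
    out = list(int(b) for b in bits)
    for p in mask:
        if behavior is Behavior.SET_ONES:
            out[p] = 1
        elif behavior is Behavior.SET_ZEROS:
            out[p] = 0
        elif behavior is Behavior.INVERT:
            out[p] = 1 - out[p]
        else:
            raise ValueError("stochastic behavior has no naive oracle")
    return np.array(out, dtype=np.uint8)


def naive_explore_candidates(bits, heuristic, n_loci):
    """The N shifted-mask candidates, masks built by literal arithmetic."""
    cands = []
    for s in range(n_loci):
        mask = [(b + s) % n_loci for b in heuristic.mask]
        cands.append(naive_apply(bits, mask, heuristic.behavior))
    return cands


def ring_distance(p, q, n):
    d = abs(p - q)
    return min(d, n - d)


def brute_force_round(land, states, network, heuristic_by_pos):
    """Re-derive every agent's post-round state from the time-t snapshot.

    Deterministic behaviors only.  Exploit: best strictly-better neighbor,
    ties by (ring distance, position index); else explore: best of the N
    candidates if strictly better.
    """
    n_agents = network.n_agents
    n = land.n_loci
    scores = [land.normalized_score(index_to_bits(s, n)) for s in states]
    new_states = []
    for p in range(n_agents):
        nbrs = network.neighbors(p)
        better = [q for q in nbrs if scores[q] > scores[p]]
        if better:
            best_score = max(scores[q] for q in better)
            best = sorted(
                (q for q in better if scores[q] == best_score),
                key=lambda q: (ring_distance(p, q, n_agents), q),
            )[0]
            new_states.append(states[best])
            continue
        bits = index_to_bits(states[p], n)
        cands = naive_explore_candidates(bits, heuristic_by_pos[p], n)
        cand_scores = [land.normalized_score(c) for c in cands]
        j = int(np.argmax(cand_scores))
        if cand_scores[j] > scores[p]:
            new_states.append(int((cands[j].astype(np.int64) << np.arange(n)).sum()))
        else:
            new_states.append(states[p])
    return new_states
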