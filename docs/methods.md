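# Methods

## Model

A population of `n_agents` (default 100) agents searches a shared NK
landscape. Agent state is a single solution (bit string) plus its score;
there is no memory. Time advances in synchronous rounds. Every agent decides
from the same time-*t* snapshot and all updates apply at once:

1. **Exploit.** If any neighbor's snapshot score strictly exceeds the
   agent's own, copy the full state of the best such neighbor. Ties among
   equally good neighbors break toward the lower ring distance, then the
   lower position index.
2. **Explore.** Otherwise, evaluate exactly *N* candidates: for shifts
   `s = 0 .. N-1`, apply the agent's manipulation behavior under the mask
   `{(b + s) mod N : b in mask}` to the agent's *current* state (the
   unshifted mask is the first candidate). Adopt the best candidate only if
   it strictly beats the current score; candidate ties break toward the
   lowest shift.
3. Otherwise keep the current state.

Because every state change strictly increases that agent's score and the
solution space is finite, every run terminates: the **equilibrium round** is
the first round in which no agent changes state. The population mean score
is non-decreasing. A consequence worth keeping in mind when interpreting
results: any equilibrium consensus state must resist every shifted-mask move
of every heuristic present in the population, i.e. it is a *mutual local
optimum* of the combined repertoire, and that condition does not depend on
how species are arranged on the ring. Arrangement therefore acts on the
*path* (which absorbing state is reached, and how much unique knowledge is
generated along the way), not on the set of possible endpoints.

## Landscape

`generate_landscape(n_loci, k_epistasis, seed)` draws, for each locus,
`k_epistasis` partner loci uniformly without replacement among the other
`N-1` loci (no adjacency structure) and a payoff table of `2^(K+1)` values
uniform on `[0, 1)`. Table indexing is fixed and test-pinned: the focal
locus contributes the most significant index bit, followed by the partners
in stored order. Raw score = mean payoff over loci; reported score =
`(raw / raw_global_max) ** exponent` with exponent 10, so the enumerated
global optimum scores exactly 1 and a random solution scores near 0. The
worst solution maps to a small positive value rather than exactly 0; with
the 10th power the distinction is numerically negligible.

The global maximum is found by exhaustive enumeration of all `2^N`
solutions (vectorized / numba-jitted; ~0.15 s at N=20, capped at N=24 by
default, `CapacityError` beyond). The full normalized score table is cached
per landscape, making per-round scoring a table lookup; ties at the maximum
(probability zero under continuous payoffs) break toward the lowest integer
encoding. Landscapes serialize to a single text file with full decimal
precision (`repr` round-trip); an optional exhaustive dump writes one
`bitstring score` line per solution for small N.

## Heuristics

A heuristic is a manipulation mask (2 to N−2 locus indices) plus one of four
behaviors: SET_ONES, SET_ZEROS, INVERT (deterministic) and JUMBLE, which
applies a uniformly random in-place permutation to the masked bits
(conserving their 1-count; fresh randomness per candidate per call). The
ability-regime pair is drawn per landscape: |mask A| uniform on {3..N−2},
|mask B| uniform on {2..min(|A|−1, N−|A|)}, masks fully disjoint, behaviors
a uniformly random ordered pair of distinct behaviors. The knowledge-regime
single heuristic has mask size uniform on {2..N−2} and a uniform behavior.
Masks are 0-indexed internally; text interfaces use 1-indexed positions.

Design choices where the design was genuinely open: masks are fully
disjoint (the weaker alternative — merely never identical — changes results
imperceptibly); JUMBLE shuffles rather than re-randomizes (re-randomization
is a strictly stronger operator; it raises absolute scores slightly but not
the arrangement contrasts); the shift set includes s = 0.

## Network and intermixing

The "torus" is the degree-4 circulant ring (offsets ±1, ±2); no 2-D grid is
built. A rewire-probability hook exists for small-world variants but is not
implemented. Ability levels use alternating contiguous species blocs of
50 / 25 / 10 / 5 / 1 starting with A at position 0 (a rotation of the
labeling is dynamics-irrelevant). Knowledge levels use contiguous blocs of
20 / 4 / 5 / 2 agents or fully random placement; bloc-to-seed assignment is
a uniformly random *balanced* assignment, so each of the 5 seed solutions
always covers exactly `n_agents/5` positions. The bloc sizes labelled "low"
(4) and "moderate" (5) are kept as configured even though the labels order
a smaller bloc as less intermixed; an explicit `bloc_size` override exists.

## Experiments and aggregation

One replicate = one landscape plus the heuristics and initial solutions
drawn for it; all intermixing levels of a replicate share that material and
differ only in arrangement. The seed hierarchy derives the landscape,
heuristic, initial-state and per-level dynamics streams from
`(master_seed, replicate, stream-key)`, with per-level streams keyed by the
level's canonical index so running a subset of levels reproduces the full
sweep's per-level results exactly.

Initial solutions: ability — `n_agents` pairwise-distinct uniform bit
strings (one per position, identical across levels); knowledge — 5 distinct
uniform strings expanded by the scheme. Fresh strings are drawn per
replicate; since landscapes are independent, nothing is intrinsically good
or bad about any start.

Aggregates are computed across replicates (landscapes): mean equilibrium
score with its cross-replicate standard error; mean per-round score
trajectories, right-padded with each run's final value before averaging
("carry forward" — a run at equilibrium by round 10 contributes its round-10
mean to all later rounds); and unique-knowledge curves, defined as the
cumulative count of distinct solutions ever present in the population,
reported as the marginal against a reference level (minimal for the ability
regime, random for the knowledge regime), whose own curve is identically
zero. Per-round first-appearance counts are also recorded.

Defaults: `n_replicates=200` (a desk-scale replicate count chosen so a full
two-regime sweep runs in about a minute on one CPU), `max_rounds=1000` with
explicit non-equilibrium flagging (runs typically equilibrate in 20–60
rounds; no run in the shipped test suite hits the cap). The acceptance
script runs the ability regime's minimal and full levels at 200 replicates.
In statistical tests, "early rounds" means the mean over rounds 1–10,
roughly the first half of the mean time to equilibrium.

## What the generator emulates — and what passing tests do not show

All inputs are synthetic by design: the study object is the model itself.
The generator reproduces the study conditions (uniform random NK payoff
structure, random heuristic assignment, uniform random starts); it does not
model real problem structure, heterogeneous agent ability within a species,
noisy evaluation, or communication failure, so conclusions transfer to real
collectives only insofar as the NK abstraction does. Statistical
arrangement contrasts are Monte-Carlo estimates at 200 replicates
(cross-landscape SEs of equilibrium means ≈ 0.015); single runs vary
widely.

## Known limitations

* Equilibrium detection ("no agent changed this round") is a one-round
  criterion; with JUMBLE heuristics a later shuffle could in principle still
  improve, though in practice extending patience after a zero-change round
  changes nothing measurably.
* The arrangement of species measurably changes how much unique knowledge
  the system generates (more intermixing → more distinct solutions; minimal
  knowledge-intermixing out-generates random placement), and the
  knowledge-regime long-run ranking (minimal best, random worst) is robust.
  Arrangement effects on the *final mean score* in the ability regime are
  small relative to cross-landscape noise in this implementation — see the
  mutual-local-optimum observation above for why the endpoint set itself is
  arrangement-independent.
* Supplementary-style robustness variants (alternative problem spaces,
  contagion thresholds, rewired networks, five-species setups) are exposed
  as extension points but intentionally not implemented.
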