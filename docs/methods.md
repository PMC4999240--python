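# Methods

## The two models

Both models are finite discrete dynamical systems driven by a shared
alphabet of regulator actions — activators `K_i` and deactivators `P_j` —
applied one at a time, left to right.  A *configuration* assigns a state
to every target; a *word* is a finite action sequence.  Because actions
are not commutative, the temporal order of a word, not just its content,
determines the outcome.  The scientific question both models answer is
how many distinct configurations a small set of promiscuous regulators
can specifically prepare when it is allowed to act sequentially.

**Ratchet network** (`RatchetSpec(n, m, l_n, l_m, T)`).  Each of the
`N = C(n, l_n) · C(m, l_m)` targets is wired to exactly `l_n` of the `n`
K's and `l_m` of the `m` P's and carries an integer state in `{0..T}`.
`K_i` increments (saturating at `T`) every target wired to it; `P_j`
decrements (floored at 0).  This is a one-pot abstraction of multisite
phosphorylation (kinases/phosphatases) or summating neural inputs.
All-K words commute, all-P words commute; mixed words are noncommutative
exactly because of the saturation edges.  At `l_n = l_m = 1` a
configuration is an `n × m` matrix; the package keeps per-target integer
states as the primary representation and derives the matrix (or, for
`l > 1`, the ON-indicator per regulator pair) as a summary, because the
indicator loses information the deletion experiment needs.

**Sequestration network** (`SeqSpec(n, reduced)`).  A target is a set of
*arms* `g ⊆ {1..n}`; its states are `{0} ∪ g`.  `K_i` captures every
free (state-0) target with arm `i` into the protected state `i`; `P_i`
releases state-`i` targets back to 0; a target in state `j` ignores all
other regulators.  This abstracts silencing by recruitment to nuclear
compartments: a captured locus is shielded from further modification.
The *full* network has all `2^n − 1` nonempty arm sets as targets; the
*reduced* network keeps the `2^(n−1) − 1` targets that contain arm 1
(RNA polymerase) plus at least one other arm.  Canonical target order is
(arm count, lexicographic arms), which fixes the printed form of
configuration vectors.

## Counting laws

All counting uses exact Python integers; the sequences grow
super-exponentially (the `n = 6` one-coloring count is 780 304 385) and
would overflow fixed-width arithmetic.

* **Poly-Bernoulli numbers.**  The threshold-1, connectivity-1 ratchet
  reaches exactly the *lonesum* matrices — binary matrices avoiding the
  2×2 patterns `10/01` and `01/10`, equivalently those permutable to a
  descending staircase.  Their count is the poly-Bernoulli number
  `B(n, m) = Σ_j (j!)² S(n+1, j+1) S(m+1, j+1)` (Stirling numbers of the
  second kind).  `is_lonesum` tests the staircase property by nested row
  supports; `staircase_word` constructively replays any lonesum matrix
  from zero (rows in ascending row-sum order, ties by ascending index —
  any valid order works; replay is the contract).
* **Threshold 2.**  With two rungs per target every binary ON/OFF
  pattern becomes reachable; `t2_constructive_word` builds the witness
  row by row (stage each row in a 1–2 configuration, cycle earlier rows
  down and back up, then normalize with a P-sweep and a K-sweep so the
  ON set is the state-2 set).
* **Minimal-sequence recursion.**  At connectivity `l > 1` many words
  become redundant: no non-redundant word uses more than `n − l_n + 1`
  K's or `m − l_m` P's.  The recursion (tables `a_n^m`, `b_m^n(l_m)`,
  `c_n^m(l_n, l_m)`) eliminates them level by level.  The printed form
  of the defining recurrences is ambiguous about which pool size anchors
  `a_n^m`; this implementation anchors `a_n^m` at pool size `m + 1`
  (the smallest pool in which a non-redundant word can use `m` P's),
  which makes `c_n^m(1,1) = B(n, m)` an identity.  Its validity is
  certified *only* through exact agreement with the brute-force word
  oracle on every `(n, m, l_n, l_m)` with `n, m ≤ 4` — the quantity that
  agrees is the number of surviving minimal words counted up to
  reordering inside maximal same-kind runs (all-K and all-P runs are
  internally commutative).
* **Connected one-colorings.**  A one-coloring (states in `{0, 1}`) of
  the reduced network is reachable iff it is *connected*: every ON
  target with ≥ 3 arms has an ON 2-arm supporter among its arm pairs.
  The closed form is `f(n) = 2^(2^(n−1)−1) − (violation count)`.  The
  violation sum as printed runs its inner indices only to the number of
  OFF pairs, which contradicts the printed sequence itself (it would
  give 0 violations at `n = 3` instead of 1); the implementation lets
  the inner sums run over all arm counts `3 ≤ k ≤ n` with `C(m, k−1)`
  vanishing naturally for `k−1 > m`.  This reading reproduces
  1, 2, 7, 89, 16897, 780304385 exactly and is verified against
  exhaustive enumeration of all `2^(2^(n−1)−1)` colorings for `n ≤ 5`.
  We treat the printed limits as an erratum hypothesis validated by the
  enumeration oracle, not as authorial intent.  (A related prose count
  of "90 out of 128" configurations at `n = 4` disagrees with the
  formula's 89; enumeration — which includes the all-zero origin —
  gives 89, and the package reports what it enumerates.)
* **Full-network bounds.**  The full `n`-network count `c_n` (2, 7, 94,
  37701 for `n = 1..4` by BFS) has no closed form; `f(n+1)` is a lower
  bound (the reduced `(n+1)`-network embeds a full `n`-network) and a
  falling-factorial sum over nested k-colorings,
  `1 + Σ_k (n)_k f(n−k+1) Π_{j>n−k+1} (f(j) − 1)`, an upper bound.

## Enumeration

Reachability is plain breadth-first search over action alphabets;
configurations are state tuples in canonical target order, so the BFS is
deterministic and its witness words are the lexicographically first
shortest words.  Explicit enumeration is capped at 10^7 states by
default (`cap=` arguments override).  Problem sizes used throughout the
tests and the acceptance script — ratchet up to 4×4, sequestration up to
`n = 4` full (37 701 reachable states) and `n = 5` reduced colorings
(32 768 candidates) — were chosen as the largest instances the printed
reference values cover; all run in seconds.

The brute-force minimal-sequence oracle follows a three-step procedure:
enumerate all shortest words of the connectivity-1 network level by
level (prefixes of shortest words are shortest, so the list is closed
under truncation), replay those words in the higher-connectivity
network, group by generated configuration, and keep the minimal length
per group.

## Constructive words for one-colorings

`opposite_word` returns a word replaying any connected one-coloring of
the reduced network from zero.  Three constructions are tried in order:

1. a *round scheduler* — per round, temporary "dodge" colors are raised,
   shield colors park every OFF target in a protected state, the temps
   are released, `K_1` paints what is free, the shields come down;
2. a rule engine that additionally parks unshieldable OFF targets in
   state 1 (releasing them later with `P_1`, sacrificing and repainting
   ON targets) and lets contested ON targets sit out a `P_1` release in
   a reserved dodge color;
3. a policy-guided depth-first search over the raw action alphabet with
   depth-aware memoization.

Every produced word is verified by replay in the tests, exhaustively
over all connected one-colorings for `n ≤ 4`.  Words are valid but not
minimal.  Beyond `n = 4` the constructions cover typical colorings;
deeply nested shield dependencies (an OFF target whose arms nest inside
an ON target's arms, several levels deep) can exhaust the search budget,
which raises a capacity error rather than returning a wrong word.

## Orbits

An orbit is a maximal set of configurations mutually accessible under a
restricted alphabet.  Sequestration orbits are found globally: an
undirected edge joins two configurations when single actions map each to
the other, and orbits are the connected components — well defined
because every intra-orbit path in this model is reversible.  Ratchet
orbits are seeded by forbidden (non-lonesum) `i × j` blocks on restricted
rows/columns; each surviving block is an origin explored by BFS with the
unrestricted regulators, with two origin representatives (remaining
entries all 0, or all 1 so that pure-P orbits mirror pure-K ones).  A
block is discarded when either representative is reachable from a
smaller family's origin *without the currently restricted regulators*.
With this reading the orbit-count recursion and brute-force discovery
agree at every block shape for `n, m ≤ 3`.  At larger grids the
recursion's bookkeeping for fully-restricted shapes (e.g. the 4×2 block
of the 4×2 network) does not correspond to any single reachability
semantics we could identify; `orbit_count_check` reports per-shape
equality so the divergence is visible rather than silently absorbed.

## Operators

The matrix formulation assigns each target a block of `D·T + 1`
population states (shared 0, then `T` rungs along each of `D`
dimensions; ratchet: `D = 1`, variable `T`; sequestration: `D = n`,
`T = 1`).  Rate generators have `±g` entries and zero column sums;
their `t → ∞` exponentials are exact 0/1 idempotent limit operators
(sub-diagonal raise for K with absorbing top, super-diagonal lower for P
with absorbing 0), constructed symbolically and checked numerically
against `expm(G t)` at `g·t = 50` to 1e−10.  Because ratchet activators
share a dimension but differ in which targets respond, responsiveness is
stored per action rather than per (target, dimension).  Ratchet networks
with `l > 1` are rejected: shared targets break the independent-block
assumption, and approximating them would betray the exactness contract.
Equivalence with the rule-based dynamics is verified on 100 seeded
random words per model instance.

## Robustness experiment

`recovery_analysis` deletes one activator, BFS-enumerates full and
impaired reachable sets, drops full-network configurations with exact
impaired matches, and correlates the lost ON/OFF vectors against every
impaired one.  The similarity measure is Pearson correlation with a
degenerate-case convention (zero-variance vectors: 1 for identity, 0
otherwise); cosine similarity is available because no formula is
canonical for this statistic.  By default the impaired set is
length-agnostic; an optional minimum-witness-length filter restricts it
to configurations needing longer words.  The published versions of these
results are figure-only, so the package asserts structure — impaired ⊆
full, reach counts non-increasing in connectivity, bit-for-bit
reproducible CDFs — rather than pixel values.

## Synthetic fixtures

`fixture_generator(family, seed=...)` draws random small specs (ratchet
`n, m ≤ 4`, thresholds 1–3; sequestration `n ≤ 4`, both variants) and
uniform random words of length 0–12 over each spec's alphabet.  These
emulate arbitrary regulation schedules on desk-scale networks — the
regime where every claim can be checked exhaustively — and deliberately
not any empirical network topology, expression noise, or kinetic rates;
passing tests certify the combinatorial laws, not fit to data.  A fixed
seed fully determines a suite.

## Known limitations

* Explicit enumeration only; no symbolic/BDD reachability, so state
  spaces beyond ~10^7 are out of reach by design.
* `opposite_word` beyond `n = 4` is best-effort (see above).
* The orbit recursion/brute-force correspondence is established for
  `n, m ≤ 3`; larger fully-restricted shapes are reported, not asserted.
* Continuous-time kinetics, stochasticity and graded expression levels
  are out of scope; the models are exactly the two discrete semantics
  above.
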