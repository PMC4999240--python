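"""Exhaustive reachability and pattern characterizations.

The configuration spaces of both models are finite, so reachability from a
start configuration is plain breadth-first search over the action alphabet.
On top of BFS this module provides the combinatorial characterizations that
make enumeration unnecessary for counting:

* threshold-1 ratchet configurations are exactly the binary *lonesum*
  matrices (no 2x2 sub-block equal to ``10/01`` or ``01/10``), equivalently
  the matrices row/column-permutable to a descending staircase of ones;
* threshold-2 ratchet networks reach every binary ON/OFF pattern;
* reduced sequestration networks reach exactly the *connected*
  one-colorings (every ON multi-arm target is supported by an ON 2-arm
  target sharing an arm).

Each characterization comes with a constructive word builder whose output
is verified by replay, plus the brute-force minimal-sequence oracle used to
cross-check the counting recursion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np

from .models import (
    Action,
    Config,
    K,
    P,
    RatchetSpec,
    SeqSpec,
    SeqTarget,
    Spec,
    Word,
    apply_action,
    apply_word,
    build_seq_targets,
    full_alphabet,
    zero_config,
)

__all__ = [
    "ReachableSet",
    "bfs_reachable",
    "is_lonesum",
    "staircase_word",
    "t2_constructive_word",
    "is_connected",
    "enumerate_connected_one_colorings",
    "one_coloring_to_config",
    "config_to_one_coloring",
    "opposite_word",
    "minimal_sequences_bruteforce",
    "commuting_run_sort",
    "minimal_word_class_count",
]

#: hard cap on explicitly enumerated state spaces
DEFAULT_CAP = 10**7


@dataclass(frozen=True)
class ReachableSet:
    """Result of a BFS closure: the set of reachable configurations and one
    shortest witness word per configuration."""

    start: Config
    configs: frozenset[Config]
    word_index: Mapping[Config, Word]

    def __len__(self) -> int:
        return len(self.configs)

    def __contains__(self, config: Config) -> bool:
        return config in self.configs

    def __iter__(self):
        return iter(sorted(self.configs))


def bfs_reachable(
    spec: Spec,
    start: Config | None = None,
    alphabet: Sequence[Action] | None = None,
    *,
    cap: int = DEFAULT_CAP,
) -> ReachableSet:
    """Breadth-first closure of ``start`` under the given action alphabet.

    Deterministic: actions are tried in alphabet order, the frontier is
    processed FIFO, so the recorded witness words are the lexicographically
    first shortest words.
    """
    if start is None:
        start = zero_config(spec)
    if alphabet is None:
        alphabet = full_alphabet(spec)
    word_index: dict[Config, Word] = {start: ()}
    frontier = [start]
    while frontier:
        nxt: list[Config] = []
        for config in frontier:
            w = word_index[config]
            for a in alphabet:
                child = apply_action(config, a, spec)
                if child not in word_index:
                    if len(word_index) >= cap:
                        raise RuntimeError(
                            f"reachable set exceeded capacity cap {cap}"
                        )
                    word_index[child] = w + (a,)
                    nxt.append(child)
        frontier = nxt
    return ReachableSet(start, frozenset(word_index), word_index)


# ---------------------------------------------------------------------------
# Lonesum / staircase characterization (ratchet, T = 1)
# ---------------------------------------------------------------------------


def is_lonesum(A: np.ndarray | Sequence[Sequence[int]]) -> bool:
    """True iff the binary matrix avoids the 2x2 patterns 10/01 and 01/10.

    Equivalent to being row/column-permutable to a descending staircase of
    ones, which is the condition for a threshold-1 ratchet configuration to
    be reachable.
    """
    A = np.asarray(A, dtype=int)
    if A.ndim != 2:
        raise ValueError("need a 2-D matrix")
    if not np.isin(A, (0, 1)).all():
        raise ValueError("lonesum test requires a binary matrix")
    # rows must be nested as sets once sorted by row sum: two rows with
    # incomparable supports contain a forbidden block.
    order = np.argsort(-A.sum(axis=1), kind="stable")
    rows = A[order]
    for r1, r2 in zip(rows, rows[1:]):
        if np.any(r2 & ~r1):
            return False
    return True


def staircase_word(A: np.ndarray | Sequence[Sequence[int]]) -> Word:
    """A word driving the all-zero threshold-1 ratchet to the lonesum matrix
    ``A`` (l = 1 wiring, target order row-major).

    Rows are emitted in ascending row-sum order (ties by descending row
    index): activate the row, then knock its zero columns back down.  Later
    rows have nested-superset supports, so their P's never touch an earlier
    row's ones.
    """
    A = np.asarray(A, dtype=int)
    if not is_lonesum(A):
        raise ValueError("matrix is not lonesum; unreachable at threshold 1")
    n, m = A.shape
    word: list[Action] = []
    rows = sorted(range(n), key=lambda i: (A[i].sum(), -i))
    for i in rows:
        if A[i].sum() == 0:
            continue
        word.append(K(i + 1))
        word.extend(P(j + 1) for j in range(m) if A[i, j] == 0)
    return tuple(word)


def t2_constructive_word(pattern: np.ndarray | Sequence[Sequence[int]]) -> Word:
    """A word reaching an arbitrary binary ON/OFF pattern in the threshold-2
    ratchet network (l = 1).

    Builds each row k = n..1 into a 1-2 configuration (2 on the ON set,
    1 elsewhere) while cycling the previously built rows down and back up,
    then normalizes: a final P-sweep takes every row to 0-1 form and a final
    K-sweep lifts it to 1-2 form, so the ON set is exactly the state-2 set.
    """
    B = np.asarray(pattern, dtype=int)
    if B.ndim != 2 or not np.isin(B, (0, 1)).all():
        raise ValueError("need a binary 2-D pattern")
    n, m = B.shape
    word: list[Action] = []
    for depth, k in enumerate(range(n, 0, -1)):
        on = [j + 1 for j in range(m) if B[k - 1, j]]
        off = [j + 1 for j in range(m) if not B[k - 1, j]]
        # lower the already-built rows on the ON columns first, so every
        # column is lowered exactly once by the time this row is staged
        word.extend(P(j) for j in on)
        word.extend([K(k), K(k)])
        word.extend(P(j) for j in off)
        # restore rows n .. k+1 to their 1-2 staging
        word.extend(K(i) for i in range(n, k, -1))
    word.extend(P(j) for j in range(1, m + 1))
    word.extend(K(i) for i in range(1, n + 1))
    return tuple(word)


# ---------------------------------------------------------------------------
# Connected colorings (sequestration)
# ---------------------------------------------------------------------------

#: binary vector over the targets of a SeqSpec, 1 = state 1, 0 = state 0
OneColoring = tuple[int, ...]


def one_coloring_to_config(bits: Sequence[int], spec: SeqSpec) -> Config:
    if len(bits) != spec.n_targets:
        raise ValueError("coloring length does not match target count")
    return tuple(int(b) for b in bits)


def config_to_one_coloring(config: Config, spec: SeqSpec) -> OneColoring:
    if any(s not in (0, 1) for s in config):
        raise ValueError("configuration is not a one-coloring")
    return tuple(config)


def is_connected(config: Sequence[int], spec: SeqSpec) -> bool:
    """Connectivity rule: every target with >= 3 arms in a nonzero state must
    share that state with a 2-arm target whose arms are among its own.

    For the reduced network the 2-arm targets are the pairs {1, j}; for the
    full network they are all pairs.  A nonzero state s of target g is only
    ever s in g, so a supporting pair must itself contain s.
    """
    targets = build_seq_targets(spec)
    pair_state: dict[SeqTarget, int] = {
        g: config[t] for t, g in enumerate(targets) if len(g) == 2
    }
    for t, g in enumerate(targets):
        if len(g) < 3 or config[t] == 0:
            continue
        s = config[t]
        supported = any(
            pair_state.get(pair) == s
            for pair in combinations(g, 2)
            if pair in pair_state
        )
        if not supported:
            return False
    return True


def enumerate_connected_one_colorings(
    spec: SeqSpec, *, cap: int = DEFAULT_CAP
) -> set[OneColoring]:
    """All binary colorings of the network passing the connectivity rule,
    by exhaustive filtering of the 2**n_targets candidates."""
    if 2**spec.n_targets > cap:
        raise RuntimeError(
            f"2**{spec.n_targets} colorings exceed capacity cap {cap}"
        )
    return {
        bits
        for bits in product((0, 1), repeat=spec.n_targets)
        if is_connected(bits, spec)
    }


# ---------------------------------------------------------------------------
# Constructive word for a connected one-coloring
# ---------------------------------------------------------------------------


def opposite_coloring(bits: Sequence[int], spec: SeqSpec) -> Config:
    """The opposite of a one-coloring: ON targets drop to 0 and OFF targets
    are parked in the protected state of their smallest available arm
    (preferring an arm whose 2-arm anchor is OFF)."""
    targets = build_seq_targets(spec)
    pair_of = {g: t for t, g in enumerate(targets) if len(g) == 2}
    out = []
    for t, g in enumerate(targets):
        if bits[t]:
            out.append(0)
            continue
        arms = [k for k in g if k != 1]
        anchored = [
            k
            for k in arms
            if (pair := tuple(sorted((1, k)))) in pair_of and not bits[pair_of[pair]]
        ]
        out.append(min(anchored) if anchored else min(arms))
    return tuple(out)


def opposite_word(bits: Sequence[int], spec: SeqSpec, *, max_nodes: int = 200_000) -> Word:
    """A word replaying from the all-zero configuration to the connected
    one-coloring ``bits``.

    Tries three constructions in order: a one-round-per-target shield
    scheduler, a rule engine with state-1 parking and dodge colors, and a
    policy-guided depth-first search.  The result is always verified by
    replay in the caller's tests; raises ``ValueError`` for disconnected
    (unreachable) colorings.  Practical envelope: exhaustive for n <= 4,
    best effort beyond.
    """
    if not is_connected(bits, spec):
        raise ValueError("coloring is disconnected, hence unreachable")
    target = one_coloring_to_config(bits, spec)
    word = _round_schedule_word(target, spec)
    if word is None:
        word = _parking_word(target, spec)
    if word is None:
        # last resort: policy-guided depth-first search
        word = _guided_forward_word(target, spec, max_nodes=max_nodes)
    if word is None:  # pragma: no cover - connectivity guarantees a word
        raise RuntimeError("constructive search exhausted; increase max_nodes")
    return word


def _parking_word(goal: Config, spec: SeqSpec, max_iters: int = 4000) -> Word | None:
    """Rule-driven construction with state-1 parking and dodge colors.

    The word is grown by a fixed rule order, simulating as it goes:

    1. *Pure shields*: a color whose capture set contains OFF targets and
       no free ON target parks those OFF targets in a protected state.
    2. *Dodge parking*: a free ON target that is contested (an OFF target's
       arms nest inside its own, so every shield wave would catch it) is
       parked in a protected color whose anchor pair is ON, where it sits
       out the next release of state 1.
    3. ``K_1`` paints every remaining free target: ON targets get their
       final state, unshieldable OFF targets are parked *in state 1*.
    4. When nothing is free, a dodge color whose class holds only its ON
       target is released, or ``P_1`` frees the 1-parked OFF targets --
       sacrificing painted ON targets, which a later ``K_1`` repaints.

    A final P-sweep releases the shields.  Every step is simulated, and the
    result is verified by replay; cycles or rule deadlock return None.
    """
    targets = build_seq_targets(spec)
    arms = [frozenset(g) - {1} for g in targets]
    n_t = len(targets)
    on_set = frozenset(t for t in range(n_t) if goal[t] == 1)
    off_set = frozenset(range(n_t)) - on_set
    pair_of = {g: t for t, g in enumerate(targets) if len(g) == 2}

    cfg = zero_config(spec)
    word: list[Action] = []
    reserved: dict[int, int] = {}  # dodge color -> parked ON target
    seen: set[tuple] = set()

    def emit(a: Action) -> None:
        nonlocal cfg
        word.append(a)
        cfg = apply_action(cfg, a, spec)

    for _ in range(max_iters):
        key = (cfg, tuple(sorted(reserved)))
        if key in seen:
            return None
        seen.add(key)

        z = [t for t in range(n_t) if cfg[t] == 0]
        z_on = [t for t in z if t in on_set]
        z_off = [t for t in z if t in off_set]
        park1 = [t for t in off_set if cfg[t] == 1]

        if not z_on and not z_off and not park1 and not any(
            cfg[t] != 1 for t in on_set
        ):
            # all ON painted, every OFF parked in colors: closing sweep
            for c in sorted({cfg[t] for t in off_set if cfg[t] > 1}):
                emit(P(c))
            return tuple(word) if cfg == goal else None

        # rule 1: pure shields
        best = None
        for c in range(2, spec.n + 1):
            if c in reserved:
                continue
            catch = [t for t in z if c in arms[t]]
            if not catch or any(t in on_set for t in catch):
                continue
            if best is None or len(catch) > best[0]:
                best = (len(catch), c)
        if best is not None:
            emit(K(best[1]))
            continue

        if z:
            # rule 2: dodge-park contested free ON targets
            parked = False
            for u in z_on:
                if len(arms[u]) < 2:
                    continue
                contested = any(
                    arms[h] <= arms[u] and cfg[h] in (0, 1)
                    for h in off_set
                )
                if not contested:
                    continue
                for d in sorted(arms[u]):
                    anchor = pair_of.get(tuple(sorted((1, d))))
                    if d in reserved or (anchor is not None and anchor not in on_set):
                        continue
                    if any(d in arms[h] for h in z_off):
                        continue  # the dodge would drag OFF targets along
                    emit(K(d))
                    reserved[d] = u
                    parked = True
                    break
                if parked:
                    break
            if parked:
                continue
            # rule 3: paint free ON targets, park unshieldable OFF in 1
            emit(K(1))
            continue

        # nothing free: release a safe dodge class, else release state 1
        released = False
        for d in sorted(reserved):
            members = [t for t in range(n_t) if cfg[t] == d]
            if all(t in on_set or t == reserved[d] for t in members):
                emit(P(d))
                del reserved[d]
                released = True
                break
        if released:
            continue
        if park1:
            emit(P(1))
            continue
        return None
    return None


def _guided_forward_word(
    goal: Config, spec: SeqSpec, *, max_nodes: int = 200_000
) -> Word | None:
    """Depth-first construction of a word for colorings the one-round-per-
    target scheduler cannot handle (an OFF target nested inside an ON
    target with no free dodge color).

    Moves are ranked by a shield policy: ``K_1`` fires only when every free
    target is meant to be ON; ``K_c`` moves are ranked by how few ON
    targets they capture (captured ON targets become temporary dodges) and
    how many OFF targets they shield; releases ``P_c`` come last, freeing
    temporarily parked ON targets so that their conflict classes shrink.
    """
    targets = build_seq_targets(spec)
    arms = [frozenset(g) - {1} for g in targets]
    on_label = [s == 1 for s in goal]
    zero = zero_config(spec)

    # memo: configuration -> largest remaining depth at which it failed;
    # a configuration is re-expanded only with a larger depth budget
    seen: dict[Config, int] = {}
    nodes = 0

    def moves(cfg: Config) -> list[Action]:
        z = [t for t, s in enumerate(cfg) if s == 0]
        z_on = [t for t in z if on_label[t]]
        z_off = [t for t in z if not on_label[t]]
        out: list[tuple[tuple, Action]] = []
        if z:
            if z_on and not z_off:
                out.append(((-1, 0, 0, 1), K(1)))
            elif z_off:
                # K_1 with OFF targets free parks them temporarily in 1
                out.append(((0, len(z_off), -len(z_on), 1), K(1)))
        present = {s for s in cfg if s > 0}
        for c in range(2, spec.n + 1):
            catch = [t for t in z if c in arms[t]]
            if catch:
                n_on = sum(1 for t in catch if on_label[t])
                n_off = len(catch) - n_on
                out.append(((0, n_on, -n_off, c), K(c)))
        for c in sorted(present):
            members = [t for t, s in enumerate(cfg) if s == c]
            # a class member is mismatched if its current state is not its
            # goal state; releasing mismatched classes is progress, while
            # releasing a clean class is only the closing sweep
            mismatched = any(
                (c == 1) != on_label[t] for t in members
            )
            out.append(((1, 0 if mismatched else 1, 0, c), P(c)))
        return [a for _, a in sorted(out, key=lambda x: x[0])]

    def dfs(cfg: Config, word: list[Action], depth: int) -> Word | None:
        nonlocal nodes
        if cfg == goal:
            return tuple(word)
        if depth <= 0:
            return None
        nodes += 1
        if nodes > max_nodes:
            return None
        for a in moves(cfg):
            child = apply_action(cfg, a, spec)
            if child == cfg or seen.get(child, -1) >= depth - 1:
                continue
            seen[child] = depth - 1
            word.append(a)
            got = dfs(child, word, depth - 1)
            if got is not None:
                return got
            word.pop()
        return None

    depth0 = 12 * spec.n
    seen[zero] = depth0
    return dfs(zero, [], depth0)


def _round_schedule_word(goal: Config, spec: SeqSpec) -> Word | None:
    """Greedy round scheduler for connected one-colorings.

    Each round paints a batch of ON targets with state 1 behind a wall of
    protected states: temporary colors E are raised first (letting ON
    targets dodge the wall), shield colors S park every OFF target in a
    protected state, the temps are released, ``K_1`` paints whatever is
    still free, and finally the shields come down.  OFF targets therefore
    never see ``K_1``; ON targets become 1 in the round where none of
    their arms is drafted into S (or where a temp arm lets them dodge).

    Returns None when no legal round exists for some remaining target
    (nested-shield colorings), in which case the caller falls back to
    search.
    """
    targets = build_seq_targets(spec)
    arms = [frozenset(g) - {1} for g in targets]
    on = {t for t, s in enumerate(goal) if s == 1}
    off = [t for t, s in enumerate(goal) if s == 0]
    off_arms = frozenset().union(*(arms[t] for t in off)) if off else frozenset()
    free = frozenset(range(2, spec.n + 1)) - off_arms

    word: list[Action] = []
    remaining = set(on)
    while remaining:
        scheduled = None
        for g in sorted(remaining):
            # build a shield transversal avoiding g's arms where possible
            S: set[int] = set()
            for h in off:
                if arms[h] & S:
                    continue
                pref = sorted(arms[h] - arms[g]) or sorted(arms[h])
                S.add(pref[0])
            E: set[int] = set()
            if arms[g] & S:
                dodge = sorted(arms[g] & free - S)
                if not dodge:
                    continue  # cannot free this target this way
                E.add(dodge[0])
            scheduled = (g, E, S)
            break
        if scheduled is None:
            return None
        _, E, S = scheduled
        word.extend(K(e) for e in sorted(E))
        word.extend(K(s) for s in sorted(S))
        word.extend(P(e) for e in sorted(E))
        word.append(K(1))
        word.extend(P(s) for s in sorted(S))
        remaining -= {
            t for t in remaining if (arms[t] & E) or not (arms[t] & S)
        }
    return tuple(word)


# ---------------------------------------------------------------------------
# Brute-force minimal-sequence oracle (ratchet, T = 1)
# ---------------------------------------------------------------------------


def _shortest_words_l1(n: int, m: int, cap: int = DEFAULT_CAP) -> list[set[Word]]:
    """All shortest words of the (n, m, 1, 1) threshold-1 network, grouped
    by BFS level.  Every prefix of a shortest word is itself shortest, so
    the level sets are generated by extending the previous level."""
    spec = RatchetSpec(n, m, 1, 1, 1)
    total = 0
    alphabet = full_alphabet(spec)
    zero = zero_config(spec)
    dist: dict[Config, int] = {zero: 0}
    levels: list[set[Word]] = [{()}]
    frontier: list[tuple[Config, Word]] = [(zero, ())]
    depth = 0
    while frontier:
        depth += 1
        nxt: list[tuple[Config, Word]] = []
        words: set[Word] = set()
        for config, w in frontier:
            for a in alphabet:
                child = apply_action(config, a, spec)
                d = dist.get(child)
                if d is None:
                    dist[child] = depth
                    d = depth
                if d == depth:
                    nw = w + (a,)
                    if nw not in words:
                        words.add(nw)
                        nxt.append((child, nw))
        if words:
            total += len(words)
            if total > cap:
                raise RuntimeError(f"shortest-word list exceeded capacity cap {cap}")
            levels.append(words)
        frontier = nxt
    return levels


def minimal_sequences_bruteforce(
    spec: RatchetSpec, *, cap: int = DEFAULT_CAP
) -> dict[Config, set[Word]]:
    """The three-step word oracle for minimal sequences at connectivity
    (l_n, l_m), threshold 1.

    Step 1 finds all shortest words of the connectivity-1 network with the
    same (n, m).  Step 2 applies those words (they are exactly the
    non-redundant, cycle-free words) in the higher-connectivity network and
    groups them by the configuration they generate.  Step 3 keeps, for each
    configuration, only the words of minimal length.

    Returns a map from configuration to its set of surviving minimal words;
    ``len(result)`` is the configuration count that the counting recursion
    reproduces.
    """
    if spec.T != 1:
        raise ValueError("the minimal-sequence oracle is a threshold-1 construction")
    levels = _shortest_words_l1(spec.n, spec.m, cap)
    best: dict[Config, tuple[int, set[Word]]] = {}
    zero = zero_config(spec)
    for length, words in enumerate(levels):
        for w in words:
            config = apply_word(zero, w, spec)
            entry = best.get(config)
            if entry is None:
                best[config] = (length, {w})
            elif entry[0] == length:
                entry[1].add(w)
    return {config: ws for config, (_, ws) in best.items()}


def commuting_run_sort(word: Word) -> Word:
    """Canonical form of a word under reordering within maximal runs of
    same-kind actions (all-K and all-P runs are internally commutative)."""
    out: list[Action] = []
    i = 0
    while i < len(word):
        j = i
        while j < len(word) and word[j].kind == word[i].kind:
            j += 1
        out.extend(sorted(word[i:j]))
        i = j
    return tuple(out)


def minimal_word_class_count(minimal: Mapping[Config, set[Word]]) -> int:
    """Number of surviving minimal words counted up to reordering of
    commuting same-kind runs -- the quantity the counting recursion
    reproduces."""
    return len(
        {commuting_run_sort(w) for ws in minimal.values() for w in ws}
    )
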