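"""Model definitions for the two noncommutative regulation networks.

Two discrete dynamical systems share an action alphabet of activators
``K_i`` and deactivators ``P_j``:

* the **ratchet network**, in which each of ``N = C(n, l_n) * C(m, l_m)``
  targets carries an integer state in ``{0..T}``; ``K_i`` increments
  (saturating at the threshold ``T``) every target wired to it and ``P_j``
  decrements (floored at 0) every target wired to it.  Noncommutativity
  comes entirely from the saturation edges.

* the **sequestration network**, in which a target ``g`` (a nonempty subset
  of regulator-pair indices, its *arms*) sits in a state from ``{0} | g``;
  ``K_i`` moves targets from 0 into the protected state ``i`` and ``P_i``
  releases state-``i`` targets back to 0.  A target in state ``j`` is
  invisible to every regulator with index ``!= j``.

Configurations are plain tuples of per-target states in a fixed canonical
target order, which makes them hashable and cheap to BFS over.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb
from typing import Iterable, NamedTuple, Union

import numpy as np

__all__ = [
    "Action",
    "K",
    "P",
    "Word",
    "RatchetSpec",
    "SeqSpec",
    "RatchetTarget",
    "SeqTarget",
    "build_ratchet_targets",
    "build_seq_targets",
    "ratchet_apply",
    "seq_apply",
    "apply_word",
    "apply_action",
    "connectivity_matrix",
    "zero_config",
    "full_alphabet",
]


class Action(NamedTuple):
    """A single regulator action: kind ``"K"`` or ``"P"``, 1-based index."""

    kind: str
    index: int

    def __str__(self) -> str:  # "K1", "P2", ...
        return f"{self.kind}{self.index}"


def K(i: int) -> Action:
    return Action("K", i)


def P(i: int) -> Action:
    return Action("P", i)


#: A word is a finite ordered sequence of actions, applied left to right.
Word = tuple[Action, ...]


class RatchetTarget(NamedTuple):
    """A ratchet target, identified by its activator and deactivator wiring."""

    k_set: tuple[int, ...]
    p_set: tuple[int, ...]


#: A sequestration target is its sorted arm tuple (nonempty subset of 1..n).
SeqTarget = tuple[int, ...]

Config = tuple[int, ...]


@dataclass(frozen=True)
class RatchetSpec:
    """Parameters of a ratchet network.

    n, m
        number of activators (K's) and deactivators (P's), both >= 1.
    l_n, l_m
        connectivity: every target is wired to exactly ``l_n`` K's and
        ``l_m`` P's.
    T
        saturation threshold (number of rungs on each target's ladder).
    """

    n: int
    m: int
    l_n: int = 1
    l_m: int = 1
    T: int = 1

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("need n >= 1 and m >= 1")
        if not (1 <= self.l_n <= self.n):
            raise ValueError(f"l_n must satisfy 1 <= l_n <= n, got {self.l_n}")
        if not (1 <= self.l_m <= self.m):
            raise ValueError(f"l_m must satisfy 1 <= l_m <= m, got {self.l_m}")
        if self.T < 1:
            raise ValueError("threshold T must be >= 1")

    @property
    def n_targets(self) -> int:
        return comb(self.n, self.l_n) * comb(self.m, self.l_m)

    @property
    def p_n(self) -> int:
        """Targets wired to each K (row multiplicity of the wiring graph)."""
        return self.n_targets * self.l_n // self.n

    @property
    def p_m(self) -> int:
        """Targets wired to each P."""
        return self.n_targets * self.l_m // self.m

    @property
    def targets_per_pair(self) -> int:
        """M: targets shared by any one (K_i, P_j) pair."""
        return comb(self.n - 1, self.l_n - 1) * comb(self.m - 1, self.l_m - 1)

    def targets(self) -> tuple[RatchetTarget, ...]:
        return build_ratchet_targets(self)

    def alphabet(self) -> tuple[Action, ...]:
        return full_alphabet(self)


@dataclass(frozen=True)
class SeqSpec:
    """Parameters of a sequestration network.

    n
        number of regulator pairs (K_i, P_i).
    reduced
        if True, only the ``2**(n-1) - 1`` targets containing arm 1 plus at
        least one other arm exist (the network drawn on a chromosome with
        RNA polymerase as K_1); if False, all ``2**n - 1`` nonempty arm
        subsets are targets (the full network).
    """

    n: int
    reduced: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need n >= 1")
        if self.reduced and self.n < 2:
            raise ValueError("a reduced network needs n >= 2")

    @property
    def n_targets(self) -> int:
        return (2 ** (self.n - 1) - 1) if self.reduced else (2**self.n - 1)

    def targets(self) -> tuple[SeqTarget, ...]:
        return build_seq_targets(self)

    def alphabet(self) -> tuple[Action, ...]:
        return full_alphabet(self)

    @property
    def space_size(self) -> int:
        """Total number of syntactically valid configurations."""
        size = 1
        for g in self.targets():
            size *= len(g) + 1
        return size


Spec = Union[RatchetSpec, SeqSpec]


@lru_cache(maxsize=None)
def build_ratchet_targets(spec: RatchetSpec) -> tuple[RatchetTarget, ...]:
    """All C(n,l_n)*C(m,l_m) targets, lexicographic on (k_set, p_set)."""
    return tuple(
        RatchetTarget(ks, ps)
        for ks in combinations(range(1, spec.n + 1), spec.l_n)
        for ps in combinations(range(1, spec.m + 1), spec.l_m)
    )


@lru_cache(maxsize=None)
def build_seq_targets(spec: SeqSpec) -> tuple[SeqTarget, ...]:
    """Targets sorted by (arm count, lexicographic arms).

    For the reduced network this yields e.g. for n = 4:
    (1,2), (1,3), (1,4), (1,2,3), (1,2,4), (1,3,4), (1,2,3,4).
    """
    arms = range(1, spec.n + 1)
    subsets: list[SeqTarget] = []
    for k in range(1, spec.n + 1):
        for g in combinations(arms, k):
            if spec.reduced and (1 not in g or len(g) < 2):
                continue
            subsets.append(g)
    subsets.sort(key=lambda g: (len(g), g))
    return tuple(subsets)


def zero_config(spec: Spec) -> Config:
    return (0,) * spec.n_targets


def full_alphabet(spec: Spec) -> tuple[Action, ...]:
    if isinstance(spec, RatchetSpec):
        return tuple(K(i) for i in range(1, spec.n + 1)) + tuple(
            P(j) for j in range(1, spec.m + 1)
        )
    return tuple(K(i) for i in range(1, spec.n + 1)) + tuple(
        P(i) for i in range(1, spec.n + 1)
    )


def _check_ratchet_action(spec: RatchetSpec, a: Action) -> None:
    bound = spec.n if a.kind == "K" else spec.m
    if a.kind not in ("K", "P") or not (1 <= a.index <= bound):
        raise ValueError(f"action {a} out of range for {spec}")


@lru_cache(maxsize=None)
def _ratchet_action_targets(spec: RatchetSpec, a: Action) -> tuple[int, ...]:
    """Indices (into canonical target order) touched by an action."""
    targets = build_ratchet_targets(spec)
    if a.kind == "K":
        return tuple(t for t, tg in enumerate(targets) if a.index in tg.k_set)
    return tuple(t for t, tg in enumerate(targets) if a.index in tg.p_set)


def ratchet_apply(config: Config, a: Action, spec: RatchetSpec) -> Config:
    """One ratchet action: saturating increment (K) or floored decrement (P).

    The one-pot rule: every target wired to the firing regulator moves,
    simultaneously; nothing else changes.
    """
    _check_ratchet_action(spec, a)
    new = list(config)
    if a.kind == "K":
        for t in _ratchet_action_targets(spec, a):
            if new[t] < spec.T:
                new[t] += 1
    else:
        for t in _ratchet_action_targets(spec, a):
            if new[t] > 0:
                new[t] -= 1
    return tuple(new)


@lru_cache(maxsize=None)
def _seq_action_targets(spec: SeqSpec, index: int) -> tuple[int, ...]:
    return tuple(
        t for t, g in enumerate(build_seq_targets(spec)) if index in g
    )


def seq_apply(config: Config, a: Action, spec: SeqSpec) -> Config:
    """One sequestration action.

    ``K_i`` captures every 0-state target with arm ``i`` into state ``i``;
    ``P_i`` releases every state-``i`` target back to 0.  Targets occupied
    by any other state are protected and do not move.
    """
    if a.kind not in ("K", "P") or not (1 <= a.index <= spec.n):
        raise ValueError(f"action {a} out of range for {spec}")
    new = list(config)
    if a.kind == "K":
        for t in _seq_action_targets(spec, a.index):
            if new[t] == 0:
                new[t] = a.index
    else:
        for t in _seq_action_targets(spec, a.index):
            if new[t] == a.index:
                new[t] = 0
    return tuple(new)


def apply_action(config: Config, a: Action, spec: Spec) -> Config:
    if isinstance(spec, RatchetSpec):
        return ratchet_apply(config, a, spec)
    return seq_apply(config, a, spec)


def apply_word(
    config: Config,
    word: Iterable[Action],
    spec: Spec,
    *,
    trajectory: bool = False,
):
    """Left-to-right fold of a word over a configuration.

    With ``trajectory=True`` returns the full list of configurations
    (including the start), otherwise just the final configuration.
    """
    traj = [config]
    for a in word:
        config = apply_action(config, a, spec)
        if trajectory:
            traj.append(config)
    return traj if trajectory else config


def connectivity_matrix(config: Config, spec: RatchetSpec) -> np.ndarray:
    """The n x m summary matrix A of a ratchet configuration.

    For l_n = l_m = 1 the entry A[i, j] is the raw state of the unique
    target wired to (K_i, P_j).  For higher connectivity A[i, j] is 1 iff
    at least one of the M targets shared by K_i and P_j is ON (state T);
    the per-target states remain the primary description.
    """
    targets = build_ratchet_targets(spec)
    A = np.zeros((spec.n, spec.m), dtype=int)
    if spec.l_n == 1 and spec.l_m == 1:
        for state, tg in zip(config, targets):
            A[tg.k_set[0] - 1, tg.p_set[0] - 1] = state
        return A
    for state, tg in zip(config, targets):
        if state == spec.T:
            for i in tg.k_set:
                for j in tg.p_set:
                    A[i - 1, j - 1] = 1
    return A
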