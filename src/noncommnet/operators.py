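"""Matrix-operator formulation of the regulator actions.

Both models embed in a single linear picture.  Each of the ``N`` targets
contributes a block of ``D*T + 1`` population states -- the shared 0 state
followed by ``T`` rungs along each of ``D`` orthogonal dimensions -- and a
configuration becomes a 0/1 population vector of length ``N*(D*T + 1)``
with exactly one occupied state per target block.

A ``K`` action along dimension ``d`` is first written as a block-diagonal
rate generator ``G`` (columns sum to zero; mass flows one rung up the
``d`` ladder at rate ``g``).  Letting the reaction run to completion,
``lim_{t->inf} exp(G t)`` is an exact 0/1 idempotent matrix: the
sub-diagonal single-step raise with an absorbing top rung.  ``P`` actions
are the transposed structure (super-diagonal, absorbing 0).  Products of
these limit operators reproduce the rule-based dynamics of the ratchet
(``D = 1``, threshold ``T``) and sequestration (``D = n``, ``T = 1``)
models exactly, which ``operator_equivalence_check`` verifies on random
word suites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .models import (
    Action,
    Config,
    RatchetSpec,
    SeqSpec,
    Word,
    apply_word,
    build_ratchet_targets,
    build_seq_targets,
)

__all__ = [
    "OperatorSpec",
    "operator_spec_from_ratchet",
    "operator_spec_from_seq",
    "build_generator",
    "build_limit_operator",
    "action_operator",
    "config_to_population",
    "population_to_config",
    "operator_apply_word",
    "operator_equivalence_check",
    "commutator",
]


@dataclass(frozen=True)
class OperatorSpec:
    """Operator-space description of a network.

    N targets, D dimensions, threshold T; ``responsive`` maps each action
    ``(kind, index)`` to its dimension and the frozenset of target indices
    whose blocks respond to it; ``rates`` are the per-target rate constants
    g used by the pre-limit generators (the limit operators are rate-free).
    """

    N: int
    D: int
    T: int
    responsive: Mapping[tuple[str, int], tuple[int, frozenset[int]]]
    rates: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.rates:
            object.__setattr__(self, "rates", (1.0,) * self.N)
        if len(self.rates) != self.N:
            raise ValueError("need one rate per target")

    @property
    def block(self) -> int:
        return self.D * self.T + 1

    @property
    def dim(self) -> int:
        return self.N * self.block

    def state_index(self, d: int, i: int) -> int:
        """Index of state i (1..T) along dimension d within a block; i = 0
        is the shared 0 state regardless of d."""
        if i == 0:
            return 0
        return 1 + (d - 1) * self.T + (i - 1)


def operator_spec_from_ratchet(spec: RatchetSpec) -> OperatorSpec:
    """Translate an l = 1 ratchet network: one dimension, threshold T;
    K_i / P_j act on the targets in row i / column j."""
    if spec.l_n != 1 or spec.l_m != 1:
        raise ValueError(
            "shared targets (l > 1) have no per-target independent blocks; "
            "the operator picture supports l_n = l_m = 1 only"
        )
    targets = build_ratchet_targets(spec)
    responsive: dict[tuple[str, int], tuple[int, frozenset[int]]] = {}
    for i in range(1, spec.n + 1):
        responsive[("K", i)] = (
            1,
            frozenset(t for t, tg in enumerate(targets) if tg.k_set[0] == i),
        )
    for j in range(1, spec.m + 1):
        responsive[("P", j)] = (
            1,
            frozenset(t for t, tg in enumerate(targets) if tg.p_set[0] == j),
        )
    return OperatorSpec(N=len(targets), D=1, T=spec.T, responsive=responsive)


def operator_spec_from_seq(spec: SeqSpec) -> OperatorSpec:
    """Translate a sequestration network: D = n dimensions, threshold 1;
    the pair (K_i, P_i) acts along dimension i on targets with arm i."""
    targets = build_seq_targets(spec)
    responsive: dict[tuple[str, int], tuple[int, frozenset[int]]] = {}
    for i in range(1, spec.n + 1):
        on = frozenset(t for t, g in enumerate(targets) if i in g)
        responsive[("K", i)] = (i, on)
        responsive[("P", i)] = (i, on)
    return OperatorSpec(N=len(targets), D=spec.n, T=1, responsive=responsive)


def build_generator(
    spec: OperatorSpec, d: int, j: int, kind: str = "K", *,
    targets: frozenset[int] | None = None,
) -> np.ndarray:
    """Rate generator G for one rung of population transfer.

    For ``kind="K"`` mass flows from state (d, j) to (d, j+1) at rate g_A
    in every responsive block; ``kind="P"`` reverses the flow.  Columns sum
    to zero (probability conservation).
    """
    if not (1 <= d <= spec.D):
        raise ValueError(f"dimension {d} out of range")
    if not (0 <= j <= spec.T - 1):
        raise ValueError(f"rung {j} out of range for threshold {spec.T}")
    if targets is None:
        targets = frozenset(range(spec.N))
    G = np.zeros((spec.dim, spec.dim))
    lo, hi = spec.state_index(d, j), spec.state_index(d, j + 1)
    src, dst = (lo, hi) if kind == "K" else (hi, lo)
    for t in targets:
        g = spec.rates[t]
        base = t * spec.block
        G[base + src, base + src] -= g
        G[base + dst, base + src] += g
    return G


def build_limit_operator(
    spec: OperatorSpec, d: int, kind: str = "K", *,
    targets: frozenset[int] | None = None,
) -> np.ndarray:
    """Exact 0/1 limit operator for a full K or P action along dimension d.

    The product over rungs of ``lim exp(G t)``: within each responsive
    block, K maps state (d, i) one rung up with the top rung absorbing
    (sub-diagonal structure), P one rung down with 0 absorbing
    (super-diagonal); every other state is fixed.  Constructed symbolically;
    the exponential-limit consistency is a separate numerical check.
    """
    if not (1 <= d <= spec.D):
        raise ValueError(f"dimension {d} out of range")
    if targets is None:
        targets = frozenset(range(spec.N))
    op = np.zeros((spec.dim, spec.dim), dtype=int)
    ladder = [spec.state_index(d, i) for i in range(spec.T + 1)]
    for t in range(spec.N):
        base = t * spec.block
        moved: dict[int, int] = {}
        if t in targets:
            if kind == "K":
                for i in range(spec.T):
                    moved[ladder[i]] = ladder[i + 1]
                moved[ladder[spec.T]] = ladder[spec.T]
            else:
                for i in range(1, spec.T + 1):
                    moved[ladder[i]] = ladder[i - 1]
                moved[ladder[0]] = ladder[0]
        for s in range(spec.block):
            op[base + moved.get(s, s), base + s] = 1
    return op


def action_operator(spec: OperatorSpec, a: Action) -> np.ndarray:
    """Limit operator for a model action, using its responsive target set."""
    try:
        d, targets = spec.responsive[(a.kind, a.index)]
    except KeyError:
        raise ValueError(f"action {a} is not defined for this operator spec")
    return build_limit_operator(spec, d, a.kind, targets=targets)


def config_to_population(config: Sequence[int], spec: OperatorSpec, *,
                         seq: SeqSpec | None = None) -> np.ndarray:
    """Encode a rule-based configuration as a 0/1 population vector.

    For the ratchet, target state s occupies rung s of dimension 1.  For
    the sequestration model state i occupies dimension i's single rung.
    """
    x = np.zeros(spec.dim, dtype=int)
    for t, s in enumerate(config):
        if seq is not None and s > 0:
            idx = spec.state_index(s, 1)
        else:
            idx = spec.state_index(1, s) if s > 0 else 0
        x[t * spec.block + idx] = 1
    return x


def population_to_config(x: np.ndarray, spec: OperatorSpec, *,
                         seq: SeqSpec | None = None) -> Config:
    """Decode a 0/1 population vector back to a configuration tuple."""
    out = []
    for t in range(spec.N):
        block = x[t * spec.block : (t + 1) * spec.block]
        occupied = np.flatnonzero(block)
        if len(occupied) != 1:
            raise ValueError(f"block {t} does not hold exactly one target")
        idx = int(occupied[0])
        if idx == 0:
            out.append(0)
        else:
            d, i = divmod(idx - 1, spec.T)
            out.append(d + 1 if seq is not None else i + 1)
    return tuple(out)


def operator_apply_word(x: np.ndarray, word: Word, spec: OperatorSpec) -> np.ndarray:
    """Left-to-right application of a word's limit operators to a
    population vector."""
    x = np.asarray(x)
    blocks = x.reshape(spec.N, spec.block).sum(axis=1)
    if not np.allclose(blocks, 1.0):
        raise ValueError("population vector violates per-target conservation")
    for a in word:
        x = action_operator(spec, a) @ x
    return x


def commutator(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """[A, B] = AB - BA."""
    A, B = np.asarray(A), np.asarray(B)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("commutator needs two square matrices of equal shape")
    return A @ B - B @ A


def limit_consistency_error(
    spec: OperatorSpec, d: int, j: int, kind: str = "K", *, gt: float = 50.0
) -> float:
    """Max-norm distance between exp(G t) at g t = gt and the single-rung
    limit operator; tends to zero as gt grows."""
    G = build_generator(spec, d, j, kind)
    # single-rung limit: moved state j -> j+1 only
    lim = np.eye(spec.dim)
    lo, hi = spec.state_index(d, j), spec.state_index(d, j + 1)
    src, dst = (lo, hi) if kind == "K" else (hi, lo)
    for t in range(spec.N):
        base = t * spec.block
        lim[base + src, base + src] = 0.0
        lim[base + dst, base + src] = 1.0
    return float(np.abs(expm(G * gt) - lim).max())


def operator_equivalence_check(
    model_spec: RatchetSpec | SeqSpec,
    *,
    trials: int = 100,
    max_len: int = 10,
    seed: int = 0,
) -> dict:
    """Dual-route check: operator pipeline vs rule-based pipeline on random
    words from the all-zero configuration.

    Returns {"trials", "agreements", "all_agree"}.  Ratchet networks with
    l > 1 are rejected (shared targets break the independent-block
    assumption).
    """
    if isinstance(model_spec, RatchetSpec):
        op_spec = operator_spec_from_ratchet(model_spec)
        seq = None
    else:
        op_spec = operator_spec_from_seq(model_spec)
        seq = model_spec
    rng = np.random.default_rng(seed)
    alphabet = model_spec.alphabet()
    zero = (0,) * model_spec.n_targets
    agree = 0
    for _ in range(trials):
        length = int(rng.integers(0, max_len + 1))
        word = tuple(alphabet[i] for i in rng.integers(0, len(alphabet), length))
        rule_cfg = apply_word(zero, word, model_spec)
        x = config_to_population(zero, op_spec, seq=seq)
        x = operator_apply_word(x, word, op_spec)
        if population_to_config(x, op_spec, seq=seq) == rule_cfg:
            agree += 1
    return {"trials": trials, "agreements": agree, "all_agree": agree == trials}
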