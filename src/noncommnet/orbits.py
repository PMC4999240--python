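"""Orbit decompositions of configuration space for both models.

An *orbit* is a maximal set of configurations mutually accessible under a
restricted action alphabet.  The two models decompose differently:

* In the threshold-1 ratchet network, a configuration whose connectivity
  matrix contains a non-lonesum (forbidden) block on rows ``I`` x columns
  ``J`` can never clear that block without using the restricted regulators
  ``K_I`` / ``P_J``; each forbidden block is the origin of an ``(i, j)``-
  orbit explored with the remaining regulators.  Some steps inside these
  orbits are irreversible.

* In the sequestration network every intra-orbit edge is reversible, so
  the orbits are exactly the connected components of the graph whose edges
  join configurations one reversible action step apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable

import networkx as nx

from .counting import ratchet_orbit_count
from .enumeration import DEFAULT_CAP, bfs_reachable, is_lonesum
from .models import (
    Config,
    K,
    P,
    RatchetSpec,
    SeqSpec,
    apply_action,
    build_seq_targets,
    full_alphabet,
)

__all__ = [
    "Orbit",
    "OrbitPartition",
    "sequestration_orbits",
    "ratchet_orbits_bruteforce",
    "orbit_count_check",
]


@dataclass(frozen=True)
class Orbit:
    """One orbit: its member configurations, the restricted regulators that
    define it (empty for sequestration orbits), and one origin."""

    members: frozenset[Config]
    origin: Config
    restricted_k: tuple[int, ...] = ()
    restricted_p: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OrbitPartition:
    """A family of orbits plus the edge list used to discover them."""

    orbits: tuple[Orbit, ...]
    edges: tuple[tuple[Config, Config, bool], ...] = ()
    # (a, b, reversible); directed a -> b when not reversible

    def sizes(self) -> list[int]:
        return sorted((len(o) for o in self.orbits), reverse=True)


def _seq_space(spec: SeqSpec) -> list[Config]:
    state_sets = [(0,) + g for g in build_seq_targets(spec)]
    return [tuple(states) for states in product(*state_sets)]


def sequestration_orbits(spec: SeqSpec, *, cap: int = DEFAULT_CAP) -> OrbitPartition:
    """Orbits of the sequestration network as connected components of the
    reversible-edge graph over the *entire* configuration space.

    An undirected edge joins x and y when some single action maps x to y
    and some single action maps y back to x.  Every intra-orbit path is
    then reversible by construction, which is exactly the property that
    makes the decomposition well defined for this model.
    """
    if spec.space_size > cap:
        raise RuntimeError(
            f"configuration space {spec.space_size} exceeds capacity cap {cap}"
        )
    alphabet = full_alphabet(spec)
    space = _seq_space(spec)
    graph = nx.Graph()
    graph.add_nodes_from(space)
    edges = []
    for x in space:
        for a in alphabet:
            y = apply_action(x, a, spec)
            if y == x:
                continue
            back = any(apply_action(y, b, spec) == x for b in alphabet)
            if back:
                graph.add_edge(x, y)
                if x < y:
                    edges.append((x, y, True))
    orbits = tuple(
        Orbit(members=frozenset(comp), origin=min(comp))
        for comp in sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    )
    return OrbitPartition(orbits=orbits, edges=tuple(edges))


# ---------------------------------------------------------------------------
# Ratchet orbits (threshold 1, connectivity 1)
# ---------------------------------------------------------------------------


def _place_block(
    block: tuple[int, ...], rows: tuple[int, ...], cols: tuple[int, ...],
    n: int, m: int, fill: int,
) -> Config:
    """Embed an |rows| x |cols| binary block into an n x m configuration
    (row-major target order), with every remaining entry set to ``fill``."""
    A = [[fill] * m for _ in range(n)]
    it = iter(block)
    for r in rows:
        for c in cols:
            A[r - 1][c - 1] = next(it)
    return tuple(v for row in A for v in row)


def _restricted_alphabet(n: int, m: int, rows: Iterable[int], cols: Iterable[int]):
    rows, cols = set(rows), set(cols)
    return tuple(
        [K(i) for i in range(1, n + 1) if i not in rows]
        + [P(j) for j in range(1, m + 1) if j not in cols]
    )


def ratchet_orbits_bruteforce(
    n: int, m: int, *, cap: int = DEFAULT_CAP
) -> dict[tuple[int, int], OrbitPartition]:
    """Discover the (i, j)-orbits of the n x m threshold-1 ratchet network
    for one canonical restricted set per block shape.

    For each pair of restricted sets I = {1..i}, J = {1..j} (i, j >= 2) and
    each non-lonesum i x j block, the origin is the configuration with the
    block in place and every other entry 0 -- or 1 when no activator
    remains, so that pure-P orbits mirror pure-K ones.  A block only counts
    as a new origin if its origin configuration was not already reached by
    an orbit with a smaller restricted set (any I' within I, J' within J);
    the number of surviving origins is the orbit count that the counting
    recursion reproduces.
    """
    if 2 ** (n * m) > cap:
        raise RuntimeError("configuration space exceeds capacity cap")
    spec = RatchetSpec(n, m, 1, 1, 1)

    # per restricted pair: list of (origin0, origin1, reach under the
    # family's own alphabet)
    origin_memo: dict[
        tuple[tuple[int, ...], tuple[int, ...]],
        list[tuple[Config, Config, frozenset[Config]]],
    ] = {}

    def family(rows: tuple[int, ...], cols: tuple[int, ...]):
        key = (rows, cols)
        if key in origin_memo:
            return origin_memo[key]
        i, j = len(rows), len(cols)
        alphabet = _restricted_alphabet(n, m, rows, cols)
        # coverage: configurations transformable from a smaller family's
        # origin without the regulators restricted at THIS level -- a
        # configuration only counts as already belonging to an earlier
        # orbit if the transformation avoids the currently forbidden moves
        covered: set[Config] = set()
        for ip in range(2, i + 1):
            for jp in range(2, j + 1):
                if ip + jp >= i + j:
                    continue
                for rsub in combinations(rows, ip):
                    for csub in combinations(cols, jp):
                        for o0, o1, _ in family(rsub, csub):
                            covered |= bfs_reachable(spec, o0, alphabet, cap=cap).configs
                            if o1 != o0:
                                covered |= bfs_reachable(
                                    spec, o1, alphabet, cap=cap
                                ).configs
        no_k_left = not any(a.kind == "K" for a in alphabet)
        found: list[tuple[Config, Config, frozenset[Config]]] = []
        for block in product((0, 1), repeat=i * j):
            rows_mat = [block[r * j : (r + 1) * j] for r in range(i)]
            if is_lonesum(rows_mat):
                continue
            # both origin representatives: remaining entries all 0 and all 1
            origin0 = _place_block(block, rows, cols, n, m, 0)
            origin1 = _place_block(block, rows, cols, n, m, 1)
            if origin0 in covered or origin1 in covered:
                continue
            reach = bfs_reachable(spec, origin0, alphabet, cap=cap).configs
            if origin1 != origin0:
                reach = reach | bfs_reachable(spec, origin1, alphabet, cap=cap).configs
            found.append((origin0, origin1, reach))
        origin_memo[key] = found
        return found

    out: dict[tuple[int, int], OrbitPartition] = {}
    for i in range(2, n + 1):
        for j in range(2, m + 1):
            rows = tuple(range(1, i + 1))
            cols = tuple(range(1, j + 1))
            no_k_left = i == n
            orbits = tuple(
                Orbit(
                    members=reach,
                    # all-1 representative when no activator survives, so
                    # pure-P orbits mirror pure-K ones
                    origin=o1 if no_k_left else o0,
                    restricted_k=rows,
                    restricted_p=cols,
                )
                for o0, o1, reach in family(rows, cols)
            )
            out[(i, j)] = OrbitPartition(orbits=orbits)
    return out


def orbit_edges(
    orbit: Orbit, spec: RatchetSpec
) -> tuple[tuple[Config, Config, bool], ...]:
    """Directed step edges inside a ratchet orbit, flagged reversible when a
    single allowed action maps back."""
    alphabet = _restricted_alphabet(
        spec.n, spec.m, orbit.restricted_k, orbit.restricted_p
    )
    edges = []
    for x in sorted(orbit.members):
        for a in alphabet:
            y = apply_action(x, a, spec)
            if y == x or y not in orbit.members:
                continue
            back = any(apply_action(y, b, spec) == x for b in alphabet)
            edges.append((x, y, back))
    return tuple(edges)


def orbit_count_check(n: int, m: int, *, cap: int = DEFAULT_CAP) -> dict:
    """Cross-validate the orbit-count recursion against brute-force orbit
    discovery, per (i, j) block shape.

    Returns {"per_shape": {(i, j): {"recursion", "bruteforce", "match"}},
    "all_match": bool}.
    """
    recursion = ratchet_orbit_count(n, m)
    brute = ratchet_orbits_bruteforce(n, m, cap=cap)
    per_shape = {}
    for key in sorted(recursion):
        rec = recursion[key]["per_subset"]
        bf = len(brute[key].orbits)
        per_shape[key] = {"recursion": rec, "bruteforce": bf, "match": rec == bf}
    return {
        "per_shape": per_shape,
        "all_match": all(v["match"] for v in per_shape.values()),
    }


def main_orbit_size(spec: RatchetSpec | SeqSpec, *, cap: int = DEFAULT_CAP) -> int:
    """Size of the unrestricted (main) orbit: the BFS reach from all-zero
    under the full alphabet.  For the l = 1, T = 1 ratchet this equals the
    poly-Bernoulli number B(n, m)."""
    return len(bfs_reachable(spec, cap=cap))
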