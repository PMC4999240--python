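"""Closed-form and recursive counting laws for both network families.

Everything here is exact integer arithmetic (Python ints); the quantities
grow super-exponentially (the connected one-coloring count is already
780304385 at n = 6) and floating point would corrupt them.

Contents
--------
* Stirling numbers of the second kind and the poly-Bernoulli numbers
  ``B_n^(-m)``, which count the binary lonesum matrices and therefore the
  reachable configurations of the threshold-1, connectivity-1 ratchet
  network.
* Combinatorial-logic configuration counts with redundancy thresholds
  (the number of target patterns static AND-logic can produce when
  regulators are shared between targets).
* The minimal-sequence recursion for ratchet networks with connectivity
  l_n, l_m > 1.
* The connected one-coloring count f(n) for the reduced sequestration
  network and the derived lower/upper bounds for the full network.
* The orbit-count recursion for the ratchet network.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb
__all__ = [
    "stirling2",
    "poly_bernoulli",
    "CombinatorialSpec",
    "alpha_threshold",
    "combinatorial_count",
    "minimal_sequence_count",
    "one_coloring_count",
    "one_coloring_violations",
    "full_network_bounds",
    "ratchet_orbit_count",
]


@lru_cache(maxsize=None)
def stirling2(n: int, j: int) -> int:
    """Stirling number of the second kind S(n, j).

    Number of ways to partition n labelled items into j nonempty unlabelled
    blocks; triangular recurrence S(n, j) = j*S(n-1, j) + S(n-1, j-1).
    """
    if n < 0 or j < 0:
        raise ValueError("stirling2 requires nonnegative arguments")
    if n == j:
        return 1
    if j == 0 or j > n:
        return 0
    return j * stirling2(n - 1, j) + stirling2(n - 1, j - 1)


def poly_bernoulli(n: int, m: int) -> int:
    """Poly-Bernoulli number B_n^(-m) = number of n x m binary lonesum matrices.

    Uses the double-Stirling form
    B_n^(-m) = sum_j (j!)^2 S(n+1, j+1) S(m+1, j+1), which is manifestly
    symmetric in (n, m).  B(0, m) = B(n, 0) = 1.
    """
    if n < 0 or m < 0:
        raise ValueError("poly_bernoulli requires nonnegative arguments")
    return sum(
        (_fact(j)) ** 2 * stirling2(n + 1, j + 1) * stirling2(m + 1, j + 1)
        for j in range(min(n, m) + 1)
    )


@lru_cache(maxsize=None)
def _fact(j: int) -> int:
    out = 1
    for i in range(2, j + 1):
        out *= i
    return out


# ---------------------------------------------------------------------------
# Combinatorial (static AND) logic with u pools of regulators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CombinatorialSpec:
    """u pools of regulators; pool i has n_i regulators, each target wired
    to exactly l_i of them.  A target is ON iff at least one chosen
    regulator from every pool is wired to it."""

    n: tuple[int, ...]
    l: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.n) != len(self.l) or not self.n:
            raise ValueError("need one connectivity per pool")
        for ni, li in zip(self.n, self.l):
            if not (1 <= li <= ni):
                raise ValueError(f"need 1 <= l <= n per pool, got ({ni}, {li})")

    @property
    def u(self) -> int:
        return len(self.n)


def _covered(i: int, n: int, l_n: int, m: int, l_m: int) -> int:
    """Unique targets in one column of the (n, m) connectivity matrix that
    are wired to at least one of i chosen K's (inclusion-exclusion)."""
    return sum(
        (-1) ** (r + 1) * comb(i, r) * comb(n - r, l_n - r) * comb(m - 1, l_m - 1)
        for r in range(1, min(i, l_n) + 1)
    )


def alpha_threshold(spec: CombinatorialSpec, pool: int) -> int:
    """Smallest r such that any r regulators of a pool act like the whole pool.

    Redundancy threshold: choosing r >= alpha regulators from pool ``pool``
    already covers every target visible in the partner pool that maximizes
    the shared target count, so larger subsets add nothing.
    """
    if not (0 <= pool < spec.u):
        raise ValueError("pool index out of range")
    n_i, l_i = spec.n[pool], spec.l[pool]
    if spec.u == 1:
        # covering all C(n, l) targets requires emptying the complement
        return n_i - l_i + 1
    partner = max(
        (j for j in range(spec.u) if j != pool),
        key=lambda j: comb(spec.n[j], spec.l[j]),
    )
    n_j, l_j = spec.n[partner], spec.l[partner]
    # unique targets per column of the equivalent n_i x n_j matrix
    p_nj = comb(n_i, l_i) * comb(n_j, l_j) * l_j // n_j
    for r in range(1, n_i + 1):
        if _covered(r, n_i, l_i, n_j, l_j) >= p_nj:
            return r
    return n_i


def combinatorial_count(spec: CombinatorialSpec) -> int:
    """Total configurations reachable by static combinatorial logic.

    Inclusion-exclusion over pools: start from the product of the
    (2^n_i - 1) nonempty regulator choices (+1 for choosing nothing) and
    correct for subsets of size >= alpha_i, which are redundant with the
    full pool.
    """
    if spec.u == 1:
        n, l = spec.n[0], spec.l[0]
        alpha = alpha_threshold(spec, 0)
        return 1 + (2**n - 1) - sum(comb(n, j) for j in range(alpha, n))

    alphas = [alpha_threshold(spec, i) for i in range(spec.u)]
    redundant = [
        sum(comb(spec.n[i], j) for j in range(alphas[i], spec.n[i]))
        for i in range(spec.u)
    ]
    nonempty = [2 ** spec.n[i] - 1 for i in range(spec.u)]

    from itertools import combinations as _combs

    total = 1  # the choose-nothing configuration
    for k in range(spec.u + 1):
        s_k = 0
        for sigma in _combs(range(spec.u), k):
            term = 1
            for i in range(spec.u):
                term *= redundant[i] if i in sigma else nonempty[i]
            s_k += term
        total += (-1) ** k * s_k
    return total


# ---------------------------------------------------------------------------
# Minimal-sequence recursion for the ratchet network (threshold 1)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _a_table(n: int, m: int) -> int:
    """a_n^m: equivalence classes of non-redundant words using exactly m P's
    (out of an unbounded P pool) when n K's are available; classes are taken
    up to relabelling of the P indices."""
    if m == 0:
        return 0
    # anchor at pool size m + 1, the smallest pool in which a non-redundant
    # word can use m P's (Lemma: at most pool-size - 1 P's survive)
    total = poly_bernoulli(n, m + 1) - 2**n
    total -= sum(comb(m + 1, j) * _a_table(n, j) for j in range(1, m))
    assert total % (m + 1) == 0, "P-relabelling classes must divide evenly"
    return total // (m + 1)


def _c_column(n: int, m: int, l_m: int) -> int:
    """c_n^m(1, l_m): non-redundant word count at K-connectivity 1.

    Words with more than m - l_m P's are redundant, so only the P-count
    classes up to that bound survive."""
    return 2**n + sum(comb(m, j) * _a_table(n, j) for j in range(1, m - l_m + 1))


@lru_cache(maxsize=None)
def _b_table(m: int, n: int, l_m: int) -> int:
    """b_m^n(l_m): words using exactly n K's when m P's are available at
    P-connectivity l_m."""
    if n == 0:
        return 1  # the empty word
    if n == 1:
        return 2**m - sum(comb(m, j) for j in range(l_m))
    return _c_column(n, m, l_m) - sum(
        comb(n, j) * _b_table(m, j, l_m) for j in range(n)
    )


def minimal_sequence_count(n: int, m: int, l_n: int, l_m: int) -> int:
    """Number of minimal-length sequences in the (n, m, l_n, l_m) ratchet
    network at threshold 1.

    Sequences using more than n - l_n + 1 K's or more than m - l_m P's are
    redundant with shorter ones; the recursion subtracts them level by
    level.  At l_n = l_m = 1 this reduces to the poly-Bernoulli count.
    """
    if not (1 <= l_n <= n and 1 <= l_m <= m):
        raise ValueError("need 1 <= l_n <= n and 1 <= l_m <= m")
    return sum(comb(n, j) * _b_table(m, j, l_m) for j in range(n - l_n + 2))


# ---------------------------------------------------------------------------
# Connected one-colorings of the reduced sequestration network
# ---------------------------------------------------------------------------


def one_coloring_violations(n: int) -> int:
    """Number of binary colorings of the reduced n-network that violate the
    connectivity rule (an ON multi-arm target with every overlapping ON
    2-arm support missing).

    Sum over the number m of OFF 2-arm targets; the inner sums over the arm
    count k run over all 3 <= k <= n, with C(m, k-1) vanishing naturally
    once k-1 > m.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    total = 0
    for m in range(2, n):
        forced = sum(comb(m, k - 1) for k in range(3, n + 1))
        free = sum(comb(n - 1, k - 1) - comb(m, k - 1) for k in range(3, n + 1))
        total += comb(n - 1, m) * (2**forced - 1) * 2**free
    return total


def one_coloring_count(n: int) -> int:
    """f(n): connected one-colorings of the reduced n-network.

    Equals the number of reachable configurations of the reduced network;
    the sequence starts 1, 2, 7, 89, 16897, 780304385.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if n == 1:
        return 1
    return 2 ** (2 ** (n - 1) - 1) - one_coloring_violations(n)


def full_network_bounds(n: int) -> tuple[int, int]:
    """(lower, upper) bounds for c_n, the reachable count of the full
    n-network.

    Lower: f(n+1), via the embedding of the full n-network inside the
    reduced (n+1)-network.  Upper: the falling-factorial sum over nested
    k-colorings,
    1 + sum_k (n)_k f(n-k+1) prod_{j=n-k+2..n} (f(j) - 1).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    lower = one_coloring_count(n + 1)
    upper = 1
    for k in range(1, n + 1):
        term = 1
        for i in range(k):  # falling factorial (n)_k
            term *= n - i
        for j in range(n - k + 2, n + 1):
            term *= one_coloring_count(j) - 1
        term *= one_coloring_count(n - k + 1)
        upper += term
    return lower, upper


# ---------------------------------------------------------------------------
# Orbit counts for the ratchet network
# ---------------------------------------------------------------------------


def _b_prime(a: int, b: int) -> int:
    """Reachable-count factor for the unrestricted (a x b) remainder of an
    orbit: poly-Bernoulli when both sides survive, else a pure-K / pure-P
    subset count."""
    if a > 0 and b > 0:
        return poly_bernoulli(a, b)
    if b == 0:
        return 2**a
    return 2**b


@lru_cache(maxsize=None)
def _c_orbit(i: int, j: int) -> int:
    """c_i^j: orbits whose forbidden block spans a fixed set of i K's and
    j P's.  Non-lonesum i x j blocks, minus configurations already reached
    by orbits with strictly smaller forbidden blocks."""
    if i < 2 or j < 2:
        return 0
    total = 2 ** (i * j) - poly_bernoulli(i, j)
    for ip in range(2, i + 1):
        for jp in range(2, j + 1):
            if ip + jp > i + j - 1:
                continue
            total -= (
                comb(i, ip) * comb(j, jp) * _c_orbit(ip, jp) * _b_prime(i - ip, j - jp)
            )
    return total


def ratchet_orbit_count(n: int, m: int) -> dict[tuple[int, int], dict[str, int]]:
    """Orbit counts per (i, j) for the n x m threshold-1 ratchet network.

    Returns {(i, j): {"per_subset": c_i^j, "total": C(n,i)*C(m,j)*c_i^j}}
    for 2 <= i <= n, 2 <= j <= m.
    """
    out: dict[tuple[int, int], dict[str, int]] = {}
    for i in range(2, n + 1):
        for j in range(2, m + 1):
            c = _c_orbit(i, j)
            out[(i, j)] = {
                "per_subset": c,
                "total": comb(n, i) * comb(m, j) * c,
            }
    return out
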