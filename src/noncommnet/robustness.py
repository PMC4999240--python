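"""Regulator-deletion robustness analysis for the ratchet network.

The experiment: delete one activator from a network, enumerate the
configurations reachable by the impaired alphabet, and ask how well the
permanently lost configurations can be approximated by surviving ones.
Similarity is a normalized correlation between ON/OFF target vectors;
the per-row maxima of the full-vs-impaired correlation matrix (rows with
exact matches removed) summarize recoverability, and sweeping network
parameters traces the tradeoff between raw reachability and robustness to
regulator loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .enumeration import DEFAULT_CAP, ReachableSet, bfs_reachable
from .models import Action, Config, RatchetSpec, full_alphabet, zero_config

__all__ = [
    "RobustnessResult",
    "delete_regulator",
    "config_correlation",
    "recovery_analysis",
    "tradeoff_curve",
]


def delete_regulator(spec: RatchetSpec, a: Action) -> tuple[Action, ...]:
    """The action alphabet with one regulator removed.

    The network wiring (targets, connectivity) is unchanged; only the
    ability to fire the deleted regulator is lost.
    """
    alphabet = full_alphabet(spec)
    if a not in alphabet:
        raise ValueError(f"regulator {a} does not exist in {spec}")
    return tuple(b for b in alphabet if b != a)


def config_correlation(
    a: Sequence[int], b: Sequence[int], *, method: Literal["pearson", "cosine"] = "pearson"
) -> float:
    """Normalized correlation between two ON/OFF configuration vectors.

    Pearson correlation by default, with the degenerate convention that a
    zero-variance vector correlates 1.0 with an identical vector and 0.0
    with anything else.  Cosine similarity is available as an alternative
    normalization.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("need two equal-length nonempty vectors")
    if method == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            return 1.0 if np.array_equal(x, y) else 0.0
        return float(x @ y / (nx * ny))
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 1.0 if np.array_equal(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class RobustnessResult:
    """Outcome of one deletion experiment."""

    spec: RatchetSpec
    deleted: Action
    full_set: ReachableSet
    impaired_set: ReachableSet
    lost: tuple[Config, ...]          # full-only configurations (rows)
    corr: np.ndarray                  # lost rows x impaired columns
    row_max: np.ndarray               # best impaired match per lost row
    cutoff: float
    fraction_above: float             # 1 - F(cutoff)

    @property
    def reach_count(self) -> int:
        return len(self.full_set)

    def cdf(self, xs: Sequence[float] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Empirical CDF F(x) of the per-row maximum correlation."""
        vals = np.sort(self.row_max)
        if xs is None:
            xs = vals
        xs = np.asarray(xs, dtype=float)
        F = np.searchsorted(vals, xs, side="right") / max(len(vals), 1)
        return xs, F


def _on_off(config: Config, spec: RatchetSpec) -> tuple[int, ...]:
    return tuple(1 if s == spec.T else 0 for s in config)


def recovery_analysis(
    spec: RatchetSpec,
    deleted: Action,
    *,
    cutoff: float = 0.8,
    method: Literal["pearson", "cosine"] = "pearson",
    min_word_length: int | None = None,
    cap: int = DEFAULT_CAP,
) -> RobustnessResult:
    """Full vs impaired reachability with correlation-based recovery.

    Enumerates both reachable sets from the all-zero configuration,
    removes every full-network configuration that the impaired network
    matches exactly, and computes the correlation matrix between the lost
    configurations (rows) and all impaired configurations (columns), the
    per-row maxima, and the fraction of rows above the similarity cutoff.

    ``min_word_length`` optionally restricts the impaired set to
    configurations whose shortest witness word exceeds that length,
    mirroring the construction in which lost configurations are recovered
    specifically by longer sequences.  By default the impaired set is
    length-agnostic.
    """
    if spec.T != 1:
        raise ValueError("the deletion experiment is defined at threshold 1")
    full = bfs_reachable(spec, cap=cap)
    impaired_alphabet = delete_regulator(spec, deleted)
    impaired = bfs_reachable(spec, zero_config(spec), impaired_alphabet, cap=cap)

    impaired_configs = sorted(impaired.configs)
    if min_word_length is not None:
        impaired_configs = [
            c for c in impaired_configs
            if len(impaired.word_index[c]) > min_word_length
        ]
    lost = tuple(c for c in sorted(full.configs) if c not in impaired.configs)

    imp_vecs = [_on_off(c, spec) for c in impaired_configs]
    corr = np.array(
        [
            [config_correlation(_on_off(c, spec), v, method=method) for v in imp_vecs]
            for c in lost
        ]
    ) if lost and imp_vecs else np.zeros((len(lost), len(imp_vecs)))
    row_max = corr.max(axis=1) if corr.size else np.zeros(len(lost))
    fraction = float((row_max > cutoff).mean()) if len(row_max) else 0.0
    return RobustnessResult(
        spec=spec,
        deleted=deleted,
        full_set=full,
        impaired_set=impaired,
        lost=lost,
        corr=corr,
        row_max=row_max,
        cutoff=cutoff,
        fraction_above=fraction,
    )


def tradeoff_curve(
    *,
    m: int = 2,
    n_range: Sequence[int],
    l_n_range: Sequence[int],
    deleted_index: int = 1,
    cutoff: float = 0.8,
    cap: int = DEFAULT_CAP,
) -> list[dict]:
    """Reachability/robustness tradeoff over (n, l_n) grids at fixed m.

    One row per parameter combination: the full reach count and the
    fraction of lost configurations recoverable above the cutoff after
    deleting one activator.
    """
    rows = []
    for n in n_range:
        for l_n in l_n_range:
            if not (1 <= l_n <= n):
                continue
            spec = RatchetSpec(n, m, l_n, 1, 1)
            res = recovery_analysis(
                spec, Action("K", deleted_index), cutoff=cutoff, cap=cap
            )
            rows.append(
                {
                    "n": n,
                    "m": m,
                    "l_n": l_n,
                    "reach_count": res.reach_count,
                    "lost": len(res.lost),
                    "fraction_above": res.fraction_above,
                }
            )
    return rows
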