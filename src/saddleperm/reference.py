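"""Ground-truth permutation engines.

Exact enumeration walks every distinct multiset assignment of the N
clusters to groups (multinomial enumeration, not N! orderings - Q is
invariant to within-group ordering) and tabulates the exact null
distribution of Q.  The Monte Carlo engine estimates the mid-p value
``(#{Q_perm > Q_obs} + 0.5 #{Q_perm = Q_obs}) / B`` from B random urn
draws; it is the gold-standard benchmark for the analytic engine when
enumeration is out of reach.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator

import numpy as np
from scipy import linalg

from .design import DesignSpec, permutation_cardinality, sigma_matrix

__all__ = [
    "ExactNull",
    "EnumerationCapError",
    "enumerate_null",
    "exact_tail_and_atom",
    "exact_midp",
    "monte_carlo_midp",
]

DEFAULT_ENUMERATION_CAP = 2_000_000
_Q_TIE_TOL = 1e-9


class EnumerationCapError(ValueError):
    """Permutation space too large to enumerate; use the Monte Carlo engine."""


@dataclass
class ExactNull:
    """Sorted distinct Q values with exact probabilities."""

    support: np.ndarray
    pmf: np.ndarray
    cardinality: int

    def mean(self) -> float:
        return float(self.support @ self.pmf)


def _iter_group_sums(scores: np.ndarray, sizes: tuple[int, ...]) -> Iterator[np.ndarray]:
    """Yield the (k-1)-vector of group score totals for every assignment."""
    n = scores.size
    k = len(sizes)
    w = np.zeros(k - 1)

    def rec(group: int, remaining: tuple[int, ...]) -> Iterator[np.ndarray]:
        if group == k - 1:  # last group forced
            yield w.copy()
            return
        for chosen in combinations(remaining, sizes[group]):
            w[group] = scores[list(chosen)].sum()
            rest = tuple(i for i in remaining if i not in set(chosen))
            yield from rec(group + 1, rest)
        w[group] = 0.0

    yield from rec(0, tuple(range(n)))


def enumerate_null(
    scores: np.ndarray,
    spec: DesignSpec,
    *,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> ExactNull:
    """Exact permutation distribution of Q by full multiset enumeration."""
    scores = np.asarray(scores, dtype=float)
    card = permutation_cardinality(spec)
    if card > cap:
        raise EnumerationCapError(
            f"cardinality {card} exceeds cap {cap}; use monte_carlo_midp"
        )
    s2 = float(np.mean(scores**2))
    if s2 == 0.0:
        return ExactNull(np.zeros(1), np.ones(1), card)
    sigma = sigma_matrix(spec, s2)
    cho = linalg.cho_factor(sigma)
    ws = np.array(list(_iter_group_sums(scores, spec.group_sizes)))
    qs = np.einsum("ij,ij->i", ws, linalg.cho_solve(cho, ws.T).T)
    qs.sort()
    # group float ties
    support: list[float] = []
    counts: list[int] = []
    for q in qs:
        if support and abs(q - support[-1]) <= _Q_TIE_TOL * max(1.0, abs(support[-1])):
            counts[-1] += 1
        else:
            support.append(float(q))
            counts.append(1)
    pmf = np.asarray(counts, dtype=float) / card
    return ExactNull(np.asarray(support), pmf, card)


def exact_tail_and_atom(null: ExactNull, q_obs: float) -> tuple[float, float]:
    """Exact ``(P(Q > q_obs), P(Q = q_obs))`` under the tie tolerance."""
    tol = _Q_TIE_TOL * max(1.0, abs(q_obs))
    at = np.abs(null.support - q_obs) <= tol
    atom = float(null.pmf[at].sum())
    strict = float(null.pmf[(null.support > q_obs) & ~at].sum())
    return strict, atom


def exact_midp(null: ExactNull, q_obs: float) -> float:
    strict, atom = exact_tail_and_atom(null, q_obs)
    return strict + 0.5 * atom


def monte_carlo_midp(
    scores: np.ndarray,
    spec: DesignSpec,
    q_obs: float,
    b: int,
    seed: int | np.random.Generator,
) -> tuple[float, float]:
    """Monte Carlo mid-p estimate and its binomial standard error.

    Draws ``b`` urn assignments (equivalently, permutations of the
    cluster scores against fixed group slots) and recomputes Q for each.
    Equality with the observed Q is judged at 1e-9 relative tolerance.
    """
    if b < 100:
        raise ValueError("at least 100 permutations required")
    scores = np.asarray(scores, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s2 = float(np.mean(scores**2))
    if s2 == 0.0:
        return 0.5, 0.0
    sigma = sigma_matrix(spec, s2)
    cho = linalg.cho_factor(sigma)
    perms = rng.permuted(np.tile(scores, (b, 1)), axis=1)
    offsets = np.concatenate(([0], np.cumsum(spec.group_sizes)))[:-1]
    w = np.add.reduceat(perms, offsets, axis=1)[:, : spec.k - 1]
    q = np.einsum("ij,ij->i", w, linalg.cho_solve(cho, w.T).T)
    tol = _Q_TIE_TOL * max(1.0, abs(q_obs))
    greater = int(np.sum(q > q_obs + tol))
    equal = int(np.sum(np.abs(q - q_obs) <= tol))
    est = (greater + 0.5 * equal) / b
    se = float(np.sqrt(est * (1.0 - est) / b))
    return float(est), se
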