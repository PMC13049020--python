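"""Urn randomization and the k-sample quadratic statistic.

An urn with ``N_j`` balls per arm, drawn without replacement, assigns
the N clusters to k groups; every allocation with the target counts is
equally likely, so the permutation space has multinomial cardinality
``N! / (N_1! ... N_k!)``.  The test vector collects the group totals of
the centered cluster scores for the first k-1 groups; its exact
covariance under the urn law is the finite-population sampling matrix

    Var(W_j)    =  N_j (N - N_j) / (N - 1) * S_C^2,
    Cov(W_j,W_l) = -N_j N_l / (N - 1)      * S_C^2,

and the statistic Q = W' Sigma^{-1} W is asymptotically chi-squared
with k-1 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .scoring import ClusterScoreVector

__all__ = [
    "DesignSpec",
    "Assignment",
    "TestVector",
    "TestResult",
    "DegenerateScoresError",
    "urn_randomize",
    "permutation_cardinality",
    "test_vector",
    "quadratic_statistic",
    "chisq_pvalue",
    "conventional_statistic",
    "conventional_chisq_pvalue",
]


class DegenerateScoresError(ValueError):
    """All cluster scores identical: the permutation test is undefined."""


@dataclass(frozen=True)
class DesignSpec:
    """Target group sizes ``(N_1, ..., N_k)`` of the urn design."""

    group_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.group_sizes) < 2:
            raise ValueError("at least two groups required")
        if any(int(n) != n or n < 1 for n in self.group_sizes):
            raise ValueError("every group size must be a positive integer")
        object.__setattr__(self, "group_sizes", tuple(int(n) for n in self.group_sizes))

    @property
    def k(self) -> int:
        return len(self.group_sizes)

    @property
    def n_clusters(self) -> int:
        return sum(self.group_sizes)

    @property
    def label_probs(self) -> np.ndarray:
        return np.asarray(self.group_sizes, dtype=float) / self.n_clusters


@dataclass(frozen=True)
class Assignment:
    """Length-N vector of group labels in 1..k with exact group counts."""

    labels: tuple[int, ...]
    spec: DesignSpec

    def __post_init__(self) -> None:
        counts = np.bincount(self.labels, minlength=self.spec.k + 1)[1:]
        if tuple(counts) != self.spec.group_sizes:
            raise ValueError(
                f"label counts {tuple(counts)} do not match target sizes "
                f"{self.spec.group_sizes}"
            )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)


def urn_randomize(spec: DesignSpec, seed: int | np.random.Generator) -> Assignment:
    """Draw one uniformly random allocation from the urn design."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    urn = np.repeat(np.arange(1, spec.k + 1), spec.group_sizes)
    labels = rng.permutation(urn)
    return Assignment(tuple(int(x) for x in labels), spec)


def permutation_cardinality(spec: DesignSpec) -> int:
    """Exact multinomial cardinality ``N! / prod_j N_j!``."""
    out = math.factorial(spec.n_clusters)
    for nj in spec.group_sizes:
        out //= math.factorial(nj)
    return out


def sigma_matrix(spec: DesignSpec, s2: float) -> np.ndarray:
    """Exact (k-1)x(k-1) permutation covariance of the group totals."""
    sizes = np.asarray(spec.group_sizes[:-1], dtype=float)
    n = spec.n_clusters
    sigma = -np.outer(sizes, sizes) / (n - 1) * s2
    np.fill_diagonal(sigma, sizes * (n - sizes) / (n - 1) * s2)
    return sigma


@dataclass
class TestVector:
    """Group-total vector W (groups 1..k-1) and its exact covariance."""

    w: np.ndarray
    sigma: np.ndarray
    spec: DesignSpec
    s2: float

    @property
    def degenerate(self) -> bool:
        return self.s2 == 0.0


def test_vector(
    c: ClusterScoreVector | np.ndarray,
    assignment: Assignment | np.ndarray,
    spec: DesignSpec,
    *,
    centered_tol: float = 1e-8,
) -> TestVector:
    """Group totals ``W_j = sum_{c in G_j} C_c`` with the exact covariance.

    The cluster scores must be centered (they are by construction of the
    pooled scoring); a non-centered vector is rejected rather than
    silently absorbed.
    """
    scores = c.scores if isinstance(c, ClusterScoreVector) else np.asarray(c, dtype=float)
    labels = assignment.as_array() if isinstance(assignment, Assignment) else np.asarray(assignment)
    if scores.size != spec.n_clusters:
        raise ValueError("number of scores does not match the design")
    scale = max(1.0, float(np.abs(scores).max()))
    if abs(scores.sum()) > centered_tol * scale * scores.size:
        raise ValueError("cluster scores must sum to zero (centered)")
    s2 = float(np.mean(scores**2))
    w = np.array(
        [scores[labels == j].sum() for j in range(1, spec.k)], dtype=float
    )
    return TestVector(w, sigma_matrix(spec, s2), spec, s2)


def quadratic_statistic(tv: TestVector) -> float:
    """Q = W' Sigma^{-1} W via a Cholesky solve (no explicit inverse)."""
    if tv.degenerate:
        raise DegenerateScoresError("all cluster scores are zero; Q undefined")
    try:
        cho = linalg.cho_factor(tv.sigma)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise DegenerateScoresError(f"singular covariance: {exc}") from exc
    return float(tv.w @ linalg.cho_solve(cho, tv.w))


def chisq_pvalue(q: float, df: int) -> float:
    """Upper-tail chi-squared probability with k-1 degrees of freedom."""
    if q < 0:
        raise ValueError("Q must be nonnegative")
    return float(stats.chi2.sf(q, df))


def conventional_statistic(
    c: ClusterScoreVector | np.ndarray,
    assignment: Assignment | np.ndarray,
    spec: DesignSpec,
) -> float:
    """Conventional estimated-variance form ``(N-k) * SSB / SSW``.

    The practical large-sample test treats the cluster scores as an
    i.i.d. sample and estimates their variance from the data: the
    between-group sum of squares over the pooled within-group sum of
    squares, scaled by the within degrees of freedom, referred to
    ``chi2_{k-1}``.  This is a strictly increasing transform of Q
    (``Q = (N-1) SSB / (SSB + SSW)``), so permutation engines built on
    either form are the same test; the chi-squared calibrations differ,
    and it is this estimated-variance form that loses control with few
    clusters per arm (the variance estimate's own noise is ignored).
    """
    scores = c.scores if isinstance(c, ClusterScoreVector) else np.asarray(c, dtype=float)
    labels = assignment.as_array() if isinstance(assignment, Assignment) else np.asarray(assignment)
    n = scores.size
    k = spec.k
    if n <= k:
        raise DegenerateScoresError("need more clusters than groups")
    ssb = 0.0
    for j in range(1, k + 1):
        cj = scores[labels == j]
        ssb += cj.size * float(cj.mean()) ** 2  # grand mean is zero
    sst = float(np.sum(scores**2))
    ssw = sst - ssb
    if ssw <= 0:
        raise DegenerateScoresError("zero within-group variation")
    return (n - k) * ssb / ssw


def conventional_chisq_pvalue(
    c: ClusterScoreVector | np.ndarray,
    assignment: Assignment | np.ndarray,
    spec: DesignSpec,
) -> float:
    """p-value of the conventional large-sample chi-squared analysis."""
    return chisq_pvalue(conventional_statistic(c, assignment, spec), spec.k - 1)


@dataclass
class TestResult:
    """Observed Q, degrees of freedom and the p-values per engine."""

    q_obs: float
    df: int
    p_chisq: float
    p_saddle: float | None = None
    p_midp: float | None = None
    p_exact: float | None = None
    diagnostics: dict = field(default_factory=dict)
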