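"""Test-inversion confidence intervals for relative treatment effects.

For ratio endpoints the effect of group j is a multiplicative factor
``theta_j`` (null value 1): dividing every observation in group j by a
hypothesized ``theta_j`` removes that effect, so the confidence set is
the set of candidates whose adjusted-data k-sample test is not
rejected.  Log-product endpoints use the additive analogue: shifting
the log observations by ``-Delta_j`` (equivalently dividing the
products by ``exp(Delta_j)``); exponentiating the endpoints of the
additive interval returns to the multiplicative scale.

Pairwise inversion is the primary interface: one target group against
a reference, all other groups held at their null value.  Scale and
shift adjustments act on the whole observation (event or censored):
the transform models the observation-time distribution, so censoring
indicators are untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .design import (
    Assignment,
    DesignSpec,
    conventional_chisq_pvalue,
    quadratic_statistic,
    test_vector,
)
from .reference import (
    EnumerationCapError,
    enumerate_null,
    exact_midp,
    monte_carlo_midp,
)
from .saddle import SaddleConfig, saddlepoint_tail
from .scoring import SubjectRecord, scores_from_records

__all__ = [
    "EffectGrid",
    "IntervalResult",
    "adjust_ratio",
    "adjust_logproduct",
    "pvalue_profile",
    "invert",
    "default_ratio_grid",
]


@dataclass(frozen=True)
class EffectGrid:
    """Ordered candidate effects for one target group vs a reference."""

    target_group: int
    reference_group: int
    candidates: tuple[float, ...]
    scale: str = "multiplicative"  # or "additive"

    def __post_init__(self) -> None:
        cand = tuple(float(c) for c in self.candidates)
        if any(b <= a for a, b in zip(cand, cand[1:])):
            raise ValueError("candidates must be strictly increasing")
        if self.scale == "multiplicative" and any(c <= 0 for c in cand):
            raise ValueError("multiplicative candidates must be positive")
        if self.scale not in ("multiplicative", "additive"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not all(np.isfinite(cand)):
            raise ValueError("candidates must be finite")
        object.__setattr__(self, "candidates", cand)


def default_ratio_grid(target_group: int, reference_group: int, n: int = 61) -> EffectGrid:
    """61 log-spaced multiplicative candidates spanning [1/4, 4]."""
    return EffectGrid(
        target_group,
        reference_group,
        tuple(np.exp(np.linspace(np.log(0.25), np.log(4.0), n))),
    )


def adjust_ratio(
    records: Sequence[SubjectRecord], theta: dict[int, float]
) -> list[SubjectRecord]:
    """Divide each group's observed times by its hypothesized multiplier.

    Groups absent from ``theta`` are held at the null value 1.
    """
    for g, th in theta.items():
        if not th > 0:
            raise ValueError(f"multiplier for group {g} must be positive, got {th}")
    out = []
    for r in records:
        th = theta.get(r.group, 1.0)
        out.append(
            SubjectRecord(r.cluster_id, r.group, r.t_obs / th, r.delta, r.components)
        )
    return out


def adjust_logproduct(
    records: Sequence[SubjectRecord], delta: dict[int, float]
) -> list[SubjectRecord]:
    """Shift log-scale observations by ``-Delta_j`` per group.

    Observed times are stored on the positive (product) scale, so the
    shift acts as division by ``exp(Delta_j)``.
    """
    if any(not np.isfinite(v) for v in delta.values()):
        raise ValueError("shifts must be finite")
    return adjust_ratio(records, {g: float(np.exp(v)) for g, v in delta.items()})


@dataclass
class ProfilePoint:
    candidate: float
    p_value: float | None
    error: str | None = None


@dataclass
class IntervalResult:
    """Inverted-test interval with the full (candidate, p-value) profile."""

    lower: float
    upper: float
    alpha: float
    profile: list[ProfilePoint]
    engine: str
    scale: str
    disconnected: list[float] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def _engine_pvalue(
    records: Sequence[SubjectRecord],
    assignment: Assignment,
    spec: DesignSpec,
    scheme: str,
    engine: str,
    *,
    mc_b: int = 2000,
    mc_seed: int = 0,
    enumeration_cap: int = 200_000,
    saddle_config: SaddleConfig | None = None,
) -> float:
    c = scores_from_records(records, scheme)
    tv = test_vector(c, assignment, spec)
    if tv.degenerate:
        return 1.0
    q = quadratic_statistic(tv)
    if engine == "chisq":
        # conventional estimated-variance chi-squared analysis
        return conventional_chisq_pvalue(c, assignment, spec)
    if engine == "saddlepoint":
        return saddlepoint_tail(c, spec, q, saddle_config).tail
    if engine == "exact":
        null = enumerate_null(c.scores, spec, cap=enumeration_cap)
        return exact_midp(null, q)
    if engine == "midp_mc":
        est, _ = monte_carlo_midp(c.scores, spec, q, mc_b, mc_seed)
        return est
    raise ValueError(f"unknown engine {engine!r}")


def pvalue_profile(
    records: Sequence[SubjectRecord],
    assignment: Assignment,
    spec: DesignSpec,
    grid: EffectGrid,
    *,
    scheme: str = "logrank",
    engine: str = "saddlepoint",
    mc_b: int = 2000,
    seed: int = 0,
    saddle_config: SaddleConfig | None = None,
) -> list[ProfilePoint]:
    """p-value at every candidate effect (target group adjusted only).

    The Monte Carlo engine reuses one seed across candidates so the
    profile is a deterministic function of (data, grid, seed).
    """
    profile: list[ProfilePoint] = []
    for cand in grid.candidates:
        if grid.scale == "multiplicative":
            adjusted = adjust_ratio(records, {grid.target_group: cand})
        else:
            adjusted = adjust_logproduct(records, {grid.target_group: cand})
        try:
            p = _engine_pvalue(
                adjusted,
                assignment,
                spec,
                scheme,
                engine,
                mc_b=mc_b,
                mc_seed=seed,
                saddle_config=saddle_config,
            )
            profile.append(ProfilePoint(cand, p))
        except (EnumerationCapError, ValueError, RuntimeError) as exc:
            profile.append(ProfilePoint(cand, None, error=str(exc)))
    return profile


def invert(
    profile: Sequence[ProfilePoint],
    alpha: float,
    *,
    refine: Callable[[float], float] | None = None,
    rel_tol: float = 1e-3,
    scale: str = "multiplicative",
    engine: str = "saddlepoint",
    exponentiate: bool = False,
) -> IntervalResult:
    """Interval = connected accepted set around the maximal-p candidate.

    Rank-statistic profiles can be locally non-monotone; any accepted
    candidates outside the chosen connected component are reported in
    ``disconnected`` with a warning.  With ``refine`` (a callable
    candidate -> p-value) the endpoints are sharpened by bisection
    between the outermost accepted and first rejected candidates.
    """
    pts = [p for p in profile if p.p_value is not None]
    if not pts:
        raise ValueError("profile has no evaluable candidates")
    accepted = [p.candidate for p in pts if p.p_value > alpha]
    if not accepted:
        raise ValueError(
            "no candidate accepted at this level; widen the candidate grid"
        )
    best = max(pts, key=lambda p: p.p_value)
    cands = [p.candidate for p in pts]
    acc_mask = [p.p_value > alpha for p in pts]
    i_best = cands.index(best.candidate)
    lo_i = i_best
    while lo_i > 0 and acc_mask[lo_i - 1]:
        lo_i -= 1
    hi_i = i_best
    while hi_i < len(cands) - 1 and acc_mask[hi_i + 1]:
        hi_i += 1
    component = set(cands[lo_i : hi_i + 1])
    disconnected = [c for c, a in zip(cands, acc_mask) if a and c not in component]
    if disconnected:
        warnings.warn(
            f"accepted candidates outside the reported interval: {disconnected}",
            stacklevel=2,
        )
    lower, upper = cands[lo_i], cands[hi_i]
    if refine is not None:
        if lo_i > 0:
            lower = _bisect_endpoint(refine, cands[lo_i - 1], lower, alpha, rel_tol, scale)
        if hi_i < len(cands) - 1:
            upper = _bisect_endpoint(refine, cands[hi_i + 1], upper, alpha, rel_tol, scale)
    if exponentiate:
        lower, upper = float(np.exp(lower)), float(np.exp(upper))
    return IntervalResult(
        lower=float(lower),
        upper=float(upper),
        alpha=alpha,
        profile=list(profile),
        engine=engine,
        scale=scale,
        disconnected=disconnected,
    )


def _bisect_endpoint(pfun, rejected, accepted, alpha, rel_tol, scale) -> float:
    """Bisect between a rejected and an accepted candidate."""
    for _ in range(60):
        if scale == "multiplicative":
            mid = float(np.sqrt(rejected * accepted))
            if abs(np.log(rejected / accepted)) < rel_tol:
                break
        else:
            mid = 0.5 * (rejected + accepted)
            if abs(rejected - accepted) < rel_tol * max(1.0, abs(accepted)):
                break
        if pfun(mid) > alpha:
            accepted = mid
        else:
            rejected = mid
    return float(accepted)
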