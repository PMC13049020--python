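"""Readers, writers and the orchestration layer behind the CLI.

Input is a delimited text table (comma-separated, header row) with a
``cluster`` and ``group`` column plus either an observed ``time`` and
``status`` (1 = event, 0 = censored) or positive component columns
``comp1..compP`` from which a ratio (P = 2) or product endpoint is
derived; a missing ``status`` column with component input defaults to
all events.  Group labels are mapped to 1..k in first-appearance
order and the mapping is reported back.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .design import (
    Assignment,
    DesignSpec,
    TestResult,
    chisq_pvalue,
    quadratic_statistic,
    test_vector,
)
from .reference import (
    DEFAULT_ENUMERATION_CAP,
    enumerate_null,
    exact_midp,
    monte_carlo_midp,
    permutation_cardinality,
)
from .saddle import SaddleConfig, saddlepoint_tail
from .scoring import (
    SubjectRecord,
    derive_logproduct_endpoint,
    derive_ratio_endpoint,
    scores_from_records,
)

logger = logging.getLogger("saddleperm")

__all__ = ["RunConfig", "read_subject_table", "write_subject_table", "run_test",
           "run_invert", "run_simulate", "result_to_json"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for one CLI run; embedded in every result file."""

    endpoint: str = "time"  # time | ratio | product
    weight: str = "logrank"
    engines: tuple[str, ...] = ("chisq", "saddlepoint")
    alpha: float = 0.05
    mc_b: int = 2000
    seed: int = 0
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP
    auto_exact_cap: int = 50_000
    target_group: int = 1
    reference_group: int | None = None
    grid_lo: float = 0.25
    grid_hi: float = 4.0
    grid_points: int = 61
    scenario: int = 1
    reps: int = 2000
    saddle: SaddleConfig = field(default_factory=SaddleConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = _pkg_version
        return d


class ValidationError(ValueError):
    """Malformed input table (maps to CLI exit code 2)."""


def read_subject_table(
    source, endpoint: str = "time"
) -> tuple[list[SubjectRecord], dict]:
    """Parse and validate a subject table; returns records + group map."""
    df = pd.read_csv(source)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("cluster", "group"):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    comp_cols = sorted(
        (c for c in df.columns if c.startswith("comp") and c[4:].isdigit()),
        key=lambda c: int(c[4:]),
    )
    group_map: dict = {}
    records: list[SubjectRecord] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        rowd = dict(zip(df.columns, row))
        glabel = rowd["group"]
        if glabel not in group_map:
            group_map[glabel] = len(group_map) + 1
        status = rowd.get("status", 1)
        if status not in (0, 1):
            raise ValidationError(
                f"row {row_number}: status must be 0 or 1, got {status!r}"
            )
        try:
            if endpoint == "time":
                if "time" not in rowd:
                    raise ValidationError("missing required column 'time'")
                t_obs = float(rowd["time"])
                components = None
            else:
                if endpoint == "ratio":
                    use = comp_cols[:2]
                    if len(use) < 2:
                        raise ValidationError(
                            "ratio endpoint requires columns comp1 and comp2"
                        )
                else:
                    use = comp_cols
                    if len(use) < 1:
                        raise ValidationError(
                            "product endpoint requires comp1..compP columns"
                        )
                components = tuple(float(rowd[c]) for c in use)
                if endpoint == "ratio":
                    t_obs = derive_ratio_endpoint(*components)
                else:
                    t_obs = float(np.exp(derive_logproduct_endpoint(components)))
            record = SubjectRecord(
                rowd["cluster"], group_map[glabel], t_obs, int(status), components
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"row {row_number}: {exc}") from exc
        records.append(record)
    if not records:
        raise ValidationError("empty input table")
    return records, {"group_map": group_map, "endpoint": endpoint}


def write_subject_table(records: list[SubjectRecord], path) -> None:
    rows = []
    for r in records:
        row = {"cluster": r.cluster_id, "group": r.group,
               "time": r.t_obs, "status": r.delta}
        if r.components is not None:
            for i, x in enumerate(r.components, start=1):
                row[f"comp{i}"] = x
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def design_from_records(records: list[SubjectRecord]) -> tuple[DesignSpec, Assignment]:
    """Cluster-level design implied by the table (clusters are the units)."""
    cluster_group: dict = {}
    for r in records:
        prev = cluster_group.setdefault(r.cluster_id, r.group)
        if prev != r.group:
            raise ValidationError(
                f"cluster {r.cluster_id!r} appears in groups {prev} and {r.group}; "
                "clusters are the randomization units and must be nested in groups"
            )
    labels = tuple(cluster_group.values())
    k = max(labels)
    sizes = tuple(int(np.sum(np.asarray(labels) == j)) for j in range(1, k + 1))
    spec = DesignSpec(sizes)
    return spec, Assignment(labels, spec)


def run_test(records: list[SubjectRecord], config: RunConfig) -> TestResult:
    """Score the table and evaluate every requested p-value engine."""
    spec, assignment = design_from_records(records)
    c = scores_from_records(records, config.weight)
    tv = test_vector(c, assignment, spec)
    df = spec.k - 1
    if tv.degenerate:
        return TestResult(0.0, df, 1.0, diagnostics={"degenerate": True})
    q = quadratic_statistic(tv)
    # headline chi-squared = the conventional estimated-variance analysis
    # (what a standard large-sample workflow reports); the upper tail of
    # Q itself against chi2_{k-1} is kept in the diagnostics
    from .design import conventional_chisq_pvalue

    result = TestResult(q, df, conventional_chisq_pvalue(c, assignment, spec))
    result.diagnostics["p_chisq_exact_sigma"] = chisq_pvalue(q, df)
    engines = set(config.engines)
    card = permutation_cardinality(spec)
    if "exact" in engines or ("auto" in engines and card <= config.auto_exact_cap):
        null = enumerate_null(c.scores, spec, cap=config.enumeration_cap)
        result.p_exact = exact_midp(null, q)
        result.diagnostics["cardinality"] = card
    if "saddlepoint" in engines or "auto" in engines:
        sp = saddlepoint_tail(c, spec, q, config.saddle)
        result.p_saddle = sp.tail
        result.diagnostics["saddlepoint"] = {
            "mid_p": sp.mid_p,
            "t_hat": sp.t_hat,
            "r": sp.r,
            "u": sp.u,
            "p_lugannani_rice": sp.p_lugannani_rice,
            "converged": sp.converged,
            **sp.diagnostics,
        }
    if "midp" in engines:
        est, se = monte_carlo_midp(c.scores, spec, q, config.mc_b, config.seed)
        result.p_midp = est
        result.diagnostics["midp_se"] = se
    return result


def run_invert(records: list[SubjectRecord], config: RunConfig):
    """Pairwise test-inversion interval for the configured target group."""
    from .inversion import EffectGrid, invert, pvalue_profile

    spec, assignment = design_from_records(records)
    reference = config.reference_group or spec.k
    scale = "additive" if config.endpoint == "product" else "multiplicative"
    if scale == "multiplicative":
        cands = tuple(
            np.exp(np.linspace(np.log(config.grid_lo), np.log(config.grid_hi),
                               config.grid_points))
        )
    else:
        span = np.log(config.grid_hi)
        cands = tuple(np.linspace(-span, span, config.grid_points))
    grid = EffectGrid(config.target_group, reference, cands, scale)
    engine = next(
        (e for e in config.engines if e in ("saddlepoint", "exact", "midp_mc", "chisq")),
        "saddlepoint",
    )
    profile = pvalue_profile(
        records, assignment, spec, grid,
        scheme=config.weight, engine=engine,
        mc_b=config.mc_b, seed=config.seed, saddle_config=config.saddle,
    )
    return invert(profile, config.alpha, scale=scale, engine=engine)


def run_simulate(config: RunConfig, engines=("chisq", "saddlepoint", "midp")):
    """Type I error experiment for one registry scenario."""
    from .simulate import get_scenario, type1_error_experiment

    scenario = get_scenario(config.scenario)
    result = type1_error_experiment(
        scenario,
        reps=config.reps,
        engines=engines,
        seed=config.seed,
        alpha=config.alpha,
        mc_b=config.mc_b,
        saddle_config=config.saddle,
    )
    return result


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def result_to_json(result, config: RunConfig, extra: dict | None = None) -> str:
    payload = {"config": config.to_dict(), "result": _jsonable(result)}
    if extra:
        payload.update(_jsonable(extra))
    return json.dumps(_jsonable(payload), indent=2, default=str)


def write_result(result, config: RunConfig, path, extra: dict | None = None) -> None:
    Path(path).write_text(result_to_json(result, config, extra))
    logger.info("wrote %s", path)
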