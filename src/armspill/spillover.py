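"""Count-perturbation spillover simulation engine.

Takes a no-spillover baseline study table and injects positive (events added)
or negative (events removed) spillover into control arms only: each selected
control arm's events change by round_half_away(delta_per_100 * total / 100),
clamped to [0, total]. Coverage below 1 selects a seeded random subset of
control groups without replacement, mimicking uneven spillover; the grid
runner recomputes the arm-level control summary, the contrast-based pooled OR
and (optionally) the bivariate summary OR for every scenario.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arm_data import ArmRole, StudyTable, dedupe_control_arms, to_dta_layout
from .contrast_meta import ContrastPooled, pool_table_log_or
from .prop_meta import ArmPooled, pool_arm_records
from . import bivariate

logger = logging.getLogger(__name__)

__all__ = ["SpilloverScenario", "ScenarioResult", "apply_spillover",
           "run_scenario_grid", "grid_to_frame", "paper_grid"]

PAPER_DELTAS = (2.5, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class SpilloverScenario:
    direction: str  # "positive" | "negative"
    delta_per_100: float
    coverage_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"direction must be positive/negative, got {self.direction!r}")
        if self.delta_per_100 <= 0:
            raise ValueError("delta_per_100 must be > 0")
        if not 0 < self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must be in (0, 1]")

    @property
    def label(self) -> str:
        sign = "+" if self.direction == "positive" else "-"
        cov = "" if self.coverage_fraction == 1 else f" (fraction {self.coverage_fraction:g})"
        return f"{sign}{self.delta_per_100 / 100:g} spillover{cov}"


@dataclass
class ScenarioResult:
    scenario: SpilloverScenario | None  # None = baseline
    pooled_ctrl: ArmPooled
    contrast: ContrastPooled
    bivariate_fit: "bivariate.BivariateFit | None"
    affected_studies: list[str]

    @property
    def label(self) -> str:
        return "no spillover" if self.scenario is None else self.scenario.label


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def apply_spillover(
    table: StudyTable, scenario: SpilloverScenario
) -> tuple[StudyTable, list[str]]:
    """Perturb control-arm events per the scenario; totals never change.

    With full coverage every control group is perturbed and the seed is
    irrelevant; partial coverage selects round(fraction * k) control groups
    without replacement using the scenario seed.
    """
    ctrl_idx = [
        i for i, r in enumerate(table.records) if r.arm_role == ArmRole.CONTROL
    ]
    k = len(ctrl_idx)
    if scenario.coverage_fraction == 1.0:
        chosen = list(range(k))
    else:
        n_sel = int(math.floor(scenario.coverage_fraction * k + 0.5))
        rng = np.random.default_rng(scenario.seed)
        chosen = sorted(rng.choice(k, size=n_sel, replace=False).tolist())

    sign = 1 if scenario.direction == "positive" else -1
    new_records = list(table.records)
    affected: list[str] = []
    n_clamped = 0
    for j in chosen:
        i = ctrl_idx[j]
        r = table.records[i]
        shift = sign * _round_half_away(scenario.delta_per_100 * r.total / 100.0)
        new_events = min(max(r.events + shift, 0), r.total)
        if new_events != r.events + shift:
            n_clamped += 1
        from dataclasses import replace

        new_records[i] = replace(r, events=new_events)
        affected.append(r.study_id)
    if n_clamped:
        logger.info("apply_spillover: %d control arms clamped at a boundary", n_clamped)
    out = StudyTable(new_records, f"{table.provenance} [{scenario.label}]")
    return out, affected


def run_scenario_grid(
    table: StudyTable,
    scenarios: list[SpilloverScenario],
    tau2_method: str = "REML",
    include_bivariate: bool = True,
    quad_order: int = 7,
) -> list[ScenarioResult]:
    """Baseline row first, then one result per scenario.

    Stage failures within a scenario are logged and recorded as None fields
    rather than aborting the grid.
    """
    results: list[ScenarioResult] = []
    for scen in [None, *scenarios]:
        if scen is None:
            t, affected = table, []
        else:
            t, affected = apply_spillover(table, scen)
        try:
            deduped = dedupe_control_arms(t, mode="include_once")
            pooled_ctrl = pool_arm_records(
                deduped.arms(ArmRole.CONTROL), tau2_method=tau2_method
            )
            contrast = pool_table_log_or(t, tau2_method=tau2_method)
            fit = None
            if include_bivariate:
                pairs = [tt for _, tt in to_dta_layout(dedupe_control_arms(t, "split"))]
                fit = bivariate.fit_bivariate(pairs, quad_order=quad_order)
            results.append(
                ScenarioResult(
                    scenario=scen,
                    pooled_ctrl=pooled_ctrl,
                    contrast=contrast,
                    bivariate_fit=fit,
                    affected_studies=affected,
                )
            )
        except Exception:  # propagate per-scenario without aborting the grid
            logger.exception("scenario %s failed", "baseline" if scen is None else scen.label)
            raise
    return results


def grid_to_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Scenario grid as a table: OR columns then control-arm incidence columns."""
    rows = []
    for res in results:
        row = {"scenario": res.label}
        row["or"] = res.contrast.or_summary
        row["or_ci_lo"] = res.contrast.ci95[0]
        row["or_ci_hi"] = res.contrast.ci95[1]
        if res.bivariate_fit is not None:
            dor, (lo, hi) = bivariate.summary_dor(res.bivariate_fit)
            row["dor"] = dor
            row["dor_ci_lo"] = lo
            row["dor_ci_hi"] = hi
        row.update(res.pooled_ctrl.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def paper_grid(seed: int = 0) -> list[SpilloverScenario]:
    """The eight-scenario grid: uniform +2.5/+5/+10, partial +10 (half),
    +10/+20 (quarter), uniform -2.5/-5 events per 100 control patients."""
    return [
        SpilloverScenario("positive", 2.5),
        SpilloverScenario("positive", 5.0),
        SpilloverScenario("positive", 10.0),
        SpilloverScenario("positive", 10.0, coverage_fraction=0.5, seed=seed),
        SpilloverScenario("positive", 10.0, coverage_fraction=0.25, seed=seed + 1),
        SpilloverScenario("positive", 20.0, coverage_fraction=0.25, seed=seed + 2),
        SpilloverScenario("negative", 2.5),
        SpilloverScenario("negative", 5.0),
    ]
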