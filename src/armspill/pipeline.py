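"""Full-analysis orchestration: generate or ingest data, run both frameworks,
perturb, diagnose, and plot — reproducibly from one seed."""

from __future__ import annotations

import json
import logging
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .arm_data import (
    ArmRole,
    StudyTable,
    dedupe_control_arms,
    read_arm_table,
    to_dta_layout,
    write_arm_table,
)
from .bivariate import fit_bivariate, summary_dor
from .cohort import CohortSpec, default_paper_specs, generate_cohort
from .contrast_meta import pool_table_log_or
from .diagnose import (
    BenchmarkRange,
    CONSERVATIVE_RANGE,
    DiagnosisThresholds,
    LIBERAL_RANGE,
    diagnose_spillover,
)
from .plots import PlotSpec, plot_caterpillar, plot_sroc
from .prop_meta import arm_summary_table, pool_arm_records
from .spillover import SpilloverScenario, grid_to_frame, paper_grid, run_scenario_grid

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "stage_seed", "load_config"]

_BENCHMARKS = {"liberal": LIBERAL_RANGE, "conservative": CONSERVATIVE_RANGE}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived by hashing the stage name."""
    return (zlib.crc32(stage.encode()) ^ global_seed) % (2**31)


@dataclass
class RunConfig:
    input: str = "synthetic"  # path to an arm CSV, or "synthetic"
    categories: list[str] = field(
        default_factory=lambda: [
            "non_antimicrobial",
            "antimicrobial",
            "antimicrobial_duplex",
        ]
    )
    tau2_method: str = "REML"
    quad_order: int = 7
    ellipse_scaling: str = "chi2"
    benchmark: str = "liberal"
    thresholds: DiagnosisThresholds = field(default_factory=DiagnosisThresholds)
    spillover_grid: bool = True
    spillover_bivariate: bool = False
    seed: int = 0
    output_dir: str = "armspill_run"
    cohort_specs: dict[str, CohortSpec] | None = None

    def __post_init__(self) -> None:
        if self.benchmark not in _BENCHMARKS:
            raise ValueError(f"unknown benchmark label {self.benchmark!r}")
        valid = {"non_antimicrobial", "antimicrobial", "antimicrobial_duplex"}
        unknown = set(self.categories) - valid
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON — YAML is a superset) run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "thresholds" in raw and isinstance(raw["thresholds"], dict):
        raw["thresholds"] = DiagnosisThresholds(**raw["thresholds"])
    if "cohort_specs" in raw and isinstance(raw["cohort_specs"], dict):
        raw["cohort_specs"] = {
            k: CohortSpec.from_dict(v) for k, v in raw["cohort_specs"].items()
        }
    return RunConfig(**raw)


def _get_table(config: RunConfig) -> StudyTable:
    if config.input != "synthetic":
        return read_arm_table(config.input)
    specs = config.cohort_specs or default_paper_specs(
        seed=stage_seed(config.seed, "cohort")
    )
    records = []
    for cat in config.categories:
        table, _ = generate_cohort(specs[cat])
        records.extend(table.records)
    return StudyTable(records, provenance=f"synthetic run, seed {config.seed}")


def run_full_analysis(config: RunConfig) -> Path:
    """Run the whole analysis; returns the report directory.

    Outputs: table1.csv (contrast OR + bivariate DOR per category),
    table2.csv (arm-level pooled incidence summaries), table3.csv (spillover
    scenario grid), diagnosis.json, figures/, data.csv, run.log.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("armspill")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("armspill %s | python %s | seed %d", __version__,
                    sys.version.split()[0], config.seed)
        logger.info("config: %r", config)

        table = _get_table(config)
        write_arm_table(table, outdir / "data.csv")
        benchmark = _BENCHMARKS[config.benchmark]

        # --- table 1: contrast OR and bivariate DOR per category
        rows = []
        fits = {}
        for cat in config.categories:
            sub = table.subset(cat)
            if not sub.records:
                logger.warning("category %s empty; skipped", cat)
                continue
            contrast = pool_table_log_or(sub, tau2_method=config.tau2_method)
            pairs = [tt for _, tt in to_dta_layout(dedupe_control_arms(sub, "split"))]
            fit = fit_bivariate(pairs, quad_order=config.quad_order)
            fits[cat] = fit
            dor, (dlo, dhi) = summary_dor(fit)
            rows.append({
                "category": cat,
                **contrast.as_dict(),
                "dor": dor,
                "dor_ci_lo": dlo,
                "dor_ci_hi": dhi,
                "bivariate_converged": fit.converged,
            })
        pd.DataFrame(rows).to_csv(outdir / "table1.csv", index=False)

        # --- table 2: arm-level summaries
        deduped = dedupe_control_arms(table, mode="include_once")
        arm_summary_table(deduped, grouping="category",
                          tau2_method=config.tau2_method).to_csv(
            outdir / "table2.csv", index=False
        )

        # --- table 3: spillover grid on the reference (no-spillover) category
        if config.spillover_grid and "non_antimicrobial" in config.categories:
            base = table.subset("non_antimicrobial")
            grid = run_scenario_grid(
                base,
                paper_grid(seed=stage_seed(config.seed, "spillover")),
                tau2_method=config.tau2_method,
                include_bivariate=config.spillover_bivariate,
                quad_order=config.quad_order,
            )
            grid_to_frame(grid).to_csv(outdir / "table3.csv", index=False)

        # --- diagnosis of the antimicrobial category
        diag_out = {}
        if "antimicrobial" in config.categories:
            target = deduped.subset("antimicrobial")
            ctrl = pool_arm_records(target.arms(ArmRole.CONTROL),
                                    tau2_method=config.tau2_method)
            inter = pool_arm_records(target.arms(ArmRole.INTERVENTION),
                                     tau2_method=config.tau2_method)
            ref_ctrl = None
            if "non_antimicrobial" in config.categories:
                ref = deduped.subset("non_antimicrobial")
                ref_ctrl = pool_arm_records(ref.arms(ArmRole.CONTROL),
                                            tau2_method=config.tau2_method)
            report = diagnose_spillover(
                ctrl, inter, ref_ctrl, range_=benchmark,
                thresholds=config.thresholds, category="antimicrobial",
                ctrl_arms=target.arms(ArmRole.CONTROL),
                int_arms=target.arms(ArmRole.INTERVENTION),
            )
            diag_out = json.loads(report.to_json())
            logger.info("diagnosis verdict: %s", report.verdict)
        (outdir / "diagnosis.json").write_text(json.dumps(diag_out, indent=2))

        # --- figures
        for cat, fit in fits.items():
            sub = dedupe_control_arms(table.subset(cat), "split")
            plot_sroc(fit, sub, PlotSpec(
                benchmark=benchmark, output_path=figdir / f"sroc_{cat}"
            ))
            plot_caterpillar(
                table.subset(cat).arms(ArmRole.CONTROL),
                figdir / f"caterpillar_control_{cat}",
                benchmark=benchmark,
            )
        logger.info("run complete: %s", outdir)
        return outdir
    finally:
        root.removeHandler(handler)
        handler.close()
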