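"""Replicated simulation studies built from the package's own pieces.

These are the standing experiments the package uses to validate itself and to
characterise the diagnostic method's operating behaviour:

* a parameter-recovery / ellipse-coverage study for the bivariate model;
* a spillover-grid demonstration of how injected spillover moves the pooled
  OR and the control-arm summary;
* a discrimination study for the three-comparator diagnosis, classifying
  no-spillover (condition c) versus uneven harmful spillover (condition f)
  cohorts over many seeded replicates.

Both the test suite and the acceptance script drive these functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .arm_data import ArmRole, dedupe_control_arms, to_dta_layout
from .bivariate import fit_bivariate
from .cohort import CohortSpec, generate_cohort
from .diagnose import (
    DiagnosisThresholds,
    LIBERAL_RANGE,
    diagnose_spillover,
)
from .prop_meta import pool_arm_records
from .spillover import SpilloverScenario, grid_to_frame, run_scenario_grid

__all__ = [
    "RecoveryResult",
    "recovery_spec",
    "run_recovery_study",
    "discrimination_specs",
    "run_discrimination_study",
    "run_spillover_demo",
]


def recovery_spec(seed: int = 0, k: int = 60) -> CohortSpec:
    """Condition-c cohort used for bivariate parameter recovery.

    Sizes match the non-antimicrobial collection (log-normal, median 44,
    IQR 28-71); control incidence centres on 23% with tau 0.8 on the logit
    scale, intervention log OR centres on ln 0.82 with tau 0.49, rho -0.35.
    """
    return CohortSpec(
        k_studies=k,
        size_log_median=math.log(44),
        size_log_sd=(math.log(71) - math.log(28)) / (2 * 0.6744897501960817),
        mu_ctrl=math.log(0.23 / 0.77),
        tau_ctrl=0.80,
        mu_logor=math.log(0.82),
        tau_logor=0.49,
        rho=-0.35,
        condition="c",
        seed=seed,
        label="non_antimicrobial",
    )


@dataclass
class RecoveryResult:
    n_reps: int
    true_mu_I: float
    true_mu_C: float
    true_sigma_I: float
    true_sigma_C: float
    mu_I_hat: np.ndarray
    mu_C_hat: np.ndarray
    sigma_I_hat: np.ndarray
    sigma_C_hat: np.ndarray
    covered: np.ndarray  # confidence region covers the true means

    @property
    def coverage_pct(self) -> float:
        return 100.0 * float(np.mean(self.covered))

    def bias_in_mc_se(self, name: str) -> float:
        """Bias of the mean estimate, in units of its Monte-Carlo SE."""
        est = getattr(self, f"{name}_hat")
        true = getattr(self, f"true_{name}")
        se = np.std(est, ddof=1) / math.sqrt(len(est))
        return float((np.mean(est) - true) / se)


def run_recovery_study(
    n_reps: int = 100, seed: int = 1, k: int = 60, quad_order: int = 7
) -> RecoveryResult:
    """Fit the bivariate model to replicate condition-c cohorts.

    The generating truth on the intervention side is the marginal distribution
    of eta_I = eta_C + logOR: mean mu_ctrl + mu_logor, variance
    tau_ctrl^2 + tau_logor^2 + 2 rho tau_ctrl tau_logor.
    """
    base = recovery_spec(seed=seed, k=k)
    true_mu_C = base.mu_ctrl
    true_mu_I = base.mu_ctrl + base.mu_logor
    true_sigma_C = base.tau_ctrl
    true_sigma_I = math.sqrt(
        base.tau_ctrl**2
        + base.tau_logor**2
        + 2 * base.rho * base.tau_ctrl * base.tau_logor
    )
    chi2_95 = stats.chi2.ppf(0.95, 2)

    muI, muC, sI, sC, cov = [], [], [], [], []
    for r in range(n_reps):
        spec = replace(base, seed=seed + 1000 + r)
        table, _ = generate_cohort(spec)
        pairs = [tt for _, tt in to_dta_layout(table)]
        fit = fit_bivariate(pairs, quad_order=quad_order)
        muI.append(fit.mu_I)
        muC.append(fit.mu_C)
        sI.append(fit.sigma_I)
        sC.append(fit.sigma_C)
        d = np.array([fit.mu_I - true_mu_I, fit.mu_C - true_mu_C])
        md2 = float(d @ np.linalg.solve(fit.vcov_fixed, d))
        cov.append(md2 <= chi2_95)
    return RecoveryResult(
        n_reps=n_reps,
        true_mu_I=true_mu_I,
        true_mu_C=true_mu_C,
        true_sigma_I=true_sigma_I,
        true_sigma_C=true_sigma_C,
        mu_I_hat=np.array(muI),
        mu_C_hat=np.array(muC),
        sigma_I_hat=np.array(sI),
        sigma_C_hat=np.array(sC),
        covered=np.array(cov),
    )


def discrimination_specs(seed: int = 0) -> tuple[CohortSpec, CohortSpec, CohortSpec]:
    """(condition-c target, condition-f target, reference) cohort specs.

    Operating conditions for the discrimination study, fixed by a
    simulation-based power calibration at the design stage: k=150 trials,
    group sizes log-normal median 120 (log-sd 0.8), control incidence centred
    on 25% with the moderate baseline heterogeneity of a homogeneous trial
    subcategory (tau_ctrl 0.2), intervention OR centred on 0.6 (tau_logOR 0.3,
    rho -0.78, which places the intervention-arm logit variance between the
    spilled and unspilled control-arm variances so both tau^2 ratios have
    symmetric margins). Condition f injects +10 events per 100 control
    patients into half the trials. The reference is an independent
    ineffective-intervention cohort (condition b) sharing the
    control-incidence process.
    """
    common = dict(
        k_studies=150,
        size_log_median=math.log(120),
        size_log_sd=0.8,
        mu_ctrl=math.log(0.25 / 0.75),
        tau_ctrl=0.2,
        mu_logor=math.log(0.6),
        tau_logor=0.3,
        rho=-0.78,
    )
    target_c = CohortSpec(condition="c", seed=seed, label="antimicrobial", **common)
    target_f = CohortSpec(
        condition="f",
        spill_delta_per_100=10.0,
        spill_fraction=0.5,
        seed=seed,
        label="antimicrobial",
        **common,
    )
    reference = CohortSpec(
        condition="b", seed=seed + 7, label="non_antimicrobial", **common
    )
    return target_c, target_f, reference


def _diagnose_cohort(spec: CohortSpec, ref_spec: CohortSpec) -> str:
    table, _ = generate_cohort(spec)
    ref_table, _ = generate_cohort(ref_spec)
    ctrl = pool_arm_records(table.arms(ArmRole.CONTROL))
    inter = pool_arm_records(table.arms(ArmRole.INTERVENTION))
    ref_ctrl = pool_arm_records(ref_table.arms(ArmRole.CONTROL))
    report = diagnose_spillover(
        ctrl, inter, ref_ctrl, range_=LIBERAL_RANGE,
        thresholds=DiagnosisThresholds(), category=spec.label,
    )
    return report.verdict


def run_discrimination_study(n_reps: int = 100, seed: int = 1) -> dict[str, float]:
    """Verdict rates (%) over replicate condition-c and condition-f cohorts."""
    c_correct = f_correct = 0
    for r in range(n_reps):
        # stride keeps each replicate's reference seed (base + 7) from
        # colliding with another replicate's target seed
        spec_c, spec_f, ref = discrimination_specs(seed=seed + 5000 + 13 * r)
        if _diagnose_cohort(spec_c, ref) == "no_spillover":
            c_correct += 1
        if _diagnose_cohort(spec_f, ref) == "consistent_with_harmful":
            f_correct += 1
    return {
        "no_spillover_rate_pct": 100.0 * c_correct / n_reps,
        "harmful_rate_pct": 100.0 * f_correct / n_reps,
        "n_reps": n_reps,
    }


def run_spillover_demo(seed: int = 1, include_bivariate: bool = False):
    """Apply the uniform +/- spillover ladder to one fixed condition-c cohort.

    Returns the scenario grid as a DataFrame (baseline row first).
    """
    spec = recovery_spec(seed=seed, k=115)
    table, _ = generate_cohort(spec)
    scenarios = [
        SpilloverScenario("positive", 2.5),
        SpilloverScenario("positive", 5.0),
        SpilloverScenario("positive", 10.0),
        SpilloverScenario("negative", 2.5),
        SpilloverScenario("negative", 5.0),
    ]
    results = run_scenario_grid(
        table, scenarios, include_bivariate=include_bivariate
    )
    return grid_to_frame(results)
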