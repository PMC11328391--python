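"""Three-comparator spillover diagnosis.

Spillover onto concurrent control groups cannot be seen in a contrast-based
summary; it shows up as excess dispersion of the control-arm incidences. The
diagnosis combines three comparisons of the (arm-based) pooled control
incidence of a target trial category:

1. against the corresponding intervention arms (same category);
2. against the control arms of trials of an ineffective intervention
   (the reference category);
3. against a clinically relevant benchmark incidence range.

The default decision rule (configurable, echoed in the report): call
*consistent_with_harmful* when the control tau^2 exceeds the intervention
tau^2 by more than ``ratio_vs_int`` AND exceeds the reference-control tau^2 by
more than ``ratio_vs_ref`` AND the control 95% prediction interval reaches
above the benchmark range; *consistent_with_beneficial* under the mirrored
conditions below the range; *indeterminate* when the dispersion criteria fire
but the prediction interval stays inside the range; otherwise *no_spillover*.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

from .arm_data import ArmRecord
from .prop_meta import ArmPooled

__all__ = [
    "BenchmarkRange",
    "DiagnosisThresholds",
    "DiagnosisReport",
    "range_coverage",
    "dispersion_comparison",
    "diagnose_spillover",
    "LIBERAL_RANGE",
    "CONSERVATIVE_RANGE",
]


@dataclass(frozen=True)
class BenchmarkRange:
    """A clinically relevant incidence range, closed at both ends."""

    lo: float
    hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi < 1:
            raise ValueError("need 0 < lo < hi < 1")


LIBERAL_RANGE = BenchmarkRange(0.05, 0.40, "liberal")
CONSERVATIVE_RANGE = BenchmarkRange(0.08, 0.28, "conservative")


@dataclass(frozen=True)
class DiagnosisThresholds:
    ratio_vs_int: float = 1.5
    ratio_vs_ref: float = 1.2


@dataclass
class DiagnosisReport:
    category: str
    tau2_ratio_ctrl_vs_int: float
    tau2_ratio_ctrl_vs_reference: float | None
    pi_exceeds_benchmark: bool
    pi_below_benchmark: bool
    range_counts: dict[str, tuple[int, int, int]]
    verdict: str
    condition_label: str | None
    narrative: str
    thresholds: DiagnosisThresholds
    benchmark: BenchmarkRange

    def to_json(self) -> str:
        d = asdict(self)
        # inf is not valid JSON; serialise as a string marker
        for key in ("tau2_ratio_ctrl_vs_int", "tau2_ratio_ctrl_vs_reference"):
            if d[key] is not None and math.isinf(d[key]):
                d[key] = "inf"
        return json.dumps(d, indent=2)

    def render_text(self) -> str:
        lines = [
            f"Spillover diagnosis — category: {self.category}",
            f"  tau2 ratio control vs intervention: {self.tau2_ratio_ctrl_vs_int:.3g}"
            f" (threshold {self.thresholds.ratio_vs_int})",
        ]
        if self.tau2_ratio_ctrl_vs_reference is not None:
            lines.append(
                f"  tau2 ratio control vs reference control: "
                f"{self.tau2_ratio_ctrl_vs_reference:.3g}"
                f" (threshold {self.thresholds.ratio_vs_ref})"
            )
        else:
            lines.append("  no reference category supplied")
        lines.append(
            f"  benchmark range [{self.benchmark.lo:.0%}, {self.benchmark.hi:.0%}]"
            f" ({self.benchmark.label}); control PI exceeds upper bound: "
            f"{self.pi_exceeds_benchmark}"
        )
        for arm, (below, within, above) in self.range_counts.items():
            lines.append(
                f"  {arm} groups vs range: {below} below / {within} within / {above} above"
            )
        lines.append(f"  verdict: {self.verdict}"
                     + (f" (condition {self.condition_label})" if self.condition_label else ""))
        lines.append(f"  {self.narrative}")
        return "\n".join(lines)


def range_coverage(
    arms: list[ArmRecord], range_: BenchmarkRange
) -> tuple[int, int, int]:
    """Counts of groups strictly below, within [lo, hi], and strictly above."""
    below = within = above = 0
    for r in arms:
        inc = r.incidence
        if inc < range_.lo:
            below += 1
        elif inc > range_.hi:
            above += 1
        else:
            within += 1
    return below, within, above


def _tau2_ratio(a: float, b: float) -> float:
    if b == 0.0:
        return 1.0 if a == 0.0 else float("inf")
    return a / b


def dispersion_comparison(a: ArmPooled, b: ArmPooled) -> tuple[float, float, float]:
    """(tau2 ratio, logit-scale PI width ratio, I2 difference in points) of a vs b."""
    tau2_ratio = _tau2_ratio(a.tau2, b.tau2)

    def pi_width_logit(p: ArmPooled) -> float:
        lo, hi = p.pi95
        if not (0 < lo < 1 and 0 < hi < 1):
            return float("nan")
        return math.log(hi / (1 - hi)) - math.log(lo / (1 - lo))

    wa, wb = pi_width_logit(a), pi_width_logit(b)
    width_ratio = wa / wb if wb else float("inf")
    return tau2_ratio, width_ratio, a.I2 - b.I2


def diagnose_spillover(
    target_ctrl: ArmPooled,
    target_int: ArmPooled,
    reference_ctrl: ArmPooled | None,
    range_: BenchmarkRange = LIBERAL_RANGE,
    thresholds: DiagnosisThresholds = DiagnosisThresholds(),
    category: str = "",
    ctrl_arms: list[ArmRecord] | None = None,
    int_arms: list[ArmRecord] | None = None,
) -> DiagnosisReport:
    """Combine the three dispersion comparisons into a reproducible verdict.

    Without a reference category the verdict rests on the remaining two
    criteria alone and is capped at *indeterminate* unless both fire.
    """
    r_int, _, i2_diff = dispersion_comparison(target_ctrl, target_int)
    r_ref = (
        dispersion_comparison(target_ctrl, reference_ctrl)[0]
        if reference_ctrl is not None
        else None
    )

    dispersed_vs_int = r_int > thresholds.ratio_vs_int
    dispersed_vs_ref = r_ref is not None and r_ref > thresholds.ratio_vs_ref
    pi_lo, pi_hi = target_ctrl.pi95
    pi_above = pi_hi > range_.hi
    pi_below = pi_lo < range_.lo

    if reference_ctrl is None:
        dispersed = dispersed_vs_int
        if dispersed and pi_above:
            verdict = "consistent_with_harmful"
        elif dispersed and pi_below:
            verdict = "consistent_with_beneficial"
        elif dispersed:
            verdict = "indeterminate"
        else:
            verdict = "indeterminate" if dispersed_vs_int else "no_spillover"
    else:
        dispersed = dispersed_vs_int and dispersed_vs_ref
        if dispersed and pi_above:
            verdict = "consistent_with_harmful"
        elif dispersed and pi_below:
            verdict = "consistent_with_beneficial"
        elif dispersed:
            verdict = "indeterminate"
        else:
            verdict = "no_spillover"

    if verdict == "consistent_with_harmful":
        condition = "f" if i2_diff > 0 else "e"
    elif verdict == "consistent_with_beneficial":
        condition = "d"
    elif verdict == "no_spillover":
        condition = "c"
    else:
        condition = None

    counts: dict[str, tuple[int, int, int]] = {}
    if ctrl_arms is not None:
        counts["control"] = range_coverage(ctrl_arms, range_)
    if int_arms is not None:
        counts["intervention"] = range_coverage(int_arms, range_)

    narrative = (
        f"Control-arm dispersion is {r_int:.2f}x the intervention-arm dispersion"
        + (f" and {r_ref:.2f}x the reference control dispersion" if r_ref is not None else "")
        + f"; the control 95% PI ({pi_lo:.1%}-{pi_hi:.1%}) "
        + ("exceeds" if pi_above else "stays below")
        + f" the benchmark upper bound {range_.hi:.0%}."
    )

    return DiagnosisReport(
        category=category,
        tau2_ratio_ctrl_vs_int=r_int,
        tau2_ratio_ctrl_vs_reference=r_ref,
        pi_exceeds_benchmark=pi_above,
        pi_below_benchmark=pi_below,
        range_counts=counts,
        verdict=verdict,
        condition_label=condition,
        narrative=narrative,
        thresholds=thresholds,
        benchmark=range_,
    )
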