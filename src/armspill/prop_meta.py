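"""Arm-level meta-analysis of logit-transformed incidence proportions.

Pools each trial arm's pneumonia incidence separately (arm-based framework),
reporting the back-transformed summary proportion, its 95% CI, a 95%
prediction interval for the incidence of a new comparable group, and the
heterogeneity statistics Q, tau^2, I^2 and H^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from . import _pooling
from .arm_data import ArmRecord, ArmRole, Category, StudyTable

logger = logging.getLogger(__name__)

__all__ = ["ArmEffect", "ArmPooled", "logit_effect", "pool_arms", "arm_summary_table"]


@dataclass(frozen=True)
class ArmEffect:
    """A single arm on the logit scale: y = logit incidence, v its variance."""

    study_id: str
    y: float
    v: float
    events: int
    total: int


@dataclass(frozen=True)
class ArmPooled:
    """A pooled arm-level summary row (proportions as fractions in (0,1))."""

    k: int
    summary_prop: float
    se_logit: float
    ci95: tuple[float, float]
    pi95: tuple[float, float]
    Q: float
    df: int
    tau2: float
    I2: float
    H2: float
    mu_logit: float

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "summary_pct": 100 * self.summary_prop,
            "se_logit": self.se_logit,
            "ci95_lo_pct": 100 * self.ci95[0],
            "ci95_hi_pct": 100 * self.ci95[1],
            "Q": self.Q,
            "df": self.df,
            "tau2": self.tau2,
            "I2_pct": self.I2,
            "H2": self.H2,
            "pi95_lo_pct": 100 * self.pi95[0],
            "pi95_hi_pct": 100 * self.pi95[1],
        }


def logit_effect(events: int, total: int, correction: float = 0.5,
                 study_id: str = "") -> ArmEffect:
    """Logit-transformed incidence with its large-sample variance.

    The continuity correction is added to both cells only for boundary counts
    (0 or all events), leaving interior counts exact.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if correction < 0:
        raise ValueError("correction must be >= 0")
    e = float(events)
    n = float(total)
    if events == 0 or events == total:
        e += correction
        n += 2 * correction
    y = math.log(e / (n - e))
    v = 1.0 / e + 1.0 / (n - e)
    return ArmEffect(study_id=study_id, y=y, v=v, events=events, total=total)


def pool_arms(effects: list[ArmEffect], tau2_method: str = "REML") -> ArmPooled:
    """Pool logit-proportion arm effects and back-transform to proportions."""
    if len(effects) < 2:
        raise ValueError("pool_arms requires at least 2 arms")
    y = np.array([e.y for e in effects])
    v = np.array([e.v for e in effects])
    for e in effects:
        if not (np.isfinite(e.y) and np.isfinite(e.v)):
            raise ValueError(f"non-finite effect for study {e.study_id!r}")
    res = _pooling.pool_effects(y, v, tau2_method=tau2_method)
    return ArmPooled(
        k=res.k,
        summary_prop=float(expit(res.mu)),
        se_logit=res.se,
        ci95=(float(expit(res.ci95[0])), float(expit(res.ci95[1]))),
        pi95=(float(expit(res.pi95[0])), float(expit(res.pi95[1]))),
        Q=res.Q,
        df=res.df,
        tau2=res.tau2,
        I2=res.I2,
        H2=res.H2,
        mu_logit=res.mu,
    )


def _records_to_effects(records: list[ArmRecord], correction: float = 0.5) -> list[ArmEffect]:
    return [
        logit_effect(r.events, r.total, correction=correction, study_id=r.study_id)
        for r in records
    ]


def pool_arm_records(records: list[ArmRecord], tau2_method: str = "REML") -> ArmPooled:
    """Convenience wrapper: pool a list of arm records directly."""
    return pool_arms(_records_to_effects(records), tau2_method=tau2_method)


def arm_summary_table(
    table: StudyTable, grouping: str = "category", tau2_method: str = "REML"
) -> pd.DataFrame:
    """Pooled incidence summaries per group x arm role.

    Mirrors the layout of an arm-level summary table: an "all" block first,
    then one block per group, control before intervention. Groups with fewer
    than 2 arms are flagged rather than pooled.
    """
    if grouping not in ("category", "subcategory", "all"):
        raise ValueError(f"unknown grouping {grouping!r}")

    def groups() -> list[tuple[str, list[ArmRecord]]]:
        out: list[tuple[str, list[ArmRecord]]] = [("all", list(table.records))]
        if grouping == "all":
            return out
        key = (lambda r: r.category.value) if grouping == "category" else (
            lambda r: r.subcategory
        )
        seen: dict[str, list[ArmRecord]] = {}
        for r in table.records:
            seen.setdefault(key(r), []).append(r)
        out.extend(seen.items())
        return out

    rows = []
    for gname, recs in groups():
        for role in (ArmRole.CONTROL, ArmRole.INTERVENTION):
            arms = [r for r in recs if r.arm_role == role]
            base = {"group": gname, "arm_role": role.value}
            if len(arms) < 2:
                logger.warning("group %s/%s has k=%d < 2; flagged", gname, role.value, len(arms))
                rows.append({**base, "k": len(arms), "flagged": True})
                continue
            pooled = pool_arm_records(arms, tau2_method=tau2_method)
            rows.append({**base, "flagged": False, **pooled.as_dict()})
    return pd.DataFrame(rows)
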