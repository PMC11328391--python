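"""Contrast-based random-effects meta-analysis of the log odds ratio.

The conventional RCCT synthesis: each study contributes one log OR comparing
intervention to control pneumonia odds (OR < 1 means the intervention reduces
pneumonia), pooled with the same inverse-variance machinery as the arm-based
proportion analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import _pooling
from .arm_data import StudyTable, TwoByTwo, dedupe_control_arms, to_dta_layout

logger = logging.getLogger(__name__)

__all__ = ["ContrastPooled", "study_log_or", "contrast_effects", "pool_log_or",
           "pool_table_log_or"]


@dataclass(frozen=True)
class ContrastPooled:
    k: int
    or_summary: float
    ci95: tuple[float, float]
    Q: float
    df: int
    tau2: float
    I2: float
    H2: float
    mu_log: float
    se_log: float

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "or": self.or_summary,
            "ci95_lo": self.ci95[0],
            "ci95_hi": self.ci95[1],
            "Q": self.Q,
            "df": self.df,
            "tau2": self.tau2,
            "I2_pct": self.I2,
            "H2": self.H2,
        }


def study_log_or(tt: TwoByTwo, correction: float = 0.5) -> tuple[float, float]:
    """Log odds ratio and its variance for one study's 2x2 table.

    When any cell is zero the correction is added to all four cells. Studies
    with no events in either arm carry no information about the OR and must be
    excluded upstream (:func:`contrast_effects` does this).
    """
    cells = [float(tt.tp), float(tt.fn), float(tt.fp), float(tt.tn)]
    if min(cells) == 0.0:
        cells = [c + correction for c in cells]
    tp, fn, fp, tn = cells
    y = math.log((tp * tn) / (fn * fp))
    v = 1.0 / tp + 1.0 / fn + 1.0 / fp + 1.0 / tn
    return y, v


def contrast_effects(
    pairs: list[tuple[str, TwoByTwo]], correction: float = 0.5
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-study (y, v) log-OR effects, excluding double-zero studies."""
    ids, ys, vs = [], [], []
    for sid, tt in pairs:
        if tt.tp == 0 and tt.fp == 0:
            logger.info("study %s excluded: no events in either arm", sid)
            continue
        y, v = study_log_or(tt, correction=correction)
        ids.append(sid)
        ys.append(y)
        vs.append(v)
    return ids, np.array(ys), np.array(vs)


def pool_log_or(
    y: np.ndarray, v: np.ndarray, tau2_method: str = "REML"
) -> ContrastPooled:
    res = _pooling.pool_effects(y, v, tau2_method=tau2_method)
    return ContrastPooled(
        k=res.k,
        or_summary=math.exp(res.mu),
        ci95=(math.exp(res.ci95[0]), math.exp(res.ci95[1])),
        Q=res.Q,
        df=res.df,
        tau2=res.tau2,
        I2=res.I2,
        H2=res.H2,
        mu_log=res.mu,
        se_log=res.se,
    )


def pool_table_log_or(
    table: StudyTable, tau2_method: str = "REML", dedupe: bool = True
) -> ContrastPooled:
    """Contrast-based pooled OR for a study table.

    Multi-arm studies enter via split deduplication so shared control patients
    are not double counted.
    """
    t = dedupe_control_arms(table, mode="split") if dedupe else table
    pairs = to_dta_layout(t)
    _, y, v = contrast_effects(pairs)
    return pool_log_or(y, v, tau2_method=tau2_method)
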