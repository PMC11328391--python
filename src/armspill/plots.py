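"""Publication-style figures: SROC, caterpillar and L'Abbe plots.

Every figure writes a sidecar CSV of its plotted coordinates next to the
image, so plot content is testable without image comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .arm_data import ArmRecord, ArmRole, StudyTable, to_dta_layout
from .bivariate import BivariateFit, confidence_ellipse, prediction_ellipse, sroc_curve
from .diagnose import BenchmarkRange

__all__ = ["PlotSpec", "plot_sroc", "plot_caterpillar", "plot_labbe", "or_locus"]


@dataclass
class PlotSpec:
    show_curve: bool = True
    show_conf_ellipse: bool = True
    show_pred_ellipse: bool = True
    show_summary_point: bool = True
    show_diag_line: bool = True
    benchmark: BenchmarkRange | None = None
    symbol_scale: str = "proportional_to_n"  # or "fixed"
    output_path: str | Path = "sroc.png"
    image_format: str = "png"


def _save(fig, path: Path, fmt: str) -> Path:
    path = path.with_suffix(f".{fmt}")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def _sidecar(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path.with_suffix(".csv"), index=False)


def plot_sroc(fit: BivariateFit, table: StudyTable, spec: PlotSpec) -> Path:
    """SROC-style scatter: control incidence (x) vs intervention incidence (y).

    Effective interventions place most studies below the y = x diagonal;
    harmful spillover stretches the point cloud (and prediction region) along
    the x axis.
    """
    pairs = to_dta_layout(table)
    xs = np.array([tt.control_incidence for _, tt in pairs])
    ys = np.array([tt.intervention_incidence for _, tt in pairs])
    ns = np.array([tt.control_total + tt.intervention_total for _, tt in pairs])

    fig, ax = plt.subplots(figsize=(6, 6))
    if spec.symbol_scale == "proportional_to_n":
        sizes = 200.0 * ns / ns.max()
    else:
        sizes = np.full_like(ns, 40.0, dtype=float)
    ax.scatter(xs, ys, s=sizes, facecolors="none", edgecolors="C0", label="studies")

    frames = [pd.DataFrame({"element": "study", "x": xs, "y": ys, "n": ns})]
    if spec.show_diag_line:
        ax.plot([0, 1], [0, 1], color="grey", lw=0.8, ls="-")
    if spec.benchmark is not None:
        ax.axvspan(spec.benchmark.lo, spec.benchmark.hi, color="gold", alpha=0.15)
        ax.axvline(spec.benchmark.lo, color="gold", ls=":")
        ax.axvline(spec.benchmark.hi, color="red", ls=":")
    if spec.show_conf_ellipse:
        ell = confidence_ellipse(fit)
        ax.plot(ell.points[:, 0], ell.points[:, 1], "r:", label="95% confidence")
        frames.append(pd.DataFrame({"element": "confidence",
                                    "x": ell.points[:, 0], "y": ell.points[:, 1]}))
    if spec.show_pred_ellipse:
        ell = prediction_ellipse(fit)
        ax.plot(ell.points[:, 0], ell.points[:, 1], ls=":", color="purple",
                label="95% prediction")
        frames.append(pd.DataFrame({"element": "prediction",
                                    "x": ell.points[:, 0], "y": ell.points[:, 1]}))
    if spec.show_curve and fit.sigma_C > 1e-8:
        obs_range = (max(xs.min(), 0.01), min(xs.max(), 0.99))
        curve = sroc_curve(fit, x_range=obs_range)
        ax.plot(curve.points[:, 0], curve.points[:, 1], "g-", label="SROC curve")
        frames.append(pd.DataFrame({"element": "curve",
                                    "x": curve.points[:, 0], "y": curve.points[:, 1]}))
    if spec.show_summary_point:
        sx, sy = fit.summary_point
        ax.plot(sx, sy, "rs", ms=9, label="summary")
        frames.append(pd.DataFrame({"element": "summary", "x": [sx], "y": [sy]}))

    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("control group incidence (as 1 − specificity)")
    ax.set_ylabel("intervention group incidence (as sensitivity)")
    ax.legend(loc="upper left", fontsize=8)
    out = _save(fig, Path(spec.output_path), spec.image_format)
    _sidecar(out, pd.concat(frames, ignore_index=True))
    return out


def plot_caterpillar(
    arms: list[ArmRecord],
    output_path: str | Path,
    benchmark: BenchmarkRange | None = None,
    image_format: str = "png",
) -> Path:
    """Forest plot of group incidences ordered by increasing incidence.

    Exact (Clopper-Pearson) binomial 95% CIs per group; ordering is canonical
    so a shuffled input yields the identical figure.
    """
    if not arms:
        raise ValueError("plot_caterpillar needs at least one arm")
    order = sorted(arms, key=lambda r: (r.incidence, r.study_id))
    inc = np.array([r.incidence for r in order])
    e = np.array([r.events for r in order])
    n = np.array([r.total for r in order])
    lo = np.where(e == 0, 0.0, stats.beta.ppf(0.025, e, n - e + 1))
    hi = np.where(e == n, 1.0, stats.beta.ppf(0.975, e + 1, n - e))

    fig, ax = plt.subplots(figsize=(6, max(2.5, 0.12 * len(order))))
    ypos = np.arange(len(order))
    ax.errorbar(inc, ypos, xerr=[inc - lo, hi - inc], fmt="o", ms=3,
                color="C0", ecolor="grey", elinewidth=0.7)
    if benchmark is not None:
        ax.axvspan(benchmark.lo, benchmark.hi, color="gold", alpha=0.15)
    ax.set_xlim(0, 1)
    ax.set_xlabel("pneumonia incidence")
    ax.set_yticks([])
    out = _save(fig, Path(output_path), image_format)
    _sidecar(out, pd.DataFrame({
        "study_id": [r.study_id for r in order],
        "incidence": inc, "ci_lo": lo, "ci_hi": hi, "events": e, "total": n,
    }))
    return out


def or_locus(o: float, x: np.ndarray) -> np.ndarray:
    """Iso-OR locus on the incidence plane: y such that odds(y)/odds(x) = o."""
    return o * x / (1 - x + o * x)


def plot_labbe(
    table: StudyTable,
    es_type: str,
    es_value: float,
    output_path: str | Path,
    image_format: str = "png",
) -> Path:
    """L'Abbe plot with the iso-effect locus for an OR, RR or RD effect size."""
    if es_type not in ("OR", "RR", "RD"):
        raise ValueError(f"es_type must be OR/RR/RD, got {es_type!r}")
    pairs = to_dta_layout(table)
    xs = np.array([tt.control_incidence for _, tt in pairs])
    ys = np.array([tt.intervention_incidence for _, tt in pairs])

    grid = np.linspace(0.001, 0.999, 200)
    if es_type == "OR":
        locus = or_locus(es_value, grid)
    elif es_type == "RR":
        locus = np.clip(es_value * grid, 0, 1)
    else:
        locus = np.clip(grid + es_value, 0, 1)

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(xs, ys, facecolors="none", edgecolors="C0")
    ax.plot([0, 1], [0, 1], color="grey", lw=0.8)
    ax.plot(grid, locus, "C3-", label=f"{es_type} = {es_value:g}")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("control group incidence")
    ax.set_ylabel("intervention group incidence")
    ax.legend()
    out = _save(fig, Path(output_path), image_format)
    _sidecar(out, pd.concat([
        pd.DataFrame({"element": "study", "x": xs, "y": ys}),
        pd.DataFrame({"element": "locus", "x": grid, "y": locus}),
    ], ignore_index=True))
    return out
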