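"""Data model and I/O for arm-level trial count data.

Each randomized concurrent controlled trial (RCCT) contributes one control and
one or more intervention arms, each an (events, total) pneumonia count pair.
The same records can be re-arrayed as 2x2 tables in the diagnostic-test layout,
where the intervention arm plays the "diseased" group (its incidence maps to
sensitivity) and the control arm the "non-diseased" group (its incidence maps
to 1 - specificity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "ArmRole",
    "ArmRecord",
    "StudyTable",
    "TwoByTwo",
    "ValidationError",
    "read_arm_table",
    "write_arm_table",
    "to_dta_layout",
    "dedupe_control_arms",
    "filter_by_control_incidence",
]

CSV_COLUMNS = [
    "study_id",
    "review_id",
    "category",
    "subcategory",
    "arm_role",
    "events",
    "total",
    "shared_control_of",
]


class ValidationError(ValueError):
    """Raised when arm-level count data violate their invariants."""


class Category(str, Enum):
    NON_ANTIMICROBIAL = "non_antimicrobial"
    ANTIMICROBIAL = "antimicrobial"
    ANTIMICROBIAL_DUPLEX = "antimicrobial_duplex"


class ArmRole(str, Enum):
    CONTROL = "control"
    INTERVENTION = "intervention"


@dataclass(frozen=True)
class ArmRecord:
    """One trial arm: pneumonia events out of a group of patients.

    ``shared_control_of`` marks a control row that duplicates the physical
    control group of another study entry (multi-arm trials listed as separate
    pairwise comparisons share one control group).
    """

    study_id: str
    review_id: str
    category: Category
    subcategory: str
    arm_role: ArmRole
    events: int
    total: int
    shared_control_of: str | None = None

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValidationError(
                f"study {self.study_id!r}: total must be >= 1, got {self.total}"
            )
        if not 0 <= self.events <= self.total:
            raise ValidationError(
                f"study {self.study_id!r}: events={self.events} outside [0, total={self.total}]"
            )

    @property
    def incidence(self) -> float:
        return self.events / self.total


@dataclass(frozen=True)
class TwoByTwo:
    """Paired arm counts in the diagnostic-test 2x2 layout.

    tp = intervention events, fn = intervention non-events,
    fp = control events, tn = control non-events.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("2x2 cells must be non-negative")
        if self.tp + self.fn < 1 or self.fp + self.tn < 1:
            raise ValidationError("each arm of a 2x2 table needs at least one patient")

    @property
    def intervention_events(self) -> int:
        return self.tp

    @property
    def intervention_total(self) -> int:
        return self.tp + self.fn

    @property
    def control_events(self) -> int:
        return self.fp

    @property
    def control_total(self) -> int:
        return self.fp + self.tn

    @property
    def intervention_incidence(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def control_incidence(self) -> float:
        return self.fp / (self.fp + self.tn)


@dataclass
class StudyTable:
    """An ordered collection of arm records with a provenance note."""

    records: list[ArmRecord] = field(default_factory=list)
    provenance: str = ""

    def __iter__(self) -> Iterator[ArmRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def study_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.study_id, None)
        return list(seen)

    def arms(self, role: ArmRole | str) -> list[ArmRecord]:
        role = ArmRole(role)
        return [r for r in self.records if r.arm_role == role]

    def by_study(self) -> dict[str, list[ArmRecord]]:
        out: dict[str, list[ArmRecord]] = {}
        for r in self.records:
            out.setdefault(r.study_id, []).append(r)
        return out

    def subset(self, category: Category | str | None = None) -> "StudyTable":
        if category is None:
            return StudyTable(list(self.records), self.provenance)
        category = Category(category)
        recs = [r for r in self.records if r.category == category]
        return StudyTable(recs, f"{self.provenance} [category={category.value}]")

    def validate(self, require_paired: bool = True) -> None:
        """Check table-level invariants.

        ``require_paired=False`` relaxes the one-control-per-study rule, which
        no longer holds after ``dedupe_control_arms(mode='include_once')``.
        """
        seen: set[tuple[str, str, str]] = set()
        for r in self.records:
            key = (r.study_id, r.arm_role.value, r.subcategory)
            if key in seen:
                raise ValidationError(
                    f"duplicate study_id/arm_role/subcategory combination {key}"
                )
            seen.add(key)
        if require_paired:
            for sid, recs in self.by_study().items():
                roles = {r.arm_role for r in recs}
                if ArmRole.CONTROL not in roles:
                    raise ValidationError(f"study {sid!r} has no control arm")
                if ArmRole.INTERVENTION not in roles:
                    raise ValidationError(f"study {sid!r} has no intervention arm")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "study_id": r.study_id,
                "review_id": r.review_id,
                "category": r.category.value,
                "subcategory": r.subcategory,
                "arm_role": r.arm_role.value,
                "events": r.events,
                "total": r.total,
                "shared_control_of": r.shared_control_of or "",
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def read_arm_table(path: str | Path, format: str = "csv") -> StudyTable:
    """Read a one-row-per-arm CSV into a validated :class:`StudyTable`."""
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "shared_control_of"]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    records: list[ArmRecord] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            records.append(
                ArmRecord(
                    study_id=row["study_id"],
                    review_id=row["review_id"],
                    category=Category(row["category"]),
                    subcategory=row["subcategory"],
                    arm_role=ArmRole(row["arm_role"]),
                    events=int(row["events"]),
                    total=int(row["total"]),
                    shared_control_of=row.get("shared_control_of", "") or None,
                )
            )
        except ValidationError:
            raise
        except (ValueError, KeyError) as exc:
            raise ValidationError(f"{path}:{line}: malformed row ({exc})") from exc
    if not records:
        logger.warning("%s: no data rows (header only)", path)
    table = StudyTable(records, provenance=str(path))
    table.validate(require_paired=False)
    return table


def write_arm_table(table: StudyTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def to_dta_layout(table: StudyTable) -> list[tuple[str, TwoByTwo]]:
    """Re-array paired arms as (study_id, 2x2) tuples in input order.

    Multi-intervention studies yield one 2x2 per intervention arm, all paired
    with the study's single control.
    """
    out: list[tuple[str, TwoByTwo]] = []
    for sid, recs in table.by_study().items():
        controls = [r for r in recs if r.arm_role == ArmRole.CONTROL]
        interventions = [r for r in recs if r.arm_role == ArmRole.INTERVENTION]
        if not controls:
            raise ValidationError(f"study {sid!r} has no control arm")
        if not interventions:
            raise ValidationError(f"study {sid!r} has no intervention arm")
        if len(controls) > 1:
            raise ValidationError(
                f"study {sid!r} has {len(controls)} control arms; dedupe first"
            )
        ctrl = controls[0]
        for inter in interventions:
            out.append(
                (
                    sid,
                    TwoByTwo(
                        tp=inter.events,
                        fn=inter.total - inter.events,
                        fp=ctrl.events,
                        tn=ctrl.total - ctrl.events,
                    ),
                )
            )
    return out


def _split_counts(events: int, total: int, m: int) -> list[tuple[int, int]]:
    """Divide (events, total) as evenly as integers allow across m shares.

    Remainders go to the earliest shares, so the first comparison gets the
    larger share when counts are odd.
    """
    shares = []
    for j in range(m):
        e = events // m + (1 if j < events % m else 0)
        n = total // m + (1 if j < total % m else 0)
        shares.append((e, n))
    return shares


def dedupe_control_arms(table: StudyTable, mode: str = "include_once") -> StudyTable:
    """Resolve duplicated control groups of multi-arm trials.

    ``include_once``: keep each physical control group exactly once (drop rows
    flagged as duplicates) — appropriate for arm-based pooling.
    ``split``: divide the physical control's events and total as evenly as
    integers allow across the comparisons sharing it — appropriate for
    contrast-based pairing, conserving patients exactly.
    """
    if mode not in ("include_once", "split"):
        raise ValueError(f"unknown dedupe mode {mode!r}")

    ctrl_by_study = {
        r.study_id: r
        for r in table.records
        if r.arm_role == ArmRole.CONTROL and r.shared_control_of is None
    }
    for r in table.records:
        if r.shared_control_of is not None and r.shared_control_of not in ctrl_by_study:
            raise ValidationError(
                f"study {r.study_id!r}: shared_control_of={r.shared_control_of!r} "
                "does not name a primary control group"
            )

    if mode == "include_once":
        recs = [
            r
            for r in table.records
            if not (r.arm_role == ArmRole.CONTROL and r.shared_control_of is not None)
        ]
        return StudyTable(recs, f"{table.provenance} [dedupe=include_once]")

    # split: group each physical control with its duplicates, in input order
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(table.records):
        if r.arm_role != ArmRole.CONTROL:
            continue
        owner = r.shared_control_of if r.shared_control_of is not None else r.study_id
        groups.setdefault(owner, []).append(i)

    new_records = list(table.records)
    for owner, idxs in groups.items():
        if len(idxs) == 1:
            continue
        physical = ctrl_by_study[owner]
        if physical.total < len(idxs):
            raise ValidationError(
                f"study {owner!r}: control group of {physical.total} patients "
                f"cannot be split across {len(idxs)} comparisons"
            )
        shares = _split_counts(physical.events, physical.total, len(idxs))
        for i, (e, n) in zip(idxs, shares):
            new_records[i] = replace(
                table.records[i], events=e, total=n, shared_control_of=None
            )
    return StudyTable(new_records, f"{table.provenance} [dedupe=split]")


def filter_by_control_incidence(
    table: StudyTable, threshold: float, side: str
) -> StudyTable:
    """Retain whole studies whose control incidence is strictly above/below a cut.

    Studies exactly at the threshold are excluded from both strata (their
    count is logged).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if side not in ("above", "below"):
        raise ValueError(f"side must be 'above' or 'below', got {side!r}")
    by_study = table.by_study()
    keep: set[str] = set()
    boundary = 0
    for sid, recs in by_study.items():
        ctrls = [r for r in recs if r.arm_role == ArmRole.CONTROL]
        if not ctrls:
            continue
        inc = ctrls[0].incidence
        if inc == threshold:
            boundary += 1
        elif (side == "above" and inc > threshold) or (side == "below" and inc < threshold):
            keep.add(sid)
    if boundary:
        logger.info(
            "filter_by_control_incidence: %d studies exactly at threshold %.3f excluded",
            boundary,
            threshold,
        )
    recs = [r for r in table.records if r.study_id in keep]
    return StudyTable(recs, f"{table.provenance} [control incidence {side} {threshold}]")
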