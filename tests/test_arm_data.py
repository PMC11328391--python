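"""Arm-level data model: parsing, the DTA layout, dedupe and subsetting."""

import pytest
from hypothesis import given, settings, strategies as st

from armspill.arm_data import (
    ArmRole,
    StudyTable,
    TwoByTwo,
    ValidationError,
    dedupe_control_arms,
    filter_by_control_incidence,
    read_arm_table,
    to_dta_layout,
    write_arm_table,
)
from conftest import make_record


class TestReadWrite:
    def test_round_trip(self, arm_csv, tmp_path):
        table = read_arm_table(arm_csv)
        assert len(table) == 4
        assert table.study_ids == ["s1", "s2"]
        out = tmp_path / "copy.csv"
        write_arm_table(table, out)
        again = read_arm_table(out)
        assert again.records == table.records

    def test_events_above_total_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "study_id,review_id,category,subcategory,arm_role,events,total,shared_control_of\n"
            "s1,r1,non_antimicrobial,x,control,12,10,\n"
        )
        with pytest.raises(ValidationError, match="s1"):
            read_arm_table(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "study_id,review_id,category,subcategory,arm_role,events,total,shared_control_of\n"
            "s1,r1,not_a_category,x,control,1,10,\n"
        )
        with pytest.raises(ValidationError, match=":2"):
            read_arm_table(path)

    def test_header_only_gives_empty_table(self, tmp_path, caplog):
        path = tmp_path / "empty.csv"
        path.write_text(
            "study_id,review_id,category,subcategory,arm_role,events,total,shared_control_of\n"
        )
        table = read_arm_table(path)
        assert len(table) == 0


class TestDtaLayout:
    def test_counts(self, two_study_table):
        layout = to_dta_layout(two_study_table)
        assert layout[0] == ("s1", TwoByTwo(tp=12, fn=48, fp=20, tn=35))
        assert len(layout) == 2
        assert [sid for sid, _ in layout] == ["s1", "s2"]

    def test_boundary_counts(self):
        table = StudyTable(
            [
                make_record("s1", "intervention", 0, 30),
                make_record("s1", "control", 30, 30),
            ]
        )
        (_, tt), = to_dta_layout(table)
        assert (tt.tp, tt.fn, tt.fp, tt.tn) == (0, 30, 30, 0)

    def test_missing_arm_names_study(self):
        table = StudyTable([make_record("lonely", "control", 5, 20)])
        with pytest.raises(ValidationError, match="lonely"):
            to_dta_layout(table)

    def test_layout_is_lossless(self, two_study_table):
        for (sid, tt), recs in zip(
            to_dta_layout(two_study_table), two_study_table.by_study().values()
        ):
            ctrl = next(r for r in recs if r.arm_role == ArmRole.CONTROL)
            inter = next(r for r in recs if r.arm_role == ArmRole.INTERVENTION)
            assert (tt.control_events, tt.control_total) == (ctrl.events, ctrl.total)
            assert (tt.intervention_events, tt.intervention_total) == (
                inter.events,
                inter.total,
            )


def three_arm_table(ctrl_events=40, ctrl_total=100):
    return StudyTable(
        [
            make_record("a", "control", ctrl_events, ctrl_total),
            make_record("a", "intervention", 10, 50, subcategory="x"),
            make_record("b", "control", ctrl_events, ctrl_total, shared="a"),
            make_record("b", "intervention", 12, 50, subcategory="y"),
        ]
    )


class TestDedupe:
    def test_split_even(self):
        out = dedupe_control_arms(three_arm_table(40, 100), "split")
        ctrls = out.arms("control")
        assert [(r.events, r.total) for r in ctrls] == [(20, 50), (20, 50)]

    def test_split_odd_larger_share_first(self):
        out = dedupe_control_arms(three_arm_table(41, 101), "split")
        ctrls = out.arms("control")
        assert [(r.events, r.total) for r in ctrls] == [(21, 51), (20, 50)]

    def test_include_once(self):
        out = dedupe_control_arms(three_arm_table(), "include_once")
        assert len(out.arms("control")) == 1
        assert len(out.arms("intervention")) == 2

    def test_dangling_reference(self):
        table = StudyTable(
            [
                make_record("b", "control", 5, 20, shared="ghost"),
                make_record("b", "intervention", 2, 20),
            ]
        )
        with pytest.raises(ValidationError, match="ghost"):
            dedupe_control_arms(table, "split")

    @given(
        events=st.integers(0, 500),
        extra=st.integers(0, 500),
        m=st.integers(1, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_split_conserves_counts(self, events, extra, m):
        total = events + extra + m  # every comparison must get >= 1 patient
        records = [
            make_record("a", "control", events, total),
            make_record("a", "intervention", 0, 10, subcategory="sub0"),
        ]
        for j in range(m - 1):
            records.append(
                make_record(f"dup{j}", "control", events, total, shared="a")
            )
            records.append(
                make_record(f"dup{j}", "intervention", 0, 10, subcategory=f"sub{j}")
            )
        out = dedupe_control_arms(StudyTable(records), "split")
        ctrls = out.arms("control")
        assert sum(r.events for r in ctrls) == events
        assert sum(r.total for r in ctrls) == total


class TestIncidenceFilter:
    def test_above_below_and_boundary(self):
        records = []
        for sid, e in (("lo", 30), ("at", 40), ("hi", 50)):
            records.append(make_record(sid, "control", e, 100))
            records.append(make_record(sid, "intervention", 10, 100))
        table = StudyTable(records)
        above = filter_by_control_incidence(table, 0.4, "above")
        below = filter_by_control_incidence(table, 0.4, "below")
        assert above.study_ids == ["hi"]
        assert below.study_ids == ["lo"]

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 50)), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_partition_is_exhaustive(self, counts):
        records = []
        for i, (e, extra) in enumerate(counts):
            n = e + extra
            records.append(make_record(f"s{i}", "control", e, n))
            records.append(make_record(f"s{i}", "intervention", 0, 10))
        table = StudyTable(records)
        above = set(filter_by_control_incidence(table, 0.4, "above").study_ids)
        below = set(filter_by_control_incidence(table, 0.4, "below").study_ids)
        boundary = {
            sid
            for sid, recs in table.by_study().items()
            if any(r.arm_role == ArmRole.CONTROL and r.incidence == 0.4 for r in recs)
        }
        assert above | below | boundary == set(table.study_ids)
        assert above.isdisjoint(below)
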