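import textwrap

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from armspill.arm_data import (
    ArmRecord,
    ArmRole,
    Category,
    StudyTable,
    TwoByTwo,
)


def make_record(
    study_id: str,
    role: str,
    events: int,
    total: int,
    category: str = "non_antimicrobial",
    subcategory: str = "s",
    shared: str | None = None,
) -> ArmRecord:
    return ArmRecord(
        study_id=study_id,
        review_id="r1",
        category=Category(category),
        subcategory=subcategory,
        arm_role=ArmRole(role),
        events=events,
        total=total,
        shared_control_of=shared,
    )


@pytest.fixture
def two_study_table() -> StudyTable:
    return StudyTable(
        [
            make_record("s1", "control", 20, 55),
            make_record("s1", "intervention", 12, 60),
            make_record("s2", "control", 30, 100),
            make_record("s2", "intervention", 15, 90),
        ]
    )


@pytest.fixture
def toy_pairs() -> list[TwoByTwo]:
    return [
        TwoByTwo(5, 20, 8, 17),
        TwoByTwo(2, 28, 10, 20),
        TwoByTwo(12, 38, 20, 30),
    ]


@pytest.fixture
def arm_csv(tmp_path):
    text = textwrap.dedent(
        """\
        study_id,review_id,category,subcategory,arm_role,events,total,shared_control_of
        s1,r1,non_antimicrobial,ugit,control,20,55,
        s1,r1,non_antimicrobial,ugit,intervention,12,60,
        s2,r1,antimicrobial,sdd,control,30,100,
        s2,r1,antimicrobial,sdd,intervention,15,90,
        """
    )
    path = tmp_path / "arms.csv"
    path.write_text(text)
    return path
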