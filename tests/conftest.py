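import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def filter_fixture_records() -> pd.DataFrame:
    """A 25-record raw cohort exercising every stage of the filter cascade.

    Expected survivor flow with min_class_size=5, derived by hand:
    25 -> 23 (2 selected) -> 17 (2 invalid + 4 not well-defined)
    -> 15 (2 redundant clones) -> 13 (modal 34 and 58 out; 35 and 57 stay)
    -> 11 (class B has 2 < 5 survivors).
    """
    losses = ",".join(f"-{c}" for c in range(1, 13))
    losses11 = ",".join(f"-{c}" for c in range(1, 12))
    gains11 = ",".join(f"+{c}" for c in range(1, 12))
    gains12 = ",".join(f"+{c}" for c in range(1, 13))
    rows = [
        ("R01", "C01", 0, "46,XX", "A", 0),
        ("R02", "C02", 0, "47,XY,+8", "A", 0),
        ("R03", "C03", 0, "46,XX,t(9;22)(q34;q11)", "A", 0),
        ("R04", "C04", 0, "46,XX", "A", 1),
        ("R05", "C05", 0, "46,XY", "B", 1),
        ("R06", "C06", 0, "4x,XX", "A", 0),
        ("R07", "C07", 0, "46,XX,?inv(3)", "A", 0),
        ("R08", "C08", 0, "46,XY,mar", "A", 0),
        ("R09", "C09", 0, "4x,XY", "A", 0),
        ("R10", "C10", 0, "46,XX,add(5)", "A", 0),
        ("R11", "C11", 0, f"34,XX,{losses}", "A", 0),
        ("R12", "C12", 0, f"35,XY,{losses11}", "A", 0),
        ("R13", "C13", 0, f"57,XX,{gains11}", "A", 0),
        ("R14", "C14", 0, f"58,XY,{gains12}", "A", 0),
        ("R15", "C15", 0, "46,XX,del(5)(q13q33)", "B", 0),
        ("R16", "C16", 0, "46,XX,?del(7)", "A", 0),
        ("R17", "C16", 1, "46,XX,del(7)(q22q32)", "A", 0),
        ("R18", "C17", 0, "47,XY,+21", "A", 0),
        ("R19", "C17", 1, "46,XY", "A", 0),
        ("R20", "C18", 0, "46,XX", "A", 0),
        ("R21", "C18", 1, "47,XX,+8", "A", 0),
        ("R22", "C19", 0, "46,XY,inv(3)(p21q26)", "B", 0),
        ("R23", "C20", 0, "46,XX,i(17)(q10)", "A", 0),
        ("R24", "C21", 0, "45,XY,-7", "A", 0),
        ("R25", "C22", 0, "48,XX,+8,+21", "A", 0),
    ]
    df = pd.DataFrame(
        rows,
        columns=["record_id", "case_id", "clone_index", "iscn", "tumor_class", "selected"],
    )
    df["category"] = "lymphoid"
    return df[
        ["record_id", "case_id", "clone_index", "iscn", "tumor_class", "category", "selected"]
    ]


EXPECTED_SURVIVORS = {
    "R01", "R02", "R03", "R12", "R13", "R17", "R18", "R20", "R23", "R24", "R25",
}

EXPECTED_STAGE_FLOW = [
    ("unselected", 25, 23, {"selected": 2}),
    ("parse_validity", 23, 17, {"invalid": 2, "not_well_defined": 4}),
    ("clone_case_dedupe", 17, 15, {"redundant_clone_or_case": 2}),
    ("near_diploid", 15, 13, {"not_near_diploid": 2}),
    ("class_size", 13, 11, {"small_class": 2}),
]


@pytest.fixture
def raw_filter_records() -> pd.DataFrame:
    return filter_fixture_records()
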