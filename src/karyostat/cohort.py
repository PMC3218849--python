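"""Karyotype cohort assembly and the fixed selection cascade.

Records enter as a TSV with one row per clone (record_id, case_id,
clone_index, iscn, tumor_class, category, selected) and pass through a
fixed, idempotent cascade:

1. drop records flagged as selected (biased sampling), unless bypassed;
2. drop records whose ISCN is invalid or not well-defined;
3. per case, keep the first (lowest clone_index) surviving clone;
4. keep near-diploid records only (35 <= modal count <= 57);
5. drop tumor classes with fewer than ``min_class_size`` karyotypes,
   together with their karyotypes.

Every stage emits a :class:`FilterReport` so exclusion counts can be
inspected and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .iscn import parse_iscn

logger = logging.getLogger(__name__)

NEAR_DIPLOID_MIN = 35
NEAR_DIPLOID_MAX = 57
DEFAULT_MIN_CLASS_SIZE = 50

RECORD_COLUMNS = [
    "record_id",
    "case_id",
    "clone_index",
    "iscn",
    "tumor_class",
    "category",
    "selected",
]

CATEGORIES = (
    "lymphoid",
    "non-lymphoid hematological",
    "benign solid",
    "malignant solid",
)


@dataclass
class FilterReport:
    stage: str
    n_in: int
    n_out: int
    reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError("filter stage cannot create records")
        if sum(self.reasons.values()) != self.n_in - self.n_out:
            raise ValueError("reason counts must sum to the number excluded")


def load_records(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"record_id": str, "case_id": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"karyotype table is missing columns: {missing}")
    return df


def parse_records(df: pd.DataFrame) -> pd.DataFrame:
    """Attach parse results (modal_count, valid, well_defined) to records."""
    df = df.copy()
    parses = [parse_iscn(s) for s in df["iscn"]]
    df["modal_count"] = [p.modal_count for p in parses]
    df["valid"] = [p.valid for p in parses]
    df["well_defined"] = [p.well_defined for p in parses]
    df["parsed"] = parses
    return df


def filter_unselected(df: pd.DataFrame, bypass: bool = False) -> tuple[pd.DataFrame, FilterReport]:
    """Keep only records not flagged as selected (i.e. unbiased samples).

    ``bypass=True`` keeps everything, reproducing the extended robustness
    analysis that re-admits selected records.
    """
    if "selected" not in df.columns:
        raise ValueError("records lack the 'selected' flag")
    if bypass:
        out = df
        report = FilterReport("unselected", len(df), len(df), {})
    else:
        keep = df["selected"].astype(int) == 0
        out = df[keep]
        report = FilterReport(
            "unselected", len(df), len(out), _reason("selected", len(df) - len(out))
        )
    logger.info("stage %s: %d -> %d", report.stage, report.n_in, report.n_out)
    return out.reset_index(drop=True), report


def filter_parse_validity(df: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop invalid and not-well-defined records."""
    n_invalid = int((~df["valid"]).sum())
    n_partial = int((df["valid"] & ~df["well_defined"]).sum())
    out = df[df["valid"] & df["well_defined"]]
    report = FilterReport(
        "parse_validity",
        len(df),
        len(out),
        {"invalid": n_invalid, "not_well_defined": n_partial},
    )
    logger.info("stage %s: %d -> %d", report.stage, report.n_in, report.n_out)
    return out.reset_index(drop=True), report


def dedupe_clones_and_cases(df: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Per case, keep the first (lowest clone_index) surviving clone.

    Expects the parse-validity stage to have run already, so every row
    here is well-defined; earlier clones of the case may have been
    dropped there.  Duplicate (case_id, clone_index) pairs are an input
    error.
    """
    if df.duplicated(subset=["case_id", "clone_index"]).any():
        raise ValueError("duplicate (case_id, clone_index) in input")
    out = (
        df.sort_values(["case_id", "clone_index"], kind="mergesort")
        .groupby("case_id", sort=False)
        .head(1)
    )
    report = FilterReport(
        "clone_case_dedupe",
        len(df),
        len(out),
        _reason("redundant_clone_or_case", len(df) - len(out)),
    )
    logger.info("stage %s: %d -> %d", report.stage, report.n_in, report.n_out)
    return out.reset_index(drop=True), report


def filter_near_diploid(df: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Keep records with 35 <= modal count <= 57 (near-diploid)."""
    keep = (df["modal_count"] >= NEAR_DIPLOID_MIN) & (
        df["modal_count"] <= NEAR_DIPLOID_MAX
    )
    out = df[keep]
    report = FilterReport(
        "near_diploid", len(df), len(out), _reason("not_near_diploid", len(df) - len(out))
    )
    logger.info("stage %s: %d -> %d", report.stage, report.n_in, report.n_out)
    return out.reset_index(drop=True), report


def filter_small_classes(
    df: pd.DataFrame, min_n: int = DEFAULT_MIN_CLASS_SIZE
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Drop tumor classes with fewer than ``min_n`` karyotypes.

    Returns (records, surviving class table, report); the class table
    has columns name/category/n_karyotypes.
    """
    sizes = df.groupby("tumor_class").size()
    keep_classes = set(sizes[sizes >= min_n].index)
    out = df[df["tumor_class"].isin(keep_classes)]
    classes = (
        out.groupby(["tumor_class", "category"], sort=True)
        .size()
        .reset_index(name="n_karyotypes")
        .rename(columns={"tumor_class": "name"})
    )
    report = FilterReport(
        "class_size", len(df), len(out), _reason("small_class", len(df) - len(out))
    )
    logger.info("stage %s: %d -> %d", report.stage, report.n_in, report.n_out)
    return out.reset_index(drop=True), classes, report


def apply_filter_cascade(
    df: pd.DataFrame,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
    include_selected: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, list[FilterReport]]:
    """Run the full fixed-order cascade; returns (records, classes, reports)."""
    reports: list[FilterReport] = []
    df, rep = filter_unselected(df, bypass=include_selected)
    reports.append(rep)
    if "valid" not in df.columns:
        df = parse_records(df)
    df, rep = filter_parse_validity(df)
    reports.append(rep)
    df, rep = dedupe_clones_and_cases(df)
    reports.append(rep)
    df, rep = filter_near_diploid(df)
    reports.append(rep)
    df, classes, rep = filter_small_classes(df, min_n=min_class_size)
    reports.append(rep)
    return df, classes, reports


def report_frame(reports: list[FilterReport]) -> pd.DataFrame:
    """Flatten stage reports into a TSV-ready frame."""
    rows = []
    for rep in reports:
        if rep.reasons:
            for reason, count in rep.reasons.items():
                rows.append((rep.stage, rep.n_in, rep.n_out, reason, count))
        else:
            rows.append((rep.stage, rep.n_in, rep.n_out, "", 0))
    return pd.DataFrame(rows, columns=["stage", "n_in", "n_out", "reason", "count"])


def _reason(name: str, count: int) -> dict[str, int]:
    return {name: count} if count else {}
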