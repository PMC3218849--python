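"""Trisomy-index tests (TI-T) for hyperdiploid multiple myeloma.

A TI-T declares a multiple-myeloma karyotype hyperdiploid (H-MM) when it
carries whole-chromosome gains for at least k chromosomes of a chosen
set.  Ground truth is the modal-count definition of hyperdiploidy
(48-74 chromosomes).  ``search_best`` evaluates every (chromosome
combination, k) pair exhaustively and ranks by F-score, with ties broken
by specificity, then lexicographic chromosome order, then k.

A tetrasomy (or higher gain) satisfies the trisomy criterion: the test
only asks whether the gain aberration is present.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .stats import ConfusionMetrics, confusion_metrics

HYPERDIPLOID_MIN = 48
HYPERDIPLOID_MAX = 74

# recurrent H-MM gains; the default search pool
DEFAULT_POOL = (3, 5, 7, 9, 11, 15, 19)


@dataclass(frozen=True)
class TrisomyIndexTest:
    """A chromosome set and the minimum number k of trisomies required."""

    chromosomes: frozenset[int]
    min_trisomies: int

    def __post_init__(self) -> None:
        if not all(1 <= c <= 22 for c in self.chromosomes):
            raise ValueError("TI-T chromosomes must be autosomes 1-22")
        if not (1 <= self.min_trisomies <= len(self.chromosomes)):
            raise ValueError("need 1 <= k <= |chromosomes|")

    def label(self) -> str:
        chroms = "+".join(str(c) for c in sorted(self.chromosomes))
        return f"{{{chroms}}}, k={self.min_trisomies}"


@dataclass(frozen=True)
class TITEvaluation:
    test: TrisomyIndexTest
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: ConfusionMetrics


def is_hyperdiploid(modal_count: int) -> bool:
    """H-MM ground truth: 48 to 74 chromosomes inclusive."""
    return HYPERDIPLOID_MIN <= modal_count <= HYPERDIPLOID_MAX


def predict(gains, chromosomes, k: int) -> bool:
    """TI-T call: at least k of the set's chromosomes gained."""
    return sum(1 for c in chromosomes if c in gains) >= k


def _gain_set(aberration_ids) -> set[int]:
    out = set()
    for ab in aberration_ids:
        if ab.startswith("+") and ab[1:].isdigit():
            out.add(int(ab[1:]))
    return out


def prepare_cohort(karyotypes: pd.DataFrame) -> pd.DataFrame:
    """Attach gain sets and H-MM labels to a cohort frame.

    Expects columns modal_count and aberrations (iterables of canonical
    ids); adds ``gains`` (set of gained autosomes) and ``hmm`` (bool).
    """
    df = karyotypes.copy()
    df["gains"] = [_gain_set(abs_) for abs_ in df["aberrations"]]
    df["hmm"] = [is_hyperdiploid(int(m)) for m in df["modal_count"]]
    return df


def evaluate(test: TrisomyIndexTest, cohort: pd.DataFrame) -> TITEvaluation:
    """Confusion counts and metrics of one TI-T against modal-count truth."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    tp = fp = tn = fn = 0
    for gains, truth in zip(cohort["gains"], cohort["hmm"]):
        pred = predict(gains, test.chromosomes, test.min_trisomies)
        if pred and truth:
            tp += 1
        elif pred and not truth:
            fp += 1
        elif not pred and truth:
            fn += 1
        else:
            tn += 1
    return TITEvaluation(test, tp, fp, tn, fn, confusion_metrics(tp, fp, tn, fn))


def search_best(
    cohort: pd.DataFrame,
    candidate_pool=DEFAULT_POOL,
    set_size: int = 3,
    k_range=(1, 2, 3),
) -> list[TITEvaluation]:
    """Exhaustive TI-T search ranked by F-score (deterministic).

    Ties break by specificity, then lexicographic chromosome order,
    then k.  Raises when the cohort has no hyperdiploid karyotype
    (no positives to detect).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if not cohort["hmm"].any():
        raise ValueError("cohort contains no hyperdiploid karyotype")
    evaluations = []
    for chroms in combinations(sorted(candidate_pool), set_size):
        for k in k_range:
            if not (1 <= k <= set_size):
                continue
            test = TrisomyIndexTest(frozenset(chroms), k)
            evaluations.append(evaluate(test, cohort))
    evaluations.sort(
        key=lambda e: (
            -e.metrics.f_score,
            -e.metrics.specificity,
            tuple(sorted(e.test.chromosomes)),
            e.test.min_trisomies,
        )
    )
    return evaluations


def report_frame(evaluations: list[TITEvaluation]) -> pd.DataFrame:
    rows = [
        (
            "+".join(str(c) for c in sorted(e.test.chromosomes)),
            e.test.min_trisomies,
            e.tp,
            e.fp,
            e.tn,
            e.fn,
            e.metrics.sensitivity,
            e.metrics.specificity,
            e.metrics.ppv,
            e.metrics.f_score,
        )
        for e in evaluations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chromosomes",
            "k",
            "tp",
            "fp",
            "tn",
            "fn",
            "sensitivity",
            "specificity",
            "ppv",
            "f_score",
        ],
    )
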