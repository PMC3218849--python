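"""Whole-chromosome calling from CGH segments and the CGH co-occurrence test.

Every gained (lost) segment whose band interval spans the centromere —
i.e. includes at least one p-arm and one q-arm band of the cytoband
model — is called as a whole-chromosome gain (loss); segments internal
to one arm are ignored.  The co-occurrence test then runs the same
permutation machinery as the karyotype analysis but with no row-support
threshold, no hypergeometric prefilter, a single stratum (histology
ignored) and FDR instead of Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import CytoBand, CytobandModel
from .cooccurrence import PairCooccurrence, PairCooccurrenceResults
from .matrix import AberrationKaryotypeMatrix

SEGMENT_COLUMNS = ["sample_id", "chromosome", "start_band", "end_band", "direction"]


@dataclass(frozen=True)
class CGHSegment:
    """One gained or lost chromosomal segment, band-resolved."""

    chromosome: str
    start_band: CytoBand
    end_band: CytoBand
    direction: str  # 'gain' or 'loss'

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain/loss, got {self.direction!r}")
        if not (
            self.start_band.chromosome == self.chromosome == self.end_band.chromosome
        ):
            raise ValueError("segment endpoints must lie on the declared chromosome")


@dataclass
class CGHSample:
    """A sample's segments plus its derived whole-chromosome call set."""

    sample_id: str
    segments: list[CGHSegment] = field(default_factory=list)
    called: frozenset[str] = frozenset()


def load_segments(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chromosome": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CGH table is missing columns: {missing}")
    return df


def _segment_from_row(row) -> CGHSegment:
    chrom = str(row.chromosome)
    return CGHSegment(
        chrom,
        CytoBand(chrom, row.start_band[0], row.start_band[1:]),
        CytoBand(chrom, row.end_band[0], row.end_band[1:]),
        row.direction,
    )


def call_whole_chromosome(
    segments: list[CGHSegment], model: CytobandModel
) -> frozenset[str]:
    """Whole-chromosome gain/loss calls for one sample.

    A segment spanning the centromere yields ``+N``/``-N``; arm-internal
    segments contribute nothing; duplicate calls collapse.  A band
    absent from the model raises a KeyError naming it.
    """
    calls = set()
    for seg in segments:
        if model.spans_centromere(seg.start_band, seg.end_band):
            sign = "+" if seg.direction == "gain" else "-"
            calls.add(sign + seg.chromosome)
    return frozenset(calls)


def call_samples(segments: pd.DataFrame, model: CytobandModel) -> list[CGHSample]:
    """Group a segment table by sample and call each; order-independent."""
    samples = []
    for sample_id, group in segments.groupby("sample_id", sort=True):
        segs = [_segment_from_row(row) for row in group.itertuples(index=False)]
        samples.append(
            CGHSample(str(sample_id), segs, call_whole_chromosome(segs, model))
        )
    return samples


def calls_frame(samples: list[CGHSample]) -> pd.DataFrame:
    rows = [
        (s.sample_id, ab) for s in samples for ab in sorted(s.called)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "canonical_id"])


def build_cgh_matrix(samples: list[CGHSample]) -> AberrationKaryotypeMatrix:
    """Aberration x sample matrix; all aberrations kept, empty samples too."""
    col_ids = [s.sample_id for s in samples]
    row_ids = sorted({ab for s in samples for ab in s.called})
    if not row_ids:
        raise ValueError("no whole-chromosome call in any sample")
    entries = np.zeros((len(row_ids), len(col_ids)), dtype=np.uint8)
    row_idx = {ab: i for i, ab in enumerate(row_ids)}
    for j, s in enumerate(samples):
        for ab in s.called:
            entries[row_idx[ab], j] = 1
    return AberrationKaryotypeMatrix(entries, row_ids, col_ids)  # single stratum


def cgh_cooccurrence(
    samples: list[CGHSample],
    n_permutations: int,
    seed: int,
    fdr_level: float = 0.05,
    swaps_per_sample: int | None = None,
    burn_in: int | None = None,
) -> PairCooccurrenceResults:
    """Pair test on CGH calls: no support filter, no prefilter, FDR 5%."""
    matrix = build_cgh_matrix(samples)
    model = PairCooccurrence(matrix, prefilter_p_max=None, correction="fdr")
    return model.fit(
        n_permutations=n_permutations,
        seed=seed,
        swaps_per_sample=swaps_per_sample,
        burn_in=burn_in,
        alpha=fdr_level,
    )
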