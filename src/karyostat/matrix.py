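"""Binary presence matrices with column strata.

The :class:`AberrationKaryotypeMatrix` is the substrate of the
permutation null: rows are aberrations, columns karyotypes, and each
column carries a stratum label (its tumor class).  All null moves are
checkerboard swaps confined to one stratum, so row sums, column sums
and per-stratum row sums are invariant.  The same container (with a
single stratum) backs the class-similarity and CGH tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class AberrationKaryotypeMatrix:
    """Binary matrix entries with row ids, column ids and column strata."""

    def __init__(self, entries, row_ids, col_ids, col_strata=None):
        entries = np.asarray(entries, dtype=np.uint8)
        if entries.ndim != 2:
            raise ValueError("entries must be a 2-D matrix")
        if not np.isin(entries, (0, 1)).all():
            raise ValueError("entries must be binary")
        if entries.shape != (len(row_ids), len(col_ids)):
            raise ValueError("entries shape does not match id lists")
        if col_strata is None:
            col_strata = ["all"] * len(col_ids)
        if len(col_strata) != len(col_ids):
            raise ValueError("one stratum label per column required")
        self.entries = entries
        self.row_ids = list(row_ids)
        self.col_ids = list(col_ids)
        self.col_strata = list(col_strata)

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    @property
    def nnz(self) -> int:
        return int(self.entries.sum())

    def row_sums(self) -> np.ndarray:
        return self.entries.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.entries.sum(axis=0)

    def stratum_row_sums(self) -> pd.DataFrame:
        """Per-stratum row sums: rows = row_ids, columns = stratum labels."""
        codes, labels = self.stratum_codes()
        data = {
            lab: self.entries[:, codes == i].sum(axis=1)
            for i, lab in enumerate(labels)
        }
        return pd.DataFrame(data, index=self.row_ids)

    def stratum_codes(self) -> tuple[np.ndarray, list[str]]:
        """Integer stratum code per column plus the label list."""
        labels = sorted(set(self.col_strata))
        index = {lab: i for i, lab in enumerate(labels)}
        codes = np.array([index[s] for s in self.col_strata], dtype=np.int64)
        return codes, labels

    def row_index(self, row_id: str) -> int:
        return self.row_ids.index(row_id)

    def copy(self) -> "AberrationKaryotypeMatrix":
        return AberrationKaryotypeMatrix(
            self.entries.copy(), self.row_ids, self.col_ids, self.col_strata
        )

    def drop_rows(self, keep: list[str]) -> "AberrationKaryotypeMatrix":
        """Restrict to the given row ids (columns are always retained)."""
        idx = [self.row_ids.index(r) for r in keep]
        return AberrationKaryotypeMatrix(
            self.entries[idx, :], keep, self.col_ids, self.col_strata
        )


def build_matrix(
    aberration_table: pd.DataFrame,
    karyotypes: pd.DataFrame,
    min_row_support: int = 10,
) -> AberrationKaryotypeMatrix:
    """Assemble the aberration x karyotype presence matrix.

    Rows are aberrations occurring in at least ``min_row_support``
    karyotypes; columns are *all* karyotypes (a karyotype with no
    retained aberration keeps its all-zero column so column margins
    reflect it); strata are tumor classes.
    """
    col_ids = list(karyotypes["record_id"])
    strata = list(karyotypes["tumor_class"])
    occ = aberration_table.drop_duplicates(["record_id", "canonical_id"])
    support = occ.groupby("canonical_id")["record_id"].nunique()
    row_ids = sorted(support[support >= min_row_support].index)
    if not row_ids:
        raise ValueError(
            f"no aberration reaches the support threshold ({min_row_support})"
        )
    col_index = {c: j for j, c in enumerate(col_ids)}
    row_index = {r: i for i, r in enumerate(row_ids)}
    entries = np.zeros((len(row_ids), len(col_ids)), dtype=np.uint8)
    for rec, ab in occ[["record_id", "canonical_id"]].itertuples(index=False):
        if ab in row_index and rec in col_index:
            entries[row_index[ab], col_index[rec]] = 1
    return AberrationKaryotypeMatrix(entries, row_ids, col_ids, strata)
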