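"""Margin-preserving permutation null via checkerboard edge swaps.

The null space is the set of binary matrices sharing the observed row
sums, column sums and per-stratum row sums.  It is explored by a long
chain of checkerboard swaps: pick two rows and two columns within one
stratum; if the 2x2 submatrix is a checkerboard (10/01 or 01/10), flip
it, otherwise do nothing.  Swaps within a stratum connect every matrix
in the null space (the classical swap-randomization result applied per
stratum), and the chain's stationary distribution over margin classes
is uniform, which the test suite checks against exhaustive enumeration.

p-values follow the exceedance convention: with r samples at or above
the observed statistic out of N, p = r/N, floored at 1/N when r = 0.

The sampling kernel is numba-compiled; a pure-Python single move
(:func:`checkerboard_swap`) is exposed for inspection and testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from numba import njit

from .matrix import AberrationKaryotypeMatrix


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, exceedances r out of N samples, p = r/N (floor 1/N)."""

    observed: float
    N: int
    r: int

    @property
    def p(self) -> float:
        if self.N <= 0:
            raise ValueError("N must be positive")
        return self.r / self.N if self.r > 0 else 1.0 / self.N


def permutation_pvalue(r: int, N: int) -> float:
    return PermutationResult(0.0, N, r).p


def checkerboard_swap(matrix: AberrationKaryotypeMatrix, rng: np.random.Generator) -> bool:
    """One attempted swap move in place; returns True iff accepted.

    Proposals never span two strata; rejected proposals are silent no-ops.
    """
    m = matrix.entries
    nrows, ncols = m.shape
    if nrows < 2 or ncols < 2:
        return False
    codes, _ = matrix.stratum_codes()
    c1 = int(rng.integers(ncols))
    same = np.flatnonzero(codes == codes[c1])
    if same.size < 2:
        return False
    c2 = int(same[rng.integers(same.size)])
    if c1 == c2:
        return False
    r1, r2 = int(rng.integers(nrows)), int(rng.integers(nrows))
    if r1 == r2:
        return False
    a, b, c, d = m[r1, c1], m[r1, c2], m[r2, c1], m[r2, c2]
    if a == 1 and d == 1 and b == 0 and c == 0:
        m[r1, c1] = m[r2, c2] = 0
        m[r1, c2] = m[r2, c1] = 1
        return True
    if a == 0 and d == 0 and b == 1 and c == 1:
        m[r1, c1] = m[r2, c2] = 1
        m[r1, c2] = m[r2, c1] = 0
        return True
    return False


@njit(cache=True)
def _try_swap(mat, col_stratum, offsets, strata_cols, nrows, ncols):  # pragma: no cover
    c1 = np.random.randint(0, ncols)
    s = col_stratum[c1]
    lo = offsets[s]
    hi = offsets[s + 1]
    if hi - lo < 2:
        return 0
    c2 = strata_cols[lo + np.random.randint(0, hi - lo)]
    if c2 == c1:
        return 0
    r1 = np.random.randint(0, nrows)
    r2 = np.random.randint(0, nrows)
    if r1 == r2:
        return 0
    a = mat[r1, c1]
    b = mat[r1, c2]
    c = mat[r2, c1]
    d = mat[r2, c2]
    if a == 1 and d == 1 and b == 0 and c == 0:
        mat[r1, c1] = 0
        mat[r2, c2] = 0
        mat[r1, c2] = 1
        mat[r2, c1] = 1
        return 1
    if a == 0 and d == 0 and b == 1 and c == 1:
        mat[r1, c1] = 1
        mat[r2, c2] = 1
        mat[r1, c2] = 0
        mat[r2, c1] = 0
        return 1
    return 0


@njit(cache=True)
def _run_swaps(mat, col_stratum, offsets, strata_cols, attempts, seed):  # pragma: no cover
    np.random.seed(seed)
    nrows, ncols = mat.shape
    accepted = 0
    for _ in range(attempts):
        accepted += _try_swap(mat, col_stratum, offsets, strata_cols, nrows, ncols)
    return accepted


@njit(cache=True)
def _chain_exceedances(
    mat,
    col_stratum,
    offsets,
    strata_cols,
    pairs,
    obs,
    n_samples,
    spacing,
    burn_accept,
    seed,
):  # pragma: no cover
    np.random.seed(seed)
    nrows, ncols = mat.shape
    n_pairs = pairs.shape[0]
    exceed = np.zeros(n_pairs, dtype=np.int64)
    accepted = 0
    attempts = 0
    max_attempts = 50 * burn_accept + 1000
    while accepted < burn_accept and attempts < max_attempts:
        attempts += 1
        accepted += _try_swap(mat, col_stratum, offsets, strata_cols, nrows, ncols)
    for _ in range(n_samples):
        for _ in range(spacing):
            _try_swap(mat, col_stratum, offsets, strata_cols, nrows, ncols)
        for pi in range(n_pairs):
            r1 = pairs[pi, 0]
            r2 = pairs[pi, 1]
            cnt = 0
            for cc in range(ncols):
                if mat[r1, cc] == 1 and mat[r2, cc] == 1:
                    cnt += 1
            if cnt >= obs[pi]:
                exceed[pi] += 1
    return exceed


def _stratum_arrays(matrix: AberrationKaryotypeMatrix):
    codes, labels = matrix.stratum_codes()
    order = np.argsort(codes, kind="stable").astype(np.int64)
    counts = np.bincount(codes, minlength=len(labels))
    offsets = np.zeros(len(labels) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum(counts)
    return codes, offsets, order


def run_swaps(
    matrix: AberrationKaryotypeMatrix, attempts: int, seed: int
) -> tuple[AberrationKaryotypeMatrix, int]:
    """Run ``attempts`` swap attempts on a copy; returns (matrix, accepted)."""
    out = matrix.copy()
    codes, offsets, order = _stratum_arrays(out)
    accepted = _run_swaps(out.entries, codes, offsets, order, attempts, seed)
    return out, int(accepted)


def pair_counts(matrix: AberrationKaryotypeMatrix, pairs: np.ndarray) -> np.ndarray:
    """Co-occurrence count (shared columns) for each row pair."""
    m = matrix.entries.astype(np.int64)
    return np.array([int(m[i] @ m[j]) for i, j in pairs], dtype=np.int64)


def permutation_test(
    matrix: AberrationKaryotypeMatrix,
    pairs: np.ndarray,
    n_samples: int,
    seed: int,
    swaps_per_sample: int | None = None,
    burn_in: int | None = None,
) -> list[PermutationResult]:
    """Monte-Carlo exceedance test for row-pair co-occurrence counts.

    Default chain schedule: burn-in of 10x(number of ones) *accepted*
    swaps, then 2x(number of ones) attempted swaps between consecutive
    samples.  One chain serves all candidate pairs; the statistic of
    pair (r1, r2) is the number of columns where both rows are 1.
    """
    if n_samples <= 0:
        raise ValueError("the number of permutation samples must be positive")
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    nnz = matrix.nnz
    if swaps_per_sample is None:
        swaps_per_sample = 2 * nnz
    if burn_in is None:
        burn_in = 10 * nnz
    obs = pair_counts(matrix, pairs)
    work = matrix.entries.copy()
    codes, offsets, order = _stratum_arrays(matrix)
    exceed = _chain_exceedances(
        work,
        codes,
        offsets,
        order,
        pairs,
        obs,
        n_samples,
        swaps_per_sample,
        burn_in,
        seed % (2**31),
    )
    return [
        PermutationResult(float(o), n_samples, int(r)) for o, r in zip(obs, exceed)
    ]


# -- exact enumeration oracle (tiny matrices only) ---------------------------


def enumerate_margin_matrices(matrix: AberrationKaryotypeMatrix):
    """Yield every binary matrix with the same margins and strata.

    Brute force over per-column fills; intended for matrices with a
    handful of cells (the independent oracle for the Monte-Carlo test).
    """
    m = matrix.entries
    nrows, ncols = m.shape
    col_sums = m.sum(axis=0)
    codes, labels = matrix.stratum_codes()
    target = [
        m[:, codes == s].sum(axis=1) for s in range(len(labels))
    ]  # per-stratum row sums
    col_choices = [
        list(combinations(range(nrows), int(col_sums[j]))) for j in range(ncols)
    ]
    for fill in product(*col_choices):
        cand = np.zeros((nrows, ncols), dtype=np.uint8)
        for j, rows in enumerate(fill):
            for i in rows:
                cand[i, j] = 1
        ok = True
        for s in range(len(labels)):
            if not np.array_equal(cand[:, codes == s].sum(axis=1), target[s]):
                ok = False
                break
        if ok:
            yield cand


def exact_pair_tail(
    matrix: AberrationKaryotypeMatrix, pairs: np.ndarray
) -> np.ndarray:
    """Exact null tail P(count >= observed) by exhaustive enumeration."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    obs = pair_counts(matrix, pairs)
    total = 0
    hits = np.zeros(len(pairs), dtype=np.int64)
    for cand in enumerate_margin_matrices(matrix):
        total += 1
        for idx, (i, j) in enumerate(pairs):
            if int(cand[i] @ cand[j]) >= obs[idx]:
                hits[idx] += 1
    if total == 0:
        raise RuntimeError("enumeration produced no matrices")
    return hits / total
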