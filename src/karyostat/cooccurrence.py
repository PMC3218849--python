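"""Aberration pair co-occurrence under the stratified permutation null.

:class:`PairCooccurrence` is built from an
:class:`~karyostat.matrix.AberrationKaryotypeMatrix`; ``fit`` runs the
checkerboard-swap chain and returns a
:class:`PairCooccurrenceResults` carrying, per candidate pair, the
observed co-occurrence count, the permutation p-value (r/N, floor 1/N)
and its multiplicity correction, plus helpers to export the significant
network.

Candidate pairs must co-occur in at least one karyotype; in the default
(karyotype) configuration they must additionally pass a hypergeometric
prefilter at p <= 0.001, and rows appearing in no surviving pair are
removed from the matrix before permutation.  The CGH configuration
(``prefilter_p_max=None, correction='fdr'``) skips the prefilter and
uses FDR instead of Bonferroni.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .aberrations import kind_of_id, parse_canonical, TRANSLOCATION
from .matrix import AberrationKaryotypeMatrix
from .permutation import pair_counts, permutation_test
from .stats import bh_fdr, bonferroni, hypergeom_tail

DEFAULT_N_PERMUTATIONS = 10**6


def expected_link(ab1: str, ab2: str) -> bool:
    """Mechanistically expected co-occurrence between two aberrations.

    Expected links are (a) a translocation with a gain/loss of one of
    its derivative chromosomes, and (b) two translocations sharing a
    breakpoint band (the signature of a single three-break event).
    """
    try:
        a, b = parse_canonical(ab1), parse_canonical(ab2)
    except ValueError:
        return False
    for t, other in ((a, b), (b, a)):
        if t.kind == TRANSLOCATION and other.kind in ("gain", "loss"):
            if other.loci[0] in t.chromosomes:
                return True
    if a.kind == TRANSLOCATION and b.kind == TRANSLOCATION:
        if set(a.loci) & set(b.loci):
            return True
    return False


def prefilter_pairs(
    matrix: AberrationKaryotypeMatrix, p_max: float | None = 0.001
) -> pd.DataFrame:
    """Candidate pairs: co-occurring at least once, optional hypergeometric cut.

    The hypergeometric universe is all karyotypes (columns): for a pair
    with supports K and n and overlap k, p = P(X >= k), X ~ HG(M, K, n).
    """
    nrows, ncols = matrix.shape
    supports = matrix.row_sums().astype(int)
    rows = []
    all_pairs = np.array(list(combinations(range(nrows), 2)), dtype=np.int64)
    if all_pairs.size:
        counts = pair_counts(matrix, all_pairs)
        for (i, j), n_obs in zip(all_pairs, counts):
            if n_obs < 1:
                continue
            p = hypergeom_tail(int(n_obs), int(supports[j]), int(supports[i]), ncols)
            if p_max is None or p <= p_max:
                rows.append(
                    (matrix.row_ids[i], matrix.row_ids[j], int(i), int(j), int(n_obs), p)
                )
    return pd.DataFrame(
        rows, columns=["ab1", "ab2", "i", "j", "n_obs", "prefilter_p"]
    )


class PairCooccurrence:
    """Model object for the pair co-occurrence permutation test."""

    def __init__(
        self,
        matrix: AberrationKaryotypeMatrix,
        prefilter_p_max: float | None = 0.001,
        correction: str = "bonferroni",
    ):
        if correction not in ("bonferroni", "fdr"):
            raise ValueError("correction must be 'bonferroni' or 'fdr'")
        self.matrix = matrix
        self.prefilter_p_max = prefilter_p_max
        self.correction = correction
        self.candidates = prefilter_pairs(matrix, prefilter_p_max)
        # drop rows appearing in no candidate pair before permutation
        used = sorted(set(self.candidates["ab1"]) | set(self.candidates["ab2"]))
        self.pruned = matrix.drop_rows(used) if used else None

    def fit(
        self,
        n_permutations: int = DEFAULT_N_PERMUTATIONS,
        seed: int = 0,
        swaps_per_sample: int | None = None,
        burn_in: int | None = None,
        alpha: float = 0.05,
    ) -> "PairCooccurrenceResults":
        frame = self.candidates.copy()
        if frame.empty:
            frame = frame.assign(r=[], N=[], p=[], p_corrected=[], expected_link=[])
            return PairCooccurrenceResults(self, frame, alpha)
        idx = {ab: k for k, ab in enumerate(self.pruned.row_ids)}
        pairs = np.array(
            [(idx[a], idx[b]) for a, b in zip(frame["ab1"], frame["ab2"])],
            dtype=np.int64,
        )
        results = permutation_test(
            self.pruned,
            pairs,
            n_samples=n_permutations,
            seed=seed,
            swaps_per_sample=swaps_per_sample,
            burn_in=burn_in,
        )
        frame["r"] = [res.r for res in results]
        frame["N"] = n_permutations
        frame["p"] = [res.p for res in results]
        if self.correction == "bonferroni":
            _, frame["p_corrected"] = bonferroni(frame["p"].to_numpy(), alpha)
        else:
            _, frame["p_corrected"] = bh_fdr(frame["p"].to_numpy(), alpha)
        frame["expected_link"] = [
            expected_link(a, b) for a, b in zip(frame["ab1"], frame["ab2"])
        ]
        return PairCooccurrenceResults(self, frame, alpha)


class PairCooccurrenceResults:
    """Fitted pair test: per-pair statistics plus network exports."""

    def __init__(self, model: PairCooccurrence, frame: pd.DataFrame, alpha: float):
        self.model = model
        self.frame = frame.drop(columns=["i", "j"], errors="ignore")
        self.alpha = alpha

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = self.alpha if alpha is None else alpha
        return self.frame[self.frame["p_corrected"] < alpha].reset_index(drop=True)

    def to_network(self, alpha: float | None = None) -> nx.Graph:
        return build_network(self.frame, self.alpha if alpha is None else alpha)

    def summary(self) -> str:
        sig = self.significant()
        kinds = [
            tuple(sorted((kind_of_id(a), kind_of_id(b))))
            for a, b in zip(sig["ab1"], sig["ab2"])
        ]
        lines = [
            "Pair co-occurrence permutation test",
            f"  matrix: {self.model.matrix.shape[0]} aberrations x "
            f"{self.model.matrix.shape[1]} karyotypes "
            f"({len(set(self.model.matrix.col_strata))} strata)",
            f"  candidate pairs: {len(self.frame)}"
            + (
                f" (hypergeometric prefilter at {self.model.prefilter_p_max})"
                if self.model.prefilter_p_max is not None
                else " (no prefilter)"
            ),
            f"  correction: {self.model.correction}, alpha = {self.alpha}",
            f"  significant pairs: {len(sig)}",
            f"    gain-gain: {kinds.count(('gain', 'gain'))}",
            f"    loss-loss: {kinds.count(('loss', 'loss'))}",
            f"    gain-loss: {kinds.count(('gain', 'loss'))}",
            f"    involving other kinds: "
            f"{sum(1 for k in kinds if 'other' in k)}",
        ]
        return "\n".join(lines)

    def write_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def build_network(results: pd.DataFrame, alpha: float = 0.05) -> nx.Graph:
    """Significant co-occurrence graph with expected-link flags.

    Edges are pairs with corrected p below ``alpha``; an edge is flagged
    ``expected`` per :func:`expected_link`, and nodes incident only to
    expected edges are marked ``hidden`` (for display suppression).
    Node attribute ``kind`` is gain/loss/other.
    """
    g = nx.Graph()
    sig = results[results["p_corrected"] < alpha]
    for row in sig.itertuples(index=False):
        exp = bool(getattr(row, "expected_link", expected_link(row.ab1, row.ab2)))
        g.add_edge(
            row.ab1,
            row.ab2,
            n_obs=int(row.n_obs),
            p=float(row.p),
            p_corrected=float(row.p_corrected),
            expected=exp,
        )
    for node in g.nodes:
        g.nodes[node]["kind"] = kind_of_id(node)
        g.nodes[node]["hidden"] = all(
            data["expected"] for _, _, data in g.edges(node, data=True)
        )
    return g


def write_graphml(g: nx.Graph, path: str) -> None:
    nx.write_graphml(g, path)


def write_sif(g: nx.Graph, path: str) -> None:
    """Simple interaction format: one `node cooccurs node` line per edge."""
    with open(path, "w") as fh:
        for u, v in sorted(g.edges):
            fh.write(f"{u}\tcooccurs\t{v}\n")
        for node in sorted(g.nodes):
            if g.degree(node) == 0:
                fh.write(f"{node}\n")
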