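"""Tumor-class similarity from shared correlative aberrations.

An aberration is *t-correlative* to a class when its hypergeometric
enrichment p-value in that class is <= t.  The binary aberration x class
matrix M_t is permuted by unstratified checkerboard swaps (preserving
how many classes each aberration marks and how many aberrations each
class has), and each class pair is scored by the number of t-correlative
aberrations it shares.  Class similarity is S[C1,C2] = -log p with
S[C,C] = log N; classes are clustered by average linkage on
1 - Pearson(S rows).  The clustering is invariant to the log base
(a global positive rescaling of S), which the test suite asserts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import AberrationKaryotypeMatrix
from .permutation import permutation_test
from .stats import bh_fdr

DEFAULT_N_PERMUTATIONS = 10**7


@dataclass
class CorrelativeMatrix:
    """Binary aberration x class matrix M_t at correlativity threshold t."""

    entries: np.ndarray
    aberrations: list[str]
    classes: list[str]
    t: float

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.uint8)
        if self.entries.shape != (len(self.aberrations), len(self.classes)):
            raise ValueError("entries shape does not match id lists")

    @property
    def density(self) -> float:
        return float(self.entries.mean()) if self.entries.size else 0.0


def build_correlative_matrix(
    enrichment: pd.DataFrame,
    t: float = 0.05,
    use_fdr: bool = False,
    fdr_level: float = 0.05,
) -> CorrelativeMatrix:
    """M_t from an enrichment table (columns aberration/class/p/q).

    ``use_fdr=True`` selects the FDR-significant correlation set
    (q <= fdr_level) instead of the uncorrected p <= t cut, matching the
    stricter of the two published analyses.
    """
    aberrations = sorted(enrichment["aberration"].unique())
    classes = sorted(enrichment["class"].unique())
    ab_idx = {a: i for i, a in enumerate(aberrations)}
    cl_idx = {c: j for j, c in enumerate(classes)}
    entries = np.zeros((len(aberrations), len(classes)), dtype=np.uint8)
    hit = (
        enrichment["q"] <= fdr_level if use_fdr else enrichment["p"] <= t
    )
    sub = enrichment[hit]
    for ab, cls in zip(sub["aberration"], sub["class"]):
        entries[ab_idx[ab], cl_idx[cls]] = 1
    return CorrelativeMatrix(entries, aberrations, classes, t)


class ClassSimilarity:
    """Model object for the shared-correlative-aberration test."""

    def __init__(self, mt: CorrelativeMatrix):
        if mt.entries.size == 0:
            raise ValueError("empty correlative matrix")
        self.mt = mt
        # transpose: rows = classes, columns = aberrations, one stratum;
        # a checkerboard swap here preserves both matrix margins of M_t
        self._matrix = AberrationKaryotypeMatrix(
            mt.entries.T, mt.classes, mt.aberrations
        )

    def fit(
        self,
        n_permutations: int = DEFAULT_N_PERMUTATIONS,
        seed: int = 0,
        swaps_per_sample: int | None = None,
        burn_in: int | None = None,
        fdr_level: float = 0.05,
    ) -> "ClassSimilarityResults":
        classes = self.mt.classes
        pairs = np.array(list(combinations(range(len(classes)), 2)), dtype=np.int64)
        if pairs.size == 0:
            raise ValueError("need at least two classes")
        results = permutation_test(
            self._matrix,
            pairs,
            n_samples=n_permutations,
            seed=seed,
            swaps_per_sample=swaps_per_sample,
            burn_in=burn_in,
        )
        frame = pd.DataFrame(
            {
                "class1": [classes[i] for i, _ in pairs],
                "class2": [classes[j] for _, j in pairs],
                "n_shared": [int(res.observed) for res in results],
                "r": [res.r for res in results],
                "N": n_permutations,
                "p": [res.p for res in results],
            }
        )
        _, frame["q"] = bh_fdr(frame["p"].to_numpy(), level=fdr_level)
        return ClassSimilarityResults(self, frame, fdr_level)


@dataclass
class ClusteringResult:
    """Average-linkage dendrogram over the retained classes."""

    classes: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str


class ClassSimilarityResults:
    """Fitted class-pair test plus the similarity matrix and clustering."""

    def __init__(self, model: ClassSimilarity, frame: pd.DataFrame, fdr_level: float):
        self.model = model
        self.frame = frame
        self.fdr_level = fdr_level

    @property
    def n_permutations(self) -> int:
        return int(self.frame["N"].iloc[0])

    def significant(self, fdr_level: float | None = None) -> pd.DataFrame:
        level = self.fdr_level if fdr_level is None else fdr_level
        return self.frame[self.frame["q"] <= level].reset_index(drop=True)

    def retained_classes(self, fdr_level: float | None = None) -> list[str]:
        """Classes with at least one FDR-significant similarity partner."""
        sig = self.significant(fdr_level)
        return sorted(set(sig["class1"]) | set(sig["class2"]))

    def similarity_matrix(
        self, classes: list[str] | None = None, log_base: float = math.e
    ) -> pd.DataFrame:
        """S with S[C1,C2] = -log(p) and S[C,C] = log(N), symmetric."""
        classes = self.model.mt.classes if classes is None else classes
        scale = math.log(log_base)
        s = pd.DataFrame(0.0, index=classes, columns=classes)
        for c in classes:
            s.loc[c, c] = math.log(self.n_permutations) / scale
        wanted = set(classes)
        for row in self.frame.itertuples(index=False):
            if row.class1 in wanted and row.class2 in wanted:
                v = -math.log(row.p) / scale
                s.loc[row.class1, row.class2] = v
                s.loc[row.class2, row.class1] = v
        return s

    def cluster(self, fdr_level: float | None = None) -> ClusteringResult:
        """Average-linkage clustering on 1 - Pearson(S rows).

        Classes without any FDR-significant partner are dropped before S
        is assembled; ties in merge order follow scipy's deterministic
        lowest-index convention.  A change of the logarithm base in S is
        a global positive rescaling, under which Pearson correlation is
        exactly invariant; the correlation is therefore computed once on
        the natural-log S, making the merge order base-independent by
        construction.
        """
        retained = self.retained_classes(fdr_level)
        if len(retained) < 2:
            raise ValueError("fewer than two classes show significant similarity")
        s = self.similarity_matrix(retained)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(s.to_numpy())
        # a constant S row (every partner at the same level) has undefined
        # correlation; treat it as uncorrelated rather than propagate NaN
        corr = np.where(np.isfinite(corr), corr, 0.0)
        np.fill_diagonal(corr, 1.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        order = [retained[i] for i in hierarchy.leaves_list(link)]
        newick = _linkage_to_newick(link, retained)
        return ClusteringResult(retained, link, order, newick)

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            "Class similarity permutation test",
            f"  M_t: {len(self.model.mt.aberrations)} aberrations x "
            f"{len(self.model.mt.classes)} classes "
            f"(t = {self.model.mt.t}, density {self.model.mt.density:.4f})",
            f"  permutations: {self.n_permutations}",
            f"  class pairs tested: {len(self.frame)}",
            f"  significant at FDR {self.fdr_level:g}: {len(sig)}",
        ]
        return "\n".join(lines)

    def write_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a rooted Newick string."""
    tree = hierarchy.to_tree(link)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
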