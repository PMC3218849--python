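"""Class similarity: M_t construction, shared-aberration test, clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from karyostat.class_similarity import (
    ClassSimilarity,
    CorrelativeMatrix,
    build_correlative_matrix,
)
from karyostat.matrix import AberrationKaryotypeMatrix
from karyostat.permutation import exact_pair_tail


def _enrichment(rows):
    return pd.DataFrame(rows, columns=["aberration", "class", "p", "q"])


class TestCorrelativeMatrix:
    def test_threshold_is_inclusive(self):
        e = _enrichment([("+8", "A", 0.05, 0.3), ("+9", "A", 0.051, 0.3)])
        mt = build_correlative_matrix(e, t=0.05)
        assert mt.entries[mt.aberrations.index("+8"), 0] == 1
        assert mt.entries[mt.aberrations.index("+9"), 0] == 0

    def test_t_zero_gives_empty_matrix(self):
        e = _enrichment([("+8", "A", 0.001, 0.01)])
        assert build_correlative_matrix(e, t=0.0).entries.sum() == 0

    def test_fdr_selection_mode(self):
        e = _enrichment([("+8", "A", 0.01, 0.04), ("+9", "A", 0.02, 0.2)])
        mt = build_correlative_matrix(e, use_fdr=True, fdr_level=0.05)
        assert mt.entries.sum() == 1

    def test_density_reported(self):
        e = _enrichment([("+8", "A", 0.01, 0.01), ("+8", "B", 0.9, 0.9)])
        assert build_correlative_matrix(e, t=0.05).density == pytest.approx(0.5)


def _block_mt():
    """Three class groups sharing group-private aberrations."""
    classes = [f"c{j}" for j in range(6)]
    aberrations = [f"ab{i}" for i in range(12)]
    entries = np.zeros((12, 6), dtype=np.uint8)
    entries[0:4, 0] = entries[0:4, 1] = 1  # group 1: c0, c1
    entries[4:8, 2] = entries[4:8, 3] = 1  # group 2: c2, c3
    entries[8:12, 4] = entries[8:12, 5] = 1  # group 3: c4, c5
    return CorrelativeMatrix(entries, aberrations, classes, t=0.05)


class TestSharedPValues:
    def test_disjoint_classes_p_is_one(self):
        mt = _block_mt()
        res = ClassSimilarity(mt).fit(n_permutations=300, seed=0)
        row = res.frame[(res.frame["class1"] == "c0") & (res.frame["class2"] == "c2")]
        assert row["n_shared"].iloc[0] == 0
        assert row["p"].iloc[0] == 1.0

    def test_planted_pair_matches_exact_enumeration(self):
        # two classes with identical single-aberration profiles among fillers
        entries = np.zeros((4, 5), dtype=np.uint8)
        entries[0, 0] = entries[0, 1] = 1  # shared aberration for c0, c1
        entries[1, 2] = entries[2, 3] = entries[3, 4] = 1
        mt = CorrelativeMatrix(
            entries, [f"ab{i}" for i in range(4)], [f"c{j}" for j in range(5)], 0.05
        )
        model = ClassSimilarity(mt)
        transposed = AberrationKaryotypeMatrix(
            entries.T, mt.classes, mt.aberrations
        )
        exact = exact_pair_tail(transposed, [(0, 1)])[0]
        n = 20_000
        res = model.fit(n_permutations=n, seed=1)
        got = res.frame[
            (res.frame["class1"] == "c0") & (res.frame["class2"] == "c1")
        ]["p"].iloc[0]
        se = math.sqrt(exact * (1 - exact) / n)
        assert abs(got - exact) <= max(3 * se, 1.5 / n)
        assert exact < 0.5  # genuinely enriched configuration

    def test_floor_applies(self):
        mt = _block_mt()
        res = ClassSimilarity(mt).fit(n_permutations=200, seed=2)
        assert (res.frame["p"] >= 1 / 200).all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ClassSimilarity(CorrelativeMatrix(np.zeros((0, 0)), [], [], 0.05))


@pytest.fixture(scope="module")
def fitted():
    return ClassSimilarity(_block_mt()).fit(n_permutations=3000, seed=3)


class TestSimilarityAndClustering:
    def test_significant_pairs_within_groups_only(self, fitted):
        sig = fitted.significant()
        groups = {"c0": 0, "c1": 0, "c2": 1, "c3": 1, "c4": 2, "c5": 2}
        assert len(sig) == 3
        for c1, c2 in zip(sig["class1"], sig["class2"]):
            assert groups[c1] == groups[c2]

    def test_similarity_matrix_structure(self, fitted):
        s = fitted.similarity_matrix()
        n = fitted.n_permutations
        assert np.allclose(s.to_numpy(), s.to_numpy().T)
        assert np.allclose(np.diag(s), math.log(n))
        assert s.loc["c0", "c2"] == pytest.approx(-math.log(1.0))  # p = 1 -> 0

    def test_three_cluster_cut_recovers_groups(self, fitted):
        from scipy.cluster.hierarchy import fcluster

        clustering = fitted.cluster()
        assert len(clustering.leaf_order) == len(clustering.classes)
        labels = fcluster(clustering.linkage, t=3, criterion="maxclust")
        partition = {}
        for cls, lab in zip(clustering.classes, labels):
            partition.setdefault(lab, set()).add(cls)
        assert set(map(frozenset, partition.values())) == {
            frozenset({"c0", "c1"}),
            frozenset({"c2", "c3"}),
            frozenset({"c4", "c5"}),
        }

    def test_log_base_invariance(self, fitted):
        """Pearson of S rows is invariant to the log base; merge order bit-wise."""
        s_e = fitted.similarity_matrix(log_base=math.e).to_numpy()
        s_10 = fitted.similarity_matrix(log_base=10.0).to_numpy()
        assert np.allclose(np.corrcoef(s_e), np.corrcoef(s_10), rtol=1e-12, atol=1e-12)
        a, b = fitted.cluster(), fitted.cluster()
        assert np.array_equal(a.linkage[:, :2], b.linkage[:, :2])
        assert a.leaf_order == b.leaf_order

    def test_unrelated_class_absent_from_dendrogram(self):
        entries = np.zeros((5, 5), dtype=np.uint8)
        entries[0:4, 0] = entries[0:4, 1] = 1
        entries[4, 4] = 1  # c4 shares nothing
        mt = CorrelativeMatrix(
            entries, [f"ab{i}" for i in range(5)], [f"c{j}" for j in range(5)], 0.05
        )
        res = ClassSimilarity(mt).fit(n_permutations=3000, seed=4)
        retained = res.retained_classes()
        assert "c4" not in retained
        if len(retained) >= 2:
            assert "c4" not in res.cluster().leaf_order

    def test_newick_leaf_count(self, fitted):
        clustering = fitted.cluster()
        assert clustering.newick.count(",") == len(clustering.classes) - 1
        assert clustering.newick.endswith(";")
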