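"""Pair co-occurrence: matrix building, prefilter, fit, network flags."""

import numpy as np
import pandas as pd
import pytest

from karyostat.cooccurrence import (
    PairCooccurrence,
    build_network,
    expected_link,
    prefilter_pairs,
)
from karyostat.matrix import AberrationKaryotypeMatrix, build_matrix


def _cohort_frames(n_with=12, n_without=8):
    """Karyotypes where +8 occurs in n_with records, +21 in the same ones."""
    records = pd.DataFrame(
        {
            "record_id": [f"r{i}" for i in range(n_with + n_without)],
            "tumor_class": ["A"] * (n_with + n_without),
        }
    )
    rows = []
    for i in range(n_with):
        rows.append((f"r{i}", "+8"))
        rows.append((f"r{i}", "+21"))
    table = pd.DataFrame(rows, columns=["record_id", "canonical_id"])
    return table, records


class TestBuildMatrix:
    def test_support_threshold_at_ten(self):
        table, records = _cohort_frames(n_with=12)
        table = pd.concat(
            [
                table,
                pd.DataFrame(
                    {"record_id": [f"r{i}" for i in range(9)], "canonical_id": "-7"}
                ),
            ]
        )
        m = build_matrix(table, records, min_row_support=10)
        assert "-7" not in m.row_ids  # 9 karyotypes < 10
        assert set(m.row_ids) == {"+8", "+21"}
        table10 = pd.concat(
            [
                table,
                pd.DataFrame({"record_id": ["r9"], "canonical_id": ["-7"]}),
            ]
        )
        m = build_matrix(table10, records, min_row_support=10)
        assert "-7" in m.row_ids  # exactly 10 qualifies

    def test_zero_columns_retained(self):
        table, records = _cohort_frames(n_with=12, n_without=8)
        m = build_matrix(table, records, min_row_support=10)
        assert m.shape[1] == 20
        assert (m.col_sums() == 0).sum() == 8

    def test_empty_matrix_errors(self):
        table, records = _cohort_frames(n_with=3)
        with pytest.raises(ValueError):
            build_matrix(table, records, min_row_support=10)


class TestPrefilter:
    def test_disjoint_pair_excluded(self):
        entries = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.uint8)
        m = AberrationKaryotypeMatrix(entries, ["a", "b"], list("wxyz"))
        assert len(prefilter_pairs(m, p_max=None)) == 0  # n_obs = 0

    def test_hypergeometric_cut(self):
        # overlap of 2 in 20 karyotypes with supports 4/4: p > 0.001 -> cut
        entries = np.zeros((2, 20), dtype=np.uint8)
        entries[0, :4] = 1
        entries[1, 2:6] = 1
        m = AberrationKaryotypeMatrix(
            entries, ["a", "b"], [f"k{j}" for j in range(20)]
        )
        loose = prefilter_pairs(m, p_max=None)
        assert len(loose) == 1 and loose["n_obs"].iloc[0] == 2
        assert len(prefilter_pairs(m, p_max=0.001)) == 0

    def test_always_joint_pair_retained(self):
        # a and b always together in 15 of 30 karyotypes: p far below 0.001
        entries = np.zeros((3, 30), dtype=np.uint8)
        entries[0, :15] = entries[1, :15] = 1
        entries[2, 15:] = 1
        m = AberrationKaryotypeMatrix(
            entries, ["a", "b", "c"], [f"k{j}" for j in range(30)]
        )
        got = prefilter_pairs(m, p_max=0.001)
        assert ("a", "b") in set(zip(got["ab1"], got["ab2"]))
        assert got["prefilter_p"].min() < 1e-6

    def test_unused_rows_pruned_before_permutation(self):
        entries = np.zeros((3, 30), dtype=np.uint8)
        entries[0, :10] = 1
        entries[1, :10] = 1
        entries[2, 20:25] = 1  # co-occurs with nothing
        m = AberrationKaryotypeMatrix(
            entries, ["a", "b", "c"], [f"k{j}" for j in range(30)]
        )
        model = PairCooccurrence(m, prefilter_p_max=0.001)
        assert set(model.pruned.row_ids) == {"a", "b"}
        assert model.pruned.shape[1] == 30


class TestFit:
    def test_planted_pair_significant(self):
        rng = np.random.default_rng(0)
        entries = (rng.random((6, 300)) < 0.10).astype(np.uint8)
        # ab1 strongly tracks ab0 without being identical
        entries[0] = (rng.random(300) < 0.15).astype(np.uint8)
        entries[1] = np.where(
            entries[0] == 1,
            rng.random(300) < 0.7,
            rng.random(300) < 0.03,
        ).astype(np.uint8)
        m = AberrationKaryotypeMatrix(
            entries, [f"ab{i}" for i in range(6)], [f"k{j}" for j in range(300)]
        )
        # keep every co-occurring pair so all rows stay in the matrix: with
        # only the two planted rows retained, the margins would freeze the
        # overlap entirely (a singleton null space)
        res = PairCooccurrence(m, prefilter_p_max=None).fit(
            n_permutations=2000, seed=1
        )
        sig = res.significant()
        assert ("ab0", "ab1") in set(zip(sig["ab1"], sig["ab2"]))

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(2)
        entries = (rng.random((5, 100)) < 0.2).astype(np.uint8)
        m = AberrationKaryotypeMatrix(
            entries, [f"ab{i}" for i in range(5)], [f"k{j}" for j in range(100)]
        )
        model = PairCooccurrence(m, prefilter_p_max=None)
        a = model.fit(n_permutations=500, seed=7).frame
        b = model.fit(n_permutations=500, seed=7).frame
        pd.testing.assert_frame_equal(a, b)

    def test_p_floor_and_bounds(self):
        table, records = _cohort_frames(n_with=12)
        m = build_matrix(table, records)
        res = PairCooccurrence(m).fit(n_permutations=250, seed=3)
        assert ((res.frame["p"] >= 1 / 250) & (res.frame["p"] <= 1)).all()


class TestExpectedLinks:
    def test_two_whole_gains_not_expected(self):
        assert not expected_link("+8", "+21")

    def test_translocation_with_derivative_chromosome_gain(self):
        assert expected_link("t(9;22)(q34;q11)", "+22")
        assert expected_link("t(9;22)(q34;q11)", "-9")

    def test_band_sharing_translocations(self):
        assert expected_link("t(8;14)(q24;q32)", "t(14;18)(q32;q21)")
        assert not expected_link("t(8;14)(q24;q32)", "t(9;22)(q34;q11)")

    def test_network_hides_nodes_with_only_expected_edges(self):
        frame = pd.DataFrame(
            {
                "ab1": ["t(9;22)(q34;q11)", "+8"],
                "ab2": ["+22", "+21"],
                "n_obs": [5, 5],
                "p": [1e-4, 1e-4],
                "p_corrected": [1e-3, 1e-3],
                "expected_link": [True, False],
            }
        )
        g = build_network(frame, alpha=0.05)
        assert g.nodes["t(9;22)(q34;q11)"]["hidden"]
        assert g.nodes["+22"]["hidden"]
        assert not g.nodes["+8"]["hidden"]
        assert g.nodes["+8"]["kind"] == "gain"
        assert g.edges[("t(9;22)(q34;q11)", "+22")]["expected"]

    def test_network_excludes_non_significant_edges(self):
        frame = pd.DataFrame(
            {
                "ab1": ["+8"],
                "ab2": ["+21"],
                "n_obs": [5],
                "p": [0.2],
                "p_corrected": [1.0],
                "expected_link": [False],
            }
        )
        assert build_network(frame, alpha=0.05).number_of_edges() == 0
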