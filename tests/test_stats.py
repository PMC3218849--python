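"""Statistical primitives against brute-force oracles and hand computations."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from karyostat.stats import (
    bh_fdr,
    bonferroni,
    confusion_metrics,
    enrichment_table,
    hypergeom_tail,
)


def brute_force_tail(k, n, K, M):
    """P(overlap >= k) by enumerating all C(M, n) draws of n items."""
    marked = set(range(K))
    hits = total = 0
    for draw in combinations(range(M), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeomTail:
    def test_full_overlap_five_of_ten(self):
        assert hypergeom_tail(5, 5, 5, 10) == pytest.approx(1 / comb(10, 5))

    def test_zero_overlap_is_one(self):
        assert hypergeom_tail(0, 3, 4, 10) == 1.0

    def test_single_draw(self):
        assert hypergeom_tail(1, 1, 4, 10) == pytest.approx(0.4)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            hypergeom_tail(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_tail(2, 3, 11, 10)

    def test_matches_enumeration_up_to_m12(self):
        """Exact tail equals draw enumeration for every (k,n,K,M), M <= 12."""
        for M in range(1, 13):
            for K in range(M + 1):
                marked = set(range(K))
                for n in range(M + 1):
                    overlaps = [
                        len(marked.intersection(d))
                        for d in combinations(range(M), n)
                    ]
                    total = len(overlaps)
                    for k in range(min(n, K) + 1):
                        expected = sum(1 for o in overlaps if o >= k) / total
                        assert hypergeom_tail(k, n, K, M) == pytest.approx(
                            expected, abs=1e-12
                        )


class TestCorrections:
    def test_bh_hand_computation(self):
        reject, adj = bh_fdr([0.01, 0.02, 0.03, 0.5], level=0.05)
        assert reject.tolist() == [True, True, True, False]
        assert adj[:3] == pytest.approx([0.04, 0.04, 0.04])

    def test_bh_all_ones(self):
        reject, _ = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_bh_single(self):
        reject, _ = bh_fdr([0.04], level=0.05)
        assert reject.all()

    def test_bonferroni_adjustment(self):
        reject, adj = bonferroni([0.001] + [0.5] * 99, alpha=0.05)
        assert adj[0] == pytest.approx(0.1)
        assert not reject[0]
        reject, adj = bonferroni([1e-4] + [0.5] * 99, alpha=0.05)
        assert adj[0] == pytest.approx(0.01)
        assert reject[0]

    def test_bonferroni_single_is_identity(self):
        _, adj = bonferroni([0.04])
        assert adj[0] == pytest.approx(0.04)

    def test_empty_inputs(self):
        assert bh_fdr([])[0].size == 0
        assert bonferroni([])[0].size == 0

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
        st.floats(min_value=0.01, max_value=0.2),
    )
    def test_bh_rejections_superset_of_bonferroni(self, pvals, level):
        bh_reject, _ = bh_fdr(pvals, level=level)
        bonf_reject, _ = bonferroni(pvals, alpha=level)
        assert np.all(bh_reject | ~bonf_reject)


class TestConfusionMetrics:
    def test_balanced_half(self):
        m = confusion_metrics(tp=5, fp=5, tn=5, fn=5)
        assert m.sensitivity == m.ppv == 0.5
        assert m.f_score == pytest.approx(0.5)

    def test_perfect(self):
        m = confusion_metrics(tp=10, fp=0, tn=10, fn=0)
        assert (m.sensitivity, m.specificity, m.ppv, m.f_score) == (1, 1, 1, 1)

    def test_harmonic_mean_formula(self):
        # sens 0.88 with ppv 0.99 combine to F about 0.932
        m = confusion_metrics(tp=88, fp=1, tn=111, fn=12)
        ppv = 88 / 89
        f = 2 * ppv * 0.88 / (ppv + 0.88)
        assert m.f_score == pytest.approx(f)
        assert m.f_score == pytest.approx(0.9317, abs=5e-4)

    def test_zero_denominator_flagged(self):
        m = confusion_metrics(tp=0, fp=0, tn=5, fn=5)
        assert m.ppv == 0 and m.undefined
        assert m.f_score == 0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
    )
    def test_f_between_min_and_max_of_components(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m = confusion_metrics(tp, fp, tn, fn)
        assert min(m.sensitivity, m.ppv) - 1e-12 <= m.f_score
        assert m.f_score <= max(m.sensitivity, m.ppv) + 1e-12


class TestEnrichmentTable:
    def test_counts_and_family_corrections(self):
        import pandas as pd

        karyotypes = pd.DataFrame(
            {
                "record_id": [f"r{i}" for i in range(10)],
                "tumor_class": ["A"] * 5 + ["B"] * 5,
            }
        )
        ab = pd.DataFrame(
            {
                "record_id": ["r0", "r1", "r2", "r3", "r4"],
                "canonical_id": ["+8"] * 5,
            }
        )
        table = enrichment_table(ab, karyotypes)
        row = table.iloc[0]
        assert (row["M"], row["K"], row["n"], row["k"]) == (10, 5, 5, 5)
        assert row["p"] == pytest.approx(1 / comb(10, 5))
        assert (table["q"] <= table["p_bonferroni"] + 1e-12).all()
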