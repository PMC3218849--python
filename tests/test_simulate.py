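"""Synthetic generator: determinism, calibration, contamination, feasibility."""

import numpy as np
import pandas as pd
import pytest

from karyostat.cohort import apply_filter_cascade, parse_records
from karyostat.simulate import (
    BlockSpec,
    ClassSpec,
    CohortConfig,
    MMConfig,
    default_cgh_config,
    default_cohort_config,
    generate_cgh,
    generate_cohort,
    generate_mm_cohort,
    three_group_config,
)


class TestDeterminism:
    def test_same_config_and_seed_identical_output(self):
        cfg = default_cohort_config(seed=21)
        a_rec, a_tru = generate_cohort(cfg)
        b_rec, b_tru = generate_cohort(default_cohort_config(seed=21))
        pd.testing.assert_frame_equal(a_rec, b_rec)
        pd.testing.assert_frame_equal(a_tru, b_tru)
        assert a_rec.to_csv() == b_rec.to_csv()

    def test_cgh_and_mm_deterministic(self):
        a = generate_cgh(default_cgh_config(seed=3))[0]
        b = generate_cgh(default_cgh_config(seed=3))[0]
        pd.testing.assert_frame_equal(a, b)
        a = generate_mm_cohort(MMConfig(seed=3))[0]
        b = generate_mm_cohort(MMConfig(seed=3))[0]
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_cohort(default_cohort_config(seed=1))[0]
        b = generate_cohort(default_cohort_config(seed=2))[0]
        assert not a.equals(b)


class TestCalibration:
    def test_single_aberration_frequency_one(self):
        cfg = CohortConfig(
            classes=[ClassSpec("A", "lymphoid", 20)],
            aberration_pool={"A": {"+8": 1.0}},
            contamination={},
            seed=5,
        )
        records, truth = generate_cohort(cfg)
        assert len(records) == 20
        assert all(",+8" in s for s in records["iscn"])
        assert (truth["true_events"] == "+8").all()

    def test_marginal_frequency_within_three_binomial_ses(self):
        n = 10_000
        freq = 0.3
        cfg = CohortConfig(
            classes=[ClassSpec("A", "lymphoid", n)],
            aberration_pool={"A": {"+8": freq}},
            contamination={},
            seed=6,
        )
        _, truth = generate_cohort(cfg)
        hits = (truth["true_events"].str.contains(r"\+8", regex=True)).sum()
        se = np.sqrt(freq * (1 - freq) / n)
        assert abs(hits / n - freq) <= 3 * se

    def test_block_preserves_marginal_frequency(self):
        n = 10_000
        freq = 0.08
        cfg = CohortConfig(
            classes=[ClassSpec("A", "lymphoid", n)],
            aberration_pool={"A": {"+8": freq, "+9": freq}},
            gain_block=BlockSpec(("+8", "+9"), multiplier=6.0, activation_prob=1 / 6),
            contamination={},
            seed=7,
        )
        _, truth = generate_cohort(cfg)
        hits = truth["true_events"].str.contains(r"\+8", regex=True).sum()
        se = np.sqrt(freq * (1 - freq) / n)
        assert abs(hits / n - freq) <= 3 * se

    def test_mm_hyperdiploid_share(self):
        records, truth = generate_mm_cohort(MMConfig(seed=10))
        n, frac = 385, 0.29
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(truth["hmm"].mean() - frac) <= 3 * se


class TestContamination:
    def test_fractions_materialise_and_filter_out(self):
        cfg = default_cohort_config(seed=30)
        records, truth = generate_cohort(cfg)
        counts = truth["contaminant"].value_counts()
        n_core = (truth["contaminant"] == "").sum()
        assert n_core == 1200
        for kind in ("selected", "invalid", "non_near_diploid", "multiclonal"):
            assert counts[kind] == round(cfg.contamination[kind] * n_core)
        filtered, _, _ = apply_filter_cascade(parse_records(records))
        kept = set(filtered["record_id"])
        bad = set(truth[truth["contaminant"] != ""]["record_id"])
        assert not (kept & bad)

    def test_zero_contamination_clean(self):
        cfg = three_group_config(seed=1)
        records, truth = generate_cohort(cfg)
        assert (truth["contaminant"] == "").all()
        parsed = parse_records(records)
        assert parsed["valid"].all() and parsed["well_defined"].all()


class TestFeasibility:
    def test_infeasible_multiplier_raises(self):
        cfg = CohortConfig(
            classes=[ClassSpec("A", "lymphoid", 10)],
            aberration_pool={"A": {"+8": 0.3}},
            gain_block=BlockSpec(("+8",), multiplier=5.0, activation_prob=0.5),
            contamination={},
        )
        with pytest.raises(ValueError, match="infeasible"):
            generate_cohort(cfg)

    def test_bad_frequency_raises(self):
        cfg = CohortConfig(
            classes=[ClassSpec("A", "lymphoid", 10)],
            aberration_pool={"A": {"+8": 1.3}},
            contamination={},
        )
        with pytest.raises(ValueError):
            generate_cohort(cfg)

    def test_multiplier_below_one_raises(self):
        with pytest.raises(ValueError):
            BlockSpec(("+8",), multiplier=0.5).validate({"+8": 0.1})


class TestCGHGeneration:
    def test_truth_matches_calls_exactly(self):
        from karyostat.bands import default_cytoband_model
        from karyostat.cgh import call_samples

        cfg = default_cgh_config(seed=11)
        segments, truth = generate_cgh(cfg)
        samples = {s.sample_id: s.called for s in call_samples(segments, default_cytoband_model())}
        for sid, expected in zip(truth["sample_id"], truth["true_calls"]):
            want = frozenset(e for e in str(expected).split("|") if e)
            assert samples.get(sid, frozenset()) == want

    def test_all_internal_no_plants_calls_empty(self):
        from karyostat.bands import default_cytoband_model
        from karyostat.cgh import call_samples

        cfg = default_cgh_config(seed=12)
        cfg.call_freqs = {k: 0.0 for k in cfg.call_freqs}
        cfg.gain_block = cfg.loss_block = None
        segments, truth = generate_cgh(cfg)
        assert (truth["true_calls"] == "").all()
        for s in call_samples(segments, default_cytoband_model()):
            assert s.called == frozenset()
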