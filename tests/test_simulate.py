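"""Synthetic-data generators: composition, determinism, ground truth."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from aptamarkers import (
    FLANK3,
    FLANK5,
    SimulationConfig,
    simulate_amplification_curves,
    simulate_cohort,
    simulate_selection_reads,
)


class TestCohort:
    def test_study_composition_70_samples(self):
        cohort = simulate_cohort(SimulationConfig(n_samples=70, seed=1))
        counts = Counter(s.amyloid_class for s in cohort)
        assert counts["neg"] == 31 and counts["pos"] == 39

    def test_default_69_samples_after_outlier_exclusion(self):
        cohort = simulate_cohort(SimulationConfig(seed=5))
        counts = Counter(s.amyloid_class for s in cohort)
        assert counts["neg"] == 31 and counts["pos"] == 38

    def test_minimal_balanced_cohort(self):
        cohort = simulate_cohort(SimulationConfig(n_samples=2, pos_fraction=0.5, seed=0))
        assert Counter(s.amyloid_class for s in cohort) == {"neg": 1, "pos": 1}

    def test_class_threshold_invariant(self):
        for s in simulate_cohort(SimulationConfig(seed=3)):
            assert s.suvr > 0
            assert (s.amyloid_class == "pos") == (s.suvr > 0.79)

    def test_determinism(self):
        cfg = SimulationConfig(seed=17)
        assert simulate_cohort(cfg) == simulate_cohort(cfg)

    def test_single_class_config_raises_with_sizes(self):
        with pytest.raises(ValueError, match=r"0 negative|negative"):
            simulate_cohort(SimulationConfig(n_samples=3, pos_fraction=0.99, seed=0))


class TestCurves:
    def test_curve_count_and_length(self):
        cfg = SimulationConfig(n_samples=10, panel_size=4, n_informative=2, seed=2)
        cohort = simulate_cohort(cfg)
        curves, _ = simulate_amplification_curves(cohort, cfg)
        assert len(curves) == 10 * 4 * cfg.n_cycles
        per_curve = curves.groupby(["sample_id", "aptamer_id"]).size()
        assert (per_curve == cfg.n_cycles).all()

    def test_zero_shift_zero_noise_classes_identical(self):
        cfg = SimulationConfig(
            n_samples=10, panel_size=4, n_informative=2,
            cq_shift=0.0, cq_noise_sd=0.0, seed=2,
        )
        cohort = simulate_cohort(cfg)
        _, truth = simulate_amplification_curves(cohort, cfg)
        mids = truth["true_midpoints"].pivot(
            index="sample_id", columns="aptamer_id", values="true_midpoint"
        )
        assert (mids.nunique() == 1).all()  # one midpoint per aptamer, both classes

    def test_called_cq_class_difference_tracks_shift(self, small_config):
        """Downstream-called Cq means per class differ by ~cq_shift."""
        from aptamarkers import call_cq_table, cohort_to_frame, cq_long_to_wide

        cfg = small_config.replace(n_samples=40, cq_shift=2.0, cq_noise_sd=0.3)
        cohort = simulate_cohort(cfg)
        curves, truth = simulate_amplification_curves(cohort, cfg)
        wide = cq_long_to_wide(call_cq_table(curves, with_efficiency=False))
        cls = cohort_to_frame(cohort).set_index("sample_id")["amyloid_class"]
        for apt in truth["informative_aptamers"]:
            gap = abs(wide[apt].groupby(cls).mean().diff().iloc[-1])
            assert gap == pytest.approx(2.0, abs=0.6)

    def test_short_run_rejected(self):
        cfg = SimulationConfig(n_cycles=11, seed=0)
        cohort = simulate_cohort(cfg)
        with pytest.raises(ValueError, match="baseline window"):
            simulate_amplification_curves(cohort, cfg)

    def test_determinism(self):
        cfg = SimulationConfig(n_samples=5, panel_size=3, n_informative=1, seed=9)
        cohort = simulate_cohort(cfg)
        a, _ = simulate_amplification_curves(cohort, cfg)
        b, _ = simulate_amplification_curves(cohort, cfg)
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def libraries(tmp_path_factory, small_config):
    cfg = small_config.replace(reads_per_library=1500, seed=8)
    cohort = simulate_cohort(cfg)
    neg = [s for s in cohort if s.amyloid_class == "neg"][:4]
    pos = [s for s in cohort if s.amyloid_class == "pos"][:4]
    out = tmp_path_factory.mktemp("libs")
    return cfg, neg + pos, simulate_selection_reads(neg + pos, cfg, out)


class TestSelectionReads:
    def test_read_count_and_structure(self, libraries):
        cfg, samples, libs = libraries
        assert set(libs.fastq_paths) == {s.sample_id for s in samples}
        path = next(iter(libs.fastq_paths.values()))
        lines = path.read_text().splitlines()
        assert len(lines) == 4 * cfg.reads_per_library
        seqs = lines[1::4]
        assert all(len(s) == len(FLANK5) + 40 + len(FLANK3) == 86 for s in seqs)
        assert all(s.startswith(FLANK5) and s.endswith(FLANK3) for s in seqs)

    def test_enrichment_ratio_matches_binomial_expectation(self, tmp_path):
        cfg = SimulationConfig(
            n_samples=8, pos_fraction=0.5, reads_per_library=20_000,
            n_enriched_sequences=3, enrichment_fold=10.0,
            background_pool_size=200, seed=21,
        )
        cohort = simulate_cohort(cfg)
        libs = simulate_selection_reads(cohort, cfg, tmp_path)
        enriched = set(libs.enriched_sequences)
        freq = {"neg": [], "pos": []}
        for s in cohort:
            lines = libs.fastq_paths[s.sample_id].read_text().splitlines()
            kmers = [ln[23:63] for ln in lines[1::4]]
            hits = sum(1 for k in kmers if k in enriched)
            freq[s.amyloid_class].append(hits / len(kmers))
        # expected pooled frequency: 3/203 in neg, 30/230 in pos
        assert np.mean(freq["neg"]) == pytest.approx(3 / 203, rel=0.15)
        assert np.mean(freq["pos"]) == pytest.approx(30 / 230, rel=0.15)

    def test_no_enrichment_equal_frequencies(self, tmp_path):
        cfg = SimulationConfig(
            n_samples=6, pos_fraction=0.5, reads_per_library=20_000,
            enrichment_fold=1.0, background_pool_size=100, seed=4,
        )
        cohort = simulate_cohort(cfg)
        libs = simulate_selection_reads(cohort, cfg, tmp_path)
        enriched = set(libs.enriched_sequences)
        freq = {"neg": [], "pos": []}
        for s in cohort:
            lines = libs.fastq_paths[s.sample_id].read_text().splitlines()
            kmers = [ln[23:63] for ln in lines[1::4]]
            freq[s.amyloid_class].append(
                sum(k in enriched for k in kmers) / len(kmers)
            )
        assert np.mean(freq["pos"]) == pytest.approx(np.mean(freq["neg"]), abs=0.01)

    def test_byte_identical_determinism(self, tmp_path, small_config):
        cfg = small_config.replace(reads_per_library=500)
        cohort = simulate_cohort(cfg)
        subset = cohort[:6]
        if len({s.amyloid_class for s in subset}) < 2:  # ensure both classes
            subset = cohort
        a = simulate_selection_reads(subset, cfg, tmp_path / "a")
        b = simulate_selection_reads(subset, cfg, tmp_path / "b")
        for sid in a.fastq_paths:
            assert a.fastq_paths[sid].read_bytes() == b.fastq_paths[sid].read_bytes()

    def test_errors(self, tmp_path, small_cohort, small_config):
        neg_only = [s for s in small_cohort if s.amyloid_class == "neg"]
        with pytest.raises(ValueError, match="both classes"):
            simulate_selection_reads(neg_only, small_config, tmp_path)
        with pytest.raises(ValueError, match="reads_per_library"):
            simulate_selection_reads(
                small_cohort, small_config.replace(reads_per_library=0), tmp_path
            )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(panel_size=4, n_informative=5)
        with pytest.raises(ValueError):
            SimulationConfig(enrichment_fold=0.5)
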