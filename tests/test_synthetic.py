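"""Generator: transcriptome, genome, expression and library simulation."""

import numpy as np
import pandas as pd
import pytest

from dgetag.digest import canonical_3prime_tag, reverse_complement
from dgetag.synthetic import (SyntheticConfig, generate_genome,
                              generate_transcriptome, simulate_dge_library,
                              simulate_expression, simulate_study)


def small_config(**kw):
    defaults = dict(n_transcripts=20, length_mean=300.0, length_sd=50.0,
                    library_depths={"X1": 5000, "X2": 4000, "Xin": 2000},
                    de_spec=[("X1", 2, 8.0)], seed=42)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_impossible_length_rejected(self):
        with pytest.raises(ValueError, match="shorter than"):
            small_config(length_mean=10.0)

    def test_fold_below_one_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            small_config(de_spec=[("X1", 2, 0.5)])

    def test_overassigned_de_rejected(self):
        with pytest.raises(ValueError, match="more transcripts"):
            small_config(de_spec=[("X1", 15, 8.0), ("X2", 15, 8.0)])

    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError, match="antisense_rate"):
            small_config(antisense_rate=1.5)


class TestGenerateTranscriptome:
    def test_deterministic_under_fixed_seed(self):
        cfg = small_config(n_transcripts=1, length_mean=100.0, length_sd=0.0,
                           de_spec=[], seed=7)
        r1, _ = generate_transcriptome(cfg)
        r2, _ = generate_transcriptome(cfg)
        assert r1 == r2

    def test_gc_zero_yields_at_only_and_tagless(self):
        cfg = small_config(gc_fraction=0.0, novel_rate=0.0)
        records, truth = generate_transcriptome(cfg)
        for tid, seq in records:
            assert not set(seq) - set("AT")
            assert tid in truth.tagless_ids

    def test_most_transcripts_carry_valid_tag_site(self):
        cfg = small_config(n_transcripts=50, length_mean=500.0, novel_rate=0.0)
        records, _ = generate_transcriptome(cfg)
        with_site = sum(canonical_3prime_tag(seq) is not None for _, seq in records)
        assert with_site >= 48

    def test_withheld_ids_disjoint_from_reference(self):
        records, truth = generate_transcriptome(small_config(n_transcripts=100))
        assert truth.withheld_ids.isdisjoint({tid for tid, _ in records})
        assert len(truth.withheld_ids) == len(truth.withheld_records) == 5


class TestSimulateExpression:
    def test_columns_identical_without_de(self):
        cfg = small_config(de_spec=[], x2_mixture=None, fraction_dispersion=0.0)
        expr, labels = simulate_expression(cfg)
        assert labels == {}
        pd.testing.assert_series_equal(expr["X1"], expr["Xin"], check_names=False)

    def test_column_sums_are_one_million(self):
        expr, _ = simulate_expression(small_config(n_transcripts=200))
        assert np.allclose(expr.sum(axis=0), 1e6, rtol=1e-9)

    def test_planted_fold_recovered_within_renormalization_drift(self):
        cfg = small_config(n_transcripts=200, de_spec=[("X1", 1, 8.0)],
                           x2_mixture=None, fraction_dispersion=0.0, seed=17)
        expr, labels = simulate_expression(cfg)
        (tid, (sample, fold)), = labels.items()
        assert sample == "X1" and fold == 8.0
        ratio = expr.loc[tid, "X1"] / expr.loc[tid, "Xin"]
        assert ratio == pytest.approx(8.0, rel=0.05)

    def test_x2_mixture_blends_x1_and_xin(self):
        cfg = small_config(n_transcripts=100, de_spec=[("X1", 10, 8.0)], seed=3)
        expr, labels = simulate_expression(cfg)
        x1_ids = [t for t, (s, _) in labels.items() if s == "X1"]
        # X1-planted transcripts are partially elevated in the X2 blend
        assert (expr.loc[x1_ids, "X2"] > expr.loc[x1_ids, "Xin"]).all()
        assert (expr.loc[x1_ids, "X2"] < expr.loc[x1_ids, "X1"]).all()


class TestSimulateDgeLibrary:
    def _one_transcript(self):
        seq = "GG" + "CATG" + "ACGTACGTACGTACGTA" + "TT"
        cfg = SyntheticConfig(n_transcripts=1, length_mean=30.0,
                              library_depths={"X1": 1000}, de_spec=[],
                              antisense_rate=0.0, error_rate=0.0, novel_rate=0.0,
                              x2_mixture=None, seed=1)
        expr = pd.DataFrame({"X1": [1e6]}, index=["t1"])
        return [("t1", seq)], expr, cfg

    def test_single_transcript_single_tag(self):
        records, expr, cfg = self._one_transcript()
        lib = simulate_dge_library(records, expr, cfg, "X1")
        assert lib.counts == {"CATGACGTACGTACGTACGTA": 1000}
        assert lib.total_reads == 1000

    def test_error_rate_one_mutates_every_read(self):
        records, expr, cfg = self._one_transcript()
        cfg.error_rate = 1.0
        lib = simulate_dge_library(records, expr, cfg, "X1")
        canonical = "CATGACGTACGTACGTACGTA"
        assert canonical not in lib.counts
        for tag in lib.counts:
            assert sum(a != b for a, b in zip(tag, canonical)) == 1

    def test_depth_conserved_and_counts_near_multinomial(self):
        cfg = SyntheticConfig(n_transcripts=200, library_depths={"X1": 1_000_000},
                              de_spec=[], antisense_rate=0.0, error_rate=0.0,
                              novel_rate=0.0, x2_mixture=None, seed=42)
        records, truth = generate_transcriptome(cfg)
        expr, _ = simulate_expression(cfg)
        lib = simulate_dge_library(records, expr, cfg, "X1", truth=truth)
        assert lib.n_reads_retained == 1_000_000
        depth = 1_000_000
        taggable = [tid for tid, _ in records if tid in truth.canonical_tags]
        weights = expr.loc[taggable, "X1"].to_numpy()
        weights = weights / weights.sum()
        within = 0
        for tid, p in zip(taggable, weights):
            observed = lib.counts.get(truth.canonical_tags[tid], 0)
            sd = np.sqrt(depth * p * (1 - p))
            if abs(observed - depth * p) <= 3 * sd:
                within += 1
        assert within >= 0.95 * len(taggable)

    def test_truth_linkage_with_zero_noise(self, clean_scenario):
        """Every emitted tag is the canonical tag of exactly one transcript."""
        tag_to_tid = {}
        for tid, tag in clean_scenario.truth.canonical_tags.items():
            assert tag not in tag_to_tid
            tag_to_tid[tag] = tid
        for lib in clean_scenario.libraries.values():
            assert set(lib.counts) <= set(tag_to_tid)
            assert lib.n_reads_retained == lib.total_reads


class TestGenerateGenome:
    def test_zero_spacer_single_transcript_covers_contig(self):
        seq = "CATG" + "ACGT" * 10
        contigs, placements = generate_genome([("t1", seq)], spacer_mean=0.0,
                                              seed=2)
        (cid, genome_seq), = contigs
        (p,) = placements
        assert p.start == 1 and p.end == len(seq) == len(genome_seq)
        if p.strand == "+":
            assert genome_seq == seq
        else:
            assert genome_seq == reverse_complement(seq)

    def test_reverse_strand_definition(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        for seed in range(6):
            contigs, (p,) = generate_genome([("t1", seq)], spacer_mean=100.0,
                                            seed=seed)
            genome_seq = contigs[0][1]
            if p.strand == "-":
                assert genome_seq.find(seq) == -1 or len(seq) < 30
                assert genome_seq[p.start - 1:p.end] == reverse_complement(seq)
                break
        else:
            pytest.fail("no reverse-strand placement in 6 seeds")

    def test_placements_recover_transcripts(self, clean_scenario):
        genome = dict(clean_scenario.genome)
        seqs = dict(clean_scenario.reference + clean_scenario.truth.withheld_records)
        for p in clean_scenario.placements:
            embedded = genome[p.contig][p.start - 1:p.end]
            expected = seqs[p.transcript_id]
            if p.strand == "-":
                expected = reverse_complement(expected)
            assert embedded == expected


class TestSimulateStudy:
    def test_deterministic(self):
        cfg = small_config()
        s1 = simulate_study(cfg)
        s2 = simulate_study(cfg)
        assert s1.reference == s2.reference
        for sample in cfg.samples:
            assert s1.libraries[sample].counts == s2.libraries[sample].counts

    def test_depths_match_config(self, default_scenario):
        for sample, depth in default_scenario.config.library_depths.items():
            assert default_scenario.libraries[sample].n_reads_retained == depth
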