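"""Synthetic-locus generator: determinism, structural invariants, and the
statistical behavior of the read sampler."""

import dataclasses

import numpy as np
import pytest

from locuskit.models import model_lengths, splice_transcript
from locuskit.simulate import (SimulationConfig, plant_retrocopy,
                               plant_tandem_duplicate, simulate_gene,
                               simulate_neighborhood, simulate_reads,
                               simulate_reads_from_transcripts, substream)


class TestConfigValidation:
    def test_intron_exon_count_mismatch(self):
        with pytest.raises(ValueError, match="introns"):
            SimulationConfig(exon_lengths=(100, 100), intron_lengths=())

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(isoform_weights=(0.5, 0.2),
                             isoforms=((1, 2, 3, 4, 5, 6), (1, 2, 3)))

    def test_coding_frame_violation_rejected(self):
        cfg = SimulationConfig(exon_lengths=(100,), intron_lengths=(),
                               utr5_length=10, utr3_length=20)
        # 70 coding nt is not a multiple of 3
        with pytest.raises(ValueError, match="multiple of 3"):
            simulate_gene(cfg)


class TestSimulateGene:
    def test_fixed_seed_is_bit_identical(self, small_config):
        g1, t1 = simulate_gene(small_config)
        g2, t2 = simulate_gene(small_config)
        assert g1 == g2
        assert t1.gene_model == t2.gene_model
        r1 = simulate_reads(g1, t1, small_config)
        r2 = simulate_reads(g2, t2, small_config)
        assert r1.reads == r2.reads

    def test_structure_matches_config(self, simulated, small_config):
        genome, truth, _ = simulated
        lengths = model_lengths(truth.gene_model)
        assert lengths.mrna_length == sum(small_config.exon_lengths)
        assert lengths.gene_length == small_config.gene_span
        assert len(genome) == small_config.chromosome_length

    def test_spliced_transcript_equals_concatenated_exons(self, simulated):
        genome, truth, _ = simulated
        transcript = splice_transcript(genome, truth.gene_model)
        spans = truth.gene_model.exon_genomic_spans()
        assert transcript == "".join(genome[s:e] for s, e in spans)
        assert len(transcript) == model_lengths(truth.gene_model).mrna_length

    def test_introns_are_gt_ag(self, simulated):
        genome, truth, _ = simulated
        spans = truth.gene_model.exon_genomic_spans()
        for (_, e1), (s2, _) in zip(spans[:-1], spans[1:]):
            intron = genome[e1:s2]
            assert intron.startswith("GT") and intron.endswith("AG")

    def test_cds_start_stop(self, simulated, small_config):
        genome, truth, _ = simulated
        transcript = splice_transcript(genome, truth.gene_model)
        cds = transcript[small_config.utr5_length:
                         small_config.utr5_length + small_config.coding_length]
        assert cds.startswith("ATG")
        assert cds[-3:] in ("TAA", "TAG", "TGA")

    def test_hexamer_planted_at_offset(self, simulated, small_config):
        genome, truth, _ = simulated
        hp = truth.hexamer_position
        assert genome[hp : hp + 6] == small_config.polya_hexamer
        assert truth.cleavage_position - (hp + 6) == small_config.cleavage_offset

    def test_single_fully_coding_exon(self):
        cfg = SimulationConfig(exon_lengths=(300,), intron_lengths=(),
                               utr5_length=0, utr3_length=0, n_reads=10,
                               read_length=50, chromosome_length=2000)
        genome, truth = simulate_gene(cfg)
        lengths = model_lengths(truth.gene_model)
        assert lengths.gene_length == lengths.mrna_length == 300
        transcript = splice_transcript(genome, truth.gene_model)
        assert transcript == genome[truth.tss_position:truth.tss_position + 300]


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = SimulationConfig(seed=5, n_reads=300, error_rate=0.0,
                               polya_tail_rate=0.0)
        genome, truth = simulate_gene(cfg)
        reads = simulate_reads(genome, truth, cfg)
        transcript = splice_transcript(genome, truth.gene_model)
        for _, seq, _ in reads.reads:
            assert seq in transcript

    def test_tailed_reads_end_in_a_run(self):
        cfg = SimulationConfig(seed=5, n_reads=500, error_rate=0.0,
                               polya_tail_rate=0.5)
        genome, truth = simulate_gene(cfg)
        reads = simulate_reads(genome, truth, cfg)
        transcript = splice_transcript(genome, truth.gene_model)
        tailed = [r for r, p in zip(reads.reads, reads.provenance)
                  if p["tail_length"] > 0]
        assert tailed
        for rid, seq, _ in tailed:
            prov = next(p for p in reads.provenance if p["read_id"] == rid)
            tail = prov["tail_length"]
            assert 5 <= tail <= 20
            assert seq.endswith("A" * tail)
            assert seq[: len(seq) - tail] == transcript[-(len(seq) - tail):]

    def test_zero_weight_isoform_never_sampled(self):
        cfg = SimulationConfig(seed=9, n_reads=400, error_rate=0.0,
                               polya_tail_rate=0.0,
                               isoforms=((1, 2, 3, 4, 5, 6), (1, 2, 3, 6)),
                               isoform_weights=(1.0, 0.0))
        genome, truth = simulate_gene(cfg)
        reads = simulate_reads(genome, truth, cfg)
        assert all(p["isoform"] == 0 for p in reads.provenance)

    def test_read_length_exceeding_transcript_rejected(self):
        cfg = SimulationConfig(seed=1, exon_lengths=(60,), intron_lengths=(),
                               utr5_length=0, utr3_length=0, read_length=100,
                               n_reads=10, chromosome_length=2000)
        genome, truth = simulate_gene(cfg)
        with pytest.raises(ValueError, match="read length"):
            simulate_reads(genome, truth, cfg)

    def test_error_count_matches_binomial_expectation(self):
        cfg = SimulationConfig(seed=13, n_reads=2000, error_rate=0.01,
                               polya_tail_rate=0.0)
        genome, truth = simulate_gene(cfg)
        reads = simulate_reads(genome, truth, cfg)
        transcript = splice_transcript(genome, truth.gene_model)
        mismatches = 0
        for (rid, seq, _), prov in zip(reads.reads, reads.provenance):
            expected = transcript[prov["start"]:prov["start"] + len(seq)]
            mismatches += sum(1 for a, b in zip(seq, expected) if a != b)
        n_bases = cfg.n_reads * cfg.read_length
        expectation = n_bases * cfg.error_rate
        sigma = np.sqrt(n_bases * cfg.error_rate * (1 - cfg.error_rate))
        assert abs(mismatches - expectation) <= 3 * sigma


class TestPlanting:
    def test_zero_divergence_copy_is_identical(self, simulated):
        genome, truth, _ = simulated
        new_genome, new_truth = plant_retrocopy(genome, truth, 0.0, 19000)
        lo, hi = new_truth.retrocopy_span
        transcript = splice_transcript(new_genome, new_truth.gene_model)
        assert new_genome[lo:hi] == transcript

    def test_divergence_within_binomial_bounds(self, simulated):
        genome, truth, _ = simulated
        new_genome, new_truth = plant_retrocopy(genome, truth, 0.1, 19000)
        lo, hi = new_truth.retrocopy_span
        transcript = splice_transcript(new_genome, new_truth.gene_model)
        n = len(transcript)
        observed = sum(1 for a, b in zip(new_genome[lo:hi], transcript) if a != b)
        sigma = np.sqrt(n * 0.1 * 0.9)
        assert abs(observed - 0.1 * n) <= 3 * sigma

    def test_insertion_inside_parent_rejected(self, simulated):
        genome, truth, _ = simulated
        inside = truth.tss_position + 100
        with pytest.raises(ValueError, match="inside the parent"):
            plant_retrocopy(genome, truth, 0.05, inside)

    def test_upstream_insertion_shifts_truth_coordinates(self, simulated):
        genome, truth, _ = simulated
        new_genome, new_truth = plant_retrocopy(genome, truth, 0.0, 100)
        shift = new_truth.retrocopy_span[1] - new_truth.retrocopy_span[0]
        assert new_truth.tss_position == truth.tss_position + shift
        assert new_truth.cleavage_position == truth.cleavage_position + shift
        # the shifted model still splices to the same transcript
        assert (splice_transcript(new_genome, new_truth.gene_model)
                == splice_transcript(genome, truth.gene_model))

    def test_tandem_duplicate_retains_introns(self, simulated):
        genome, truth, _ = simulated
        new_genome, new_truth = plant_tandem_duplicate(genome, truth, 0.0, 19000)
        lo, hi = new_truth.paralog_span
        parent_lo = new_truth.gene_model.genomic_start
        span = new_truth.gene_model.gene_span()
        assert new_genome[lo:hi] == new_genome[parent_lo:parent_lo + span]


class TestNeighborhood:
    def test_order_and_orientation_preserved(self, small_config):
        genome, locus = simulate_neighborhood(small_config)
        expected = [(n, s) for n, s, _ in small_config.neighbor_genes]
        assert [(g.name, g.strand) for g in locus.genes] == expected
        assert len(genome) == small_config.chromosome_length

    def test_empty_gene_list_rejected(self, small_config):
        cfg = dataclasses.replace(small_config, neighbor_genes=())
        with pytest.raises(ValueError, match="non-empty"):
            simulate_neighborhood(cfg)

    def test_overlong_genes_rejected(self, small_config):
        cfg = dataclasses.replace(
            small_config,
            neighbor_genes=(("a", "+", 15000), ("b", "-", 15000)))
        with pytest.raises(ValueError, match="do not fit"):
            simulate_neighborhood(cfg)

    def test_single_strand_flip_changes_only_that_gene(self, small_config):
        flipped_genes = tuple(
            (n, "+" if n == "Hars2" else s, l)  # Hars2 is "-" by default
            for n, s, l in small_config.neighbor_genes)
        cfg2 = dataclasses.replace(small_config, neighbor_genes=flipped_genes)
        _, locus1 = simulate_neighborhood(small_config)
        _, locus2 = simulate_neighborhood(cfg2)
        diffs = [(g1.name) for g1, g2 in zip(locus1.genes, locus2.genes)
                 if (g1.name, g1.strand) != (g2.name, g2.strand)]
        assert diffs == ["Hars2"]


def test_substreams_are_independent_and_stable():
    a1 = substream(7, "gene").integers(0, 1000, 5)
    a2 = substream(7, "gene").integers(0, 1000, 5)
    b = substream(7, "reads").integers(0, 1000, 5)
    assert list(a1) == list(a2)
    assert list(a1) != list(b)
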