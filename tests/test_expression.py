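"""Read matching, probe hit counting, boundary calls, poly(A) detection,
exon usage, and paralog expression ratios."""

import dataclasses

import numpy as np
import pytest

from locuskit.expression import (ACCEPTED_HEXAMERS, HitProfile, ReadSet,
                                 call_five_prime, call_three_prime,
                                 count_probe_hits, exon_usage,
                                 map_reads_to_region,
                                 paralog_expression_ratio, scan_polya_signals)
from locuskit.models import splice_transcript
from locuskit.probes import tile_probes
from locuskit.simulate import (SimulationConfig, random_sequence,
                               simulate_gene, simulate_reads)


def _reads(seqs, name="lib"):
    return ReadSet(reads=[(f"r{i}", s, None) for i, s in enumerate(seqs)],
                   library_name=name)


class TestProbeCounting:
    def test_exact_containment_counts_every_read(self, rng):
        probe_seq = random_sequence(rng, 60)
        probes = tile_probes(probe_seq, 60, source="p")
        flank = random_sequence(rng, 20)
        reads = _reads([flank + probe_seq + random_sequence(rng, 20)] * 10)
        profile = count_probe_hits(probes, reads)
        assert profile.counts["p-a"] == 10

    def test_three_mismatches_rejected_two_accepted(self, rng):
        probe_seq = random_sequence(rng, 60)
        probes = tile_probes(probe_seq, 60, source="p")
        sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
        two = list(probe_seq)
        for pos in (20, 40):
            two[pos] = sub[two[pos]]
        three = list(probe_seq)
        for pos in (15, 30, 45):
            three[pos] = sub[three[pos]]
        reads = _reads(["".join(two), "".join(three)])
        profile = count_probe_hits(probes, reads, max_mismatches=2)
        assert profile.counts["p-a"] == 1

    def test_reverse_strand_reads_counted(self, rng):
        from locuskit.expression import reverse_complement
        probe_seq = random_sequence(rng, 60)
        probes = tile_probes(probe_seq, 60, source="p")
        reads = _reads([reverse_complement(probe_seq)])
        assert count_probe_hits(probes, reads).counts["p-a"] == 1

    def test_empty_read_set_warns_all_zero(self, rng):
        probes = tile_probes(random_sequence(rng, 60), 60, source="p")
        with pytest.warns(UserWarning, match="empty read set"):
            profile = count_probe_hits(probes, _reads([]))
        assert all(v == 0 for v in profile.counts.values())

    def test_counts_monotone_in_mismatch_tolerance(self):
        cfg = SimulationConfig(seed=23, n_reads=800, error_rate=0.01,
                               polya_tail_rate=0.0)
        genome, truth = simulate_gene(cfg)
        reads = simulate_reads(genome, truth, cfg)
        transcript = splice_transcript(genome, truth.gene_model)
        probes = tile_probes(transcript, 60, source="tx")
        totals = []
        for mm in (0, 1, 2, 3):
            profile = count_probe_hits(probes, reads, max_mismatches=mm)
            totals.append(sum(profile.counts.values()))
        assert totals == sorted(totals)

    def test_hit_counts_within_poisson_bounds_of_coverage_expectation(self):
        cfg = SimulationConfig(seed=31, n_reads=10_000, error_rate=0.0,
                               polya_tail_rate=0.0)
        genome, truth = simulate_gene(cfg)
        reads = simulate_reads(genome, truth, cfg)
        transcript = splice_transcript(genome, truth.gene_model)
        probes = tile_probes(transcript, 60, source="tx")
        profile = count_probe_hits(probes, reads)
        length = len(transcript)
        n_starts = length - cfg.read_length + 1
        for p in probes:
            # a read starting at s overlaps the probe by
            # min(p+60, s+rl) - max(p, s); hits need overlap >= seed (11)
            count = sum(
                1 for s in range(n_starts)
                if min(p.offset + 60, s + cfg.read_length) - max(p.offset, s) >= 11
            )
            expected = cfg.n_reads * count / n_starts
            assert abs(profile.counts[p.id] - expected) <= 3 * np.sqrt(expected)


class TestFivePrime:
    def test_longest_clone_rule_on_fixed_offsets(self, rng):
        region = random_sequence(rng, 300)
        reads = _reads([region[o : o + 50] for o in (10, 5, 23)])
        call = call_five_prime(region, reads)
        assert call.position == 5
        assert call.method == "longest-clone"

    def test_no_reads_is_an_error(self, rng):
        with pytest.raises(ValueError, match="no expression evidence"):
            call_five_prime(random_sequence(rng, 300), _reads(["ACGT" * 20]))

    def test_utr_lower_bound_from_atg(self, rng):
        region = random_sequence(rng, 300)
        reads = _reads([region[40:140]])
        call = call_five_prime(region, reads, atg_position=120)
        assert call.utr_length == 80

    def test_call_never_shrinks_with_added_reads(self, rng):
        region = random_sequence(rng, 400)
        base = [region[o : o + 60] for o in (50, 90)]
        more = [region[o : o + 60] for o in (30, 200)]
        pos_base = call_five_prime(region, _reads(base)).position
        pos_more = call_five_prime(region, _reads(base + more)).position
        assert pos_more <= pos_base

    def test_simulated_utr_recovery_within_two_nt(self):
        cfg = SimulationConfig(seed=47, n_reads=5000, error_rate=0.001,
                               polya_tail_rate=0.0)
        genome, truth = simulate_gene(cfg)
        reads = simulate_reads(genome, truth, cfg)
        pad = 200
        spans = truth.gene_model.exon_genomic_spans()
        region = genome[truth.tss_position - pad : spans[0][1] + 50]
        call = call_five_prime(region, reads,
                               atg_position=pad + cfg.utr5_length)
        assert abs(call.utr_length - cfg.utr5_length) <= 2


class TestPolyA:
    def test_single_hexamer_found(self, rng):
        seq = "C" * 50 + "AATAAA" + "C" * 44
        hits = scan_polya_signals(seq)
        assert len(hits) == 1
        assert hits[0].hexamer_position == 50

    def test_chicken_style_variant_accepted(self):
        assert "ATTTTA" in ACCEPTED_HEXAMERS
        hits = scan_polya_signals("G" * 10 + "ATTTTA" + "G" * 10)
        assert [h.hexamer for h in hits] == ["ATTTTA"]

    def test_no_signal_empty(self):
        assert scan_polya_signals("GAGAGAGAGAGAGAGAGAGA") == []

    def test_hits_in_five_to_three_order(self):
        seq = "C" * 10 + "AATAAA" + "C" * 10 + "ATTAAA" + "C" * 10
        hits = scan_polya_signals(seq)
        assert [h.hexamer_position for h in hits] == [10, 26]


class TestThreePrime:
    @pytest.mark.parametrize("hexamer,offset", [("ATTTTA", 8), ("ATTAAA", 12)])
    def test_planted_cleavage_offset_recovered_exactly(self, hexamer, offset):
        cfg = SimulationConfig(seed=61, n_reads=2000, error_rate=0.001,
                               polya_tail_rate=0.25, polya_hexamer=hexamer,
                               cleavage_offset=offset)
        genome, truth = simulate_gene(cfg)
        reads = simulate_reads(genome, truth, cfg)
        spans = truth.gene_model.exon_genomic_spans()
        lo = spans[-1][0] - 50
        region = genome[lo : truth.cleavage_position + 150]
        call, site = call_three_prime(region, reads)
        assert lo + call.position == truth.cleavage_position
        assert site is not None
        assert site.hexamer == hexamer
        assert site.offset == offset
        assert lo + site.hexamer_position == truth.hexamer_position

    def test_no_tails_falls_back_to_coverage_terminus(self):
        cfg = SimulationConfig(seed=71, n_reads=1500, error_rate=0.0,
                               polya_tail_rate=0.0)
        genome, truth = simulate_gene(cfg)
        reads = simulate_reads(genome, truth, cfg)
        spans = truth.gene_model.exon_genomic_spans()
        lo = spans[-1][0] - 50
        region = genome[lo : truth.cleavage_position + 150]
        call, _ = call_three_prime(region, reads)
        assert call.method == "coverage-terminus"
        assert call.confidence == "low"
        assert lo + call.position <= truth.cleavage_position

    def test_no_coverage_is_an_error(self, rng):
        with pytest.raises(ValueError, match="coverage"):
            call_three_prime(random_sequence(rng, 400), _reads(["ACGT" * 25]))


class TestExonUsage:
    def test_skipped_exon_unsupported(self):
        cfg = SimulationConfig(seed=83, n_reads=2000, error_rate=0.0,
                               polya_tail_rate=0.0,
                               isoforms=((1, 2, 3, 4, 6),),
                               isoform_weights=(1.0,))
        genome, truth = simulate_gene(cfg)
        reads = simulate_reads(genome, truth, cfg)
        usage = exon_usage(truth.gene_model, genome, reads)
        by_index = {u.index: u for u in usage}
        assert not by_index[5].supported
        for k in (1, 2, 3, 4, 6):
            assert by_index[k].supported

    def test_single_isoform_supports_exactly_its_exons(self):
        cfg = SimulationConfig(seed=89, n_reads=3000, error_rate=0.0,
                               polya_tail_rate=0.0)
        genome, truth = simulate_gene(cfg)
        reads = simulate_reads(genome, truth, cfg)
        usage = exon_usage(truth.gene_model, genome, reads)
        assert all(u.supported for u in usage)
        assert all(u.junction_support > 0 for u in usage)

    def test_isoform_mixture_supports_all_configured_exons(self):
        cfg = SimulationConfig(seed=97, n_reads=4000, error_rate=0.001,
                               polya_tail_rate=0.0,
                               isoforms=((1, 2, 3, 4, 6), (1, 2, 3, 5, 6),
                                         (1, 2, 3, 6)),
                               isoform_weights=(0.5, 0.3, 0.2))
        genome, truth = simulate_gene(cfg)
        reads = simulate_reads(genome, truth, cfg)
        usage = exon_usage(truth.gene_model, genome, reads)
        assert all(u.supported for u in usage)


class TestParalogRatio:
    def test_printed_count_arithmetic(self):
        p1 = HitProfile(counts={"a": 200})
        p2 = HitProfile(counts={"a": 5})
        assert paralog_expression_ratio(p1, p2) == 2.5

    def test_identical_profiles_are_100_percent(self):
        p = HitProfile(counts={"a": 7, "b": 13})
        assert paralog_expression_ratio(p, p) == 100.0

    def test_zero_denominator_undefined(self):
        p1 = HitProfile(counts={"a": 0})
        p2 = HitProfile(counts={"a": 10})
        assert paralog_expression_ratio(p1, p2) is None

    def test_probe_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal numbers"):
            paralog_expression_ratio(HitProfile(counts={"a": 1}),
                                     HitProfile(counts={"a": 1, "b": 2}))


class TestRegionMapping:
    def test_spliced_read_clipped_at_junction(self):
        cfg = SimulationConfig(seed=3, n_reads=2000, error_rate=0.0,
                               polya_tail_rate=0.0)
        genome, truth = simulate_gene(cfg)
        reads = simulate_reads(genome, truth, cfg)
        spans = truth.gene_model.exon_genomic_spans()
        exon1_len = truth.gene_model.exons[0].length
        region = genome[truth.tss_position - 100 : spans[0][1] + 200]
        placements = map_reads_to_region(region, reads)
        assert placements
        # exon 1 is 36 nt: no placement may extend into the intron
        for p in placements:
            assert p.end <= 100 + exon1_len
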