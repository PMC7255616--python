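"""Parameter-recovery studies on synthetic loci with matched truth values.

Species-specific quantities that would require the real genome assemblies
(UTR lengths, terminal-exon lengths, poly(A) offsets, paralog expression
ratios) are validated here by construction: a synthetic gene is built with
the published structural measurements as ground truth, reads are sampled
from it, and the mapping machinery must recover the planted values.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

from .expression import (call_five_prime, call_three_prime, count_probe_hits,
                         paralog_expression_ratio)
from .models import extract_cds, splice_transcript, translate_cds
from .probes import discriminating_probes
from .reference_tables import GENE_STRUCTURE_ROWS
from .retrocopy import chain_blocks, classify_retrocopy, exon_homology_scan
from .simulate import (SimulationConfig, plant_retrocopy, simulate_gene,
                       simulate_reads, simulate_reads_from_transcripts,
                       substream)

__all__ = [
    "POLYA_BY_SPECIES",
    "species_config",
    "simulated_protein_length",
    "recover_five_prime_utr",
    "recover_three_prime_end",
    "retrocopy_detection_study",
    "paralog_ratio_study",
]

# Poly(A) signal hexamer and hexamer-end-to-cleavage offset used when a
# species' own boundary mapping reported them; canonical defaults otherwise.
POLYA_BY_SPECIES: dict[str, tuple[str, int]] = {
    "chicken": ("ATTTTA", 8),
    "zebrafish": ("ATTAAA", 12),
}

DEFAULT_POLYA = ("AATAAA", 12)


def species_config(species: str, seed: int, n_reads: int = 5000,
                   flank: int = 2000, **overrides) -> SimulationConfig:
    """A SimulationConfig whose gene reproduces a curated structural row."""
    row = GENE_STRUCTURE_ROWS[species]
    hexamer, offset = POLYA_BY_SPECIES.get(species, DEFAULT_POLYA)
    span = sum(row.exon_lengths) + sum(row.intron_lengths)
    params = dict(
        seed=seed,
        chromosome_length=span + 2 * flank,
        exon_lengths=row.exon_lengths,
        intron_lengths=row.intron_lengths,
        utr5_length=row.utr5,
        utr3_length=row.utr3,
        polya_hexamer=hexamer,
        cleavage_offset=offset,
        n_reads=n_reads,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def simulated_protein_length(species: str, seed: int) -> int:
    """Residue count of the protein encoded by a synthetic gene built from
    the species' structural row (CDS simulated, spliced, translated)."""
    cfg = species_config(species, seed, n_reads=10)
    genome, truth = simulate_gene(cfg)
    transcript = splice_transcript(genome, truth.gene_model)
    return translate_cds(extract_cds(transcript, truth.gene_model)).length


def recover_five_prime_utr(config: SimulationConfig, pad: int = 200,
                           max_mismatches: int = 2) -> int:
    """Simulate, map the 5' end by the longest-clone rule, and return the
    recovered 5' UTR length (truth: config.utr5_length)."""
    genome, truth = simulate_gene(config)
    reads = simulate_reads(genome, truth, config)
    exon1_end = truth.gene_model.exon_genomic_spans()[0][1]
    region = genome[truth.tss_position - pad : exon1_end + 50]
    call = call_five_prime(region, reads, max_mismatches=max_mismatches,
                           atg_position=pad + config.utr5_length)
    return call.utr_length


def recover_three_prime_end(config: SimulationConfig, pad: int = 150,
                            max_mismatches: int = 2
                            ) -> tuple[int, Optional[str], Optional[int]]:
    """Simulate and map the 3' end.

    Returns (recovered terminal-exon length, detected hexamer, detected
    hexamer-to-cleavage offset); truth is (last exon length,
    config.polya_hexamer, config.cleavage_offset).
    """
    genome, truth = simulate_gene(config)
    reads = simulate_reads(genome, truth, config)
    exon_lo = truth.gene_model.exon_genomic_spans()[-1][0]
    lo = exon_lo - 50
    region = genome[lo : truth.cleavage_position + pad]
    call, site = call_three_prime(region, reads, max_mismatches=max_mismatches)
    exon_length = (lo + call.position) - exon_lo
    if site is None:
        return exon_length, None, None
    return exon_length, site.hexamer, site.offset


def retrocopy_detection_study(n_seeds: int = 20, divergence: float = 0.10,
                              base_seed: int = 0, min_exons: int = 4) -> dict:
    """Planted-retrocopy sensitivity and the false-call count on genomes
    without a planted copy.

    For each seed, one genome carries a retrocopy of the default gene at the
    given divergence and one does not; a detection is a >= ``min_exons``
    intronless chain overlapping the planted span.
    """
    detected = 0
    false_calls = 0
    for k in range(n_seeds):
        seed = base_seed + k
        cfg = SimulationConfig(seed=seed, n_reads=10)
        genome, truth = simulate_gene(cfg)
        genome_with, truth_with = plant_retrocopy(
            genome, truth, divergence, len(genome) - 500)
        for planted, (g, t) in ((True, (genome_with, truth_with)),
                                (False, (genome, truth))):
            spans = t.gene_model.exon_genomic_spans()
            exon_seqs = [g[s:e] for s, e in spans]
            parent = (min(s for s, _ in spans), max(e for _, e in spans))
            lengths = [e.length for e in t.gene_model.exons]
            blocks = exon_homology_scan(exon_seqs, g, exclude_span=parent)
            calls = [classify_retrocopy(c, exon_lengths=lengths)
                     for c in chain_blocks(blocks)
                     if len(set(c.exon_indices)) >= min_exons
                     and c.intronless(exon_lengths=lengths)]
            if planted:
                lo, hi = t.retrocopy_span
                hit = any(lo <= call.blocks[0].start
                          and call.blocks[-1].end <= hi for call in calls)
                detected += int(hit)
            else:
                false_calls += len(calls)
    return {
        "n_seeds": n_seeds,
        "sensitivity_pct": 100.0 * detected / n_seeds,
        "false_calls": false_calls,
    }


def paralog_ratio_study(true_ratio_pct: float = 25.0, seed: int = 0,
                        n_reads: int = 100_000, divergence: float = 0.05,
                        n_probes: int = 6, probe_length: int = 60) -> dict:
    """Recover a planted paralog abundance ratio from discriminating probes.

    A retrocopy diverged at ``divergence`` is expressed at
    ``true_ratio_pct`` percent of the parent; a mixed library of ``n_reads``
    reads is counted against discriminating probes of each gene.
    """
    cfg = SimulationConfig(seed=seed, n_reads=n_reads, polya_tail_rate=0.0)
    genome, truth = simulate_gene(cfg)
    genome, truth = plant_retrocopy(genome, truth, divergence,
                                    len(genome) - 500)
    parent_tx = splice_transcript(genome, truth.gene_model)
    lo, hi = truth.retrocopy_span
    copy_tx = genome[lo:hi]
    frac_copy = true_ratio_pct / (100.0 + true_ratio_pct)
    reads = simulate_reads_from_transcripts(
        [parent_tx, copy_tx], [1.0 - frac_copy, frac_copy], cfg,
        rng=substream(cfg.seed, "reads"))
    # spread the discriminating windows across the transcript
    d_parent = discriminating_probes(parent_tx, copy_tx, probe_length,
                                     source="parent")[::80][:n_probes]
    d_copy = discriminating_probes(copy_tx, parent_tx, probe_length,
                                   source="copy")[::80][:n_probes]
    n = min(len(d_parent), len(d_copy))
    prof_parent = count_probe_hits(d_parent[:n], reads,
                                   min_overlap=probe_length)
    prof_copy = count_probe_hits(d_copy[:n], reads, min_overlap=probe_length)
    measured = paralog_expression_ratio(prof_parent, prof_copy)
    return {
        "true_ratio_pct": true_ratio_pct,
        "measured_ratio_pct": measured,
        "n_reads": n_reads,
        "n_probes": n,
        "parent_hits": sum(prof_parent.counts.values()),
        "copy_hits": sum(prof_copy.counts.values()),
    }
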