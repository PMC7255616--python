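"""Synthetic genomes, gene models, read libraries, retrocopies, and
neighbor-gene loci with known ground truth.

The generator emulates the experimental setting of comparative gene-locus
characterization: a chromosome segment carrying a multi-exon gene (default:
a compact 6-exon fish-like gene of 6404 bp producing a 1114-nt mRNA and a
198-residue protein), canonical GT..AG introns, a poly(A) signal hexamer
placed a fixed offset upstream of the cleavage site, optional alternative
isoforms, an intronless retrocopy and/or intron-containing duplicate planted
elsewhere on the chromosome, flanking neighbor genes in configured
order/orientation, and short single-end reads sampled from the mature
transcripts with per-base substitution errors and non-templated poly(A)
tails on a fraction of 3'-terminal reads.

Everything is deterministic under the configured seed; each stage draws
from its own named substream so stages are independently reproducible.

The generator guarantees the planted boundaries are unambiguous: the last
transcribed base is not an A, the genome does not continue the transcript
with an A-run past the cleavage site, and no competing accepted hexamer sits
between the planted signal and the cleavage site.  Without these guarantees
"exact cleavage-offset recovery" would be ill-posed on a small fraction of
seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .expression import ACCEPTED_HEXAMERS, ReadSet
from .models import GeneModel, assemble_model, splice_transcript
from .synteny import LocusGene, LocusMap

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "substream",
    "random_sequence",
    "mutate_sequence",
    "simulate_gene",
    "simulate_reads",
    "simulate_reads_from_transcripts",
    "plant_retrocopy",
    "plant_tandem_duplicate",
    "simulate_neighborhood",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
STOPS = {"TAA", "TAG", "TGA"}

# fixed substream keys: stage name -> spawn key
_STAGES = {"gene": 0, "reads": 1, "retrocopy": 2, "duplicate": 3,
           "neighborhood": 4, "clade": 5}


def substream(seed: int, stage: str) -> np.random.Generator:
    """A named, reproducible random substream derived from the run seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],))
    )


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform A/C/G/T background (50% GC), the neutral null for alignment."""
    if length <= 0:
        return ""
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-site substitutions at the given rate (never to self)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("substitution rate must be in [0, 1]")
    if rate == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic locus, with compact-fish-gene defaults."""

    seed: int = 0
    chromosome_length: int = 20_000
    exon_lengths: tuple[int, ...] = (36, 91, 124, 74, 146, 643)
    intron_lengths: tuple[int, ...] = (978, 503, 85, 1040, 2684)
    utr5_length: int = 18
    utr3_length: int = 499
    polya_hexamer: str = "ATTAAA"
    cleavage_offset: int = 12  # nt from hexamer 3' end to cleavage site
    n_reads: int = 100_000
    read_length: int = 100
    error_rate: float = 0.001
    polya_tail_rate: float = 0.2
    isoform_weights: tuple[float, ...] = (1.0,)
    # 1-based exon index tuples, one per isoform; None = single full isoform
    isoforms: Optional[tuple[tuple[int, ...], ...]] = None
    paralog_divergence: float = 0.05
    neighbor_genes: tuple[tuple[str, str, int], ...] = (
        ("Ik", "+", 2000),
        ("Hars", "-", 3000),
        ("Hars2", "-", 2500),
        ("Zmat2", "+", 6404),
    )
    gene_start: Optional[int] = None  # default: centered on the chromosome
    five_prime_decay: float = 0.0  # optional 5'-truncation bias (0 = uniform)

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError(
                f"{len(self.intron_lengths)} introns for "
                f"{len(self.exon_lengths)} exons (need exons - 1)"
            )
        if any(l <= 0 for l in self.exon_lengths):
            raise ValueError("exon lengths must be positive")
        if any(l < 4 for l in self.intron_lengths):
            raise ValueError("introns must hold GT..AG (length >= 4)")
        if self.utr5_length < 0 or self.utr3_length < 0:
            raise ValueError("UTR lengths must be non-negative")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be a probability")
        if not 0.0 <= self.paralog_divergence <= 1.0:
            raise ValueError("paralog_divergence must be a probability")
        if not 0.0 <= self.polya_tail_rate <= 1.0:
            raise ValueError("polya_tail_rate must be a probability")
        if self.cleavage_offset < 0:
            raise ValueError("cleavage_offset must be non-negative")
        if len(self.polya_hexamer) != 6:
            raise ValueError("polya_hexamer must be a 6-mer")
        if abs(sum(self.isoform_weights) - 1.0) > 1e-9:
            raise ValueError("isoform_weights must sum to 1")
        n_iso = 1 if self.isoforms is None else len(self.isoforms)
        if len(self.isoform_weights) != n_iso:
            raise ValueError("one weight per isoform required")
        if self.isoforms is not None:
            for iso in self.isoforms:
                if not iso or list(iso) != sorted(iso) or len(set(iso)) != len(iso):
                    raise ValueError("isoform exon indices must be unique and increasing")
                if iso[0] < 1 or iso[-1] > len(self.exon_lengths):
                    raise ValueError("isoform exon index out of range")

    @property
    def coding_length(self) -> int:
        return sum(self.exon_lengths) - self.utr5_length - self.utr3_length

    @property
    def gene_span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


@dataclass
class GroundTruth:
    """Simulator-side truth for parameter-recovery tests."""

    seed: int
    gene_model: GeneModel
    tss_position: int
    cleavage_position: int  # 0-based: first genomic base past the transcript
    hexamer_position: int  # 0-based start of the planted hexamer
    isoform_models: list[GeneModel] = field(default_factory=list)
    retrocopy_span: Optional[tuple[int, int]] = None
    paralog_span: Optional[tuple[int, int]] = None
    read_provenance: Optional[list[dict]] = None

    def __post_init__(self) -> None:
        if self.tss_position >= self.cleavage_position:
            raise ValueError("TSS must lie 5' of the cleavage site")


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + random non-stop codons + TGA."""
    if length % 3 != 0:
        raise ValueError(f"CDS length {length} is not a multiple of 3")
    if length < 6:
        raise ValueError("CDS must hold at least start and stop codons")
    codons = []
    for _ in range(length // 3 - 2):
        while True:
            codon = random_sequence(rng, 3)
            if codon not in STOPS:
                break
        codons.append(codon)
    return "ATG" + "".join(codons) + "TGA"


def _scrub_hexamers(seq: str, keep: tuple[int, int],
                    rng: np.random.Generator) -> str:
    """Destroy accepted hexamer occurrences outside the kept span."""
    arr = list(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(arr)
        for pos in range(len(s) - 5):
            if keep[0] <= pos < keep[1]:
                continue
            if s[pos : pos + 6] in ACCEPTED_HEXAMERS:
                # overlapping the kept hexamer is fine only if entirely inside
                if keep[0] - 5 <= pos < keep[1]:
                    # overlaps the planted signal: mutate the non-kept edge
                    edit = pos if pos < keep[0] else pos + 5
                else:
                    edit = pos + rng.integers(0, 6)
                old = arr[edit]
                choices = [b for b in "ACGT" if b != old]
                arr[edit] = choices[rng.integers(0, 3)]
                changed = True
                break
    return "".join(arr)


def _build_isoform_model(full: GeneModel, exon_indices: Sequence[int],
                         name: str) -> GeneModel:
    """A model retaining a subset of exons; skipped exons join the introns."""
    offsets = full.exon_offsets()
    kept = [full.exons[i - 1] for i in exon_indices]
    introns = []
    for a, b in zip(exon_indices[:-1], exon_indices[1:]):
        start_a_end = offsets[a - 1] + full.exons[a - 1].length
        introns.append(offsets[b - 1] - start_a_end)
    exons = [dataclasses.replace(e, index=k + 1) for k, e in enumerate(kept)]
    start = full.genomic_start
    if start is not None:
        start = start + offsets[exon_indices[0] - 1]
    return GeneModel(name=name, exons=exons, introns=introns,
                     strand=full.strand, genomic_start=start)


def simulate_gene(config: SimulationConfig) -> tuple[str, GroundTruth]:
    """Generate a chromosome carrying one gene with full ground truth.

    The spliced transcript equals the concatenated exons, introns are
    GT..AG, the CDS starts with ATG and ends with a stop, and the configured
    hexamer's 3' end lies ``cleavage_offset`` nt upstream of the cleavage
    site (= the position just past the last exon base).
    """
    cfg = config
    rng = substream(cfg.seed, "gene")
    coding = cfg.coding_length
    if coding < 6 or coding % 3 != 0:
        raise ValueError(
            f"coding length {coding} (exons minus UTRs) must be a positive "
            "multiple of 3 with room for start and stop codons"
        )
    if cfg.utr3_length < cfg.cleavage_offset + 6 and cfg.utr3_length > 0:
        raise ValueError(
            "3' UTR too short to hold the poly(A) hexamer at the configured offset"
        )

    utr5 = random_sequence(rng, cfg.utr5_length)
    cds = _random_cds(rng, coding)
    utr3 = random_sequence(rng, cfg.utr3_length)
    if cfg.utr3_length >= cfg.cleavage_offset + 6:
        # plant the hexamer so its 3' end is cleavage_offset nt upstream of
        # the transcript end
        pos = cfg.utr3_length - cfg.cleavage_offset - 6
        utr3 = utr3[:pos] + cfg.polya_hexamer + utr3[pos + 6 :]
        if cfg.cleavage_offset > 0 and utr3[-1] == "A":
            utr3 = utr3[:-1] + "CGT"[rng.integers(0, 3)]
        # no competing accepted hexamer in the upstream search window
        window_lo = max(0, cfg.utr3_length - 46)
        scrubbed = _scrub_hexamers(
            utr3[window_lo:], (pos - window_lo, pos - window_lo + 6), rng
        )
        utr3 = utr3[:window_lo] + scrubbed

    transcript = utr5 + cds + utr3
    # cut into exons
    exon_seqs = []
    at = 0
    for length in cfg.exon_lengths:
        exon_seqs.append(transcript[at : at + length])
        at += length
    introns = ["GT" + random_sequence(rng, l - 4) + "AG"
               for l in cfg.intron_lengths]
    gene_parts = [exon_seqs[0]]
    for intron, exon in zip(introns, exon_seqs[1:]):
        gene_parts.append(intron)
        gene_parts.append(exon)
    gene_seq = "".join(gene_parts)

    span = cfg.gene_span
    start = cfg.gene_start
    if start is None:
        start = (cfg.chromosome_length - span) // 2
    if start < 0 or start + span > cfg.chromosome_length:
        raise ValueError(
            f"gene span {span} at start {start} does not fit on a "
            f"chromosome of {cfg.chromosome_length} nt"
        )
    upstream = random_sequence(rng, start)
    downstream = random_sequence(rng, cfg.chromosome_length - start - span)
    # the genome must not extend the transcript with an A-run
    if downstream[:1] == "A":
        downstream = "CGT"[rng.integers(0, 3)] + downstream[1:]
    genome = upstream + gene_seq + downstream

    model = assemble_model(cfg.exon_lengths, cfg.intron_lengths,
                           utr5=cfg.utr5_length, utr3=cfg.utr3_length,
                           name="simgene", genomic_start=start)
    if cfg.isoforms is None:
        isoform_models = [model]
    else:
        isoform_models = [
            _build_isoform_model(model, iso, name=f"simgene.iso{k + 1}")
            for k, iso in enumerate(cfg.isoforms)
        ]
    cleavage = start + span
    hexamer_pos = cleavage - cfg.cleavage_offset - 6
    truth = GroundTruth(
        seed=cfg.seed,
        gene_model=model,
        tss_position=start,
        cleavage_position=cleavage,
        hexamer_position=hexamer_pos,
        isoform_models=isoform_models,
    )
    return genome, truth


def simulate_reads_from_transcripts(
    transcripts: Sequence[str],
    weights: Sequence[float],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    library_name: str = "simlib",
) -> ReadSet:
    """Sample error-prone short reads from mature transcript sequences.

    Read starts are uniform over each transcript (optionally biased toward
    the 3' end by ``five_prime_decay``); a ``polya_tail_rate`` fraction of
    reads is anchored at the 3' terminus and carries a non-templated A-run
    of 5-20 nt.  Per-base substitution errors occur at ``error_rate``.
    """
    cfg = config
    if cfg.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if rng is None:
        rng = substream(cfg.seed, "reads")
    if len(transcripts) != len(weights):
        raise ValueError("one weight per transcript required")
    shortest = min(len(t) for t in transcripts)
    if cfg.read_length > shortest:
        raise ValueError(
            f"read length {cfg.read_length} exceeds shortest isoform ({shortest} nt)"
        )
    weights = np.asarray(weights, dtype=float)
    iso_choice = rng.choice(len(transcripts), size=cfg.n_reads, p=weights)
    reads = []
    provenance = []
    qual = "?" * cfg.read_length  # constant Q30
    for k in range(cfg.n_reads):
        iso = int(iso_choice[k])
        t = transcripts[iso]
        tailed = rng.random() < cfg.polya_tail_rate
        if tailed:
            tail_len = int(rng.integers(5, 21))
            genomic_len = cfg.read_length - tail_len
            start = len(t) - genomic_len
            seq = t[start:] + "A" * tail_len
        else:
            tail_len = 0
            limit = len(t) - cfg.read_length
            if cfg.five_prime_decay > 0:
                # truncation bias: starts decay geometrically from the 5' end
                u = rng.random()
                start = int(min(limit, -np.log(1 - u) / cfg.five_prime_decay))
            else:
                start = int(rng.integers(0, limit + 1))
            seq = t[start : start + cfg.read_length]
        seq = mutate_sequence(seq, cfg.error_rate, rng)
        rid = f"read{k:07d}"
        reads.append((rid, seq, qual))
        provenance.append({"read_id": rid, "isoform": iso, "start": start,
                           "tail_length": tail_len})
    rs = ReadSet(reads=reads, library_name=library_name, provenance=provenance)
    return rs


def simulate_reads(genome: str, truth: GroundTruth,
                   config: SimulationConfig) -> ReadSet:
    """Sample reads from the simulated gene's mature isoforms.

    Reads are substrings of the spliced isoforms chosen by the configured
    weights; provenance (isoform, start, tail length) is recorded on the
    ReadSet and mirrored into the truth object.
    """
    transcripts = [splice_transcript(genome, m) for m in truth.isoform_models]
    rs = simulate_reads_from_transcripts(
        transcripts, config.isoform_weights, config,
        rng=substream(config.seed, "reads"),
    )
    truth.read_provenance = rs.provenance
    return rs


def _insert(genome: str, truth: GroundTruth, insert_seq: str,
            insertion_point: int) -> tuple[str, GroundTruth, tuple[int, int]]:
    model = truth.gene_model
    parent_lo = model.genomic_start
    parent_hi = parent_lo + model.gene_span()
    if parent_lo < insertion_point < parent_hi:
        raise ValueError(
            f"insertion point {insertion_point} lies inside the parent gene "
            f"span [{parent_lo}, {parent_hi})"
        )
    if not 0 <= insertion_point <= len(genome):
        raise ValueError("insertion point outside the genome")
    new_genome = genome[:insertion_point] + insert_seq + genome[insertion_point:]
    span = (insertion_point, insertion_point + len(insert_seq))
    shift = len(insert_seq) if insertion_point <= parent_lo else 0

    def _shift_span(s):
        if s is None:
            return None
        return (s[0] + len(insert_seq), s[1] + len(insert_seq)) \
            if insertion_point <= s[0] else s

    new_truth = dataclasses.replace(
        truth,
        gene_model=dataclasses.replace(model, genomic_start=parent_lo + shift),
        tss_position=truth.tss_position + shift,
        cleavage_position=truth.cleavage_position + shift,
        hexamer_position=truth.hexamer_position + shift,
        isoform_models=[dataclasses.replace(
            m, genomic_start=(m.genomic_start + shift
                              if m.genomic_start is not None else None))
            for m in truth.isoform_models],
        retrocopy_span=_shift_span(truth.retrocopy_span),
        paralog_span=_shift_span(truth.paralog_span),
    )
    return new_genome, new_truth, span


def plant_retrocopy(genome: str, truth: GroundTruth, divergence: float,
                    insertion_point: int,
                    seed: Optional[int] = None) -> tuple[str, GroundTruth]:
    """Insert an intronless, mutated copy of the spliced transcript.

    The mature transcript of the primary isoform, substituted at the given
    per-site rate, is inserted intact at ``insertion_point`` (which must lie
    outside the parent gene span); the retrocopy span is recorded in the
    returned truth.
    """
    rng = substream(truth.seed if seed is None else seed, "retrocopy")
    transcript = splice_transcript(genome, truth.gene_model)
    mutated = mutate_sequence(transcript, divergence, rng)
    new_genome, new_truth, span = _insert(genome, truth, mutated, insertion_point)
    new_truth.retrocopy_span = span
    return new_genome, new_truth


def plant_tandem_duplicate(genome: str, truth: GroundTruth, divergence: float,
                           insertion_point: int,
                           seed: Optional[int] = None) -> tuple[str, GroundTruth]:
    """Insert a full (intron-containing) mutated copy of the gene span."""
    rng = substream(truth.seed if seed is None else seed, "duplicate")
    model = truth.gene_model
    lo = model.genomic_start
    hi = lo + model.gene_span()
    mutated = mutate_sequence(genome[lo:hi], divergence, rng)
    new_genome, new_truth, span = _insert(genome, truth, mutated, insertion_point)
    new_truth.paralog_span = span
    return new_genome, new_truth


def simulate_neighborhood(config: SimulationConfig) -> tuple[str, LocusMap]:
    """Place the configured neighbor genes, in order, on one chromosome.

    Genes are separated by equal intergenic gaps; the returned LocusMap
    lists them left to right with the configured strands.
    """
    cfg = config
    if not cfg.neighbor_genes:
        raise ValueError("neighbor_genes must be non-empty")
    rng = substream(cfg.seed, "neighborhood")
    total = sum(length for _, _, length in cfg.neighbor_genes)
    n = len(cfg.neighbor_genes)
    gap = (cfg.chromosome_length - total) // (n + 1)
    if gap < 1:
        raise ValueError(
            f"requested genes total {total} nt; they do not fit on a "
            f"chromosome of {cfg.chromosome_length} nt"
        )
    genome = random_sequence(rng, cfg.chromosome_length)
    genes = []
    at = gap
    for name, strand, length in cfg.neighbor_genes:
        genes.append(LocusGene(name=name, strand=strand, span=(at, at + length)))
        at += length + gap
    anchor = cfg.neighbor_genes[-1][0]
    return genome, LocusMap(species="simulated", anchor=anchor, genes=genes)
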