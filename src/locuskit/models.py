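"""Exon/intron/UTR gene models and their arithmetic.

A gene model here is the minimal object needed for comparative gene
characterization: an ordered list of exons, each partitioned into 5' UTR,
coding, and 3' UTR segments, separated by introns of known length.  All
internal coordinates are 0-based half-open; GFF3 emission (1-based closed)
lives in :mod:`locuskit.io`.

The arithmetic operations (gene length, mRNA length, CDS length, protein
length) are deliberately exact integer bookkeeping: they are used both to
summarize assembled models and to audit externally reported totals, where a
discrepancy is a finding rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

from Bio.Seq import Seq

__all__ = [
    "ExonRecord",
    "GeneModel",
    "ProteinRecord",
    "ModelLengths",
    "ValidationReport",
    "assemble_model",
    "model_lengths",
    "splice_transcript",
    "extract_cds",
    "translate_cds",
    "validate_reported_totals",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ExonRecord:
    """One exon with its UTR/coding partition, lengths in nucleotides."""

    index: int  # 1-based ordinal within the gene
    length: int
    utr5: int = 0
    coding: int = 0
    utr3: int = 0

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"exon index must be >= 1, got {self.index}")
        for name in ("length", "utr5", "coding", "utr3"):
            if getattr(self, name) < 0:
                raise ValueError(f"exon {self.index}: negative {name}")
        if self.utr5 + self.coding + self.utr3 != self.length:
            raise ValueError(
                f"exon {self.index}: utr5 + coding + utr3 = "
                f"{self.utr5 + self.coding + self.utr3} != length {self.length}"
            )


@dataclass
class GeneModel:
    """Ordered exons on a strand, with intron lengths between them."""

    name: str
    exons: list[ExonRecord]
    introns: list[int]
    strand: str = "+"
    genomic_start: Optional[int] = None  # 0-based leftmost genomic coordinate

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        if len(self.introns) != len(self.exons) - 1:
            raise ValueError(
                f"{self.name}: {len(self.introns)} introns for "
                f"{len(self.exons)} exons (need exons - 1)"
            )
        if any(i <= 0 for i in self.introns):
            raise ValueError(f"{self.name}: intron lengths must be positive")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e.coding for e in self.exons)

    @property
    def translatable(self) -> bool:
        """True when the coding portion can encode a protein (length % 3 == 0).

        Models with inconsistent coding arithmetic stay representable so that
        audits can hold them; they are merely flagged non-translatable.
        """
        return self.cds_length > 0 and self.cds_length % 3 == 0

    def exon_offsets(self) -> list[int]:
        """Start of each exon relative to the gene's 5'-most base (+ sense)."""
        offsets = [0]
        for exon, intron in zip(self.exons[:-1], self.introns):
            offsets.append(offsets[-1] + exon.length + intron)
        return offsets

    def exon_genomic_spans(self) -> list[tuple[int, int]]:
        """0-based half-open genomic spans, left to right on the + axis.

        For a minus-strand gene the first listed exon is still the
        transcription-order first exon; its span is the rightmost.
        """
        if self.genomic_start is None:
            raise ValueError(f"{self.name}: no genomic coordinates attached")
        spans = []
        pos = self.genomic_start
        for k, exon in enumerate(self.exons):
            spans.append((pos, pos + exon.length))
            if k < len(self.introns):
                pos += exon.length + self.introns[k]
        if self.strand == "-":
            # transcription order runs right-to-left: mirror the layout
            total = self.gene_span()
            right = self.genomic_start + total
            spans = [(right - (e - self.genomic_start), right - (s - self.genomic_start))
                     for (s, e) in spans]
        return spans

    def gene_span(self) -> int:
        return sum(e.length for e in self.exons) + sum(self.introns)


@dataclass(frozen=True)
class ProteinRecord:
    """A translated protein: sequence, residue count, codon count (incl. stop)."""

    sequence: str
    length: int
    codon_count: int

    def __post_init__(self) -> None:
        if self.length != self.codon_count - 1:
            raise ValueError("protein length must equal codon_count - 1")
        if "*" in self.sequence:
            raise ValueError("protein sequence contains an internal stop")


class ModelLengths(NamedTuple):
    gene_length: int
    mrna_length: int
    cds_length: int


def assemble_model(
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int],
    utr5: int = 0,
    utr3: int = 0,
    name: str = "gene",
    strand: str = "+",
    genomic_start: Optional[int] = None,
) -> GeneModel:
    """Build a GeneModel from length lists plus terminal UTR annotations.

    Interior exons are fully coding; the 5' UTR lies in exon 1 and the 3'
    UTR in the last exon (single-exon genes carry both).
    """
    exon_lengths = list(exon_lengths)
    intron_lengths = list(intron_lengths)
    if len(intron_lengths) != len(exon_lengths) - 1:
        raise ValueError(
            f"{len(intron_lengths)} introns for {len(exon_lengths)} exons"
        )
    if any(l <= 0 for l in exon_lengths):
        raise ValueError("exon lengths must be positive")
    if utr5 < 0 or utr3 < 0:
        raise ValueError("UTR lengths must be non-negative")

    n = len(exon_lengths)
    exons = []
    for i, length in enumerate(exon_lengths, start=1):
        u5 = utr5 if i == 1 else 0
        u3 = utr3 if i == n else 0
        coding = length - u5 - u3
        if coding < 0:
            raise ValueError(
                f"exon {i}: UTR annotation ({u5} + {u3}) exceeds exon length {length}"
            )
        exons.append(ExonRecord(index=i, length=length, utr5=u5, coding=coding, utr3=u3))
    return GeneModel(name=name, exons=exons, introns=intron_lengths,
                     strand=strand, genomic_start=genomic_start)


def model_lengths(model: GeneModel) -> ModelLengths:
    """Gene span, mature mRNA length, and CDS length of a model."""
    mrna = sum(e.length for e in model.exons)
    return ModelLengths(
        gene_length=mrna + sum(model.introns),
        mrna_length=mrna,
        cds_length=model.cds_length,
    )


def splice_transcript(genome: str, model: GeneModel) -> str:
    """Concatenate exon sequences in transcription order.

    Minus-strand models are reverse-complemented so the returned string is
    the mature sense-strand transcript.
    """
    spans = model.exon_genomic_spans()
    for s, e in spans:
        if s < 0 or e > len(genome):
            raise ValueError(
                f"{model.name}: exon span [{s}, {e}) outside genome of "
                f"length {len(genome)}"
            )
    if model.strand == "+":
        return "".join(genome[s:e] for s, e in spans)
    return "".join(str(Seq(genome[s:e]).reverse_complement()) for s, e in spans)


def extract_cds(transcript: str, model: GeneModel) -> str:
    """Cut the coding sequence out of a mature transcript using the model's
    UTR partition."""
    utr5 = model.exons[0].utr5
    cds_len = model.cds_length
    return transcript[utr5 : utr5 + cds_len]


def translate_cds(cds_sequence: str, allow_non_atg_start: bool = False) -> ProteinRecord:
    """Translate a CDS (standard genetic code) into a ProteinRecord.

    The sequence must be a whole ORF: length divisible by 3, ATG start
    (unless ``allow_non_atg_start``, for proteins annotated without an
    amino-terminal methionine), terminal stop codon, no internal stops.
    """
    cds = cds_sequence.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if len(cds) < 6:
        raise ValueError("CDS must contain at least a start and a stop codon")
    if not allow_non_atg_start and not cds.startswith("ATG"):
        raise ValueError(f"CDS does not start with ATG (got {cds[:3]})")
    if cds[-3:] not in STOP_CODONS:
        raise ValueError(f"CDS does not end with a stop codon (got {cds[-3:]})")
    aa = str(Seq(cds).translate(table=1))
    if "*" in aa[:-1]:
        pos = aa.index("*")
        raise ValueError(f"internal stop codon at codon {pos + 1}")
    protein = aa[:-1]
    return ProteinRecord(sequence=protein, length=len(protein),
                         codon_count=len(cds) // 3)


@dataclass
class ValidationReport:
    """Computed-vs-reported audit of a model's printed totals."""

    name: str
    comparisons: list[dict] = field(default_factory=list)

    def add(self, quantity: str, computed: Optional[int],
            reported: Optional[int]) -> None:
        entry = {
            "quantity": quantity,
            "computed": computed,
            "reported": reported,
            "status": "n/a" if reported is None
            else ("pass" if computed == reported else "flag"),
        }
        self.comparisons.append(entry)

    @property
    def all_pass(self) -> bool:
        return all(c["status"] != "flag" for c in self.comparisons)

    @property
    def flags(self) -> list[dict]:
        return [c for c in self.comparisons if c["status"] == "flag"]


def validate_reported_totals(
    model: GeneModel,
    reported_gene_length: Optional[int] = None,
    reported_mrna_length: Optional[int] = None,
    reported_protein_length: Optional[int] = None,
) -> ValidationReport:
    """Audit reported totals against the model's own arithmetic.

    Exact equality is required to pass; a discrepancy is recorded as a flag,
    never raised, so inconsistent published rows remain representable.
    """
    lengths = model_lengths(model)
    report = ValidationReport(name=model.name)
    report.add("gene_length", lengths.gene_length, reported_gene_length)
    report.add("mrna_length", lengths.mrna_length, reported_mrna_length)
    if reported_protein_length is not None:
        # None when the CDS arithmetic cannot yield a protein at all
        computed_aa = (lengths.cds_length // 3 - 1
                       if model.translatable else None)
        report.add("protein_length", computed_aa, reported_protein_length)
    return report
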