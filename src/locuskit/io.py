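"""Readers/writers for FASTA, FASTQ, GFF3, BED and TSV, plus the one place
where coordinate conventions are converted.

Conventions: all in-memory coordinates are 0-based half-open.  GFF3 is
emitted and parsed as 1-based closed; BED as 0-based half-open.  The two
conversion helpers below are the only code that adds or subtracts the 1.

FASTQ is handled record-by-record so malformed input fails with an error
naming the offending line.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ReadSet
from .models import ExonRecord, GeneModel
from .probes import Probe

__all__ = [
    "ParseError",
    "to_gff3_interval",
    "from_gff3_interval",
    "read_fasta", "write_fasta",
    "read_fastq", "write_fastq",
    "write_gff3", "read_gff3",
    "write_bed", "probes_to_bed", "write_probe_fasta",
    "write_tsv", "config_hash",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


# -- coordinate conversion (the single authority) ---------------------------

def to_gff3_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based closed."""
    return start + 1, end


def from_gff3_interval(start: int, end: int) -> tuple[int, int]:
    """1-based closed -> 0-based half-open."""
    return start - 1, end


# -- FASTA / FASTQ -----------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path), "fasta",
    )


def read_fastq(path: PathLike, library_name: Optional[str] = None) -> ReadSet:
    """Read Phred+33 FASTQ; structural errors name the offending line."""
    path = Path(path)
    reads: list[tuple[str, str, Optional[str]]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ParseError(
            f"{path}: truncated FASTQ record starting at line "
            f"{len(lines) - len(lines) % 4 + 1}"
        )
    for k in range(0, len(lines), 4):
        header, seq, plus, qual = lines[k : k + 4]
        if not header.startswith("@"):
            raise ParseError(f"{path}: line {k + 1}: header does not start with '@'")
        if not plus.startswith("+"):
            raise ParseError(f"{path}: line {k + 3}: separator does not start with '+'")
        if len(seq) != len(qual):
            raise ParseError(
                f"{path}: line {k + 4}: quality length {len(qual)} != "
                f"sequence length {len(seq)}"
            )
        reads.append((header[1:].split()[0], seq.upper(), qual))
    return ReadSet(reads=reads, library_name=library_name or path.stem)


def write_fastq(path: PathLike, readset: ReadSet) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in readset.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual or '?' * len(seq)}\n")


# -- GFF3 --------------------------------------------------------------------

def _model_feature_rows(model: GeneModel, seqid: str, source: str) -> list[str]:
    spans = model.exon_genomic_spans()
    lo = min(s for s, _ in spans)
    hi = max(e for _, e in spans)
    gid = model.name
    g1, g2 = to_gff3_interval(lo, hi)
    rows = [
        f"{seqid}\t{source}\tgene\t{g1}\t{g2}\t.\t{model.strand}\t.\tID=gene:{gid}",
        f"{seqid}\t{source}\tmRNA\t{g1}\t{g2}\t.\t{model.strand}\t.\t"
        f"ID=mrna:{gid};Parent=gene:{gid}",
    ]
    for exon, (s, e) in zip(model.exons, spans):
        e1, e2 = to_gff3_interval(s, e)
        rows.append(
            f"{seqid}\t{source}\texon\t{e1}\t{e2}\t.\t{model.strand}\t.\t"
            f"ID=exon:{gid}.{exon.index};Parent=mrna:{gid}"
        )
        if exon.coding > 0:
            if model.strand == "+":
                c_lo, c_hi = s + exon.utr5, e - exon.utr3
            else:
                c_lo, c_hi = s + exon.utr3, e - exon.utr5
            c1, c2 = to_gff3_interval(c_lo, c_hi)
            rows.append(
                f"{seqid}\t{source}\tCDS\t{c1}\t{c2}\t.\t{model.strand}\t.\t"
                f"ID=cds:{gid}.{exon.index};Parent=mrna:{gid}"
            )
    return rows


def write_gff3(path: PathLike, models: Sequence[GeneModel], seqid: str = "chr1",
               source: str = "locuskit",
               metadata: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for key, value in (metadata or {}).items():
            fh.write(f"#!{key} {value}\n")
        for model in models:
            fh.write("\n".join(_model_feature_rows(model, seqid, source)) + "\n")


def _parse_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if part and "=" in part:
            key, value = part.split("=", 1)
            out[key] = value
    return out


def read_gff3(path: PathLike) -> list[GeneModel]:
    """Reconstruct GeneModels from gene/mRNA/exon/CDS features."""
    path = Path(path)
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    strands: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            _, _, ftype, start, end, _, strand, _, attrs = fields
            try:
                lo, hi = from_gff3_interval(int(start), int(end))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad coordinates") from exc
            if ftype not in ("exon", "CDS"):
                continue
            parent = _parse_attributes(attrs).get("Parent", "")
            name = parent.removeprefix("mrna:")
            if not name:
                raise ParseError(f"{path}: line {lineno}: {ftype} without Parent")
            strands[name] = strand
            (exons if ftype == "exon" else cds).setdefault(name, []).append((lo, hi))

    models = []
    for name, spans in exons.items():
        spans.sort()
        strand = strands[name]
        c_spans = sorted(cds.get(name, []))
        if strand == "-":
            spans = spans[::-1]  # transcription order
            c_spans = c_spans[::-1]
        records = []
        for k, (lo, hi) in enumerate(spans, start=1):
            length = hi - lo
            overlap = [(cl, ch) for cl, ch in c_spans if cl < hi and ch > lo]
            if not overlap:
                # terminal exon fully UTR: 5' side before any CDS, else 3'
                coding_seen = any(ch <= lo if strand == "+" else cl >= hi
                                  for cl, ch in c_spans)
                if coding_seen:
                    records.append(ExonRecord(k, length, utr3=length))
                else:
                    records.append(ExonRecord(k, length, utr5=length))
                continue
            cl, ch = overlap[0]
            if strand == "+":
                u5, u3 = cl - lo, hi - ch
            else:
                u5, u3 = hi - ch, cl - lo
            records.append(ExonRecord(k, length, utr5=u5, coding=ch - cl, utr3=u3))
        # introns: gaps between consecutive spans in genomic order,
        # reported in transcription order
        genomic = sorted(spans)
        introns = [l2 - h1 for (_, h1), (l2, _) in zip(genomic[:-1], genomic[1:])]
        if strand == "-":
            introns = introns[::-1]
        models.append(GeneModel(name=name, exons=records, introns=introns,
                                strand=strand, genomic_start=genomic[0][0]))
    return models


# -- BED ---------------------------------------------------------------------

def write_bed(path: PathLike, intervals: Iterable[tuple], chrom: str = "chr1") -> None:
    """Intervals as (start, end, name[, strand]) in 0-based half-open coords."""
    with open(path, "w") as fh:
        for iv in intervals:
            start, end, name = iv[0], iv[1], iv[2]
            strand = iv[3] if len(iv) > 3 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def probes_to_bed(path: PathLike, probes: Sequence[Probe], region_offset: int = 0,
                  chrom: str = "chr1") -> None:
    write_bed(path,
              ((region_offset + p.offset, region_offset + p.offset + len(p.sequence),
                p.tag) for p in probes),
              chrom=chrom)


def write_probe_fasta(path: PathLike, probes: Sequence[Probe]) -> None:
    write_fasta(path, {p.id: p.sequence for p in probes})


# -- TSV with provenance header ----------------------------------------------

def config_hash(config_dict: dict) -> str:
    canonical = repr(sorted(config_dict.items())).encode()
    return hashlib.sha256(canonical).hexdigest()[:12]


def write_tsv(path: PathLike, frame: pd.DataFrame,
              metadata: Optional[dict] = None, index: bool = True) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", index=index)


def read_tsv(path: PathLike, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
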