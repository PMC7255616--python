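"""Detection of intronless gene copies (retrocopies / processed pseudogenes).

A retrocopy is a reverse-transcribed mRNA reinserted into the genome as DNA:
the exons of the parent gene reappear elsewhere, co-linear and directly
adjacent, with the introns gone.  Detection proceeds exon by exon: each exon
sequence is located in the genome (outside the parent locus) by seeded local
alignment, the resulting homology blocks are chained by genomic position,
and chains are classified by exon coverage, inter-block gaps, and expression
evidence from discriminating probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import dna_scoring, local_align, percent_identity
from .expression import HitProfile, SeedMatcher, reverse_complement

__all__ = ["HomologyBlock", "BlockChain", "RetrocopyCall",
           "exon_homology_scan", "chain_blocks", "classify_retrocopy"]


@dataclass(frozen=True)
class HomologyBlock:
    """A local alignment of one exon to a genomic span."""

    exon_index: int  # 1-based index in the parent gene
    start: int  # 0-based half-open genomic span
    end: int
    identity: float  # percent
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty homology block span")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass
class BlockChain:
    """Co-linear, same-strand homology blocks in genomic order."""

    blocks: list[HomologyBlock]
    gaps: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("empty chain")
        strands = {b.strand for b in self.blocks}
        if len(strands) != 1:
            raise ValueError("chain mixes strands")

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def max_gap(self) -> int:
        return max(self.gaps, default=0)

    @property
    def exon_indices(self) -> list[int]:
        return [b.exon_index for b in self.blocks]

    @property
    def span(self) -> tuple[int, int]:
        return (self.blocks[0].start, self.blocks[-1].end)

    def intronless(self, gap_threshold: int = 50,
                   exon_lengths: Optional[Sequence[int]] = None) -> bool:
        """True when no inter-block gap shows intron-scale extra sequence.

        When ``exon_lengths`` (parent exon lengths, 1-based indexing by
        exon_index) is given and a chain skips exons whose homology decayed
        below the scan thresholds, the skipped exons' summed length is the
        expected gap; only the excess over it counts against the threshold.
        """
        for (a, b), gap in zip(zip(self.blocks[:-1], self.blocks[1:]),
                               self.gaps):
            expected = 0
            if exon_lengths is not None:
                lo, hi = sorted((a.exon_index, b.exon_index))
                expected = sum(exon_lengths[k - 1] for k in range(lo + 1, hi))
            if gap - expected > gap_threshold:
                return False
        return True


@dataclass
class RetrocopyCall:
    blocks: list[HomologyBlock]
    intronless: bool
    max_gap_observed: int
    expressed: bool
    expression_ratio: Optional[float]
    classification: str  # retrocopy | processed-pseudogene | tandem-duplicate | fragment


def _overlaps(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> bool:
    return a_lo < b_hi and b_lo < a_hi


def exon_homology_scan(
    exon_sequences: Sequence[str],
    genome: str,
    exclude_span: Optional[tuple[int, int]] = None,
    min_identity: float = 75.0,
    min_span: int = 30,
    min_score: float = 30.0,
    seed_size: int = 11,
    window_pad: int = 100,
) -> list[HomologyBlock]:
    """Locate each exon elsewhere in the genome as best-local blocks.

    Candidate placements come from exact seed diagonals (both strands);
    each candidate window is refined with Smith-Waterman under the
    nucleotide scoring scheme, and blocks above the identity/span/score
    thresholds and outside ``exclude_span`` (the parent locus) are returned.
    """
    genome = genome.upper()
    matcher = SeedMatcher({"genome": genome}, seed_size=seed_size)
    scoring = dna_scoring()
    blocks: list[HomologyBlock] = []
    for exon_idx, exon in enumerate(exon_sequences, start=1):
        exon = exon.upper()
        for strand in ("+", "-"):
            oriented = exon if strand == "+" else reverse_complement(exon)
            diagonals = sorted(
                d + r for (_tid, d), r in matcher._candidates(oriented).items()
            )  # seed target positions
            # cluster seed positions within one exon length of each other
            clusters: list[tuple[int, int]] = []
            for pos in diagonals:
                if clusters and pos - clusters[-1][1] <= len(exon):
                    clusters[-1] = (clusters[-1][0], pos)
                else:
                    clusters.append((pos, pos))
            found: list[HomologyBlock] = []
            for lo, hi in clusters:
                w_lo = max(0, lo - window_pad)
                w_hi = min(len(genome), hi + len(exon) + window_pad)
                aln = local_align(oriented, genome[w_lo:w_hi], scoring=scoring)
                if aln is None or aln.score < min_score:
                    continue
                if aln.aligned_length < min_span:
                    continue
                ident = percent_identity(aln)
                if ident.percent_identity < min_identity:
                    continue
                g_lo, g_hi = w_lo + aln.b_start, w_lo + aln.b_end
                if exclude_span is not None and _overlaps(g_lo, g_hi, *exclude_span):
                    continue
                found.append(HomologyBlock(
                    exon_index=exon_idx, start=g_lo, end=g_hi,
                    identity=ident.percent_identity, strand=strand,
                    score=aln.score))
            # merge duplicate hits of the same locus (overlapping spans)
            found.sort(key=lambda b: (-b.score, b.start))
            kept: list[HomologyBlock] = []
            for b in found:
                if not any(_overlaps(b.start, b.end, k.start, k.end) for k in kept):
                    kept.append(b)
            blocks.extend(kept)
    blocks.sort(key=lambda b: (b.start, b.exon_index))
    return blocks


def chain_blocks(blocks: Sequence[HomologyBlock],
                 gap_threshold: int = 50) -> list[BlockChain]:
    """Partition position-sorted blocks into maximal co-linear chains.

    A chain is a maximal run of consecutive blocks (genomic order) on one
    strand whose exon indices are strictly increasing (+ strand) or strictly
    decreasing (-).  Inter-block gaps are recorded; a chain is intronless
    when no gap exceeds ``gap_threshold``.
    """
    ordered = sorted(blocks, key=lambda b: (b.start, b.end))
    chains: list[BlockChain] = []
    current: list[HomologyBlock] = []
    gaps: list[int] = []
    for b in ordered:
        if current:
            prev = current[-1]
            compatible = (
                b.strand == prev.strand
                and (b.exon_index > prev.exon_index if b.strand == "+"
                     else b.exon_index < prev.exon_index)
                and b.start >= prev.end
            )
            if compatible:
                gaps.append(b.start - prev.end)
                current.append(b)
                continue
            chains.append(BlockChain(blocks=current, gaps=gaps))
        current = [b]
        gaps = []
    if current:
        chains.append(BlockChain(blocks=current, gaps=gaps))
    return chains


def classify_retrocopy(
    chain: BlockChain,
    expression_profile: Optional[HitProfile] = None,
    ratio: Optional[float] = None,
    gap_threshold: int = 50,
    min_exons: int = 4,
    exon_lengths: Optional[Sequence[int]] = None,
) -> RetrocopyCall:
    """Classify a chained candidate locus.

    An intronless chain covering at least ``min_exons`` exons is a
    retrocopy — labelled ``retrocopy`` when discriminating-probe evidence
    shows expression, ``processed-pseudogene`` when silent.  A chain with
    parent-like gaps but full exon coverage is a tandem duplicate; anything
    covering fewer exons is a fragment.  ``exon_lengths`` (parent exon
    lengths) lets a chain with an undetected internal exon still count as
    intronless over the hole it leaves.
    """
    if not chain.blocks:
        raise ValueError("empty chain")
    intronless = chain.intronless(gap_threshold, exon_lengths)
    n_exons = len(set(chain.exon_indices))
    expressed = bool(
        expression_profile is not None
        and any(c > 0 for c in expression_profile.counts.values())
    )
    if n_exons < min_exons:
        classification = "fragment"
    elif intronless:
        classification = "retrocopy" if expressed else "processed-pseudogene"
    else:
        classification = "tandem-duplicate"
    return RetrocopyCall(
        blocks=list(chain.blocks),
        intronless=intronless,
        max_gap_observed=chain.max_gap,
        expressed=expressed,
        expression_ratio=ratio,
        classification=classification,
    )
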