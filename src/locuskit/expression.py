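"""Read-evidence expression mapping.

Short reads are matched against probes, regions, or spliced transcripts by
exact k-mer seeding (word size 11) followed by ungapped extension with a
small mismatch tolerance — the regime where query and subject are
near-identical, so gapped alignment adds nothing.  On top of the matcher sit
the boundary callers:

* 5' end by the longest-clone rule — the 5'-most coordinate covered by any
  matched read, a lower bound on the true transcript start;
* 3' end from reads that transition into non-templated poly(A) runs, which
  pin the cleavage site exactly; without tailed reads the coverage terminus
  is reported at low confidence;
* poly(A) signal detection against the accepted hexamer set
  {AATAAA, ATTAAA, ATTTTA};
* per-exon usage (body and junction support) and paralog expression ratios
  from discriminating probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .models import GeneModel, splice_transcript

__all__ = [
    "ACCEPTED_HEXAMERS",
    "SEED_SIZE",
    "ReadSet",
    "HitProfile",
    "BoundaryCall",
    "PolyASite",
    "ReadPlacement",
    "ExonSupport",
    "reverse_complement",
    "SeedMatcher",
    "count_probe_hits",
    "map_reads_to_region",
    "call_five_prime",
    "scan_polya_signals",
    "call_three_prime",
    "exon_usage",
    "paralog_expression_ratio",
]

# Canonical polyadenylation signal plus the two variants observed in the
# boundary analyses (frog AATAAA, zebrafish ATTAAA, chicken ATTTTA).
ACCEPTED_HEXAMERS: tuple[str, ...] = ("AATAAA", "ATTAAA", "ATTTTA")

SEED_SIZE = 11
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

READ_ALPHABET = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class ReadSet:
    """A collection of (id, sequence, quality) short reads."""

    reads: list[tuple[str, str, Optional[str]]]
    library_name: str = "library"
    provenance: Optional[list[dict]] = None  # simulator truth, when available

    def __post_init__(self) -> None:
        for rid, seq, _ in self.reads:
            if not seq:
                raise ValueError(f"read {rid}: empty sequence")
            if not set(seq.upper()) <= READ_ALPHABET:
                raise ValueError(f"read {rid}: alphabet outside ACGTN")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class HitProfile:
    """Per-probe read hit counts for one library."""

    counts: dict[str, int]
    library_name: str = "library"

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("hit counts must be non-negative")

    def mean(self) -> float:
        if not self.counts:
            return 0.0
        return sum(self.counts.values()) / len(self.counts)


@dataclass
class BoundaryCall:
    """An inferred transcript boundary."""

    position: int
    side: str  # "5'" | "3'"
    support_reads: int
    method: str  # longest-clone | polyA-site | coverage-terminus
    confidence: str = "normal"  # normal | low
    utr_length: Optional[int] = None
    alternates: list[int] = field(default_factory=list)  # tandem candidates, 5'->3'

    def __post_init__(self) -> None:
        if self.confidence != "low" and self.support_reads < 1:
            raise ValueError("non-low-confidence call needs read support")


@dataclass
class PolyASite:
    """A poly(A) signal hexamer and (when known) its cleavage site."""

    hexamer: str
    hexamer_position: int  # 0-based start of the hexamer
    cleavage_position: Optional[int] = None  # 0-based: first non-transcribed base
    offset: Optional[int] = None  # nt between hexamer 3' end and cleavage site

    def __post_init__(self) -> None:
        if len(self.hexamer) != 6:
            raise ValueError("poly(A) signal must be a hexamer")
        if self.cleavage_position is not None:
            if self.cleavage_position <= self.hexamer_position:
                raise ValueError("cleavage site must lie 3' of the hexamer")


@dataclass(frozen=True)
class ReadPlacement:
    """An ungapped placement of a read on a target sequence."""

    read_id: str
    start: int  # target coordinate of the read's first matched base
    end: int  # target coordinate past the last matched base
    strand: str
    mismatches: int
    tail_length: int = 0  # non-templated 3' A-run, 0 if none
    # when tail_length > 0, `end` is the inferred cleavage position


class SeedMatcher:
    """Exact k-mer seed index over target sequences with ungapped verification.

    A read matches a target when they share an ungapped overlap of at least
    ``min_overlap`` with at most ``max_mismatches`` mismatching positions
    over the overlap.  Both read orientations are tested.
    """

    def __init__(self, targets: dict[str, str], seed_size: int = SEED_SIZE):
        self.targets = {tid: seq.upper() for tid, seq in targets.items()}
        self.seed_size = seed_size
        self._index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in self.targets.items():
            for pos in range(len(seq) - seed_size + 1):
                self._index.setdefault(seq[pos : pos + seed_size], []).append((tid, pos))

    def _candidates(self, read: str) -> dict[tuple[str, int], int]:
        """Seed diagonals: (target id, read start in target coords) ->
        leftmost seeding read position."""
        k = self.seed_size
        out: dict[tuple[str, int], int] = {}
        index = self._index
        for i in range(len(read) - k + 1):
            hits = index.get(read[i : i + k])
            if hits:
                for tid, pos in hits:
                    key = (tid, pos - i)
                    if key not in out:
                        out[key] = i
        return out

    @staticmethod
    def _verify(target: str, read: str, start: int, max_mismatches: int,
                min_overlap: int) -> Optional[tuple[int, int, int]]:
        """Check the ungapped placement of `read` at target offset `start`.

        Returns (overlap_start, overlap_end, mismatches) in target
        coordinates, or None if the placement fails the thresholds.
        """
        lo = max(0, start)
        hi = min(len(target), start + len(read))
        if hi - lo < min_overlap:
            return None
        mism = 0
        for t_pos in range(lo, hi):
            if target[t_pos] != read[t_pos - start]:
                mism += 1
                if mism > max_mismatches:
                    return None
        return lo, hi, mism

    def match_read(self, read: str, max_mismatches: int = 2,
                   min_overlap: Optional[int] = None) -> list[tuple[str, int, int, int, str]]:
        """All accepted placements: (target_id, overlap_start, overlap_end,
        mismatches, strand)."""
        if min_overlap is None:
            min_overlap = self.seed_size
        read = read.upper()
        results = []
        for strand, oriented in (("+", read), ("-", reverse_complement(read))):
            for tid, start in self._candidates(oriented):
                hit = self._verify(self.targets[tid], oriented, start,
                                   max_mismatches, min_overlap)
                if hit is not None:
                    results.append((tid, hit[0], hit[1], hit[2], strand))
        return results

    @staticmethod
    def _xdrop_extend(target: str, read: str, t_seed: int, r_seed: int,
                      seed_len: int, match: float = 1.0, mismatch: float = -3.0,
                      xdrop: float = 12.0) -> tuple[int, int, int, int, int]:
        """Ungapped X-drop extension of an exact seed in both directions.

        Returns (t_lo, t_hi, r_lo, r_hi, mismatches) of the max-scoring
        extent.  Extension in each direction stops when the running score
        falls ``xdrop`` below its running maximum; the extent is then
        trimmed back to the scoring maximum, so a spliced or tailed read is
        clipped at the point where it stops matching the target.
        """
        # rightward
        cur = 0.0
        best = 0.0
        ext_r = 0
        i, j = r_seed + seed_len, t_seed + seed_len
        k = 0
        while i + k < len(read) and j + k < len(target):
            cur += match if read[i + k] == target[j + k] else mismatch
            k += 1
            if cur > best:
                best = cur
                ext_r = k
            elif cur < best - xdrop:
                break
        # leftward
        cur = 0.0
        best = 0.0
        ext_l = 0
        i, j = r_seed - 1, t_seed - 1
        k = 0
        while i - k >= 0 and j - k >= 0:
            cur += match if read[i - k] == target[j - k] else mismatch
            k += 1
            if cur > best:
                best = cur
                ext_l = k
            elif cur < best - xdrop:
                break
        r_lo, r_hi = r_seed - ext_l, r_seed + seed_len + ext_r
        t_lo, t_hi = t_seed - ext_l, t_seed + seed_len + ext_r
        mism = sum(1 for a, b in zip(read[r_lo:r_hi], target[t_lo:t_hi]) if a != b)
        return t_lo, t_hi, r_lo, r_hi, mism

    def place_read(self, read: str, max_mismatches: int = 2,
                   min_overlap: int = 30,
                   sense_only: bool = False) -> Optional[tuple[str, int, int, int, int, str]]:
        """Best clipped placement of a read on the targets.

        Seeds are extended ungapped with X-drop, so only the locally
        matching segment of the read is placed (splice junctions and
        non-templated tails are clipped off).  Returns
        (target_id, t_lo, t_hi, r_lo, r_hi, strand, mismatches) of the
        best-scoring accepted extent, or None.
        """
        read = read.upper()
        best = None
        orientations = (("+", read),) if sense_only else \
            (("+", read), ("-", reverse_complement(read)))
        for strand, oriented in orientations:
            for (tid, _d), r_seed in self._candidates(oriented).items():
                t_seed = _d + r_seed
                t_lo, t_hi, r_lo, r_hi, mism = self._xdrop_extend(
                    self.targets[tid], oriented, t_seed, r_seed, self.seed_size)
                if t_hi - t_lo < min_overlap or mism > max_mismatches:
                    continue
                if best is None or (t_hi - t_lo) - 3 * mism > \
                        (best[2] - best[1]) - 3 * best[6]:
                    best = (tid, t_lo, t_hi, r_lo, r_hi, strand, mism)
        return best


def count_probe_hits(probes: Sequence, reads: ReadSet,
                     max_mismatches: int = 2,
                     min_overlap: Optional[int] = None) -> HitProfile:
    """Count, per probe, the reads sharing an ungapped overlap with it.

    Each read counts at most once per probe; both strands are tested.
    Mismatches are counted over the probe/read overlap, which must be at
    least ``min_overlap`` (default: the seed length).  For discriminating
    probes, set ``min_overlap`` to the probe length so a partial overlap
    cannot dodge the discriminating positions.
    """
    counts = {p.id: 0 for p in probes}
    if len(reads) == 0:
        warnings.warn("empty read set: all probe hit counts are zero")
        return HitProfile(counts=counts, library_name=reads.library_name)
    matcher = SeedMatcher({p.id: p.sequence for p in probes})
    for rid, seq, _ in reads.reads:
        seen: set[str] = set()
        for tid, *_ in matcher.match_read(seq, max_mismatches=max_mismatches,
                                          min_overlap=min_overlap):
            if tid not in seen:
                counts[tid] += 1
                seen.add(tid)
    return HitProfile(counts=counts, library_name=reads.library_name)


def _longest_a_suffix(seq: str) -> int:
    n = 0
    for ch in reversed(seq):
        if ch == "A":
            n += 1
        else:
            break
    return n


def map_reads_to_region(region_sequence: str, reads: ReadSet,
                        max_mismatches: int = 2,
                        min_overlap: int = 30) -> list[ReadPlacement]:
    """Place reads on a region, recognizing non-templated 3' poly(A) tails.

    Placement is clipped (seed plus ungapped X-drop extension), so reads
    running off the region, across a splice junction, or into a poly(A)
    tail are placed on their matching segment only.  A read ending in an
    A-run of >= 5 nt whose templated part places flush against the run, and
    where the region does not itself continue with those As, is recorded as
    tailed; its placement ``end`` is the inferred cleavage position.
    """
    region = region_sequence.upper()
    matcher = SeedMatcher({"region": region})
    placements: list[ReadPlacement] = []
    for rid, seq, _ in reads.reads:
        seq = seq.upper()
        # try the tail interpretation first: templated prefix + A-run
        tail = _longest_a_suffix(seq)
        if tail >= 5 and len(seq) - tail >= min_overlap:
            prefix = seq[: len(seq) - tail]
            hit = matcher.place_read(prefix, max_mismatches=max_mismatches,
                                     min_overlap=min_overlap, sense_only=True)
            if hit is not None:
                _, t_lo, t_hi, r_lo, r_hi, strand, mism = hit
                if r_hi == len(prefix):  # placed flush against the A-run
                    probe = region[t_hi : t_hi + min(5, tail)]
                    if not (probe and probe == "A" * len(probe)):
                        placements.append(
                            ReadPlacement(rid, t_lo, t_hi, strand, mism,
                                          tail_length=tail))
                        continue
        hit = matcher.place_read(seq, max_mismatches=max_mismatches,
                                 min_overlap=min_overlap)
        if hit is not None:
            _, t_lo, t_hi, r_lo, r_hi, strand, mism = hit
            placements.append(ReadPlacement(rid, t_lo, t_hi, strand, mism))
    return placements


def _check_probe_evidence(probes, reads: ReadSet, max_mismatches: int) -> None:
    if probes is not None:
        profile = count_probe_hits(probes, reads, max_mismatches=max_mismatches)
        if all(c == 0 for c in profile.counts.values()):
            raise ValueError("no expression evidence: all probe hit counts are zero")


def call_five_prime(region_sequence: str, reads: ReadSet, probes=None,
                    max_mismatches: int = 2, atg_position: Optional[int] = None,
                    min_overlap: int = 30) -> BoundaryCall:
    """Call the transcript 5' end by the longest-clone rule.

    The call is the 5'-most region coordinate covered by any matched read —
    a lower bound on the true transcript extent ("at least" semantics).
    When ``atg_position`` (region coordinate of the A of ATG) is given, the
    implied 5' UTR length is attached.
    """
    _check_probe_evidence(probes, reads, max_mismatches)
    placements = map_reads_to_region(region_sequence, reads,
                                     max_mismatches=max_mismatches,
                                     min_overlap=min_overlap)
    if not placements:
        raise ValueError("no expression evidence: no reads place on the region")
    position = min(p.start for p in placements)
    support = sum(1 for p in placements if p.start == position)
    call = BoundaryCall(
        position=position,
        side="5'",
        support_reads=support,
        method="longest-clone",
        confidence="low" if support < 2 else "normal",
        utr_length=None if atg_position is None else atg_position - position,
    )
    return call


def scan_polya_signals(sequence: str, window: Optional[tuple[int, int]] = None,
                       hexamers: Iterable[str] = ACCEPTED_HEXAMERS) -> list[PolyASite]:
    """All accepted poly(A) hexamer occurrences within a window, 5'->3'."""
    seq = sequence.upper()
    lo, hi = window if window is not None else (0, len(seq))
    if lo < 0 or hi > len(seq) or lo > hi:
        raise ValueError(f"window [{lo}, {hi}) outside sequence of length {len(seq)}")
    hits = []
    for pos in range(lo, hi - 5):
        if seq[pos : pos + 6] in hexamers:
            hits.append(PolyASite(hexamer=seq[pos : pos + 6], hexamer_position=pos))
    return hits


def call_three_prime(region_sequence: str, reads: ReadSet, probes=None,
                     max_mismatches: int = 2, search_window: int = 40,
                     hexamers: Iterable[str] = ACCEPTED_HEXAMERS,
                     min_overlap: int = 30,
                     min_tail_support: int = 2) -> tuple[BoundaryCall, Optional[PolyASite]]:
    """Call the cleavage/poly(A) addition site on the terminal exon region.

    With poly(A)-tailed reads, the cleavage site is the 3'-most coordinate at
    which at least ``min_tail_support`` reads transition into non-templated
    A-runs (a single erroneous tail base can mimic a one-base-later site, so
    single-read transitions only win, at low confidence, when nothing better
    exists).  Distinct supported candidate sites (tandem cleavage) are kept,
    5'->3', in the call's ``alternates``.  Without tailed reads the 3'-most
    covered coordinate is reported at low confidence.  The closest accepted
    hexamer within ``search_window`` nt upstream becomes the PolyASite, with
    the hexamer-end-to-cleavage offset.
    """
    _check_probe_evidence(probes, reads, max_mismatches)
    placements = map_reads_to_region(region_sequence, reads,
                                     max_mismatches=max_mismatches,
                                     min_overlap=min_overlap)
    if not placements:
        raise ValueError("no terminal-exon coverage")
    tail_support: dict[int, int] = {}
    for p in placements:
        if p.tail_length > 0:
            tail_support[p.end] = tail_support.get(p.end, 0) + 1
    if tail_support:
        supported = sorted(pos for pos, n in tail_support.items()
                           if n >= min_tail_support)
        if supported:
            cleavage = supported[-1]
            confidence = "normal"
            alternates = supported
        else:
            cleavage = max(tail_support)
            confidence = "low"
            alternates = sorted(tail_support)
        call = BoundaryCall(position=cleavage, side="3'",
                            support_reads=tail_support[cleavage],
                            method="polyA-site", confidence=confidence,
                            alternates=alternates)
    else:
        cleavage = max(p.end for p in placements)
        support = sum(1 for p in placements if p.end == cleavage)
        call = BoundaryCall(position=cleavage, side="3'", support_reads=support,
                            method="coverage-terminus", confidence="low",
                            alternates=[cleavage])
    lo = max(0, cleavage - search_window)
    candidates = [s for s in scan_polya_signals(region_sequence, (lo, cleavage),
                                                hexamers=hexamers)
                  if s.hexamer_position + 6 <= cleavage]
    site = None
    if candidates:
        nearest = candidates[-1]  # hexamer whose 3' end is closest to cleavage
        site = PolyASite(hexamer=nearest.hexamer,
                         hexamer_position=nearest.hexamer_position,
                         cleavage_position=cleavage,
                         offset=cleavage - (nearest.hexamer_position + 6))
    return call, site


@dataclass(frozen=True)
class ExonSupport:
    index: int
    supported: bool
    read_count: int
    junction_support: int


def exon_usage(model: GeneModel, genome: str, reads: ReadSet,
               max_mismatches: int = 2, junction_flank: int = 8,
               min_overlap: int = 30) -> list[ExonSupport]:
    """Per-exon read support against the model's spliced transcript.

    An exon is supported when at least one read places within it (with at
    least ``junction_flank`` nt inside the exon, so a chance 1-2 nt
    extension across a junction does not count) or across one of its splice
    junctions; junction support requires the read to cover
    ``junction_flank`` nt on each side of the junction.
    """
    transcript = splice_transcript(genome, model)
    placements = map_reads_to_region(transcript, reads,
                                     max_mismatches=max_mismatches,
                                     min_overlap=min_overlap)
    # exon spans in transcript coordinates
    bounds = [0]
    for exon in model.exons:
        bounds.append(bounds[-1] + exon.length)
    out = []
    for k, exon in enumerate(model.exons):
        lo, hi = bounds[k], bounds[k + 1]
        need = min(junction_flank, exon.length)
        body = sum(1 for p in placements
                   if min(p.end, hi) - max(p.start, lo) >= need)
        junctions = []
        if k > 0:
            junctions.append(lo)
        if k < len(model.exons) - 1:
            junctions.append(hi)
        junc = sum(
            1
            for p in placements
            for j in junctions
            if p.start <= j - junction_flank and p.end >= j + junction_flank
        )
        out.append(ExonSupport(index=exon.index, supported=body > 0,
                               read_count=body, junction_support=junc))
    return out


def paralog_expression_ratio(profile_1: HitProfile,
                             profile_2: HitProfile) -> Optional[float]:
    """Expression of gene 2 relative to gene 1, in percent of mean per-probe
    hit counts.  None when gene 1 has no signal (undefined ratio)."""
    if len(profile_1.counts) != len(profile_2.counts):
        raise ValueError("profiles must come from equal numbers of discriminating probes")
    mean_1 = profile_1.mean()
    if mean_1 == 0:
        return None
    return 100.0 * profile_2.mean() / mean_1
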