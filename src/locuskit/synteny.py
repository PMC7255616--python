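"""Microsynteny: ordered, oriented gene lists around an anchor gene.

A locus is reduced to the ordered list of genes in a window around the
anchor, each with a transcriptional orientation.  Comparisons are anchored,
local and name-based: shared gene content (with a synonym table for paralog
suffixes), congruence of relative order on the shared subset (allowing
whole-locus reversal), and orientation flips relative to the anchor.
Distances are deliberately not compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = ["LocusGene", "LocusMap", "SyntenyComparison",
           "build_locus_map", "compare_loci"]


@dataclass(frozen=True)
class LocusGene:
    name: str
    strand: str
    span: tuple[int, int]  # 0-based half-open genomic interval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.span[0] >= self.span[1]:
            raise ValueError(f"{self.name}: empty or inverted span {self.span}")


@dataclass
class LocusMap:
    species: str
    anchor: str
    genes: list[LocusGene]

    def __post_init__(self) -> None:
        names = [g.name.lower() for g in self.genes]
        if self.anchor.lower() not in names:
            raise ValueError(f"anchor {self.anchor!r} not among locus genes")
        starts = [g.span[0] for g in self.genes]
        if starts != sorted(starts):
            raise ValueError("locus genes must be ordered by coordinate")
        for a, b in zip(self.genes[:-1], self.genes[1:]):
            if a.span[1] > b.span[0]:
                raise ValueError(f"overlapping spans: {a.name} and {b.name}")

    def anchor_gene(self) -> LocusGene:
        return next(g for g in self.genes if g.name.lower() == self.anchor.lower())


@dataclass
class SyntenyComparison:
    shared: set[str]
    order_congruent: bool
    orientation_flips: list[str]
    jaccard: float

    def __post_init__(self) -> None:
        if not set(self.orientation_flips) <= self.shared:
            raise ValueError("orientation flips must be shared genes")
        if not 0.0 <= self.jaccard <= 1.0:
            raise ValueError("jaccard outside [0, 1]")


def _flip(map_: LocusMap) -> LocusMap:
    """Reverse the coordinate axis of a map (for anchor normalization)."""
    hi = max(g.span[1] for g in map_.genes)
    genes = [
        LocusGene(g.name, "+" if g.strand == "-" else "-",
                  (hi - g.span[1], hi - g.span[0]))
        for g in reversed(map_.genes)
    ]
    return LocusMap(species=map_.species, anchor=map_.anchor, genes=genes)


def build_locus_map(annotation: Sequence[LocusGene], anchor: str,
                    window: int, species: str = "species") -> LocusMap:
    """Select genes intersecting anchor +/- window, ordered by coordinate.

    The map is normalized so the anchor sits on the + strand: if the anchor
    is annotated on -, the whole locus is mirrored (order reversed, all
    strands flipped).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    genes = sorted(annotation, key=lambda g: g.span[0])
    anchors = [g for g in genes if g.name.lower() == anchor.lower()]
    if not anchors:
        raise ValueError(f"anchor {anchor!r} not found in annotation")
    a = anchors[0]
    lo, hi = a.span[0] - window, a.span[1] + window
    selected = [g for g in genes if g.span[1] > lo and g.span[0] < hi]
    map_ = LocusMap(species=species, anchor=anchor, genes=selected)
    if a.strand == "-":
        map_ = _flip(map_)
    return map_


def _normalize_names(map_: LocusMap, synonyms: dict[str, str]) -> list[tuple[str, str]]:
    """(canonical name, strand relative to anchor) in map order."""
    anchor_strand = map_.anchor_gene().strand
    out = []
    for g in map_.genes:
        name = g.name.lower()
        name = synonyms.get(name, name)
        rel = "+" if g.strand == anchor_strand else "-"
        out.append((name, rel))
    return out


def compare_loci(map_a: LocusMap, map_b: LocusMap,
                 synonyms: Optional[dict[str, str]] = None) -> SyntenyComparison:
    """Compare two anchored locus maps by content, order, and orientation.

    Synonyms map alternate gene names to a canonical one (lower-case),
    e.g. {"lcp2a": "lcp2"}.  Order congruence is evaluated on the shared
    subset only and tolerates whole-locus reversal; orientation flips are
    shared genes whose strand relative to the anchor differs.
    """
    syn = {k.lower(): v.lower() for k, v in (synonyms or {}).items()}
    a = _normalize_names(map_a, syn)
    b = _normalize_names(map_b, syn)
    names_a = {n for n, _ in a}
    names_b = {n for n, _ in b}
    shared = names_a & names_b
    union = names_a | names_b
    jaccard = len(shared) / len(union) if union else 1.0

    order_a = [n for n, _ in a if n in shared]
    order_b = [n for n, _ in b if n in shared]
    # duplicated shared names make order comparison ambiguous; require
    # unique occurrence, else fall back to multiset equality
    if len(set(order_a)) == len(order_a) and len(set(order_b)) == len(order_b):
        order_congruent = order_a == order_b or order_a == order_b[::-1]
    else:
        order_congruent = sorted(order_a) == sorted(order_b)

    strand_a = {n: s for n, s in a if n in shared}
    strand_b = {n: s for n, s in b if n in shared}
    flips = sorted(n for n in shared if strand_a[n] != strand_b[n])
    return SyntenyComparison(shared=shared, order_congruent=order_congruent,
                             orientation_flips=flips, jaccard=jaccard)
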