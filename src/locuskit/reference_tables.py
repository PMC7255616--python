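"""Curated exon/intron measurements for vertebrate Zmat2 genes.

These rows transcribe published, Ensembl-derived structural measurements of
the Zmat2 (zinc finger matrin-type 2) gene across terrestrial vertebrates
and fish: exon and intron lengths in base pairs, the UTR/coding partition of
the terminal exons, and the totals as reported alongside them.  They are
inputs to the gene-model audit: the package recomputes every total from the
row itself and flags rows whose printed total disagrees with its own sum.

Only species with a complete 6-exon row are included; species whose exon 1
or an intron was never delimited (flycatcher, softshell turtle, cod) cannot
be summed and are omitted from the audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .models import GeneModel, assemble_model

__all__ = ["GeneStructureRow", "GENE_STRUCTURE_ROWS", "row_to_model"]


@dataclass(frozen=True)
class GeneStructureRow:
    species: str
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    exon1_coding: int  # coding nt within exon 1; utr5 = exon1 - coding
    last_exon_coding: int  # coding nt within the terminal exon
    reported_gene_length: Optional[int] = None
    reported_mrna_length: Optional[int] = None
    reported_protein_aa: Optional[int] = None

    @property
    def utr5(self) -> int:
        return self.exon_lengths[0] - self.exon1_coding

    @property
    def utr3(self) -> int:
        return self.exon_lengths[-1] - self.last_exon_coding


# Exon 1 coding is 18 nt in most species (ATG plus five codons of the
# amino-terminal segment); the terminal exon carries 144 coding nt.
# Deviations: duck (21), spotted gar (123, the long amino terminus).
GENE_STRUCTURE_ROWS: dict[str, GeneStructureRow] = {
    "chicken": GeneStructureRow(
        "chicken",
        (107, 94, 124, 74, 146, 1903), (2807, 558, 1345, 2338, 1532),
        exon1_coding=18, last_exon_coding=144,
        reported_gene_length=9159, reported_mrna_length=2452,
        reported_protein_aa=199,
    ),
    "turkey": GeneStructureRow(
        "turkey",
        (18, 94, 124, 74, 146, 823), (807, 566, 1317, 2277, 1507),
        exon1_coding=18, last_exon_coding=144,
        reported_protein_aa=199,  # reported total is a lower bound (>7753)
    ),
    "duck": GeneStructureRow(
        "duck",
        (82, 94, 124, 74, 146, 814), (1514, 541, 1237, 2503, 1582),
        exon1_coding=21, last_exon_coding=144,
        reported_gene_length=8723, reported_protein_aa=201,
    ),
    "zebra finch": GeneStructureRow(
        "zebra finch",
        (18, 94, 124, 74, 146, 1555), (11613, 1092, 1036, 1724, 1466),
        exon1_coding=18, last_exon_coding=144,
        reported_protein_aa=199,  # reported total is a lower bound (>18202)
    ),
    "anole lizard": GeneStructureRow(
        "anole lizard",
        (48, 94, 124, 74, 146, 646), (23430, 241, 1608, 3656, 6011),
        exon1_coding=18, last_exon_coding=144,
        reported_gene_length=36078, reported_protein_aa=199,
    ),
    "tetraodon": GeneStructureRow(
        "tetraodon",
        (71, 100, 124, 74, 146, 928), (494, 213, 130, 69, 100),
        exon1_coding=18, last_exon_coding=144,
        reported_gene_length=2337, reported_protein_aa=201,
    ),
    "fugu": GeneStructureRow(
        "fugu",
        (28, 100, 124, 74, 146, 945), (477, 298, 87, 67, 114),
        exon1_coding=18, last_exon_coding=144,
        reported_gene_length=2460, reported_protein_aa=201,
    ),
    "stickleback": GeneStructureRow(
        "stickleback",
        (110, 100, 124, 74, 146, 431), (1075, 88, 84, 92, 180),
        exon1_coding=18, last_exon_coding=144,
        reported_gene_length=2504, reported_protein_aa=201,
    ),
    "medaka": GeneStructureRow(
        "medaka",
        (38, 100, 124, 74, 146, 1776), (1498, 85, 128, 1665, 172),
        exon1_coding=18, last_exon_coding=144,
        reported_gene_length=5806, reported_protein_aa=201,
    ),
    "amazon molly": GeneStructureRow(
        "amazon molly",
        (141, 100, 124, 74, 146, 795), (14216, 114, 77, 603, 561),
        exon1_coding=18, last_exon_coding=144,
        reported_gene_length=16951, reported_protein_aa=201,
    ),
    "zebrafish": GeneStructureRow(
        "zebrafish",
        (36, 91, 124, 74, 146, 643), (978, 503, 85, 1040, 2684),
        exon1_coding=18, last_exon_coding=144,
        reported_gene_length=6404, reported_mrna_length=1114,
        reported_protein_aa=198,
    ),
    "spotted gar": GeneStructureRow(
        "spotted gar",
        (183, 91, 124, 74, 146, 1787), (668, 646, 480, 363, 1633),
        exon1_coding=123, last_exon_coding=144,
        reported_gene_length=6195, reported_protein_aa=225,
    ),
    "coelacanth": GeneStructureRow(
        "coelacanth",
        (62, 123, 124, 74, 146, 1763), (3997, 774, 1463, 265, 1971),
        exon1_coding=18, last_exon_coding=144,
        reported_gene_length=10762, reported_protein_aa=199,
    ),
}


def row_to_model(row: GeneStructureRow) -> GeneModel:
    """Instantiate the curated row as a GeneModel (no genomic coordinates)."""
    return assemble_model(
        row.exon_lengths,
        row.intron_lengths,
        utr5=row.utr5,
        utr3=row.utr3,
        name=row.species,
    )
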