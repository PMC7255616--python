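"""Tiled and paralog-discriminating probe design.

Probes are in-silico counting probes: fixed-length genomic windows used to
interrogate read libraries, labelled a, b, c ... per source region.  The
default tiling step equals the probe length (abutting windows).
Discriminating probes are windows of one sequence whose aligned counterpart
in a near-identical paralog differs at enough positions that the read
matcher (mismatch tolerance 2) cannot cross-hybridize.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from typing import Optional

from .align import global_align

__all__ = ["Probe", "tile_probes", "discriminating_probes"]


def _letter_label(k: int) -> str:
    """0 -> a, 25 -> z, 26 -> aa, ..."""
    letters = string.ascii_lowercase
    label = ""
    k += 1
    while k > 0:
        k, rem = divmod(k - 1, 26)
        label = letters[rem] + label
    return label


@dataclass(frozen=True)
class Probe:
    id: str
    source: str
    offset: int  # 0-based position within the source region
    sequence: str
    tag: str  # region label, e.g. "exon1-a"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty probe sequence")
        if self.offset < 0:
            raise ValueError("negative probe offset")


def tile_probes(region_sequence: str, probe_length: int = 60,
                step: Optional[int] = None, source: str = "region") -> list[Probe]:
    """Tile a region with fixed-length probes at offsets 0, step, 2*step, ...

    Probes are emitted while offset + probe_length <= region length and
    labelled alphabetically in order.  A region shorter than one probe
    yields an empty list with a warning.
    """
    if step is None:
        step = probe_length
    if step < 1:
        raise ValueError("step must be >= 1")
    region = region_sequence.upper()
    if len(region) < probe_length:
        warnings.warn(
            f"region ({len(region)} nt) shorter than probe length "
            f"{probe_length}: no probes produced"
        )
        return []
    probes = []
    k = 0
    for offset in range(0, len(region) - probe_length + 1, step):
        label = _letter_label(k)
        probes.append(
            Probe(
                id=f"{source}-{label}",
                source=source,
                offset=offset,
                sequence=region[offset : offset + probe_length],
                tag=f"{source}-{label}",
            )
        )
        k += 1
    return probes


def discriminating_probes(seq_a: str, seq_b: str, probe_length: int = 60,
                          min_mismatches: int = 3,
                          source: str = "a") -> list[Probe]:
    """Windows of seq_a whose aligned counterpart in seq_b differs enough.

    The two sequences are globally aligned first; every window of seq_a of
    ``probe_length`` (step 1) whose alignment columns carry at least
    ``min_mismatches`` substitutions or gaps is returned.  Call with the
    arguments swapped for the symmetric probe set.
    """
    aln = global_align(seq_a.upper(), seq_b.upper())
    # per-position of seq_a: does its alignment column differ from seq_b?
    differs: list[bool] = []
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca == "-":
            continue  # no seq_a position in this column
        differs.append(ca != cb)
    n = len(seq_a)
    if n < probe_length:
        warnings.warn("sequence shorter than probe length: no probes produced")
        return []
    # prefix sums of mismatching positions
    prefix = [0]
    for d in differs:
        prefix.append(prefix[-1] + (1 if d else 0))
    probes = []
    k = 0
    for offset in range(0, n - probe_length + 1):
        if prefix[offset + probe_length] - prefix[offset] >= min_mismatches:
            label = _letter_label(k)
            probes.append(
                Probe(
                    id=f"{source}-disc-{label}",
                    source=source,
                    offset=offset,
                    sequence=seq_a[offset : offset + probe_length].upper(),
                    tag=f"{source}-disc-{label}",
                )
            )
            k += 1
    return probes
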