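"""Identity tables and progressive multiple alignment.

Builds the comparison tables of a comparative gene study: per-exon
nucleotide identity of each species against a reference gene (full-exon
global alignment or best-local block, with "no match" / "no exon"
conventions), and per-protein identity with lengths, difference counts, and
positional difference listings.  A small progressive aligner (pairwise
distances -> neighbor-joining guide tree -> profile-profile merges) covers
the multiple-protein-alignment use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import (IdentityResult, Scoring, global_align, local_best_block,
                    percent_identity, scoring_for)

__all__ = [
    "exon_identity_table",
    "protein_identity_table",
    "protein_differences",
    "TreeNode",
    "nj_tree",
    "progressive_msa",
]


def exon_identity_table(
    reference: dict[str, Optional[str]],
    others: dict[str, dict[str, Optional[str]]],
    mode: str = "global",
    min_score: float = 30.0,
    min_span: int = 30,
) -> pd.DataFrame:
    """Per-exon identity of each species against the reference exons.

    ``reference`` maps exon labels to sequences; ``others`` maps species to
    the same labelling (a missing/None exon renders as "no exon").  In
    ``global`` mode identity is over the full-exon global alignment; in
    ``local`` mode over the best local block, rendered "pct (span bp)" when
    the block is shorter than the reference exon, or "no match" below the
    block thresholds.
    """
    if mode not in ("global", "local"):
        raise ValueError("mode must be 'global' or 'local'")
    columns = list(reference.keys())
    rows = {}
    for species, exons in others.items():
        cells = []
        for label in columns:
            ref_seq = reference[label]
            other_seq = exons.get(label)
            if ref_seq is None:
                cells.append("n/a")
                continue
            if other_seq is None:
                cells.append("no exon")
                continue
            if mode == "global":
                res = percent_identity(global_align(ref_seq, other_seq))
            else:
                res = local_best_block(ref_seq, other_seq,
                                       min_score=min_score, min_span=min_span)
            cells.append(res.render(full_span=len(ref_seq)))
        rows[species] = cells
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def protein_differences(aln_ref: str, aln_other: str) -> list[str]:
    """Positional differences, numbered by reference residue: "T7 > A"."""
    diffs = []
    ref_pos = 0
    for ca, cb in zip(aln_ref, aln_other):
        if ca != "-":
            ref_pos += 1
        if ca == cb:
            continue
        if ca == "-":
            diffs.append(f"ins{ref_pos} > {cb}")
        elif cb == "-":
            diffs.append(f"{ca}{ref_pos} > del")
        else:
            diffs.append(f"{ca}{ref_pos} > {cb}")
    return diffs


def protein_identity_table(
    reference: tuple[str, str],
    others: dict[str, str],
    max_listed_differences: int = 10,
) -> pd.DataFrame:
    """Protein lengths, percent identity and differences vs a reference.

    Each species row carries the protein length, global percent identity to
    the reference (1 decimal), the number of differing alignment columns,
    and — for small counts — the differences listed positionally.
    """
    ref_name, ref_seq = reference
    if not ref_seq:
        raise ValueError("empty reference protein")
    records = []
    for species, seq in others.items():
        if not seq:
            raise ValueError(f"{species}: empty protein")
        aln = global_align(ref_seq, seq)
        res = percent_identity(aln)
        diffs = protein_differences(aln.aligned_a, aln.aligned_b)
        listed = "; ".join(diffs) if len(diffs) <= max_listed_differences \
            else f"see alignment ({len(diffs)} differences)"
        records.append({
            "species": species,
            "length": len(seq),
            "percent_identity": res.percent_identity,
            "differences": res.differences,
            "difference_list": listed,
        })
    df = pd.DataFrame.from_records(records).set_index("species")
    df.attrs["reference"] = ref_name
    return df


@dataclass
class TreeNode:
    """A (possibly internal) node of the NJ guide tree."""

    label: Optional[str] = None
    children: Optional[list[tuple["TreeNode", float]]] = None  # (child, branch length)

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


def nj_tree(distance_matrix: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Neighbor-joining on a symmetric distance matrix.

    Standard Saitou-Nei agglomeration; the final three nodes are joined in
    an (unrooted) trifurcation, which for three taxa reproduces the
    closed-form branch lengths v_i = (d_ij + d_ik - d_jk) / 2.
    """
    d = np.asarray(distance_matrix, dtype=float).copy()
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix and labels are inconsistent")
    if n == 1:
        return TreeNode(label=labels[0])
    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        i, j = active[i_], active[j_]
        dij = d[i, j]
        vi = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        vj = dij - vi
        parent = TreeNode(children=[(nodes[i], max(vi, 0.0)),
                                    (nodes[j], max(vj, 0.0))])
        # distances from the new node to the others
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    if len(active) == 1:
        return nodes[active[0]]
    if len(active) == 2:
        i, j = active
        return TreeNode(children=[(nodes[i], d[i, j] / 2),
                                  (nodes[j], d[i, j] / 2)])
    i, j, k = active
    vi = (d[i, j] + d[i, k] - d[j, k]) / 2
    vj = (d[i, j] + d[j, k] - d[i, k]) / 2
    vk = (d[i, k] + d[j, k] - d[i, j]) / 2
    return TreeNode(children=[(nodes[i], max(vi, 0.0)),
                              (nodes[j], max(vj, 0.0)),
                              (nodes[k], max(vk, 0.0))])


def _pairwise_distance(a: str, b: str, scoring: Optional[Scoring]) -> float:
    aln = global_align(a, b, scoring=scoring)
    return 1.0 - aln.identities / aln.aligned_length


def _profile_align(prof_a: list[str], prof_b: list[str], scoring: Scoring,
                   gap_open: float, gap_extend: float) -> tuple[list[str], list[str]]:
    """Profile-profile global alignment: sum-of-pairs column scores with
    affine gap costs (so an indel stays one contiguous gap run)."""
    la, lb = len(prof_a[0]), len(prof_b[0])
    codes_a = [scoring.encode(row.replace("-", scoring.alphabet[0])) for row in prof_a]
    codes_b = [scoring.encode(row.replace("-", scoring.alphabet[0])) for row in prof_b]
    gaps_a = [[c == "-" for c in row] for row in prof_a]
    gaps_b = [[c == "-" for c in row] for row in prof_b]
    mat = scoring.matrix

    def col_score(i: int, j: int) -> float:
        total = 0.0
        count = 0
        for ra in range(len(prof_a)):
            if gaps_a[ra][i]:
                continue
            for rb in range(len(prof_b)):
                if gaps_b[rb][j]:
                    continue
                total += mat[codes_a[ra][i], codes_b[rb][j]]
                count += 1
        return total / count if count else 0.0

    neg = -1e18
    first = gap_open + gap_extend
    # Gotoh states: M substitution column, U gap in b (consumes a), L gap in a
    M = np.full((la + 1, lb + 1), neg)
    U = np.full((la + 1, lb + 1), neg)
    L = np.full((la + 1, lb + 1), neg)
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    ptr_u = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    ptr_l = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        U[i, 0] = -(gap_open + gap_extend * i)
        ptr_u[i, 0] = 1
    for j in range(1, lb + 1):
        L[0, j] = -(gap_open + gap_extend * j)
        ptr_l[0, j] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cs = col_score(i - 1, j - 1)
            prev = (M[i - 1, j - 1], U[i - 1, j - 1], L[i - 1, j - 1])
            k = int(np.argmax(prev))
            M[i, j] = prev[k] + cs
            ptr_m[i, j] = k
            cand_u = (M[i - 1, j] - first, U[i - 1, j] - gap_extend,
                      L[i - 1, j] - first)
            k = int(np.argmax(cand_u))
            U[i, j] = cand_u[k]
            ptr_u[i, j] = k
            cand_l = (M[i, j - 1] - first, U[i, j - 1] - first,
                      L[i, j - 1] - gap_extend)
            k = int(np.argmax(cand_l))
            L[i, j] = cand_l[k]
            ptr_l[i, j] = k
    cols_a: list[int] = []  # -1 = gap column
    cols_b: list[int] = []
    i, j = la, lb
    state = int(np.argmax((M[i, j], U[i, j], L[i, j])))
    while i > 0 or j > 0:
        if state == 0:
            prev = ptr_m[i, j]
            i -= 1
            j -= 1
            cols_a.append(i)
            cols_b.append(j)
        elif state == 1:
            prev = ptr_u[i, j]
            i -= 1
            cols_a.append(i)
            cols_b.append(-1)
        else:
            prev = ptr_l[i, j]
            j -= 1
            cols_a.append(-1)
            cols_b.append(j)
        state = int(prev)
    cols_a.reverse()
    cols_b.reverse()
    out_a = ["".join(row[c] if c >= 0 else "-" for c in cols_a) for row in prof_a]
    out_b = ["".join(row[c] if c >= 0 else "-" for c in cols_b) for row in prof_b]
    return out_a, out_b


def progressive_msa(sequences: Sequence[str],
                    scoring: Optional[Scoring] = None) -> list[str]:
    """Progressive multiple alignment along an NJ guide tree.

    Pairwise global alignments give a distance matrix (1 - fractional
    identity); neighbor joining yields the guide tree; profiles are merged
    at each internal node.  Two sequences reduce to the plain global
    alignment.  Output rows follow the input order.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences")
    if len(seqs) == 1:
        return [seqs[0]]
    if scoring is None:
        scoring = scoring_for(seqs[0], seqs[1])
    if len(seqs) == 2:
        aln = global_align(seqs[0], seqs[1], scoring=scoring)
        return [aln.aligned_a, aln.aligned_b]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pairwise_distance(seqs[i], seqs[j], scoring)
    tree = nj_tree(d, [str(i) for i in range(n)])

    def merge(node: TreeNode) -> tuple[list[int], list[str]]:
        if node.is_leaf:
            idx = int(node.label)
            return [idx], [seqs[idx]]
        idx, prof = merge(node.children[0][0])
        for child, _ in node.children[1:]:
            idx_b, prof_b = merge(child)
            prof, prof_b = _profile_align(prof, prof_b, scoring,
                                          float(scoring.gap_open),
                                          float(scoring.gap_extend))
            idx = idx + idx_b
            prof = prof + prof_b
        return idx, prof

    idx, prof = merge(tree)
    out = [""] * n
    for k, row in zip(idx, prof):
        out[k] = row
    return out
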