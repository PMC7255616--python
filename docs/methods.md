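# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `locuskit`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Gene models and arithmetic

A gene model is an ordered list of exons, each partitioned into 5′ UTR,
coding, and 3′ UTR segments (invariant: the three parts sum to the exon
length), separated by introns of known length. Interior exons are fully
coding; terminal UTRs live in the first and last exon. All internal
coordinates are 0-based half-open; GFF3 is written and read 1-based closed,
BED 0-based half-open, and the ±1 conversion lives in exactly one utility
(`locuskit.io`).

Arithmetic is exact: gene span = Σ exons + Σ introns; mRNA = Σ exons; a CDS
of L nt encodes L/3 − 1 residues (the stop codon is excluded — this is the
convention under which a 597-nt CDS yields a 198-aa protein). Models whose
coding total is not a multiple of 3 are *representable but marked
non-translatable* rather than rejected: the totals audit must be able to
hold inconsistent published rows as data. Proteins annotated without an
amino-terminal methionine are translatable only under an explicit
`allow_non_atg_start` override.

`validate_reported_totals` compares computed against reported values under
exact equality and records discrepancies as flags, never exceptions — a
disagreement between a printed total and its own row sum is a finding. The
curated rows in `reference_tables.py` carry the published exon/intron
lengths verbatim; the audit reproduces consistent totals (zebrafish
6404/1114, Amazon molly 16951, Anole lizard 36078, medaka 5806, spotted gar
6195, coelacanth 10762) and flags the inconsistent ones (chicken 9159
printed vs 11028 summed, mRNA 2452 vs 2448; tetraodon 2337 vs 2449; duck
8723 vs 8711; spotted gar's 225-aa protein vs 233 by coding arithmetic;
coelacanth's 629 coding nt, not a multiple of 3). No intent is guessed for
either side of a flagged pair.

## Read matching

Reads are matched to probes, regions, or spliced transcripts by exact
k-mer seeding (word size 11) and ungapped verification, in two modes:

- **Full-overlap counting** (`count_probe_hits`): a read hits a probe when
  they share an ungapped overlap ≥ a minimum (default: the seed length)
  with ≤ 2 mismatches over the overlap, on either strand, counted at most
  once per probe. For *discriminating* probes the minimum overlap is raised
  to the full probe length, otherwise a partial overlap could dodge the
  discriminating positions.
- **Clipped placement** (`map_reads_to_region`): each seed is extended
  ungapped in both directions under an X-drop rule (match +1, mismatch −3,
  drop 12) and trimmed to the maximum-scoring extent, so reads running off
  a splice junction, off the region, or into a poly(A) tail are placed on
  their matching segment only. Minimum placed extent: 30 nt.

Gapped alignment of reads is deliberately omitted: probes and reads are
near-identical to their targets by construction, and substitutions dominate
short-read error profiles.

## Boundary calls

**5′ (longest-clone rule).** The call is the 5′-most region coordinate
covered by any placed read — a lower bound that can only grow with more
reads. Single-read support is allowed but flagged low-confidence. The
implied UTR length is the distance to the annotated ATG.

**3′ (cleavage site).** A read whose 3′ end is an A-run of ≥ 5 nt, whose
templated prefix places flush against that run, and where the genome does
not itself continue with those As, pins the cleavage site at the end of its
templated part. The call is the 3′-most site supported by ≥ 2 such reads;
a site seen in a single read only wins (at low confidence) when nothing
better exists, because one sequencing error in the first tail base can
fabricate a site one base downstream. All supported sites are kept 5′→3′
(tandem cleavage is reported as a list, not forced to one site). Without
tailed reads the coverage terminus is reported at low confidence.

**Poly(A) signal.** Accepted hexamers are {AATAAA, ATTAAA, ATTTTA} — the
canonical signal plus the two variants relevant here — extensible by
argument. The search window is 40 nt upstream of the cleavage candidate
(typical signal spacing; the recovered offsets in this package's studies
are 8 and 12 nt); among candidates the hexamer whose 3′ end is closest to
the cleavage site is chosen and the offset recorded.

## Alignment and identity

Needleman–Wunsch and Smith–Waterman with affine gaps (Gotoh), implemented
in numba-compiled kernels. A gap of length L costs open + L·extend.
Nucleotide scoring is +1/−3 with open 5 / extend 2 (the BLAST-style scheme
used for the nucleotide comparisons); proteins use BLOSUM62 with open 10 /
extend 0.5. Traceback ties prefer a substitution column over a gap, then a
gap in the first sequence over the second — so output is deterministic.
E-values are not computed; "no match" is operationalized as best-local-block
score < 30 or span < 30 columns, a threshold calibrated so uniform-random
sequence pairs (100 vs 2000 nt) essentially never produce a block (tested
empirically). Percent identity = 100 × identities / aligned columns,
rounded to one decimal; exon tables render partial blocks as
"percent (span bp)" and support both full-exon global and best-local-block
modes, since published tables mix the two conventions.

The progressive aligner builds pairwise distances (1 − fractional
identity), a neighbor-joining guide tree (closed-form three-taxon solution
at the root), and merges profiles with sum-of-pairs column scores under the
same affine gap costs, so a planted indel stays one contiguous gap run. It
does no iterative refinement or sequence weighting.

## Retrocopy detection

Each parent exon is located in the genome (both strands, outside the parent
span) by seed diagonals clustered within one exon length, each cluster
refined by Smith–Waterman in a ±100-nt window; blocks must reach 75%
identity, 30 nt span, and score 30. Position-sorted blocks are chained into
maximal runs with one strand and strictly increasing (+) or decreasing (−)
exon indices. A chain is *intronless* when no inter-block gap exceeds 50 nt
of unexplained sequence — "adjacent" is not defined numerically in the
published analyses, but parent introns (85–23430 nt in the curated rows)
sit orders of magnitude above this threshold. When a chain skips an exon
whose homology decayed below the scan thresholds, the skipped exon's length
is the *expected* gap and only the excess counts: an intronless copy with
one undetected exon is still intronless. An intronless chain covering ≥ 4
of 6 exons is a retrocopy (the threshold tolerates decayed terminal exons);
it is labelled *retrocopy* when discriminating probes show expression and
*processed pseudogene* when silent; an intron-bearing multi-exon chain is a
tandem duplicate; fewer than 4 exons is a fragment. Insertion-flank
features (poly(A) tracts, target-site duplications) and insertion dating
are out of scope.

## Synthetic loci

The simulator is the package's instrument for validating everything that
would otherwise need real assemblies. Defaults describe a compact 6-exon
fish-like gene: exons 36/91/124/74/146/643 nt, introns
978/503/85/1040/2684 nt (gene span 6404 bp, mRNA 1114 nt, CDS 597 nt →
198-aa protein), 18-nt 5′ UTR, 499-nt 3′ UTR, ATTAAA signal with a 12-nt
cleavage offset, on a 20-kb chromosome with uniform A/C/G/T background
(50% GC — a neutral null for the alignment thresholds). Genes are simulated
on the forward strand; minus-strand cases are produced by
reverse-complementing the finished locus. Introns are GT..AG. Read
libraries default to 100-nt single-end reads (library read lengths and
depths are fixtures of this package, not claims about any external
dataset); starts are uniform over the mature transcript with an optional
geometric 5′-truncation decay; errors are independent per-base
substitutions at 0.1% (a typical short-read scale); a configured fraction
(default 0.2) of reads is anchored at the 3′ terminus and carries a
non-templated A-run of 5–20 nt. All randomness flows from one seed through
named substreams per stage, so a fixed seed gives bit-identical genomes,
reads, and truth, and stages are independently reproducible.

The generator guarantees the planted boundaries are well-posed: the last
transcribed base is not an A, the genome does not continue the transcript
with an A-run, and no competing accepted hexamer sits between the planted
signal and the cleavage site within the search window. Without these
guarantees, "exact" cleavage recovery would fail on a small percentage of
seeds for reasons that are properties of the random background, not of the
method.

What the simulator does **not** emulate: library-prep and GC biases,
paired-end reads, realistic quality strings (constant Q30), indel
sequencing errors, repeat structure, and heterozygosity. Passing
parameter-recovery tests therefore demonstrates correctness of the
computations under substitution-dominated, uniform-coverage conditions, not
robustness to every artifact of real libraries.

## Recovery studies and problem sizes

`locuskit.validation` packages the recovery studies used by the tests, the
analysis drivers, and the acceptance script:

- 5′-UTR recovery on a chicken-style gene (89-nt UTR) across 20 seeds at
  8000 reads (≈330× transcript depth). With uniform read starts the 5′-most
  read start is geometrically distributed, so the depth is chosen to make
  ±2 nt recovery near-certain per seed; at 20× the same estimator would
  typically sit ~4–5 nt inside the true end — the longest-clone rule is a
  lower bound, and its tightness is purely a function of depth.
- Exact recovery of terminal-exon length, signal hexamer, and 8-/12-nt
  cleavage offsets at 3000 reads with 20–25% tailed reads.
- Retrocopy detection at 10% divergence over 20 planted and 20 copy-free
  genomes (sensitivity and false-call count).
- Expression-ratio recovery of a 25% planted abundance from 6
  discriminating probes per gene at 100,000 reads, judged against binomial
  sampling bounds.

These sizes keep the full property suite to a few tens of seconds on one
CPU while leaving the statistical bounds meaningful.

## Design choices on open points

- The tiling step for probe design defaults to the probe length (abutting
  windows, matching discrete lettered segments); configurable down to 1.
- Discriminating probes require ≥ 3 mismatches per window: with the 2-
  mismatch read tolerance, three differences guarantee specificity (up to
  sequencing errors, which can re-create a discriminating base at ~e/3 per
  read; classification therefore treats any nonzero discriminating count as
  expression evidence only when probes are counted at full overlap).
- Whether published exon-identity percentages were computed over full exons
  or best local blocks is ambiguous; both renderings are implemented and
  the table mode is explicit.
- Synteny comparison normalizes gene names through a caller-supplied
  synonym table (e.g. Lcp2a ≡ Lcp2) and tests order congruence on the
  shared subset only, tolerating whole-locus reversal; distances are never
  compared, only order and orientation.
- The pipeline CLI exposes the stages as thin subcommands; the numbered
  scripts under `analysis/` are the primary narrative interface.
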