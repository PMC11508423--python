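# Methods

## Coordinates, composition, and rounding

All genomic coordinates are 1-based inclusive, written `start→end` (sense)
or `start←end` (antisense); antisense extraction returns the reverse
complement so every extracted sequence reads 5'→3' on its annotated
strand. Conversion to Python slices happens in a single helper. Multi-
segment loci are concatenated in listed order before any composition or
alignment computation.

GC% and AT% are computed over called bases only: IUPAC ambiguity codes are
excluded from the denominator, so GC% + AT% = 100 exactly and the summary
is strand-invariant. Table output prints percentages at one decimal place
using round-half-to-even; full precision is carried internally and in the
JSON sidecars.

## Pairwise alignment

Alignment uses affine gap penalties with a gap of length L costing
`gap_open + (L−1)·gap_extend`. Defaults: nucleotide match +5 / mismatch −4
/ open 10 / extend 0.5 (BLAST-like); protein BLOSUM62 / open 11 / extend 1.
All parameters are configurable. The dynamic programming is delegated to
Biopython's `PairwiseAligner`; the first reported optimal alignment is
taken, which is deterministic for fixed inputs and parameters. The test
suite checks optimality against a hand-written exhaustive enumeration of
all alignment paths for short sequences, which is independent of any
alignment library.

Identity is identical columns / all alignment columns including internal
gaps. With `end_gaps_free` (the default for copy-vs-gene comparisons)
terminal gaps cost nothing and terminal overhang columns are excluded from
the denominator — the closest global analogue of a local-alignment
identity over the reported region; both global and local identities are
available when the convention matters. Protein "positives" are columns
whose substitution score is positive, over the same denominator.

Transcript mapping is a best local alignment of the transcript (query)
against the genomic copy. Query coverage = aligned transcript bases /
transcript length. Gap runs in the **transcript row** of at least
`min_intron` columns (default 20 nt) are intron candidates: an intron is
present in the genomic copy and spliced out of the transcript, so it
appears as a transcript-row gap. The 20 nt default separates genuine
intron-scale gaps (tens of nt) from small indel alleles.

## Mutation spectrum

Each mismatch column of a query(authentic)→subject(copy) alignment
increments exactly one of ten counters: eight directional channels (C→T,
G→A, T→C, A→G, C→A, G→T, A→C, T→G) and two composition-neutral
transversion channels (A↔T, C↔G). The neutral channels are kept separate
because they do not move AT content and are absent from the directional
report columns, yet they must be counted somewhere for the conservation
invariant (mismatch columns = sum of all ten channels + ambiguous columns)
to hold exactly. Columns containing an ambiguity code are never
substitutions. A maximal run of `-` in one row is one indel event with a
parallel per-base count; since the underlying observation ("indel
alleles") is ambiguous between events and bases, reports carry both.

AT-change categories: |Δ AT| ≤ 1 point = no change; ≤ 5 = slight; > 5 =
large, signed. Boundary values land on the smaller category. A family is
*bidirectional* when copies increase and decrease beyond the ±1 band,
*homologous* when every copy is ≥ 97% similar with no categorical change,
otherwise the strongest category in the shared direction.

## RIP statistics

The allelic ratio is (insertion events + deletion events + all
transversions, including the neutral ones) : (all transitions). The
verdict is `consistent_with_rip` iff RIP-direction transitions strictly
dominate reverse transitions, GC→AT changes strictly dominate AT→GC
changes, and transitions strictly outnumber indels + transversions;
`inconsistent_with_rip` iff reverse transitions dominate or indels +
transversions dominate; everything else — ties, or fewer than `min_events`
(default 10) total mutations — is `indeterminate`. The underlying argument
is qualitative dominance reasoning; the explicit rule makes it testable,
and ties are never coerced. Dinucleotide-context weighting (CpA/TpG
preference) is deliberately not part of the default verdict.

## ITS copy finding and profiling

Seed-and-extend: exact 12-mer seeds against the reference on both strands;
seed hits are projected to implied copy starts and clustered within 50 bp;
each cluster window (reference length + 50 bp margins) is aligned
semi-globally — reference end-to-end, window overhangs free. Identity is
computed over all columns from the first to the last reference residue, so
reference bases left unaligned at the ends count against identity; this
stops a truncated placement (seeded by a chance decoy k-mer) from
outranking the full-length one. Candidates need identity ≥ `min_identity`
(default 80%, chosen because AT-biased genotypes sit at ~80–90% similarity
to the GC-biased reference, so genuine copies clear it while background
does not) and a footprint ≥ `min_length_fraction` (default 0.8) of the
reference length, which excludes short partial segments. Overlapping
candidates are deduplicated keeping the best identity. Planted-copy
recovery in tests is judged by ≥ 90% reciprocal overlap plus orientation:
when a copy's terminal bases are mutated, the optimal alignment can place
the boundary a few bp into flanking sequence, which is a reporting
ambiguity rather than a retrieval failure.

Copy profiles report GC%, identity to the GC-biased reference, the
min–max identity range over the AT-biased references, EcoRI (GAATTC)
positions (1-based, overlapping allowed; a single-strand scan suffices for
palindromic motifs), and the spectrum/allelic ratio versus the GC-biased
reference. GC-content groups are compared with Welch's unequal-variance
t-test (the groups' variances differ severalfold in this system); with
zero variance in both groups, equal means give p = 1 by convention.

## Propensity profiles

The four conformational propensity scales (α-helix, β-sheet, β-turn,
coil) ship as a versioned JSON file transcribed from the published
Deléage–Roux parameter set used by the ExPASy ProtScale service; the file
is the single source of truth and can be swapped. The profile at center c
is Σ wᵢ·scale(aaᵢ) / Σ wᵢ over a window of odd length (default 21
residues, the window used for this protein family's comparisons), with
weights falling linearly from 1.0 at the center to `edge_weight`/100 at
both edges. The default edge weight is 100% (uniform — a plain moving
average) because the weighting actually used upstream is unstated; the
linear model is exposed via `--edge-weight`. Unknown residues (X) take the
scale mean. Profile comparison is the Pearson correlation over
alignment-matched center positions (≥ 10 required); conclusions drawn from
profiles are comparative, not absolute, since the exact upstream scale
values and weights are not recoverable.

## Synthetic data generator

The generator emulates the statistical structure of repeat families in a
GC-biased fungal genome: a random ancestor at configurable GC (defaults
2 kb at 60% GC, gene-scale and GC-biased like the loci studied), copies
mutated by independent per-eligible-site category rates over the ten
channels, indels at a per-site rate with geometric lengths truncated at a
maximum (defaults p = 0.25, max 60 nt — tens-of-nt indels like those seen
in real repeat copies), a RIP-only mode restricted to C→T/G→A at rate 0.05
per eligible site (enough mutations on a 2 kb ancestor for unambiguous
verdicts), multi-copy arrays overwritten into a GC-matched decoy contig at
recorded positions and strands, and genes with one planted intron plus
their spliced transcript.

A single seeded stream drives each simulation; identical configurations
are byte-identical. Events are recorded in coordinate order. Two
constraints keep the ledger in one-to-one correspondence with alignment
features: substitutions at deleted sites are skipped, and deletions are
never adjacent nor split by an insertion, so each event is exactly one
maximal gap run. Consequently classifying the true alignment reproduces
the event-derived spectrum *exactly* (asserted with no tolerance).
Rate estimation divides each category count by the ancestor's eligible-
site count (rates are defined per ancestral site) with exact
Clopper–Pearson binomial intervals, whose coverage is ≥ the nominal 95%.

What the generator does not emulate: phylogenetic structure among copies
(all copies descend independently from one ancestor), context-dependent
RIP preference (CpA/TpG), selection, and real decoy-genome repeat
structure. Passing tests therefore demonstrate the correctness of the
counting, retrieval and inference machinery under the stated model — not
that real repeat families evolved under it.

## Problem sizes in the test suite and acceptance script

Spectrum/ledger exactness uses 1000 pairs of 300 bp mixed-rate copies;
verdict power 500 replicates per direction at 2 kb; rate recovery 1000
replicates at 2 kb; copy retrieval 500 genomes of 10 kb with three planted
copies each at ≥ ~88% identity; the array demonstration embeds 17 copies
(the copy count reported for the multi-copy assembly in this system) in a
30 kb decoy. These sizes give stable pass/fail behaviour for the
properties asserted while keeping a full run to a couple of minutes.

## Known limitations

* Reported similarities for divergent copies depend on the alignment
  convention (scoring and identity denominator); upstream BLAST-derived
  similarity values for low-identity pairs may differ by a few points.
  High-identity rows (≥ 97%) are convention-insensitive.
* The copy finder is exact-seed based (k = 12); copies below ~75% identity
  to the reference may fail to seed and are out of its design range.
* The RIP verdict is a deterministic dominance rule, not a hypothesis
  test; an optional binomial test on transition direction is a possible
  extension and deliberately not the default.
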