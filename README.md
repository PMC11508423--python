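# ripscan

Mutation-spectrum analysis of repetitive genomic copies of fungal genes and
rDNA ITS repeats: did repeat-induced point mutation (RIP) shape them, or
not?

## The scientific problem

Fungal genomes often carry multiple copies of a gene or of the ribosomal
ITS1-5.8S-ITS2 unit. In many ascomycetes, duplicated sequences are attacked
by RIP, a genome-defence process that converts C:G pairs to T:A — its
fingerprint is an excess of C→T and G→A transitions and a drift toward
higher AT content. Whether a given set of repeat copies bears that
fingerprint is decided by aligning each copy to its "authentic" (primary-
locus) gene and classifying every difference.

`ripscan` implements that analysis as a reusable, tested pipeline for
people studying repeat evolution in fungal assemblies (e.g. *Ophiocordyceps
sinensis* / *Hirsutella sinensis* and relatives):

* **Mutation spectrum** — every column of an authentic-gene → repeat-copy
  alignment is classified into the four transition directions (C→T, G→A,
  T→C, A→G), the four GC-changing transversion directions (C→A, G→T, A→C,
  T→G), composition-neutral transversions (A↔T, C↔G), and indel events
  with per-base counts. Derived sums give the "G or C → A or T" vs
  "A or T → G or C" totals.
* **AT-change categories** — repeat copies are binned by the change in AT
  content relative to the authentic gene: within ±1 percentage point = no
  change, ≤5 points = slight, >5 = large, with per-family categorization
  (including bidirectional families).
* **RIP statistics** — the allelic ratio (insertions + deletions +
  transversions) : transitions and a three-way verdict
  (`consistent_with_rip` / `inconsistent_with_rip` / `indeterminate`)
  codifying the dominance argument: RIP predicts C→T+G→A > T→C+A→G,
  GC→AT > AT→GC, and transitions outnumbering everything else.
* **ITS copy profiling** — seed-and-extend retrieval of ITS repeat copies
  from an assembly, per-copy GC%, similarity to the GC-biased reference
  genotype and to AT-biased genotype references, EcoRI (GAATTC) site scans
  (a single C→T transition destroys the site), and Welch comparison of
  GC-content groups.
* **Transcript mapping** — local alignment of transcripts onto genomic
  copies with query coverage and intron-candidate gap flagging.
* **Protein propensity profiles** — ProtScale-style sliding-window
  profiles (window 21, linear weight variation model) over the
  Deléage–Roux α-helix / β-sheet / β-turn / coil scales, plus a Pearson
  profile-correlation statistic.
* **Synthetic data** — a generator producing GC-biased ancestors, mutated
  copies under per-category substitution rates (including a RIP-only
  mode), indels, multi-copy arrays in a decoy genome, and intron-bearing
  genes with spliced transcripts — each with a complete truth ledger, so
  every stage is testable without downloads.

## Worked example

Simulate a RIP-mutated repeat copy of a 900 bp gene, then classify it:

```
$ ripscan simulate --seed 11 --length 900 --gc 0.6 --rip-mode \
    --indel-rate 0.002 --out-dir sim
$ ripscan spectrum gene.fasta copy.fasta --out-dir out
$ cat out/spectrum.tsv
subject  similarity_percent  at_change        c_to_t_and_g_to_a  t_to_c_and_a_to_g  c_to_a_and_g_to_t  a_to_c_and_t_to_g  gc_to_at_total  at_to_gc_total  ...  allelic_ratio  verdict
copy     97.6                ↑ 39.6% to 42.0%  22                 0                  0                  0                  22              0               ...  0:22           consistent_with_rip
```

Reading the row: the copy is 97.6% similar to the gene; its AT content
rose from 39.6% to 42.0%; all 22 point mutations are C→T/G→A transitions
(so GC→AT = 22 vs AT→GC = 0); the allelic ratio 0:22 (indel+transversion :
transition) is transition-dominated — together the textbook RIP signature,
and the verdict says so. A copy whose differences are mostly indels and
transversions (e.g. an allelic ratio of 13:0) gets `inconsistent_with_rip`
instead — the pattern seen in the variable genomic ITS copies of
GC-biased *H. sinensis*, which argues against a RIP origin for the
AT-biased ITS genotypes.

Other subcommands: `ripscan scan-its genome.fasta gt1.fasta --at-refs
at_genotypes.fasta` (per-copy GC/similarity tables + BED),
`ripscan map-transcript`, `ripscan protscale proteins.fasta --window 21`.
Every subcommand also exists as a plain library function.

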