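# Methods

This note documents the models, parameter choices and numerical decisions
behind `teloforge`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Label maps and digestion

A label map is the ordered list of enzyme recognition-site positions on a
molecule plus its length — the only observable in optical mapping.
Digestion reports every occurrence of the motif or its reverse complement
on forward coordinates (0-based occurrence start), with IUPAC degeneracy
expanded to character classes and no mismatches. Labels closer than a merge
distance (default 450 bp, the pre-alignment merge applied to reference
maps) collapse transitively to their centroid, rounded half-up; merging is
idempotent. Spacing statistics use the **population** SD — at the real
scale (hundreds of thousands of intervals) the sample/population
distinction is negligible, but it must be fixed for reproducibility —
and exclude adjacent pairs spanning reference N-gaps, whose spacing is not
informative. Internally all coordinates are 0-based half-open; the
CMAP/XMAP dialects on disk are 1-based, converted at the I/O boundary.

## Alignment model

The aligner emulates the commercial tool's dynamic programming over label
pairs. An alignment is a monotone chain of matched (query, reference)
labels; consecutive matched pairs contribute an interval score

    m − (Δq − Δr)² / (2σ²),   σ² = sd_fixed² + (sr·Δr)²

(maximal at equal interval lengths, symmetric, strictly decreasing in the
discrepancy), interior skipped labels cost `fp`/`fn` each (default m/2),
and interior gaps are bounded by `max_skip` per side (printed assembler
value 12; the pipeline default is 6, which covers the run lengths that
occur at its false-negative rate). In `endoutlier` mode unmatched terminal
query runs are free — this is the anchoring mode, where the distal
overhang *is* the signal; in `fit` mode they pay `fp` each. Terminal
reference labels are never penalised (the reference is much longer than
any query). A single matched label spans no interval and scores zero, so
`min_labels` defaults to 3.

Numerical choices: `sd_fixed` defaults to 1 kb even though the printed
parameter string carries a zero fixed sizing SD, because σ → 0 would make
short intervals infinitely precise; the `sf` site-SD parameter is carried
for parity but does not enter this emulated score. The exact commercial
likelihood is not public; every downstream decision depends only on the
*ranking* of alignments, which the oracle and recovery tests exercise.

The DP is stratified by chain length with a saturating top layer at
`min_labels`. This keeps the constrained optimum exact: without the
stratification, an empty restart (score 0) would dominate any
negative-scoring longer chain and the best chain of ≥ `min_labels` labels
could be lost. `brute_force_align` enumerates every monotone pairing (both
orientations, same scoring, instances ≤ 10 labels) and is the independent
oracle; the DP matches it exactly on randomized instances. Multiple
matches are extracted from the top-scoring DP end cells; a secondary match
sharing more than half of its matched reference labels with a
better-scoring accepted match is suppressed. Equal scores break by leftmost
reference start, then orientation.

## Terminus anchoring and calling

Among a sample's alignments to a chromosome whose most distal matched
reference label lies within the terminal window (default 1 Mb), the
anchor is chosen by: most distal matched reference label, then highest
score, then longer aligned span, then **larger distal overhang**, then
contig id. The overhang tie-break reflects that chromosome ends behave as
a dominant marker for the longest allele — real assemblers output the
extended allele — so an extended haplotype is preferred over an equally
scoring reference-type one. Anchor candidates must also be *confident*:
at least `anchor_min_labels` matched labels (default 10) and a mean score
per matched interval of at least m/2. This stands in for the commercial
aligner's alignment-significance cutoff and is what rejects short, gappy
chains of duplication-family labels that would otherwise fake a distal
anchor on a paralogous arm.

Let (i\*, j\*) be the most terminus-distal matched pair, D_q the contig
distance from i\* to its distal end, D_r the reference distance from j\* to
the chromosome end, and D_r′ = D_r minus N-gap bp in that span. A side is
*flush* when it has no unmatched labels distal of the matched pair. When
at least one side is flush, the label-free tails carry no evidence of
divergence and net out:

    extension_len = max(0, D_q − D_r),   missing_len = max(0, D_r′ − D_q)

so self-alignment yields exactly 0/0 at every terminus and a pure planted
event measures exactly its planted length. When both sides carry unmatched
distal labels the ends are genuinely divergent and the sizes are reported
independently, supporting combined extension-and-missing calls. Each size
is compared to the threshold independently.

The threshold is μ + kσ of the inter-label spacing (k = 3): with the real
spacing of 8.2 ± 8.3 kb this reproduces the 33.1 kb cut; on the synthetic
genomes, whose spacing is ~8.2 kb by construction of the 7-bp motif on
random sequence, it lands in the same range seed by seed.

Extensions are classified by realigning the extension label subsequence
genome-wide with multiple matches: any alignment covering ≥ 50% of the
extension labels (parameter) makes the call category 1, with every
qualifying origin recorded (chromosome, arm by position within 1 Mb of an
end, span, orientation); otherwise category 2, including the case of too
few labels to align (flagged). Trio inheritance compares the distal
10-label windows (parameter; the underlying rule is "no more than one
label difference at the terminus") of child and parent anchors through the
aligner, counting unmatched window labels on both sides; diploid termini
are allele classes under the same tolerance. Excluded-termini lists and
sex-chromosome merging are configuration inputs; the synthetic genomes
declare none.

## Long-read validation and tandem estimation

For a category-1 call the predicted chimeric end is origin segment +
N-gap + reference terminal segment, all in tip-first orientation; the gap
defaults to the called extension length minus the origin span (floor 0).
Reads are compared to predictions by exact k-mer matching (k = 16,
parameter) followed by greedy collinear chaining per diagonal band
(single-linkage band tolerance 50 bp for indel drift, chain break at
500 bp gaps, segments ≥ 1 kb kept) — an aligner-free formalisation of
reading a dotplot, sufficient at the error rates exercised here (exact
16-mers survive at ~0.2 per position even at 5% read error). The verdict
is the chained fraction of the origin part (confirmed at ≥ 50%,
parameter), with uncovered internal runs > 5 kb flagged as internal
deletions. Tandem estimation collects off-main-diagonal chain offsets in
the terminal window; the unit is their greatest common approximate divisor
(5% tolerance, refined by averaging per-offset unit estimates) and the
copy number `1 + round(max offset / unit)`.

## Duplication families

Base-pair copy number of a position is the number of duplication-pair
records overlapping it, with both interval sides of a record counting;
the profile is computed by an endpoint sweep and verified against
per-base counting. High-copy regions are maximal runs ≥ 22 (the source
states the cut both inclusively and exclusively; inclusive here, exposed
as a parameter), ordered by length. Every pair side spanning the entire
region is a family copy and contributes itself and its homologous partner
as members (deduplicated); regions yielding the same member set collapse
to one family. Members intersecting the 1 Mb terminal windows are
subtelomeric; families with none are dropped. Enrichment is a one-sided
exact binomial tail on member placement with p₀ = subtelomeric bp /
genome bp (the underlying test is not named in the source; the binomial
reading is documented here as the package's interpretation). Divergence
between copies is the percentage of single-base differences over gap-free
alignment columns (indels ignored; alignments below a size filter
rejected), and ages are divergence / 0.3% per Myr. The source contains a
conflicting "3% per million" phrasing; the printed ages are only
consistent with 3% per **10** Myr, which is the default.

A note on the pair-table convention: with one copy per locus and each
unordered pair listed once, a 16-copy family tops out at copy number 15.
The real whole-genome duplication database lists each pair in both
orders, and `emit_segdup_table(both_orders=True)` (the pipeline default
for emission) follows that convention, giving a 16-copy family a
2×15 = 30-deep core — past the ≥ 22 cut. The unordered emission (one
record per pair) remains the function's default and is what the pair-count
contracts are tested against.

## The synthetic-data generator

The generator's defaults are the study conditions. Background sequence is
i.i.d. uniform A/C/G/T (the analysis depends on label and duplication
structure, not composition); the default motif GCTCTTC yields ~1 label /
8.2 kb on random sequence. Two families (9 kb and 8 kb units) are planted
with 16 copies each: 15 subtelomeric copies in terminus-distal orientation
(q-arm forward, p-arm reverse-complemented) plus one interstitial,
markedly diverged ancestral copy. Placement offsets vary per arm so that
no two subtelomeres share an identical label constellation — with equal
offsets, entire arms become label-level paralogs of each other, which is
neither realistic nor analysable. Per-copy substitution fractions are
scheduled so pairwise subtelomeric divergence spans ~0.02–0.8% and
ancestor–subtelomere divergence a few percent, the ranges observed between
real family copies. End events (extension-by-duplication, terminal
deletion, tandem expansion) are applied to parental haplotypes before
transmission; p-arm events mirror through reverse complement so one q-arm
code path serves both arms.

Contig noise follows the published assembler error parameters re-expressed
as a generative model: Gaussian sizing error per inter-label interval with
SD √(200² + (0.01·interval)²) bp (sf 0.20 kb, sr 0.01), Bernoulli label
dropout at 0.06 (FN), Poisson false labels at 0.6 / 100 kb (FP), and a
1450 bp resolution merge (res 2.9 × ~500 bp/unit). No molecule-level error
model is published — only these assembler parameters — so this generative
reading is a stand-in, and noisy-data results should be read as
sensitivity checks rather than calibrated error rates. Long reads carry
substitutions/insertions/deletions at a 60/20/20 mix of the per-base error
rate; terminal reads place the chromosome tip at the read's last base.

All randomness derives from one master seed through per-stage substreams
keyed by stage name; identical configurations reproduce byte-identical
FASTA, CMAP and table outputs.

**What passing does and does not show.** Synthetic chromosomes are far
shorter than human ones (5 Mb in the standard runs; the methods were sized
so a full trio run completes in about a minute and a half), have no
centromeres, heterochromatin, N-gaps or telomere repeat biology, and their
duplication structure is exactly two clean families. Recovery on these
genomes demonstrates the correctness of the calling logic — thresholds,
netting, origin classification, inheritance, family detection — not the
error rates that would be observed on real optical-map assemblies, where
misassembly, reference gaps and richer paralogy dominate the difficulty.

## Known limitations

- The alignment score is an emulation; absolute scores are not comparable
  to the commercial tool's, only rankings are meaningful.
- The anchoring confidence filter (label count + score per interval) is a
  crude stand-in for a proper alignment p-value; heavily duplicated arms
  with long shared constellations could still defeat it.
- Heterozygous events shorter than their homologous allele are invisible
  by construction (dominant-marker behaviour), as in the real analysis.
- k-mer chaining replaces base-level alignment in validation; above ~10%
  read error the chains thin out and coverage fractions become
  conservative.
- Tandem estimation assumes the window spans the whole repeat array; a
  window shorter than the array undercounts copies.
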