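# Methods

## Problem and approach

Gapped short-read aligners report indels contained well inside a read as
`I`/`D` CIGAR operations, but an indel longer than roughly 15-20% of the
read length usually surfaces only as soft clipping (`S`): one side of the
read anchors to the reference and the rest is trimmed.  Insertions longer
than the read cannot be spanned by any single read at all.  clipscan
therefore combines three evidence channels into one calling cascade:

1. **Gapped alignment** - small indels read directly off the initial
   alignment's CIGAR operations.
2. **Soft-clip realignment** - reads whose clip position carries breakpoint
   evidence are re-aligned with a large-gap, block-based aligner, turning
   clips into explicit `D`/`I` runs (large deletions, medium insertions).
3. **Greedy k-mer assembly** - breakpoint-supported clipped reads plus all
   unmapped reads are assembled into contigs, which re-enter the same
   mapping/realignment cascade and expose indels longer than the read.

Calls from the read branch and the contig branch are merged into one final
VCF, with duplicate alleles collapsed.

## Soft-clip triage and the breakpoint test

A read is a *high-quality soft-clipped read* when it is mapped with
MAPQ >= `min_mapq` (default 1), at least `min_clip_frac` (20%) of its bases
are soft-clipped, and at least `min_highq_frac` (80%) of the clipped bases
have base quality >= Q20.  These tiers discard clips caused by poor
sequencing quality or ambiguous placement.

Clipped reads sharing a clip coordinate and clip side form a cluster.  With
k clipped reads among n mapped reads covering the locus, the evidence
statistic is the binomial survival function

    P = sum_{i=k+1}^{n} C(n, i) q^i (1 - q)^(n - i),

the probability of seeing *more than* k clipped reads under a noise model
in which each read is independently clipped with probability q (the
*heterogeneity factor*, default 0.1).  Clusters with P < alpha (default
0.05, no multiple-testing correction) are retained, and all their member
reads proceed to realignment.  The implementation uses
`scipy.stats.binom.sf`; the test suite checks it against an exact
rational-arithmetic summation over the full grid n <= 200.

Design choices the formulation leaves open, resolved as follows:

* Clusters are keyed by the exact (chromosome, clip coordinate, clip side);
  a read clipped on both ends contributes to two clusters.  A pooling
  window (`cluster_window`, default 0) can merge near-by clip coordinates.
* n counts primary, non-duplicate mapped reads whose aligned reference
  span covers the *anchor base adjacent to the clip* (the first aligned
  base for left clips, the last for right clips).  Measuring at the anchor
  rather than the clip coordinate itself guarantees that every member read
  counts toward its own cluster's n, which a half-open right-clip
  coordinate would not.

## Realignment engine

Realignment is a seed-chain-join aligner over an exact k-mer index of the
reference (seed word 16 bp; k-mers occurring more than 16 times are
dropped as repeats).  Seeds sharing a diagonal merge into gapless
segments; segments are chained by a small dynamic program that tolerates
target gaps up to 100 kb (deletions) and query gaps up to the query length
(insertions).  The junction between two chained segments is placed at the
split point that maximizes the number of matching columns, leftmost on
ties.  Because that optimum depends only on the reference and the local
haplotype, every read crossing the same junction reports the *same* indel
allele - this is what makes per-allele support aggregation work without a
consensus step.  Gap sizes are differences of diagonals, so chance matches
at a junction can shift the reported breakpoint by a few bases (absorbed
by left-alignment and the 100-bp matching tolerance) but never change the
indel size.

Alignments are expressed as PSL-style block structures and scored like the
UCSC web BLAT: matches - mismatches - query-gap openings - target-gap
openings.  Identity is matches / (matches + mismatches) over aligned
columns (the UCSC definition has additional gap terms; the simplification
is deliberate and the threshold is configurable).  The top-ranked hit is
accepted only with score > 30 and identity > 0.90, both strict
inequalities; ties break deterministically by (chromosome, position).
Accepted hits are converted to SAM CIGARs (leading/trailing unaligned
query becomes S, query gaps I, target gaps D, simultaneous gaps I-then-D)
and replace the original record, preserving sequence, qualities and
pairing flags and recording the original alignment in an `OA` tag.  The
search runs within +-50 kb of the original locus first and genome-wide on
failure.  Minus-strand hits reverse-complement the stored sequence and
toggle the reverse flag; mate fields are left untouched.

## Assembly branch

Retained clipped reads and all unmapped reads are assembled with the
classic greedy k-mer extension scheme: canonical (strand-merged) 25-mers
are counted; contigs seed at the most abundant unused k-mer and extend
base by base through the most abundant (k-1)-overlap, alphabetically
smallest base on ties, stopping when no unused extension with count >=
`min_kmer_count` (default 1) remains.  Contigs must be at least one base
longer than the read length - shorter contigs could not witness anything a
read cannot.  Determinism holds for any input read multiset because seeds
are ordered by (count, lexicographic) and all ties are lexicographic.

Contigs then repeat the read cascade: initial mapping, clip triage, the
binomial test (with per-position *contig* depth, so a singleton clipped
contig has k = n = 1 and P = 0 - effectively a pass-through, which is the
intended behaviour for the assembly branch), and realignment.

## Calling and merging

Indel evidence is read off `I`/`D` runs of the final CIGARs, one evidence
entry per distinct (chromosome, normalized position, type, size, allele).
Alleles are minimalized and left-aligned against the reference before
aggregation (verified against a brute-force enumeration oracle).  Read
calls require `min_support` distinct read names (default 3) and an
alternate fraction of at least `min_alt_fraction` (default 0.05) of local
depth; the defaults tolerate the 2% simulated base-error rate at 10x
coverage.  Contig calls require only an accepted contig alignment
(`min_contig_support`, default 1): one assembled contig already condenses
many reads, so read-level support thresholds do not transfer - this is a
deliberate asymmetry.  Bayesian genotyping is intentionally out of scope;
`--emit-bams` writes the two refined SAM files so any external caller can
be substituted.  Merging unions the two branches; records identical in
(chrom, pos, REF, ALT) collapse into one with SOURCE `reads,contigs` and
the larger support.

## Read simulator and mapper emulation

`place_indels` divides the reference into 1-kb bins (bins containing N are
ineligible), selects bins uniformly without replacement, gives the first
half deletions and the second half insertions - one event per bin, sizes
spanning 1 bp - 1 kb evenly (exactly one of each integer size at the
full 1000 + 1000 scale), inserted sequences i.i.d. uniform ACGT.  Events
are placed uniformly within their bin subject to fitting, so the truth set
is non-overlapping by construction and genome length obeys the exact
conservation identity.  `simulate_reads` is wgsim-like: ceil(coverage x
genome / (2 x read length)) pairs, fragment length Normal(500, 50)
truncated below at twice the read length, per-base substitution error
0.02, haplotype point mutations 0.001, and no indel errors.  Qualities are
constant Q30 with error positions marked Q15, which keeps the clip-quality
tier meaningful.  Each simulator stage seeds its generator with a
distinct `[seed, stage]` key; a shared scalar seed would let the placement
stage replay the reference synthesis stream and emit inserted sequences
that are literal reference substrings.

`emulate_mapper` supplies the role of the upstream soft-clipping aligner
so the pipeline is testable end to end without external binaries (any
coordinate-sorted SAM/BAM from a real aligner is accepted equivalently).
It probes a few exact seed words per read to pick the best diagonal, then
aligns the read to a local reference window: an edit-distance screen
(edlib) covers the common indel-free case, and any read showing gaps or
noisy ends is re-aligned with affine-gap glocal scoring (match +1,
mismatch -4, gap open -6, extend -1, free end gaps on the window) via
Bio.Align.PairwiseAligner.  Two post-processing rules reproduce the
behaviour attributed to BWT-based aligners: any single gap longer than
`max_indel_frac` (20%) of the read length is converted into a soft clip of
the shorter-anchored side, and terminal columns are trimmed at the score
maximum (the big-gap rule runs first - score-trimming across a genuine
internal gap would otherwise discard a valid spanning alignment).  MAPQ is
60 for a uniquely-supported locus, 20 with a weaker distant competitor, 0
on a tie.  On indel-free, error-free input the emulator maps 100% of
reads full length with zero clipping (asserted in tests).

## What the synthetic benchmark does and does not show

The simulation reproduces a uniform-composition genome with isolated,
non-overlapping, heterozygosity-free indels and uniform random insertions.
It does not model repeat structure, segmental duplication, GC bias,
heterozygous allele balance, or library artifacts - so passing benchmarks
demonstrate the mechanics of the cascade (breakpoint detection,
realignment geometry, assembly, size-exact calling), not performance on
real genomes.  Clips at repetitive breakpoints, for example, would yield
ambiguous realignments that the uniform genome rarely produces.

## Problem sizes and numerical choices

The package's own benchmarks run at desk scale: a 1-Mb reference with 50
deletions (and 50 insertions for the mode comparison) at 50x coverage with
100-bp pairs - the same per-bin density (two events per 40-bp size bin) as
the full-scale design, at 1/20 of the events.  The full 1000 + 1000 design
on a >= 3-Mb reference is exercised for the simulator contract itself.
Binomial P values are exact to < 1e-12 against rational summation for
n <= 200 (beyond that the regularized incomplete beta function's accuracy
governs).  Ties everywhere (assembly extension, seed ordering, hit
ranking, greedy matching) break deterministically, so a fixed seed yields
byte-identical VCF output.

## Known limitations

* Insertions between roughly half the read length and the read length sit
  in a hand-off zone: too long for a single read to span with flanking
  anchors, short enough that contigs only marginally exceed the minimum
  contig length; recall there depends on coverage more than elsewhere.
* The evaluator's one-to-one greedy matching charges a duplicate
  prediction at a true locus as a false positive (the intended reading of
  the TP criteria).
* The binomial test treats reads as independent; overlapping mates are
  counted once per template name within a cluster but independently in
  depth.
* No discordant insert-size or paired-breakpoint evidence is used, and no
  genotypes are emitted.
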