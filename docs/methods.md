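# Methods

This note documents the models and procedures behind `neosexqc`: what
each statistic assumes, which knobs matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Coordinate and file conventions

All coordinates are 0-based, half-open (BED convention), applied
uniformly across truth records, window partitions and reports.  Window
partitions tile each scaffold without gaps or overlaps; the last window
may be short, and a scaffold shorter than one window gets a single
ragged window rather than being excluded.  SAM I/O goes through pysam;
tandem-repeat reports use the standard `.dat` dialect with 1-based
inclusive coordinates, converted on import.

## Synthetic data model

The generator (`synthetic.py`) emulates the statistical structure the
validation procedures rely on, not sequencing realism:

- **Background** is i.i.d. uniform ACGT - neutral for every window
  statistic used here.
- **Homolog divergence is substitution-only.** Each neo-Y-like homolog
  is a copy of its partner with i.i.d. substitutions at the requested
  rate (default scenarios use 1.5-2%, the range typical of recently
  formed neo-sex chromosomes).  No indels means truth alignments are
  trivially defined; indel support would require a liftover layer and
  is deliberately out of scope.
- **Reads are error-free by default** (a uniform substitution error
  rate exists on `ReadPlan` but defaults to 0), isolating pipeline
  logic from aligner behavior.  Reads carry their truth placements as
  coordinate-sortable alignment rows, so every coverage-based module is
  testable without an external aligner.
- **Copy-number model**: females sample {autosome 2, X 2, neoX 2, Y 0,
  neoY 0}, males {2, 1, 1, 1, 1}; fragment counts are set so expected
  depth equals copy number × haploid depth and fragment positions are
  uniform (fragments 350 ± 50 bp, reads 100 bp - library parameters are
  asserted in the plan, not inferred from any dataset).
- **Double-mapping replicates**: reads falling entirely inside a
  duplicated interval are assigned to one copy by an independent fair
  coin per replicate.  Erroneous duplications are sampled from one copy
  only (the second copy exists only in the assembly), true duplications
  from both - reproducing the half-depth vs full-depth signature.
- **BAC clones** are vector + insert circles; shotgun pairs are
  sampled uniformly on the circle, so pairs straddling the
  vector-insert junctions arise at the rate the fragment model implies.
  Chimeric clones concatenate two inserts from distant locations.  The
  chimera count is `round(fraction × n)` rather than Bernoulli so small
  clone sets always contain the planned number.
- **ChIP counts** are Poisson around a background rate per 10-kb
  window; planted log2 effects multiply the ChIP rate (enrichment over
  the pericentromere, depletion over satellite arrays, additive in
  log space).
- **Determinism**: every component draws from a child stream of the
  plan's single seed; identical plan + seed gives byte-identical FASTA,
  FASTQ, SAM and truth outputs.

Because the background is uniform and reads are error-free, passing
tests demonstrate the logic of each procedure - thresholds, merging,
normalization, test statistics - under its intended signal structure.
They do not demonstrate robustness to GC bias, mappability variation,
sequencing error or real repeat landscapes; on real data those effects
enter through the aligner and library preparation, upstream of this
package's inputs.

## Sex-linkage classification

Depth is mean aligned bases per 50-kb window (mapping quality ≥ 20 by
default - multi-mapping reads in repeats would flatten the F:M
contrast).  Normalization is two-pass: each track is scaled by its
genome-wide median, then both are re-scaled by their median over
provisionally autosomal windows.  The provisional anchor is the lowest
cluster of per-window log2(F:M) ratios among windows covered in both
sexes: ratio clusters sit 1 apart in log2 (autosomal lowest, X-linked
above), so the lower quartile of ratios lands in the autosomal cluster
whenever autosomes contribute at least ~a quarter of the covered
windows - true for any realistic genome.  Y-like windows are excluded
from the anchor by a depth floor first, since their ratios are near
-inf.

Per-contig calls use medians of normalized depth with thresholds that
bisect the expected clusters in log2 space: Y-linked if female median
< 0.1 and male median > 0.2; X-linked if log2(F:M) ≥ 0.7 and male
median > 0.2; autosomal if |log2(F:M)| ≤ 0.35 and both medians > 0.5;
ambiguous otherwise.  The F:M ratio carries a pseudodepth of 0.01 in
both terms.  These numbers are this package's choices (the underlying
published classification was visual); all are parameters.  When
replicate individuals exist per sex, depth should be averaged per sex
before normalization.

## Duplication detection

Switch statistics are symmetric by construction: each read contributes
to the window of its placement in *both* replicates, and switched reads
contribute partner votes in both directions, so the output is invariant
under swapping replicates.  Windows are 10 kb (no window size is
prescribed by the source procedure; 10 kb resolves 100-kb calls to
±1 window).  "Roughly half the reads switch" is operationalized as
switch fraction ≥ 0.35 - a binomial-0.5 margin that a window of ≥ 200
reads exceeds with near certainty when truly duplicated and essentially
never otherwise - and "half depth" as depth ratio ≤ 0.65 against the
genome-wide median, with ≥ 0.8 marking true duplications and the gap
in between called erroneous with a low-confidence flag.  A merged
region must have ≥ 50% of its switched reads agreeing on one partner
region, which separates two-copy duplicates from dispersed repeats.
Which copy of an erroneous duplication to delete is an editorial
decision and out of scope: the caller reports, it does not edit.

## BAC locus calling

The placement rule is applied literally in the published order: extract
runs of 1-kb windows at ≥ 50× mean depth; merge runs within 250 kb;
re-merge any merged region longer than 250 kb from its constituents at
5 kb; rank candidates by mean depth and drop those below half of the
best (cross-contamination); drop regions shorter than 20 kb.  The 1-kb
window granularity is this package's choice (the rule's source does not
state one) and bounds boundary error well below the ±2 kb the tests
demand.  Clones with < 10% of reads aligned anywhere fail a coverage
pre-filter; they are reported with the distinct status `filtered`
because conflating them with `unplaced` (no ≥ 50× region) would hide a
library-quality problem behind a mapping one.  Every removal is logged
(`filter_log`), and re-running the caller replays to the same loci.

Edge verification takes reads within 4 kb of either vector end and
requires ≥ 3 of their mates within 10 kb of a locus boundary; the two
vector ends are assigned to the two distinct insert boundaries in the
orientation that maximizes total support, since insert orientation in
the vector is unknown.  The support floor of 3 replaces the original
manual pileup review.

Cross-mapping specificity maps the clone's read pairs to the native and
homolog loci with and without the native locus masked.  Fragments are
assigned as units (sum of mate edit distances); fragments scoring
equally on both loci - SNP-free over their whole footprint - split
between the loci by a hash of the read sequence, which emulates the
random assignment production aligners apply to perfect multi-mappers
while remaining reproducible.  At 1.5% divergence a ~350-bp fragment is
SNP-free with probability ≈ 0.5%–5%, so pre-masking cross-mapping stays
below 5%, while after masking essentially all fragments map to the
homolog at a mismatch rate near the divergence - the signature that the
two loci are genuine diverged homologs rather than a chimeric double
assembly.

## Read mapping adapter

Operations that need sequence-level mapping (cross-mapping, Y-read
subtraction) use an internal seed-and-extend mapper: a sorted k-mer
index (k = 21 by default; 17 where 2% divergence must still seed) votes
for diagonals, and candidates are verified by banded edit-distance
(edlib, infix mode) with an acceptance ceiling of 6% of read length.
Masked regions are excluded from the index and from candidate
placements, mirroring hard-masking.  On substitution-only, error-free
synthetic reads this adapter is effectively exact; real data should be
mapped with a production aligner and supplied as SAM/BAM.

## Satellite collapsing and periodicity

Tandem arrays are found by self-match at candidate periods scanned
ascending (2-120 bp by default), so each array is reported at its
minimal period; arrays need ≥ 3 copies, ≥ 50 bp and ≥ 85% self-match.
Consensus is the per-column majority over unit-phased copies.

Family collapsing implements the 90/90 rule: two units belong together
when they align at ≥ 90% identity over ≥ 90% mutual coverage, testing
every rotation of the longer unit, both strands, and k-fold expansions
of the shorter unit (k ≤ 8, covering the observed 4× higher-order case
with headroom) whenever k × short length is within 25% of the long
length.  Tandem units are circular, so rotations are enumerated
explicitly under global alignment rather than approximated by local
alignment with its edge effects; identity counts matches over all
alignment columns and gap columns count against both identity and
coverage.  Families are connected components of the pass/fail graph;
the family consensus is the canonical form (lexicographically minimal
rotation over both strands) of the shortest member, a polarization that
need not match any particular published orientation.

The centromere diagnostic marks start positions of AA/TT/AT
dinucleotides (A/T-only trinucleotides optional, off by default) and
scores each lag by circular autocorrelation of that indicator,
normalized by squared indicator density so 1 means "no structure".
Peak lag is the argmax over lags 2-50 and prominence the peak score
over the median score at lags 5-50.  Prominence is a max/median ratio,
so it is only meaningful with enough indicator positions: on a single
~100-bp unit with ~10 markers the null distribution of the ratio sits
at 3-5 regardless of signal, which is why calibration and null checks
operate on array-scale sequence (thousands of markers), the scale at
which centromere candidates are actually nominated.  The generator's
phased unit keeps a ~30% background of unphased A/T dinucleotides -
real AT-rich repeats are not sterile off-phase - which keeps the median
score positive and the statistic finite.

## Telomeric elements and chromosome ends

Classification is by best local alignment of each library entry (both
strands) against any reference telomeric element, telomeric iff score
> 50 and identity > 75 (strict inequalities).  The score threshold is
scheme-relative; the default scheme (match +1, mismatch -1, gap open
-2, extend -1) is declared in every label so reports are reproducible.
Classification runs in nucleotide space - the synthetic truth is
nucleotide-level - with protein references usable after six-frame
translation upstream.  Genomic copies are located by k-mer clustering
(k = 13, both strands) and counted into 10-kb masked-base windows; an
end is telomere-capped when telomeric bases reach ≥ 20% of the terminal
3 windows, and internal blocks are ≥ 20% runs touching neither
terminal span.  Terminal span and fraction are invented knobs replacing
a visual call; both are parameters.

## H3K9me3 depletion

Enrichment is log2((ChIP + 1)/(input + 1)) per 10-kb window after
scaling ChIP counts by the median per-window input/ChIP ratio.
Median-of-ratios was chosen over whole-library totals deliberately:
with enrichment covering a large genome fraction (pericentromeres can
be tens of percent), total-count scaling shifts every window by the
global enrichment mass, while the median anchors the unenriched
background at 0 so planted per-window effects are recovered absolutely
(to within ±0.1 log2 at ≥ 500 counts/window).  The anchoring assumes
background windows are the majority.  A uniform ChIP/input factor is
treated as library size and normalized away.

Windows are assigned to the centromeric-array group or the
pericentromeric group by majority overlap, arrays taking precedence;
each group needs ≥ 3 windows.  The depletion test is the two-sided
Wilcoxon rank-sum (Mann-Whitney) test, invariant under monotone
transforms of the enrichment values; direction is the sign of the
median difference.  Arms differ in heterochromatin content, so the
per-arm mode is the default for multi-chromosome data, with pooling
available.

## Y-ancestry by subtractive mapping

"Only present in the male assembly" is operationalized as < 10% of
scaffold bases covered by the union of male-to-female whole-genome
alignment blocks ≥ 1 kb (the source procedure names no number; both
knobs are parameters).  Read subtraction is maximally strict: a read
counts as female-mapped on any primary alignment regardless of quality,
which sacrifices recall for specificity - the correct trade when the
retained set defines male-specificity.  Density is the fraction of
nonzero-coverage 10-kb windows per target scaffold, with helpers to
restrict to arm intervals.

## Validation scenario sizes

The canonical scenarios (`scenarios.py`) use a 5-Mb six-scaffold genome
at 20× per sex for sex linkage; a 3-Mb two-scaffold genome with 150-kb
erroneous, 150-kb true and 80-kb sub-threshold duplication plants at
40× for conflict resolution; 50 BACs of 80-120 kb (5% chimeric) at
100× over a 4-Mb genome; a 630-kb satellite block inside a 1.6-Mb
pericentromere on a 4-Mb scaffold (≥ 50 windows per group, ~800 counts
per window) for the chromatin contrast; two scaffolds with terminal and
internal telomere arrays for end calling; and a 950-kb three-scaffold
species pair with a 250-kb male-limited scaffold (8% female-homologous)
at 5× for Y ancestry.  These sizes preserve the window counts, depth
regimes and feature scales each procedure's thresholds were designed
around while keeping full runs on one CPU in minutes.

## Known limitations

- Substitution-only divergence and error-free reads: see above.
- The tandem detector's ascending-period scan reports a higher-order
  array at its base period when the internal divergence is below the
  85% self-match slack; higher-order structure is recovered at the
  collapsing stage (multimer annotation), not at detection.
- The internal mapper is exhaustive only over seeded diagonals; reads
  whose every k-mer spans a substitution (vanishingly rare below ~5%
  divergence at k = 17-21) are missed.
- The depletion test's absolute enrichment values depend on the
  normalization anchor; only rank-based conclusions are
  normalization-free.
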