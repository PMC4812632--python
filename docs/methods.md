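# Methods

## Coordinate and ordering conventions

Internally every interval is 0-based, half-open, matching BED; GFF3 I/O
converts from the 1-based inclusive convention at the boundary, and the TSV
annotation dialect is already internal. Genes on a chromosome carry an
*ordinal*, their rank by start coordinate (ties broken by end, then
gene id); all clustering and classification rules operate on ordinals, so
results are invariant to base-pair coordinates given a fixed gene order.
Strand is carried through but ignored by cluster and position logic — the
rules implemented here are strand-agnostic. Ambiguous bases (N and other
IUPAC codes) count as neither AT nor GC in every composition statistic.

## Gene-family clustering

For a family with `n_members` genes in a genome of `N` genes, the average
distribution number `D = N / n_members` is the expected ordinal spacing
under uniform placement (e.g. 9194 genes and 184 family members give
D ≈ 50: one family gene per fifty genes). A cluster is a run of at least
`min_genes` (default 3) family genes spaced at least fivefold more densely
than D:

* **max_gap** (default): every adjacent pair of members is separated by at
  most `⌊D/5⌋` non-family genes. Maximal runs under this predicate are
  unique and deterministic, which is why this mode is the default. The
  threshold uses `floor`: D = 41 yields a gap bound of 8.
* **mean_gap**: runs are grown greedily left-to-right while the mean
  intervening gap stays below `D/5`, then trimmed from whichever end has
  the larger adjacent gap while the mean violates the bound. This mode
  admits one large gap balanced by tight neighbours, at the price of a
  left-to-right growth order; the greedy choice is documented rather than
  claimed canonical.

The equivalent sliding-window formulation — at least `min_genes` members
within a window of `min_genes × ⌊D/5⌋` genes stepped one gene at a time —
is exposed as `window_parameters` (D = 50 gives gap 10, window 30).

The secreted-protein rule is adjacency-based rather than D-based: maximal
runs of ≥ 3 strictly adjacent secreted genes, or merged groups of ≥ 4
secreted genes containing exactly one interior non-secreted gene. Blocks
separated by one gene are merged greedily left-to-right, one interruption
allowed per group, and group boundaries are always secreted. When three or
more adjacent-pair merges are possible the leftmost is taken; alternative
tilings differ only in rare hand-constructed patterns.

### Significance

A t test on a single observed cluster count is not well defined, so
significance of a family's clustered fraction is assessed by a label-shuffle
permutation test: membership is reassigned uniformly at random over all
ordinal slots (chromosome sizes fixed), the clustered fraction recomputed,
and `p = (1 + #{null ≥ observed}) / (n_perm + 1)`. The p-value is exact and
super-uniform under the null at the resolution of `n_perm` (calibration is
part of the test suite); Welch's t remains available for group-mean
comparisons, where it is well posed.

## Chromosome ends

**Telomere tracts.** The longest exact tandem array of the repeat unit
(default TTAGGG) within `max_offset` (default 1 kb) of the 3′ terminus, or
of its reverse complement CCCTAA at the 5′ terminus. Matching is exact with
`min_copies = 4`: observed fungal telomere tracts are clean terminal arrays
with N ≥ 5, so a 4-copy floor gives margin without admitting noise — on
random sequence a 24-mer exact tandem within 1 kb of a terminus is
vanishingly unlikely, and the test suite confirms zero false tracts over
1000 random 50-kb sequences.

**AT/GC disparity curve.** A window-less alternative to sliding-window GC
plots: cumulative sum stepping +1 on A/T, −1 on G/C, 0 on ambiguity codes.
The GC content of any interval is recoverable from two curve values, so no
window size needs choosing. Only the AT/GC component is computed; the
purine/pyrimidine and amino/keto components add nothing to GC segmentation.

**AT-rich segments.** Per-base scores are `+(1−θ)` for A/T and `−θ` for G/C
with θ the AT threshold (default 0.80), so a segment's score is positive
exactly when its AT fraction exceeds θ — the threshold enters analytically,
with no tuned score matrix. All maximal-scoring disjoint subsequences are
found with the Ruzzo–Tompa algorithm (amortized linear time via
back-pointer hopping) and filtered to `min_length` (default 1000 bp,
matching the 1–3 kb tracts this targets). The implementation is verified
against literal all-subsequence enumeration on short instances and against
the exhaustive prefix-minimum optimum on 10-kb instances.

**Positional classes.** A feature's distance to the nearest terminus is
`min(start, L − end)` — the envelope edge nearest the end, a choice made
explicit because "within 50 kb of the end" admits several reference points.
CEC ≤ 50 kb; NCEC 65–150 kb; MCC beyond. The 50–65 kb band is undefined in
the source classification; features there follow `gap_policy` (default
NCEC) so the three classes partition the chromosome, which the suite
asserts.

**GC control.** `sample_region_gc` draws fixed-length windows (default one
hundred 20-kb regions) uniformly from sequence ≥ 50 kb from any terminus
and reports mean/sd GC plus two AT-richness readouts: the fraction of
regions whose *overall* AT content exceeds θ, and the fraction *containing*
an AT-rich segment. Both are reported because a whole 20-kb window above
80 % AT is essentially impossible at genomic composition, so "region is
AT-rich" needs a stated reading; neither is privileged.

## Expression and chromatin integration

Expression tables are gene × condition matrices of non-negative values,
either linear (RPKM) or logarithmic (hybridization intensity; ratios are
computed after de-logging, base 2 by default since the base is a
convention, not a measurement). Induction is strict: a gene is induced when
`value(condition) / value(reference) > fold` (default 2). A reference RPKM
of exactly 0 gets a 0.1 pseudo-count added to both numerator and
denominator, and the event is logged. Group summaries are arithmetic means
and sample standard deviations at the gene level; named outliers can be
excluded (the use case being single genes whose induction is orders of
magnitude above their class). Induction ratio per class is the ratio of
class means, not the mean of ratios — the former is what the class-level
comparison asks about and is robust to near-zero individual denominators.
Welch's t statistic and Welch–Satterthwaite degrees of freedom are computed
from the textbook formulas with the p-value from the t distribution; when
one report contains more than five comparisons, Benjamini–Hochberg FDR
adjustment is applied. Histone-mark summaries count genes carrying each of
H3K4me2/H3K4me3/H3K9me3 per class, with every percentage quoted against an
explicit, named denominator (the class size in the assignment used).

## Synthetic data

The generator is the package's test bed: it plants known structure and
records it in a manifest, so detector output can be scored as recovery.

* **Sequence.** i.i.d. bases at background GC 51.5 %. Telomere arrays are
  written over the termini (copy numbers 14–17 plus one 5-copy tract; two
  chromosomes with tracts at both termini, two at one, three at none), then
  AT tracts of 1000–2800 bp at 86 % AT (four chromosomes both termini,
  three one terminus) just inside them.
* **Genes.** Lengths uniform 500–3000 bp (a density-only emulation: only
  density, not the length distribution, matters downstream), intergenic
  gaps exponential with scale tuned so overall density is 0.28 genes/kb.
  Default chromosome lengths span 280–690 kb — one tenth of the 2.8–6.9 Mb
  range typical of the emulated genomes — keeping a full-pipeline run
  around a second; `paper_scale=True` restores megabase chromosomes.
* **Families.** Each family plants its clusters at a configured member
  count, cluster size and gap (defaults include a 23-member CAZyme-like
  family, D ≈ 40, whose planted gap of 2 sits well inside the detection
  bound of 8), with remaining members placed uniformly; planted clusters of
  one family are kept ≥ 15 ordinals apart so they cannot merge.
* **Expression.** Gene base abundance log-normal (median 100 RPKM,
  σ_log = 0.6); basal conditions multiply by a class factor (CEC 0.01 — the
  two-orders-of-magnitude deficit — NCEC 0.3, MCC 1.0) and per-condition
  log-normal noise (σ = 0.1). Induced genes (per-condition fractions
  4–15 %, end-proximal classes upweighted for conidiation and
  confrontation) take their *unscaled* base times a fold drawn uniform from
  4–16, so induced levels are class-comparable while induction folds order
  CEC > NCEC > MCC. The 4× fold floor keeps every planted induced gene
  above the 2-fold calling threshold despite noise, making manifest
  recovery exact.
* **Marks.** Bernoulli per gene: H3K9me3 at 8 % in CEC vs 1 % elsewhere
  (the generator does not zero out NCEC specifically); H3K4me2/me3 at
  ~45–48 % outside CEC vs 10–12 % inside.

What the generator does *not* emulate: real sequence composition beyond GC
(no codon structure, repeats or transposons), isochore-like GC variation,
gene-length/expression correlations, replicate-level expression noise, or
spatial autocorrelation of marks beyond the class structure. Passing
recovery tests therefore demonstrates correctness of the detectors under
the stated statistical structure, not performance on real assemblies with
repeat-driven artefacts.

## Numerical and degenerate-input choices

Ties in gene ordering break by (end, gene id). Empty families raise;
families smaller than `min_genes` yield no clusters. Welch's test on two
zero-variance samples returns t = 0, p = 1 when the means agree and
p = 0 otherwise rather than 0/0. Densities are reported to 2 decimals and
percentages to 1, matching tabular convention; `average_spacing_kb`
truncates to 3 decimals. Chromosomes too short for the non-terminal GC
control are skipped with a warning rather than silently biasing the
sample. All randomness flows through `numpy.random.default_rng(seed)`;
identical seeds give byte-identical generator output and pipeline
summaries.

## Problem sizes used in validation

The test suite runs the cluster oracle on 100 randomized chromosomes of up
to 200 genes, the AT-segment oracles on 20 short plus 100 ten-kb
sequences, telomere recovery on 100 planted plus 1000 random 50-kb
sequences, permutation calibration on 150 sequence-free 900-gene genomes
at `n_perm = 999`, Welch agreement on 1000 random sample pairs, and
parameter recovery over 20 generator seeds at the default (tenth-scale)
genome — sizes at which every suite completes in seconds while retaining
the statistical resolution its assertion needs.
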