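# Methods

`srnakit` re-implements, at toy scale and with planted ground truth, the
computational core of a *C. elegans* small-RNA-seq study design: endogenous
small RNAs are sequenced from wild-type and mutant animals, classified into
the worm's canonical classes, counted antisense to protein-coding genes, and
compared between genotypes by fold-change rules, replicate count tests,
gene-set overlap statistics and metagene positional statistics. A separate
module fits one-site binding isotherms to fluorescence anisotropy titrations.
Every statistical stage is validated against data the simulator planted, so
the pipeline is testable without any external sequencing archive.

## Small-RNA class model

Reads are assigned to classes with a fixed precedence (miRNA > 21U > 22G >
26G > other):

* **miRNA** — insert identical to an annotated mature miRNA sequence.
* **21U** (piRNA) — 21 nt, 5' U, aligned within an annotated 21U locus on
  the locus strand. 21U loci are an explicit annotation track, not inferred
  from upstream motifs.
* **22G** — length 21–23 nt, 5' G, aligned antisense to an annotated gene.
  The window operationalizes "generally 22 nt"; the broader 21–23-nt siRNA
  tally (which encompasses 22G) is reported separately.
* **26G** — length 25–27 nt, 5' G, antisense to a gene.
* **other** — any aligned read matching none of the above.

Precedence matters only for reads that satisfy several definitions (e.g. a
22-nt G-start mature miRNA); it is exercised directly in the tests.

### Alignment and normalization

Alignment is exact-match only (a zero-mismatch contract) via a seed-and-
verify 15-mer index over both strands; minus-strand hits are reported in
forward coordinates. Multi-mapping reads contribute weight 1/n_hits to
per-gene counts; class tallies count each read once at its lowest-coordinate
hit, conserving total read mass. Reads matching annotated rRNA/tRNA/snoRNA
sequences (either strand, substring match) are excluded before alignment.
The rpm denominator is the number of genome-mapping reads excluding those
ncRNA matches; spliced-junction reads do not exist in the toy transcript
model, a deliberate simplification of the depth definition.

## Insert extraction

A raw read is barcode + insert + 3' linker (CTGTAG) + filler. The barcode
must match exactly; the linker is found at the leftmost position `p >= 1`
whose 6-nt window is within one mismatch of the linker, full windows only.
Leftmost-wins regardless of mismatch count: a deliberate tie-break, since
the alternative (prefer exact sites) would over-trim reads carrying a
chance near-linker hexamer. Inserts are kept at 15–30 nt, covering every
analyzed class (21–26 nt) with margin. T and U are equivalent on input;
qualities are never used. If a linker longer than 6 nt is supplied, only
its first 6 nt participate in the mismatch rule — users supplying longer
linkers should be aware the implementation searches the full given linker
length instead.

## Depletion calling

Two modes mirror the two analyses such studies report:

* **simple** (one library per genotype): called iff wild-type >= 10 rpm and
  mutant <= wild-type/2, boundary inclusive ("at least 2-fold").
* **replicates**: a per-gene exact negative-binomial test integrates
  replicates; called iff BH q < 0.05, FC < 1/2 (strict, as printed) and at
  least one wild-type replicate reaches 10 rpm.

The exact test scales counts to the geometric-mean library size, estimates
a single common dispersion by pooled method of moments (within-group excess
variance over squared mean, summed across genes), and conditions on each
gene's total: replicate sums of i.i.d. NB variables with common dispersion
are NB, and the conditional distribution of the wild-type/mutant split
depends only on the shape parameters. The two-sided p-value sums the
probabilities of all splits no more likely than the one observed. Counts are
scaled linearly rather than quantile-matched to the common depth; the
contract for this stage is calibration — type-I error at the nominal level,
near-uniform null p-values, and >= 90% sensitivity/precision on planted
4-fold depletions — not numerical agreement with any particular reference
implementation (one is nonetheless used as an independent cross-check in the
test suite, requiring called-set agreement on a planted dataset). Genes with
zero total count are untestable (p = 1, FC missing) and are excluded from
the BH batch.

## Overlap statistics

Gene-set overlaps are scored by the upper-tail hypergeometric probability,
checked against exhaustive draw enumeration over the full feasible grid for
universes up to 12. "q-values" are BH step-up adjusted within a batch (one
figure-panel's worth of comparisons); BH is the default FDR procedure in
this literature and no alternative is indicated. The universe is a required
input for any significance claim — published overlap q-values are not
reproducible without the original universe and batch composition, so only
the percentages (100·k/|A|, formatted at the printed precision) are treated
as reproducible quantities.

## Metagene centroid analysis

Each antisense 22G read is placed at its 5' end — the biologically defined
coordinate of a 5'-triphosphorylated RdRP product — expressed as a fraction
of gene length from the transcription start, strand-aware. Profiles use
B = 100 bins (percent-of-gene-length statements imply percent-scale
resolution). The aggregate profile pools raw read weights by default; a
`per_gene_normalize` option averages unit-mass per-gene profiles instead,
since either convention is defensible and they differ on skewed read
distributions. The genotype contrast reports the aggregate-centroid
difference in percent of metagene length (plus the same contrast on median
per-gene centroids), with significance from the Wilcoxon rank-sum test on
per-gene centroids — exact enumeration for tie-free samples of up to 8 per
group, otherwise the normal approximation with tie and continuity
correction. The 5'-half comparison sums per-gene rpm over s < 0.5 and
reports 100·(1 − mut/wt) with a Welch t-test across genes.

## Binding fits

The one-site isotherm A = A_max·[L]/(K_D + [L]) is fit by unweighted
nonlinear least squares (mirroring a plate-reader software default), with
A_max initialized at the observed plateau and K_D at the half-max
concentration by linear interpolation. Standard errors come from the
Gauss–Newton curvature at the optimum; a case-resampling bootstrap is
available for small titrations. Baseline correction subtracts an RNA-alone
anisotropy, scalar by default with a per-point vector supported. Fits whose
K_D falls outside the range the titration can constrain (below ~min
concentration/50 or above ~max·50, or at the box bounds 1e-6–1e3 µM) are
reported as failures rather than numbers.

## What the simulator emulates

The generator plants a known truth for every stage: a random genome with
mutually disjoint gene/rRNA/tRNA/snoRNA/miRNA/21U tracks; reads drawn from a
configurable class mixture with the correct length and 5'-nucleotide
signatures (22G/26G antisense to genes, 21U loci seeded with a 5' T);
per-gene depletion fold-changes applied to mutant 22G sampling weights; and
within-gene 22G 5'-end positions drawn from genotype-specific Beta
distributions over scaled coordinates, so a mean shift plants a centroid
shift of known size. Replicate count tables are NB with configurable mean
and dispersion (dispersion 0 gives Poisson). One global seed drives
everything; per-library streams are derived by stable hashing of
(seed, library name) so adding a library never perturbs existing ones.

Default study conditions: class mixture 15% miRNA / 20% 21U / 50% 22G /
5% 26G / 10% other (22G-dominated, as in germline small-RNA libraries),
depth 1e5 reads, 4-nt barcode, CTGTAG linker, 50-nt reads, constant 'I'
qualities, error rate 0. Beta concentration a+b = 10 gives a broad,
unimodal within-gene position distribution. An optional ncRNA mixture
component plants reads copied from annotated ncRNA features to exercise the
exclusion stage. Calibration suites use 500 genes (metagene, end-to-end) or
2000 genes (count tests) at depth 1e5 — sizes at which Monte-Carlo noise is
well below the tolerances being checked.

Two deliberate departures from real data:

* **Unambiguous reads.** Emitted inserts never contain a window within one
  mismatch of the 3' linker (such candidates are resampled; fixed loci that
  violate it are excluded from sampling). Real libraries carry a small
  fraction of such reads, which any mismatch-tolerant trimmer truncates;
  the constraint makes round-trip recovery exact so that downstream stages
  can be tested against truth counts without a trimming confound.
* **No splicing, isoforms, or expression heterogeneity** beyond the planted
  fold-changes: genes are single-exon intervals sampled uniformly. Passing
  tests therefore demonstrate correctness of the statistical machinery
  under the stated generative model, not robustness to real-library
  artifacts (ligation bias, contamination, mismatched alignments).

## Numerical choices

* Internal coordinates 0-based half-open; GFF3 I/O converts to 1-based
  closed. FASTA/FASTQ/GFF3 go through Biopython/gffutils.
* 22G positions are snapped to the nearest valid G-start offset within the
  gene; with random sequence this moves positions by ~2 nt on average and
  cancels in genotype contrasts.
* The exact test's conditional pmf is computed in log space (gammaln) and
  normalized by logsumexp; the "no more likely" comparison uses a 1e-10
  log-tolerance to absorb float ties.
* Boundary conventions: simple-mode depletion is inclusive (FC <= 0.5
  passes), replicate mode strict (FC < 0.5), both as printed in the rules
  they implement. IP enrichment with zero input counts as infinite
  enrichment once the 10-rpm floor is met.
* Percent formatting rounds half up (figures' convention), not banker's
  rounding.

## Known limitations

* The exact-match index holds every 15-mer of the genome in a Python dict:
  fine for megabase toy genomes, unsuitable for real ones (a real-scale
  aligner would replace it behind the same interface).
* The common-dispersion NB test does not model per-gene dispersion trends
  (no empirical-Bayes shrinkage); with strong mean-dispersion structure the
  calibration guarantees would need re-checking.
* Metagene scaling assumes one transcript model per gene.
* The null case of the centroid-shift suite asserts a rank-sum p > 0.05
  for a planted zero shift, which any fixed random draw fails with ~5%
  probability by construction; seeds are fixed, so the suite is
  deterministic, but re-parameterizations of that check should expect the
  usual null variability.
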