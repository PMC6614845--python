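# Methods

This note documents the models implemented in `h1splice`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where more than one reasonable
option existed. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Annotation

Gene models are read from GTF (exon features only; 1-based closed
coordinates converted to 0-based half-open on input). Scaffold and
mitochondrial chromosomes are dropped; a transcript with no exon feature is
excluded with a logged warning, and malformed lines raise an error naming
the line number.

The **internal-exon table** removes each transcript's first and last exon,
then collapses duplicated or overlapping exon variants to the variant
annotated in the most transcripts, regardless of strand. Ties in support
break toward the smaller start, then the smaller end; the representative
transcript (for gene id, strand and ordinal) is the lexicographically
smallest, so the table is invariant to transcript input order. Support is
counted over transcripts in which the interval is *internal*, consistent
with first/last removal preceding deduplication.

**Region sets**: promoters are the 2000 bp upstream of each TSS (strand
oriented, truncated at position 0 and at the chromosome end when sizes are
known); junctions are the first and last 100 bp of each intron; the intron
category is each intron minus its junctions; all categories are merged for
overlaps, and bookended intervals merge (mergeBed semantics). Introns
shorter than 200 bp are split at their midpoint into two junction
intervals — there is no established convention for this corner case; the
midpoint split conserves bases (junction + intron bases always partition
each intron, which is a tested invariant) and keeps both splice-site
contexts.

## Signal tracks

* ChIP reads are shifted `floor((mean_fragment − read_length)/2)` bp
  downstream on the read strand. Floor division is a convention; it yields
  the standard 87 bp shift for 51 bp reads from 225 bp fragments and
  127 bp for 36 bp reads from 290 bp fragments. Input libraries are never
  shifted.
* MNase reads are extended in the 3′ direction of their strand to the
  147 bp nucleosome footprint.
* Depth is reads-per-million: `value(b) = (#reads spanning b) · 1e6 /
  library size`. Coverage conservation (sum of per-base coverage equals the
  sum of read lengths after shift/extension and clipping) is a tested
  invariant.
* Occupancy = ChIP RPM − input RPM, elementwise. Negative values are
  **retained**: meta-profiles must be able to show depletion, and
  normalization modes that cannot handle non-positive values refuse to run
  rather than silently shifting.
* The GC track is binary (1 at G/C, case-insensitive). N bases score 0 and
  are logged — the missing-value channel (NaN) is reserved for the
  methylation track, where non-CpG bases are genuinely unobserved and must
  be excluded from meta-profile means rather than counted as zeros.
* Reads live in data frames with `chrom, start, end, strand`; SAM/BAM is
  read through pysam, and a 4-column tab text format is accepted for the
  synthetic libraries. Tracks serialize as 4-column bedGraph.

Coordinates clipped at chromosome bounds are logged; reads clipped to zero
length are dropped.

## Meta-profiles

A signal matrix holds one per-base row per exon, anchored at the first
exonic base (3′ss side) or last exonic base (5′ss side), always oriented
5′→3′ of the gene (minus-strand rows are reversed). Positions beyond the
chromosome are NaN and excluded from column means, with the per-offset n
reported.

Normalization modes: none; divide by the profile minimum (the minimum then
equals exactly 1; requires a strictly positive minimum — difference tracks
are profiled unnormalized); divide by the value at the anchored exonic
boundary base (offset 0). Normalizing "to the lowest value" could mean
dividing or subtracting; division is used because the resulting curves are
fold-like and positive, and the mode is configurable.
Binning averages the (already normalized) per-offset means over
non-overlapping windows of `bin_width` offsets, trailing remainder
dropped.

### Randomization occupancy test

Observed statistic: the mean track value over M random L bp intervals
drawn uniformly with replacement from the eligible start positions of the
target region set (intervals shorter than L are ineligible; if none is
eligible the test refuses to run). Baseline: N such sample means drawn from
the gene space (gene loci including the 2000 bp promoter). One-sided
empirical p-values use the +1 correction, `p_enriched = (1 + #{baseline ≥
observed}) / (N + 1)`, so p is never 0 and the floor at N = 1000 is
0.000999 ≈ 0.001 — the conventional way of reporting a fully saturated
randomization test at that repetition count. Sampling uses a cumulative-sum cache so each sample mean
costs O(M); the seed is a required argument.

Desk-scale caveat, and how calibration is checked: when the target set is
much smaller than M·L, sampled windows overlap and the observed mean has
higher variance than the baseline means, making the test slightly
anticonservative — at the scale the test is meant for (tens of megabases of
target), this vanishes. The calibration test therefore uses an
exchangeable null with *structurally matched* sets: 200 genes of 5 kb split
alternately into target and baseline halves, an iid standard-normal track
regenerated each run, 500 runs at M = 500, L = 50, N = 200 (scaled down
from the production M = 10 000, N = 1000 to fit a desk run), expecting a
rejection rate of 0.05 ± 0.02 at α = 0.05.

### Group comparisons

Two-sided Wilcoxon rank-sum: exact null when both groups have ≤ 20 values
and no ties; exhaustive labeling enumeration with midranks when ties are
present and the pooled size is ≤ 14; otherwise the tie-corrected normal
approximation. Student's t is delegated to scipy.

## Exon classes

Two k-means runs (k = 5, Lloyd iterations on raw per-base rows, no
standardization, best of 10 restarts, deterministic under the seed; backed
by scikit-learn) over junction-anchored occupancy matrices. k = 5 is the
default here (an intentionally arbitrary resolution: labels, not k,
decide the classes) and is configurable.

**Window widths.** Both runs use 300 bp of intron and 150 bp of exon. The
150 bp exonic span is this package's choice: the geometry model places the
opposite-junction linker-histone site `wrap − edge + linker ≈ 141` bp into
the exon from the anchored splice site, so a 100 bp exonic span cannot
contain the opposite-junction signal that the cross-run intersection
relies on; 150 bp covers it with margin.

**Cluster labels.** A centroid whose peak is below the global matrix mean
is `low`. Otherwise the peak position decides: within 50 bp of the
anchored junction → near that site; on the exonic side, within 50 bp of
the far window edge (where the opposite junction of a typical short exon
lies) → near the opposite site; intronic peaks at least 200 bp from the
junction → distant; anything else goes to the nearest junction. The
50/200 bp thresholds operationalize "near" versus "several hundred
nucleotides away" and are configurable.

**Intersection.** The exon universe is the rows with any observed data in
both matrices (identical universes required). marked_3ss = near_3ss in
both runs; marked_5ss = near_5ss in both; distant = distant in both;
everything else unmarked — mutually exclusive classes covering the
universe. Each of the three intersections is scored with the upper-tail
hypergeometric p-value `P[X ≥ overlap]` for X ~ Hypergeom(universe, |A|,
|B|), which matches exhaustive enumeration on all universes ≤ 12 (tested).

**Distances and geometry.** The per-exon distance from a splice site to
the signal is `|argmax(row) − anchor column|`, ties broken toward the
junction; all-missing rows are excluded. The optimal exon length is
`round10(wrap − edge offset)`: 110 bp (5′ss, edge 35 bp upstream of the
start) and 100 bp (3′ss, edge 45 bp downstream of the end) at a 146 bp
wrap. Pearson correlation (with its two-sided p) links distances to
inclusion levels or exon lengths; zero-variance inputs are rejected.

## Splice-site strength

The score of a site sequence s against a per-position frequency table is

    100 · (Σᵢ fᵢ(sᵢ) − Σᵢ minᵢ) / (Σᵢ maxᵢ − Σᵢ minᵢ)

so the per-position consensus scores exactly 100 and the anti-consensus 0,
and substituting any base for a higher-frequency one can never lower the
score (a tested monotonicity property). Sequences containing ambiguity
codes are not scored (logged). Window spans follow the classical donor
3 exonic + 6 intronic / acceptor 14 intronic + 3 exonic convention, documented here because
scores are only comparable across sites scored with the same spans. Frequency tables are a pluggable TSV input (signed
positions, negative = exonic side); the tables that ship are synthetic
consensus tables mirroring the generator's planted splice sites — suitable
for testing the scorer, not estimates from real splice-site compilations.

## PSI and differential inclusion

A read is informative for an (upstream, target, downstream) exon trio when
one of its splice junctions joins flank→target or target→flank
(inclusion-supporting; at least 8 bp aligned on both sides of the
junction; 8 bp is a common junction-alignment default) or joins the two flanks (exclusion-supporting; skipping
takes precedence if a read somehow shows both). The trio is handled in
genomic order, so the rule is strand-agnostic. Exons with no informative
reads are discarded; at least one exclusion-supporting read makes an exon
alternative, otherwise constitutive.

`psi = (I/2)/(I/2 + E)` balances the two inclusion junction classes
against the single skipping junction; the estimator is scale-invariant
(tested). Sampler-based isoform quantifiers estimate PSI with a full
generative model; this closed-form estimator plus the Beta-posterior Bayes
factor below is a defined, testable alternative that honors the same
downstream filter semantics.

Differential inclusion: per condition the PSI posterior is
`Beta(1 + I/2, 1 + E)` (uniform prior); the reported per-condition PSI and
Δψ = ψ_kd − ψ_wt are posterior means. The Bayes factor for Δψ ≠ 0 is the
Savage–Dickey ratio prior(Δψ=0)/posterior(Δψ=0), where the posterior
density of the difference at zero is the overlap integral of the two
marginal densities, evaluated by trapezoid on a 1001-point grid (agreement
with independent quadrature is tested). The five-way filter requires: ≥ 1
inclusion read in the condition favoring inclusion (the higher posterior
mean), ≥ 1 exclusion read in the other condition, |Δψ| ≥ 0.1, ≥ 10
informative reads across conditions, and BF ≥ 1. The first two conditions
follow the type-level invariant (per-favoring-condition, matching the
upstream tool's documented flag meaning) rather than the looser
"any-condition" reading.

Expression: `fpkm = reads · 1e9 / (exonic length · library size)`, with
fpkm ≥ 0.1 counted as expressed. Alternative exons split into low
(ψ < 0.30) and high (ψ > 0.70) inclusion bins, strict inequalities, middle
band excluded.

## Synthetic data

The generator emulates the statistical structure the analysis targets, on
a single synthetic chromosome:

* **Genes** of 4–7 exons; 70% in a long-intron/low-GC regime (intron
  median 950 bp, exon GC 0.55 vs intron 0.40) and 30% in a short-intron/
  high-GC regime (median 300 bp, GC 0.60/0.58) — the regime split mirrors
  the observation that splice-site-marked exons sit in long-intron,
  low-GC environments. Splice sites are sampled from the shipped consensus
  tables, so every intron starts GT and ends AG.
* **Exon classes** (marked_3ss / marked_5ss / distant / unmarked) are
  planted on alternating internal exons of long-regime genes (¼/¼/¼/¼);
  short-regime genes are entirely unmarked. Class-specific length medians
  (110 / 122 / 135 bp, lognormal σ = 0.213) reproduce the quartile
  ordering of the real classes (marked: ~75% ≤ 127 bp), and marked exons
  are capped at the 146 bp wrap — splice-site-proximal marking is
  geometrically impossible for exons longer than the wrapped DNA.
* **Geometry.** Marked_5ss exons carry a nucleosome whose edge is 35 bp
  upstream of the exon start (dyad at edge + 73); the planted ChIP-site
  center sits 30 bp beyond the opposite edge — the midpoint of the
  ~20–40 bp linker stretch contacted by the linker-histone C-terminal
  domain. Marked_3ss exons mirror this with the 45 bp downstream edge
  offset. This single rule makes the distance from the marked splice site
  to the signal equal to |(wrap − edge + linker) − L|, hence the strong
  negative length–distance correlation the pipeline recovers. Distant
  exons carry sites 210–270 bp into *both* flanking introns (distant
  signal must be visible from both anchored windows for the both-runs
  intersection) plus a loosely positioned nucleosome; unmarked exons have
  no site and a 50% chance of a loosely positioned nucleosome.
* **ChIP libraries** are single-end reads (51 bp from 225 bp fragments)
  emitted from fragment 5′ ends on random strands (libraries unstranded):
  uniform background at 30× coverage plus Poisson numbers of fragments
  jittered N(site, 10 bp) around planted sites, scaled so local site
  coverage is ~ρ× background (ρ = 5 by default). The input library is the
  background process alone. MNase fragments (147 bp) center on nucleosome
  dyads at 4× enrichment; RNAP II background covers gene bodies with extra
  fragments at the 3′ss of marked exons (3× pause enrichment), using the
  same read geometry for simplicity.
* **RNA.** Per gene, 300 transcript molecules include each alternative
  exon independently with its planted ψ (wild type, or knockdown where
  marked exons drop by Δψ = 0.3); every molecule emits one read across
  each junction of its exon chain with ≥ 8 bp overhangs. Because
  alternative exons are never adjacent, the trio counts are exactly
  I = 2X, E = n − X with X ~ Binomial(n, ψ), and the estimator recovers ψ
  without cross-exon contamination. The depth of 300 molecules per gene is
  chosen by power analysis: it puts the per-exon sampling error of ψ̂
  around 0.03, so the recovery checks measure estimator correctness rather
  than shot noise, while informative counts stay far above the
  ten-read filter threshold.
* **Methylation.** CpG positions are read off the generated sequence;
  each draws Binomial(depth ~ 1 + Poisson(30), p) methylated reads with
  p = 0.8 within 200 bp of marked/distant exons and 0.4 elsewhere.

Everything is deterministic under a fixed seed (tested), with per-stage
seeds derived from one master seed.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: mappability and alignment artifacts, PCR
duplicates, bisulfite conversion errors, overlapping genes and alternative
promoters/ends, fragment-length variance within a library, expression-level
variation between genes, intron retention and alternative 3′/5′ss events,
and any coupling between chromatin classes beyond the planted rules. The
recovery results demonstrate internal consistency of the pipeline under
the planted model, not performance on real libraries.

## Problem sizes used by tests and the acceptance script

Chromatin recovery runs use ~88 genes (~300 internal exons; balanced
accuracy of marked/distant/unmarked recovery is checked against 0.90);
the geometry correlation uses ~260 genes (~190 marked exons); PSI recovery
uses 60 genes (~200 internal exons); the calibration experiment runs 500
independent tracks. These sizes give the checks stable margins while a
full suite run stays around a minute.

## Known limitations

* The exon-class labels depend on the window widths and the 50/200 bp
  label thresholds; real signal that peaks between 50 and 200 bp into an
  intron is attributed to the nearest junction rather than given its own
  class.
* The PSI estimator is a two-isoform (inclusion/skipping) model; genes
  with adjacent alternative exons violate its constitutive-flank
  assumption, and the generator deliberately avoids planting them.
* The Savage–Dickey Bayes factor uses independent per-condition
  posteriors; it is a filter statistic, not a full joint model of both
  conditions.
* The randomization test is slightly anticonservative when the target
  region set is small relative to M·L (see above); for small targets,
  reduce M or treat borderline p-values with caution.
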