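# h1splice

Linker histones (the H1 family) bind the linker DNA at the nucleosome entry
and exit sites. Because nucleosomes align at exon borders and a nucleosome
wraps ~146 bp of DNA — about the length of a typical internal exon — the
splice sites of short exons fall into exactly the linker DNA a linker
histone occupies. `h1splice` is a tested implementation of an analysis
pipeline connecting this chromatin geometry to splicing outcomes:
ChIP/MNase occupancy tracks, junction-anchored meta-profiles, a
randomization enrichment test, k-means exon classes, splice-site strength
scoring, junction-read PSI estimation with differential filters, and the
nucleosome-geometry model of optimal exon length.

It is aimed at computational epigenomics researchers who want each stage of
that analysis as a reusable, testable function rather than a chain of
one-off scripts, together with a synthetic-data generator that plants known
ground truth so the whole pipeline can be exercised end to end without any
external datasets.

## The models in brief

**Occupancy tracks.** Single-end ChIP reads of length `r` from fragments of
mean length `f` are shifted `⌊(f − r)/2⌋` bp downstream on the read strand
(87 bp for 51 bp reads / 225 bp fragments), MNase reads are extended to the
147 bp nucleosome footprint, per-base depth is normalized to reads per
million (RPM), and the normalized input is subtracted:
`occupancy(b) = RPM_chip(b) − RPM_input(b)`, negatives retained.

**Randomization test.** The observed statistic is the mean occupancy over
M random intervals of L bp drawn from a target region set (e.g. the first
and last 100 bp of each intron — the *junctions*); the baseline is N such
means drawn from the gene space. Empirical one-sided p-values use the
+1/(N+1) correction, so the smallest attainable p is 1/(N+1).

**Exon classes.** Per-exon occupancy rows anchored at the 3′ss and at the
5′ss (300 bp intron + 150 bp exon) are clustered with k-means (k = 5,
best of restarts). Centroids are labelled by peak position (near a splice
site / several hundred bp into the intron / low), and the two runs are
intersected: an exon is *H1-marked* when it is near-site at the same splice
site in both runs, *H1-distant* when intronically distant in both, and
*unmarked* otherwise. Each intersection gets an upper-tail hypergeometric
p-value over the shared exon universe.

**Geometry model.** With the nucleosome edge 35 bp upstream of the exon
start (or 45 bp downstream of the exon end) and a 146 bp wrap, the optimal
exon length placing a splice site at the linker is
`round10(146 − 35) = 110` bp for the 5′ss and `round10(146 − 45) = 100` bp
for the 3′ss — and the distance from a splice site to the signal peak
decreases with exon length, which the pipeline recovers as a strong
negative correlation.

**PSI.** From junction-spanning reads with inclusion-supporting count I
(two junction classes) and exclusion-supporting count E (the skipping
junction), `psi = (I/2) / (I/2 + E)`. Differential inclusion between
wild-type and knockdown uses Beta posteriors `Beta(1 + I/2, 1 + E)` per
condition and a Savage–Dickey Bayes factor at Δψ = 0, filtered with
`num-inc ≥ 1`, `num-exc ≥ 1`, `|Δψ| ≥ 0.1`, `total ≥ 10`, `BF ≥ 1`.

## Worked example

```python
from collections import Counter
from h1splice import synthetic_data as sd, pipeline, annotation, metaprofile

study = sd.simulate_study(sd.SimConfig(n_genes=60), seed=7)
track = pipeline.chip_occupancy_track(
    study.chip_reads["h1"], study.chip_reads["input"], study.genome_sizes,
    read_len=51, frag_len=225)

regions = annotation.derive_region_sets(study.models, study.exons)
space = annotation.gene_region_set(study.models)
res = metaprofile.randomization_test(
    track, regions["junction"], space,
    m_intervals=10_000, interval_length=50, n_repetitions=1_000, seed=0)
print(res.observed_mean, res.baseline_means.mean(), res.p_enriched)

cls = pipeline.classify_exons(track, study.exons, seed=0)
print(Counter(cls.classes.values()), cls.pvalues)

counts_wt = pipeline.estimate_condition_psi(study.rna_reads["wt"], study.truth, "wt")
counts_kd = pipeline.estimate_condition_psi(study.rna_reads["kd"], study.truth, "kd")
diff = pipeline.differential_psi_table(counts_wt, counts_kd)
print(diff["passes_filter"].sum(), len(diff), diff.loc[diff.passes_filter, "delta_psi"].mean())
```

This prints (exactly, for these seeds):

* junction occupancy 18.7 RPM against a 0.6 RPM gene-space baseline with
  `p_enriched = 0.000999` — the 1/(N+1) floor, i.e. the junction signal
  exceeded all 1000 baseline samples;
* 43 marked (20 at the 3′ss, 23 at the 5′ss), 19 distant and 145 unmarked
  exons, every intersection hypergeometric p below 1e-25;
* 45 of 207 exons pass the five-way differential filter with mean
  Δψ = −0.296 (knockdown minus wild type) — all 45 are truly planted
  marked exons (the generator lowers inclusion of marked exons by 0.3).

The same stages are available from the shell:

```bash
h1splice simulate --seed 7 --n-genes 60 --out sim/
h1splice annotate --gtf sim/annotation.gtf --out ann/
h1splice tracks chip --reads sim/reads_h1.tsv --input sim/reads_input.tsv \
    --fasta sim/genome.fa --out chip.bedGraph
h1splice profile randtest --track chip.bedGraph --target ann/junction.bed \
    --space ann/gene.bed --m 10000 --l 50 --n 1000 --seed 0 \
    --fasta sim/genome.fa --out randtest.tsv
h1splice psi estimate --reads sim/rna_wt.tsv --trios sim/truth.tsv \
    --condition wt --out psi_wt.tsv
```

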