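# Methods

This document specifies the models, algorithms, parameters, and numerical
conventions implemented in `stretchmotif`. All coordinates are 0-based
half-open; all log-odds scores are in bits (log base 2) unless noted.

## 1. Enhancer classification and compartments

Chromatin-state segmentations (BED, one state label per interval) are scanned
per cell type. Consecutive segments whose state name matches the enhancer
criterion (by default, any state containing "Enhancer", case-insensitively;
alternatively an explicit state list) are merged into runs only when they are
bookended (gap of exactly 0 bp). Each run is classified by length:

- **SE (stretch enhancer)**: run length >= 3,000 bp,
- **TE (typical enhancer)**: run length <= 800 bp,
- **OTHER**: everything in between — excluded from all downstream analyses.

Each class is partitioned against the cell's DNase peak intervals into a DHS
compartment (base-level intersection, clipped to the enhancer) and a non-DHS
compartment (base-level complement within the class). The two compartments of
a class are disjoint and tile the class exactly; nucleotide totals are
conserved (asserted in the acceptance suite).

## 2. Motif model

### Scoring

A motif is a `w x 4` probability matrix with a background distribution.
Probabilities are regularized as `(P + eps) / (1 + 4 eps)` with pseudocount
`eps = 1e-3`, then scored per column as `log2(P' / background)`. The minus
strand is scored with the reverse-complemented matrix
(`log_odds[::-1, ::-1]`) on plus-strand coordinates. Windows containing N are
never scored or called.

### Exact p-values

The null score distribution is computed by dynamic programming: per-column
log-odds values are discretized to integer steps of `1e-3` bits via
round-to-nearest (`rint`), clipped below at −64 bits, and convolved column by
column under the background distribution. A window's integer score is the
*sum of per-column rounded values* (not the rounding of the real-valued sum);
the same convention is used for scanning, so scan scores and the DP null live
on the identical lattice and p-values are exact for the discretized score.
Hits are windows with `p <= 1e-4` (default), reported on both strands.

### Compositional null and fold enrichment

The null sequence set is a dinucleotide shuffle (Altschul–Erickson: a random
Eulerian path through the dinucleotide graph), which exactly preserves
dinucleotide (hence mononucleotide) counts and the first and last base.
Fold enrichment of a motif in a sequence set is
`(real_hits + 1) / (shuffled_hits + 1)`; one shuffled copy of each set serves
as the shared control for all motifs, valid because the shuffle is
motif-agnostic.

## 3. Expression linkage and cell-identity motifs

- **Correlation**: Spearman rho between a motif's per-cell SE-DHS fold
  enrichment and its TF's per-cell RPKM.
- **Shuffled-cell null**: per motif, the correlation is recomputed after
  permuting the cell labels of the expression vector (10 permutations per
  motif, pooled); observed vs null is compared with a two-sided Wilcoxon
  rank-sum test.
- **Central enrichment**: sequences of fixed length (1,000 bp) centered on
  in-class DHS summits are scanned; only best sites with score >= 5 bits
  count. For each candidate half-width `h` in `0..ceil(center)`, a binomial
  tail probability of observing the actual number of site centers within
  `+/-h` of the sequence center is computed and Bonferroni-corrected over the
  candidate set; the reported statistic is the natural-log adjusted p of the
  best half-width (ties resolved toward the center, then leftmost).
- **Assignment cascade** (conjunctive, order-independent): TF expressed in
  the cell (> 2 RPKM), central enrichment log adjusted p < −50, and rho > 0.
  Among motifs sharing a TF, the one with the lowest log adjusted p is kept.
- **Heatmap pruning**: motifs enter the enrichment heatmap if any cell's
  log2 fold enrichment exceeds 1.5 and the across-cell range exceeds 0.75
  (both strict); rows are ordered by complete-linkage agglomeration over
  correlation distance with exemplar-based cluster labels.

## 4. Aggregate profiles and density tracks

Profiles are averaged in 10 bp bins over +/-1,500 bp around DNase summits
(300 bins; bin k covers offsets `[10k − 1500, 10k − 1490)`; the central bin
is index 150). Signal profiles sum per-base signal within each bin and
average over summits, with windows truncated by chromosome edges contributing
zeros. Dinucleotide profiles assign an occurrence to the bin of its first
base and divide by valid positions. Motif-density profiles bin site starts,
with sites called at >= 40% of the motif's maximum score (floored at 0 bits,
with a 1e-9-bit comparison tolerance so a 100% threshold never loses an exact
consensus match to summation-order rounding).

Motif-density genome tracks count, in 150 bp windows sliding by 10 bp, a
maximal non-overlapping subset of pooled motif sites whose start lies in the
window (greedy left-to-right, ties toward the higher score), written as
bedGraph.

Footprint post-processing extends intervals by 5 bp on both ends (clipped at
0 and at the chromosome end when sizes are given) and merges intervals
separated by at most 10 bp (inclusive, `mergeBed -d` semantics); the
operation is idempotent under re-merge.

## 5. GWAS locus enrichment

A locus is a genome-wide-significant lead SNP (association `p < 5e-8`,
strict) plus all proxies with `r^2 >= 0.8` (inclusive). A locus overlaps a
feature set if *any* member position falls in a feature interval (half-open);
each locus counts at most once. Enrichment of a trait's loci in a feature set
is tested by drawing trait-size locus sets from a catalog pool (without
replacement by default) and reporting the empirical p-value
`(n_ge + 1) / (n_iterations + 1)` at 10,000 iterations, with Bonferroni
correction across reported feature sets.

The empirical p is conservative (sub-uniform) when overlap counts are small,
because of tie mass at the permutation distribution's upper quantiles; the
calibration experiment in the acceptance suite therefore uses a
high-coverage feature (the union of SE intervals across cells, locus overlap
fraction ~0.4) where the discrete null is fine-grained enough for the 5%
rejection rate to be measurable.

## 6. Synthetic data generator

The generator produces a fully specified corpus with truth tables; defaults
are the study conditions (sized for a single CPU):

- **Genome**: 2 chromosomes x 2 Mb of uniform random ACGT.
- **Annotation**: per each of 9 cell types, 30 SE (3,000–5,000 bp, 3 DHS
  peaks each) and 120 TE (200–800 bp, 1 DHS peak each) placed without
  overlap with a minimum 300 bp gap; random inter-enhancer gaps are
  exponential with mean set to 60% of the free slack per unit, so placement
  succeeds with margin at the default density. DHS summits carry +/-10 bp
  jitter in the reported peak.
- **Motif library**: 10 motifs (6 activators, 2 repressors, 2 neutral),
  widths 8–12, consensus probability 0.9 per column, uniform background.
- **Planting**: per (motif, cell) a weight from a permuted even ramp over
  [0.1, 1.0] scales a maximum rate of 1/150 sites per bp in DHS
  compartments; non-DHS compartments plant at 0.1x the DHS rate. Site counts
  are Poisson(rate x length); within DHS intervals positions concentrate
  around the peak summit (normal, sd 30 bp, uniform fallback), giving the
  summit-peaked density regime; sites never overlap, rates above the 1/width
  packing limit are an error, and saturated small intervals thin their draw.
  Neutral motifs are never planted.
- **Expression**: activator TF RPKM tracks its motif's cell weight
  (scale 10), repressors anti-track it, neutral TFs sit at 0.5; Gaussian
  noise sd 0.5, floored at 0. With `expression_coupled=False` the planted
  weights are replaced by independent uniforms — the decoupled null corpus
  used to calibrate the correlation test.
- **GWAS**: a disease trait places 60% of its 40 leads inside planted SE
  non-DHS motif sites of the first cell; a control trait and 8 background
  traits (40 loci each) are uniform. Leads get 0–5 proxies within 25 kb with
  `r^2 ~ U(0.5, 1.0)` and association p-values such that 70% pass 5e-8.
- **Signal tracks** (noise-free by default): DNase is one Gaussian bump per
  summit (amplitude 5, sd 100). H3K27ac is a broad enhancer-scale bump
  (sd 800) minus a deep narrow depression at the summit (depth 0.9 of the
  bump, sd 100), evaluated over +/-2,400 bp, so the profile dips at the
  summit while flanks stay high; SE peaks get 2x the TE amplitude.

All stages derive their RNG streams from `config.seed` plus small fixed
offsets, so a corpus is byte-identical across reruns of the same seed.

## 7. Numerical conventions and limitations

- Score discretization granularity is 1e-3 bits with a −64-bit clip; p-values
  are exact for the discretized score, and agree with brute-force `4^w`
  enumeration on the same lattice.
- Empirical permutation p-values are never 0 by construction (floor
  `1/(n_iter+1)`).
- The generator is a caricature sized for one CPU: uniform base composition,
  independent cells, a single shared annotation density, and noise-free
  signal tracks by default. It is intended to make the pipeline's recovery
  behavior testable, not to emulate real chromatin data.
- Central enrichment assumes equal-length input sequences and rejects mixed
  lengths.
- The dinucleotide shuffle treats runs of N as fixed separators; only ACGT
  segments are shuffled.
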