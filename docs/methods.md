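# Methods

This note documents the statistical model, the conventions chosen where
the underlying analysis recipe is ambiguous, the synthetic-data generator,
and the limits of what the tests demonstrate.

## Progression model and differential testing

Expression is a probe × sample matrix of log2 intensities (microarray,
RMA-style), with each sample labelled NORM, DTC or ATC and tagged with a
study of origin. Progression is modelled as a two-step linear evolution
NORM → DTC → ATC; nothing in the code assumes any particular platform
beyond "log2 values, probes map many-to-one onto genes".

Three two-group comparisons are computed per probe (DTC vs NORM,
ATC vs DTC, ATC vs NORM) with a two-sided **pooled-variance Student's t**
(not Welch) and Benjamini–Hochberg correction across all probes within a
comparison. Probes constant and identical in both groups get t = 0, p = 1
and a `degenerate` flag rather than NaN.

Gene-level rules:

- a probe *qualifies* when q < α (default 0.05) in **all three** comparisons;
- a gene is deregulated iff ≥ 1 probe qualifies;
- probe trend: up iff both step fold changes are strictly positive, down
  iff both strictly negative (a qualifying probe whose fold changes have
  opposite signs carries no trend);
- gene label: the common trend of its qualifying probes; genes whose
  qualifying probes disagree are `excluded_discordant`; a gene whose only
  qualifying probes are trendless is `not_deg` (significant level shifts
  with no monotone direction are not part of either trend list);
- representative probe: the qualifying probe with the smallest ATC-vs-DTC
  q (ties → smaller probe id). Genes without qualifying probes still get a
  representative (smallest ATC-vs-DTC q among their probes) so that every
  gene contributes one fold-change pair to standardization.

## Standardized fold change and signatures

For each comparison, sFC = (FC − mean FC) / sd FC with the sample (n−1)
standard deviation. **The standardization population is all genes**, using
each gene's signed representative-probe log2 fold change. This was a
genuinely open design point (the recipe could also be read as standardizing
over deregulated genes only); standardizing over the full, mostly-null
population is the choice under which the printed cutoffs behave as
intended — the bulk of genes defines the scale and strongly deregulated
genes land several standardized units out. Restricting the population to
the trend lists makes the cutoffs unreachable whenever the trend lists are
dominated by genuinely deregulated genes (their effect sizes then set the
standard deviation), which collapses every assignment to `unassigned` on
data with a realistic number of trend genes.

Cutoffs are lo = 2 and hi = 4 standardized units with **strict**
inequalities; a value exactly at a cutoff is not assigned. Up rules:
S1 iff sFC₁ > hi and sFC₂ < lo; S2 iff sFC₁ < lo and sFC₂ > hi; S3 iff
both exceed lo. Down rules are mirrored with negated thresholds. The S3
region geometrically overlaps corners of S1/S2, so assignment precedence
S1 > S2 > S3 makes the three signatures disjoint.

## Network module

Edge lists are undirected, self-loops dropped, duplicate pairs collapsed
keeping the maximum confidence score, and filtered at `min_score = 0.4`
(the conventional "medium confidence" cutoff for STRING exports;
configurable). The gene module is the largest connected component of the
subgraph induced by the signature genes; ties on component size break to
the lexicographically smallest sorted member list so runs are
deterministic. Module fraction is reported as a half-up-rounded percentage
of *mapped* genes (genes absent from the filtered network are reported
separately, not silently counted in the denominator). Association between
module sub-clusters and signature membership uses the two-sided Fisher
exact test (sum of hypergeometric point probabilities ≤ the observed
table's).

## Nanostring normalization and validation

Per sample, on raw counts:

1. background = mean + 2·sd of the negative controls, subtracted and
   clipped at zero (a common default for this platform; the alternative
   max-of-negatives convention changes little at these count levels);
2. positive-control factor = grand geometric mean of per-sample
   positive-control geomeans / this sample's geomean;
3. housekeeping factor, computed the same way from the housekeeping genes
   *after* steps 1–2 — this ordering means positive-control counting noise
   cancels from the combined correction, which is why scale-factor
   recovery on synthetic data is sub-percent;
4. floor at 1 count and log2, so "not above background" maps to exactly 0.

The combined correction is invariant to a global per-sample scale factor.
"Percent expressing" counts samples with normalized value > 0, i.e. above
background. Differential validation is a per-gene two-sided t on log2
values with BH across the panel; `validated` means q < 0.05 *and* positive
ATC−DTC log2FC. Matched pairs use a paired t on per-patient differences.
ΔΔCt follows the textbook definition with relative expression 2^(−ΔΔCt).

## Regulome integration

Intervals are 0-based half-open internally; BED stays native and GTF is
converted at I/O. Consensus peaks: all replicate peaks are merged into
maximal overlapping spans and a span is retained iff it contains peaks
from ≥ `min_support` (default 2) **distinct** replicates; the retained
interval is the full merged span (merge-then-filter, not intersection).
Peak anchor is the summit when provided, otherwise the interval midpoint.
A gene is a direct target iff some peak anchor lies within ± 3 kb
(configurable) of one of its TSSs; per-peak annotation reports the nearest
TSS with a strand-aware signed distance, ties broken toward the smaller
signed distance then the smaller gene id. Genomic categories are assigned
per peak by anchor with precedence
TSS > 5'UTR > 3'UTR > exon > intron > downstream > distal intergenic;
"downstream" extends 3 kb past the TES (symmetric with the TSS window,
configurable) and UTRs are derived strand-aware from the exon/CDS
structure. DEG thresholding is strict (FDR < 0.05), duplicates keep the
smallest FDR, and the core program is the exact triple intersection with
all seven Venn regions reported.

## Synthetic data generator

The generator emulates the statistical structure of every input:

- **Expression**: class baseline + cumulative planted effect + per-study
  additive batch offset (one draw per study, default sd 0.3 log2) +
  Gaussian within-class noise (default sd 0.5 log2). Defaults mirror the
  emulated meta-cohort: 127 NORM / 102 DTC / 50 ATC samples from 8
  studies. Planted genes follow archetypes S1 (2, 0), S2 (0, 2) and
  S3 (1.5, 1.5) log2 units over the two steps, 20 per archetype per
  direction among 2000 genes. Genes carry 1–3 probes
  (60 % / 30 % / 10 %); a fraction (default 0.1) of multi-probe planted
  genes receives one probe with the effect sign flipped, the minimal
  construction that triggers the discordant-exclusion rule.
- **Network**: Erdős–Rényi-style edges, dense (p = 0.8) inside a planted
  module, sparse (p = 0.01) elsewhere, scores uniform in [0.4, 1).
- **Gene model**: non-overlapping multi-exon transcripts with CDS and UTR
  stubs on both strands, packed with ≥ 20 kb intergenic gaps, GTF
  round-trippable.
- **ChIP replicates**: target peaks centred within the TSS window in ≥ 2
  of 3 replicates (reproducible fraction) or exactly one; noise peaks at
  least one peak-width beyond every TSS window, in exactly one replicate.
- **DEG tables**: planted core / line-specific / null genes with FDRs well
  inside or outside the 0.05 threshold and a configurable down-regulated
  fraction (defaults 52 % / 51 %).
- **Nanostring**: Poisson counts around a 4-fold positive-control ladder,
  low-count negatives, four high-count housekeepers, per-sample log-normal
  technical scale factors (sd 0.3) applied to every code class, and a
  planted ATC effect with log-normal extra-dispersion on panel genes.

All generators are deterministic under a seed (bit-identical reruns).

### What the benchmark does and does not show

Planted effects are additive, Gaussian and study-balanced; real
meta-cohorts have correlated probes, heavier-tailed noise, confounded
study/class composition and platform-specific intensity dependence, none
of which the generator emulates. Passing the planted-truth benchmark
demonstrates that the implementation applies the stated rules correctly
and recovers effects of the stated size at the stated noise level — it
does not certify sensitivity on real cohorts. One structural property is
worth noting: planted S1/S2 archetypes have a zero effect in one step, so
they *cannot* satisfy the all-three-comparisons monotone rule; recovery
metrics therefore score trend sensitivity over genes carrying a genuine
two-step monotone trend, direction/archetype accuracy over recovered
genes, and discordant exclusion over flagged genes.

## Problem sizes and numerical choices

The benchmark uses 2000 genes × 80 samples × 10 seeds, 200-node networks,
100 kb toy chromosomes and 500-replicate calibration loops — sizes chosen
so the whole suite verifies the statistics in a couple of minutes while
keeping binomial/Monte-Carlo noise well below the tolerances tested.
Quantile normalization resolves rank ties by the mean of the tied
reference quantiles (making it idempotent to 1e-9); PCA orients each
loading vector so its largest-magnitude entry is positive; z-scoring and
sFC use the n−1 standard deviation; percentages round half-up. Degenerate
inputs (constant probes, zero-variance fold changes, empty graphs, all-zero
control lanes, incomplete patient pairs) raise typed validation errors
with the offending identifier rather than propagating NaNs.

## Known limitations

- The trend rule requires significance in all three comparisons; genes
  deregulated in only one step of the progression are invisible to it by
  construction (see the benchmark note above).
- Consensus peak support counts distinct replicates per merged span; two
  overlapping peaks from the same replicate never count as support.
- Enrichment testing is a plain hypergeometric over user-supplied gene
  sets; term hierarchies and redundancy pruning are out of scope.
- The Nanostring module consumes count tables, not vendor RCC binaries.
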