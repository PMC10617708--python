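# Methods

This note records the models, numerical choices and known limitations
behind `evohotspot`, in the order a study's data would flow through it.

## Study design being modelled

The package targets a common experimental-evolution design: two haploid
parental strains ("backgrounds" A and B) are split into precultures,
exposed to a selective drug, and hundreds of resistant clones are
isolated, phenotyped and whole-genome sequenced at moderate depth
(~60X). Resistance overwhelmingly arises through loss-of-function
mutations in a single target gene — the hotspot — while sequencing and
calling noise contaminate the per-genome variant lists. A minority of
clones instead acquire generalized resistance through loss of
respiration (petite, rho⁻) and are analysed by growth and cytometry
rather than sequencing.

## Synthetic cohorts (`simdata`)

The generator emulates this design end to end so that every pipeline
stage can be tested against a known truth.

**Genome.** `n_chromosomes` × `chromosome_length_bp` (default 2 ×
200 kb — a deliberate desk-scale reduction of a ~12-Mb fungal genome
that preserves windows-per-chromosome structure). Per-position GC
follows a sinusoid (base 0.40, amplitude 0.08, period 50 kb, clipped to
[0.25, 0.55]). Ten intronless genes per chromosome (651-bp CDS, ATG
start, stop codon, alternating strands, 500-bp promoter windows); the
hotspot gene is the first gene of chromosome 1.

**Cohort truth.** Each background contributes
`n_mutants_per_background` (default 138, i.e. a 276-genome cohort)
mutants assigned round-robin to `n_precultures` (default 25).  Each
mutant draws a causal gene — the hotspot with probability
`hotspot_fraction` (default 0.90), configurable alternatives, otherwise
none — and an effect class (missense 0.55, stop-gained 0.25, frameshift
0.15, start-lost 0.05, roughly the mix seen in loss-of-function hotspot
catalogues). A concrete variant of that class is rejection-sampled
inside the gene's CDS. Causal variants are never reused across
precultures (they model independent origins; one preculture can be
configured to share a single pre-existing mutation among its members).
Because a start codon admits only nine substitutions, a saturated class
falls back to missense. Background noise variants are Poisson per
genome (mean 3) at uniform positions — most land outside genes, so
per-genome mutated-gene counts stay qualitatively realistic without
being tuned to any published figure. Parental variants (20 per
background) are carried by every mutant of that background and by the
parental control sample. Petite status is assigned at background rates
(0.28, 0.36) and carried in the manifest.

**Caller emission.** Two default profiles mimic a permissive and a
stringent caller: detection per variant per genome with probability
`sensitivity` (0.97 vs 0.85), Poisson false positives per genome (6 vs
1). Site annotations (QUAL, QD, MQ, FS, SOR, rank sums) come from
truncated normals with a pass side clear of every hard-filter threshold
and a fail side beyond it; 5% of true calls (and ~half of false calls)
draw one annotation from the fail side, so the filters have work to do
without erasing the signal. Sample calls get Poisson depth (mean 60)
with occasional low-depth (2%) and contaminated (4%, minor-allele
fraction 0.05–0.5) draws to exercise the masking rules.

**Coverage, growth, dose response, flow.** Window counts are Poisson
with mean `base_depth · gc_multiplier(GC) · end_multiplier(d) ·
copy_ratio`; the GC multiplier is linear in GC, and the end inflation
decays from `end_ramp_factor` at the telomere either exponentially
(scale 20 kb, default) or linearly — the generative inverse of the CNV
module's corrections. Growth is logistic with a lag, per
(genotype-class, medium) parameters and multiplicative log-normal
noise, sampled every 2 h over 22 h with four replicates and wild-type
controls per background; defaults give resistant clones a small
drug-free cost (r 0.33 vs 0.35 h⁻¹) and a large advantage under drug
(0.32 vs 0.06 h⁻¹). Dose-response observations follow the Hill decay
with Gaussian noise clipped to [0, 1.2] and an exact anchor of 1 at zero
concentration. Flow samples are mixtures of log-normal populations in
FSC/SSC and two fluorescence channels.

**Determinism.** One master seed; each component uses
`default_rng([component_offset, seed, stream])` with fixed offsets, so
identical (seed, config) reproduce byte-identical outputs and components
can be regenerated independently.

## Variant filter cascade (`variants`)

Order: hard site filters → drop failing records → per-sample masking →
cohort filters with parental subtraction. All threshold comparisons are
strict, so boundary values pass. Policy decisions the written rules do
not settle:

- a record missing an annotation required by an active rule **fails that
  rule** (fail-closed) and is logged;
- AF and AC are recomputed over unmasked, non-parental samples with
  non-missing genotypes (the caller's INFO values are parsed but
  superseded);
- "total read depth" uses INFO DP when present, else the sum of sample
  depths; "mean read depth across all samples" averages all per-sample
  depths, masked or not;
- a sample call whose AD vector is all zero despite positive depth is
  masked (uninterpretable support);
- multi-allelic sites are split per alternate allele but keep the full
  AD vector, so "second most common allele" masking still sees every
  allele.

The effect annotator translates codons before/after a CDS SNP
(synonymous / missense / stop-gained / start-lost when codon 1 loses M),
classifies CDS indels by length mod 3, and assigns promoter-window hits
as upstream. It assumes intronless genes; the default promoter window is
500 bp. Reference-mismatch records are left unannotated and logged, not
fatal.

## Hotspot aggregation (`hotspots`)

Mutation identity is nucleotide-level (chrom, pos, ref, alt); genome
attribution requires an unmasked alternate genotype. Gene ranking is by
distinct-variant count, ties by genome count then gene id. Caller
concordance treats (variant, genome) as the detection unit; gene-level
membership is the union of its detections' memberships, and the
`exclusive_gene_sets` view counts each gene once ("both" wins over the
single-caller sets) for upset-style outputs. A protein-level rollup
collapses nucleotide changes that yield one amino-acid substitution.
Preculture sharing flags precultures with fewer unique causal mutations
than genomes — those clones are not independent evolutionary origins and
should be collapsed or down-weighted in any formal count.

## CNV screening (`cnv`)

5-kb tiling windows (trailing partial windows kept but excluded from
medians when shorter than 2.5 kb). GC correction is a median-ratio
rescaling within GC bins of width 0.01; bins with fewer than
`min_bin_size` (default 10) windows merge into the nearest populated
bin. The default suits thousands of windows; small tracks (~100 windows)
need a proportionally smaller `min_bin_size`, as the tests do. End-bias
correction splits each chromosome at the midpoint of its window list
(odd middle window to the left half) and divides by a per-half LOWESS
fit (span 2/3, tricube, 3 robustifying iterations) of corrected count
against distance to the near end; medians land on 1 without further
rescaling. Segment calling reports maximal runs with normalized ≥ 4
(amplification) or ≤ 0.25 (deletion — a configurable package default;
only the amplification display threshold has an external anchor)
spanning > 5 kb and < half the chromosome; NaN windows break runs.

Known limitations: the fixed 2/3 span cannot track a sharp exponential
telomeric spike at desk scale (~15–20% residual inflation in the
terminal window, well below the calling threshold); broad, smoothly
decaying ramps are removed essentially exactly. CNVs whose windows are
treated as LOWESS outliers survive correction, but a CNV abutting the
half-chromosome split sits at the fit's domain edge and its amplitude
estimate degrades (its detection does not). Breakpoints are
window-resolution only.

## Fitness, dose response, flow (`fitness`)

AUC uses the composite trapezoid, exact for the piecewise-linear data it
is applied to; a `t_max` between samples is closed by interpolation.
Relative fitness is mean AUC over the mean wild-type AUC from the same
plate/medium — the manifest, not the code, decides which WT normalizes
which plate. The maximum growth rate is the largest least-squares slope
of ln(value) in a sliding 5-point window; this estimator is a package
choice (none is externally specified) and IC50-adjacent quantities
inherit it. Inhibition coefficients are 100·(1 − r_c/r_0), unclipped by
default so stimulation is visible. The Hill fit is two-parameter
(responses are pre-normalized to 1 at c = 0), optimized on log(IC50),
log(h) by Levenberg–Marquardt from IC50₀ = the geometric mean of the
doses bracketing r = 0.5 and h₀ = 1; non-convergence is flagged on the
result rather than raised. Retention thresholds maximize (fraction of
negative-control events below) + (fraction of positive-control events
above) over observed control values and midpoints, ties toward the
larger threshold; overlapping controls are flagged low-separation.

## Statistics (`stats`)

Fisher's exact test computes the hypergeometric pmf over the a-cell's
support with vectorized log-gamma arithmetic; the two-sided p sums all
tables whose point probability is ≤ the observed (with 1e-12 relative
slack against float ties) — the same convention as scipy and R, which
the test suite cross-checks; an exhaustive enumeration over every 2×2
table with N ≤ 60 agrees to < 1e-9. Sidedness defaults to two-sided and
is parameterized. Chi-square uses no continuity correction by default
(flag available). Spearman's rho is the Pearson correlation of
tie-averaged ranks; p is exact by full permutation enumeration for
n ≤ 9 (bounded at 9! permutations) and t-approximated above.

## What passing tests do and do not show

The simulation screens demonstrate internal correctness — that the
cascade implements its written rules exactly, that planted signals
(hotspot gene, 15-kb amplifications, Hill parameters) are recovered
under the generator's noise — at deliberately reduced scale (200-kb
chromosomes, 100–276-genome cohorts, 20-seed screens). The generator
does not model read-level artifacts, alignment error, repetitive
sequence, linked selection or diploid genetics, so these results bound
algorithmic behaviour, not performance on real sequencing data.
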