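# Methods

This note documents the models implemented in `gradmap`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## Gradient-cross design

The phenotypic difference index between two parents is
`PDI = (m_high − m_low)/m_low`, always computed on per-accession means of
replicates.  It is undefined for non-positive low-parent means (the
toolkit targets strictly positive size-like traits).

**Grouping.** The method literature specifies the *properties* of gradient
groups (within-group PDI < 5%, adjacent steps ~8–25%) but not an
algorithm.  We sort accessions by mean and agglomerate greedily left to
right while the group's spread — max vs min member mean, as a PDI — stays
below the threshold.  This is deterministic, order-free given the sort,
and reproduces the obvious partitions on well-separated data.  Adjacent
group steps outside the advised band are flagged, never refused: practical
gradient crosses with PDI up to ~30% are known to work.

**Minimum crosses.** `N = ceil(((max−min)/min)/threshold)`, threshold
default 0.20.  Ceiling (not rounding) is used because both published
worked examples round 6.68 → 7 and 5.15 → 6; the result is floored at 1.

**Cross proposal.** One cross per adjacent group pair.  Representatives
are the accessions nearest their group means, unless a known-gene allele
table is supplied, in which case the pair maximising shared known-gene
alleles is chosen (ties by proximity to the group means) — parents sharing
alleles at already-cloned loci leave those loci monomorphic in the cross
and raise the odds of catching a new one.

## Forward simulator

Individuals are diploids over a marker map; alleles are coded by parent of
origin (0 = low-value parent, 1 = high-value parent).  Meiosis draws an
independent crossover decision per inter-marker interval with Haldane
fractions `r = (1 − exp(−2 d_Morgan))/2`; chromosomes assort
independently.  Haldane (no interference) rather than Kosambi: at the
sparse marker densities simulated here interference is irrelevant, and the
closed form doubles as the test oracle.

Genotype effects follow the Falconer convention: −a, d, +a for the low
homozygote, heterozygote and high homozygote.  The three verbal effect
classes map one-to-one onto d/a: complete dominance d = ±a, semi-dominance
(additivity) d = 0, over-dominance |d| > a.  Phenotype = baseline + sum of
locus effects + Normal(0, σ_e²).  With σ_e = 0 and one locus the F2
genotypic variance is a²/2 + d²/4, which the tests check against
simulation; `sigma_e_for_pve` inverts this decomposition to hit a target
single-locus PVE.

Pooled sequencing of a bulk draws total reads per marker from
Poisson(depth) and alternate reads from Binomial(total, bulk allele
frequency).  No sequencing error by default — error realism is out of
scope; the statistics studied here are driven by sampling noise, not
miscalls.  Array-style pooled calls use frequency cuts ≥0.9 → A, ≤0.1 → B,
else H, mimicking cluster calling on pooled DNA.

## Bulked-segregant analysis

Bulks are the top and bottom 15% of the population by phenotype (expanded
to a 30-member minimum with a warning; ties broken by stable id order).
SNP index = alt/(ref+alt) per bulk per marker; markers under 10 total
reads in a bulk are masked, never NaN-propagated.  Δ(SNP index) is
smoothed over 1 Mb windows with 200 kb steps; contiguous windows with
|Δ| ≥ 0.5 merge into candidate regions, ranked by peak |Δ| and padded by
±1 Mb into the working interval where verification markers are designed
(matching the 2–4 Mb intervals used in practice).  The |Δ| threshold
stands in for QTL-seq's simulation-based confidence bands, which are
deliberately out of scope; 0.5 is chosen so the degenerate fixed-bulk case
(index 1 vs 0.5) is always called while null fluctuations at 50× depth
and 30-member bulks stay well below it.

Chip mode declares a marker discriminating when the two pooled bulk calls
differ and at least one is homozygous; runs of ≥3 such markers merge into
regions.  Read mode and chip mode agree on noiseless high-depth
simulations (tested).

## Co-segregation standard

Individuals are classed by their joint genotype at the two flanking
markers: AA, BB, HH (identical calls), recombinant (discordant), missing.
Verification uses homozygotes only: a Welch two-sample test on AA vs BB
phenotypes at α = 10⁻³, **and** a midpoint-misclassification bound — the
fraction of homozygotes on the wrong side of the class-mean midpoint must
not exceed `max_overlap`.  Fewer than 8 members in either class yields
"undetermined", never a silent pass.

`max_overlap` defaults to 0.20.  Calibration: the weakest verified cross
in the field data this method comes from had an F2 PVE of 44%; for an
additive locus at that heritability the expected homozygote
misclassification is Φ(−a/σ_e) ≈ 0.105, so a 0.10 cut would reject a
genuine weak QTL about half the time, while the permutation-null overlap
concentrates near 0.5.  0.20 sits between the two regimes: ≥95%
verification power at PVE 0.44 (measured in the test suite), with the
false-verification rate still dominated by the Welch gate (≤10⁻³,
measured on 1,000 permutation nulls).

**12 models.** 3 effect classes × 2 allele orientations × 2 boundary
states.  The degree of dominance is estimated as
`ĥ = (mean_H − midparent)/(½(mean_AA − mean_BB))`; with tolerance
τ = 0.25, |ĥ| ≤ τ is semi-dominant, 1−τ ≤ |ĥ| ≤ 1+τ complete dominant
(orientation by sign), |ĥ| > 1+τ over-dominant.  Values in the gap
(τ, 1−τ) return "none" with diagnostics rather than a forced label; τ =
0.25 separates the classes cleanly at the simulated noise levels (≥90%
recovery over the 12-cell truth table at n = 300).  Boundary state is
"discrete" iff the model's phenotype classes have non-overlapping ranges.
Class counts are chi-squared against 3:1 / 1:3, 1:2:1 or 1:1:2 / 2:1:1.

**PVE.** One-way ANOVA R² over the three genotype classes AA/HH/BB
(between-class SS over total SS).  Three classes, not two: the
heterozygotes carry real genetic variance under any non-additive model,
and the three-class R² reduces to the two-class one when H is empty.

**Replacement families.** When an F2 fails verification, candidate lines
heterozygous at the region are selfed in phenotype order medium → low →
high (medium-value lines are most likely heterozygous at the major locus
and homozygous at the minor ones) and the first family passing the
standard is returned, with per-family diagnostics otherwise.

## Fine mapping

Recombinants (discordant flanks) carry a breakpoint localised between the
last marker matching the left-flank call and the first matching the
right-flank call.  Each recombinant's QTL genotype is inferred from its
phenotype by nearest homozygous class mean; phenotypes within ε (default
5% of the class separation) of the midpoint are ambiguous and excluded —
under additivity this correctly discards heterozygous-at-QTL
recombinants.  A recombinant whose inferred genotype matches its
left-flank call bounds the locus above by its breakpoint's right edge, and
symmetrically for the right.  The interval is the intersection of the
constraints of the largest consistent set (one-sided bounds, so a sweep
over candidate positions finds the consistent majority); the remainder are
reported as conflicts, and an empty intersection is an error naming them.
Intersection guarantees monotone refinement: an added consistent
recombinant can only narrow the interval.

Per-boundary support counts (the number of consistent recombinants whose
breakpoint abuts each marker) are reported the way fine-mapping figures
tabulate recombinants under each marker.

## Effects model

Allele coding is categorical one-hot minus reference (most frequent
allele), not dosage — functional markers are multi-allelic gene classes
(e.g. a six-allele series at a major gene).  Ordinary least squares; raw
(unadjusted) R² is reported, matching how such totals are usually quoted;
with ~15 predictors and n ≈ 541 the adjustment would be < 0.01.
Rank-deficient designs drop aliased columns (pivoted QR) with a warning.

Relative importance uses Johnson relative weights: predictors are passed
through the symmetric square root of their correlation matrix
(eigendecomposition, pseudo-inverse for collinear designs), each column's
weight is its share of the orthogonalised regression variance, and
gene-level importance sums the gene's columns.  Weights are non-negative
and sum to R² (to 10⁻⁶ on full-rank designs; collinear duplicates split
their share).  Johnson weights match the phrase "relative weight" in the
method literature; LMG decomposition gives near-identical answers on
these designs.

Cross-validation: seeded 10-fold random partition; out-of-fold predictions
for allele levels unseen in a training fold fall back to the intercept and
are logged; the reported statistic is the Pearson correlation between
observed and out-of-fold predicted values.  For large n this approaches
√R², which the acceptance check uses.

## Population genetics

π is the average pairwise per-site difference among haplotypes, computed
per site as `2p(1−p)·n/(n−1)` — algebraically identical to enumerating all
haplotype pairs, which the tests verify exactly.  The "silent-site"
restriction of the original analysis requires annotation this artifact
does not model: π is computed over all supplied sites and callers
pre-filter (a deliberate simplification).  Unphased diploids expand to two
haplotypes per individual (a heterozygote contributes one copy of each
allele); every statistic here is frequency-driven, so phase is irrelevant.

Windowed scans default to 100 kb windows / 20 kb steps.  Sweep scans
contrast the favoured vs unfavoured allele classes within ±500 kb of a
focal gene; the valley is the maximal run of windows with π-ratio < 0.25
containing the gene (windows with zero unfavoured diversity are masked).
The 0.25 cut cleanly separates constructed sweeps (ratio ≈ 0.1) from
neutral windows (ratio ≈ 1) at the simulated panel sizes.  Selection
pressure on a gene is the mean cultivar/landrace π-ratio over its
windows.  Directional selection along wild → landrace → cultivar allows
dips up to δ = 0.01 (sampling noise at realistic panel sizes).

## Synthetic-data generator

`gradmap.fixtures` generates every input from a seed; defaults encode the
study conditions: a 541-accession core collection, eight functional genes
(one major six-allele gene plus seven smaller two-to-three-allele genes)
with the favoured allele's frequency rising 0.12 → 0.45 → 0.80 along wild
→ landrace → cultivar, total true PVE 0.67 (σ_e calibrated against the
realised genetic variance), ~200-plant F2 populations, 15% bulks at 50×
depth, and a 300 kb suppressed-diversity block (10% residual
heterozygosity) for the sweep fixture.  Per-locus F2 PVE presets span
0.4–0.9, the range reported for verified crosses.

What the generator does **not** emulate: genotyping or sequencing error,
linkage disequilibrium within the population-genetic panels (sites are
drawn independently given their frequencies), population structure or
kinship within groups, segregation distortion, epistasis, and
genotype-by-environment interaction.  Passing tests therefore demonstrate
the statistical machinery under the stated models, not robustness to
those real-data complications.

## Problem sizes and numerics

The test suite simulates at the scales the corresponding checks need:
40,000 F2 plants for segregation ratios (3-SE binomial bands), 1,000
permutation nulls and 200 power replicates for the co-segregation
standard, 20 seeds per cell of the 12-model truth table (n = 300), 20
seeds for fine mapping (1,200 progeny, ≥50 informative recombinants), and
the full 541-accession collection for the effects model.  Reported
fractions are exact rationals of counts; ANOVA R² is clipped to [0, 1]
against floating-point overshoot; degenerate zero-variance Welch
comparisons are resolved analytically (equal means → p = 1, distinct
means → p = 0).  All randomness flows from a single integer seed through
`numpy.random.SeedSequence` splitting, and every fixture directory records
its seed.
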