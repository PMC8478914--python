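# gradmap

Rapid multi-QTL mapping with **F2 gradient populations** — a toolkit for
designing, simulating and analysing the gradient-cross mapping strategy
used to dissect quantitative traits (e.g. rice grain size) one Mendelian
locus at a time.

The idea: instead of crossing two phenotypic extremes (which segregates
many loci at once), pick pairs of parents with a *small, controlled*
phenotypic difference, quantified by the **phenotypic difference index**

```
PDI = (mean_high_parent − mean_low_parent) / mean_low_parent .
```

A core collection is partitioned into gradient groups (within-group
PDI < 5%, adjacent-group steps of ~8–25%), and one cross per adjacent pair
tiles the whole trait range.  The minimum number of crosses needed is

```
N = ceil( ((max − min) / min) / PDI_threshold ),      PDI_threshold = 20% .
```

Each resulting F2 gradient population usually segregates at a single major
locus, which is then:

1. **located** by bulked-segregant analysis — the SNP index (alternate-read
   fraction) of top/bottom-15% phenotype bulks approaches 1 at markers
   linked to the causal locus and stays near 0.5 elsewhere;
2. **verified** by the **co-segregation standard** — the two homozygous
   flanking-marker classes (AA vs BB) must have distinguishable phenotypes
   (Welch test at α = 10⁻³ plus a bound on midpoint misclassification),
   heterozygotes disregarded — and classified into one of 12 single-locus
   genetic models (complete-dominant / semi-dominant / over-dominant ×
   allele orientation × discrete or overlapping boundaries, with expected
   F2 class ratios 3:1, 1:2:1, 1:1:2);
3. **fine-mapped** using recombinants from selfed NIL-like heterozygotes,
   each informative recombinant pinning the locus to one side of its
   breakpoint;
4. **quantified population-wide** by multiple regression of the trait on
   functional-marker genotypes (`Y = g₀ + Σ gᵢ·Markerᵢ + e`), with Johnson
   relative weights per gene and 10-fold cross-validated prediction;
5. **traced through domestication** by grouped allele frequencies
   (wild → landrace → cultivar), windowed nucleotide diversity π, and
   allele-contrast π-ratio sweep valleys.

A forward genetic simulator (Haldane meiosis, Falconer −a/d/+a genotype
effects, Poisson–binomial pooled sequencing) generates every input the
pipeline consumes, so the whole method is testable end to end without any
field data.

## Worked example

```python
import numpy as np, pandas as pd
from gradmap import min_crosses, group_gradient, propose_crosses
from gradmap.io import PhenotypeTable
from gradmap.fixtures import single_locus_architecture, sigma_e_for_pve
from gradmap.simulate import f2_from_inbreds, genotype_calls
from gradmap.bsa import make_bulks, bulk_read_counts, snp_index, smooth_track, call_candidate
from gradmap.coseg import classify_flanks, coseg_test, classify_model

# 1. design: a 30-accession collection spanning 5.6-13.8 mm
rng = np.random.default_rng(0)
means = np.sort(rng.uniform(5.6, 13.8, 30))
tab = PhenotypeTable(pd.DataFrame({"gl": means},
        index=pd.Index([f"ACC{i:02d}" for i in range(30)], name="accession")))
print(min_crosses(means.min(), means.max(), 0.20))   # -> 8
groups, _ = group_gradient(tab)
plans = propose_crosses(groups, tab)                  # 12 groups -> 11 crosses

# 2-3. simulate one F2 gradient population (one QTL, PVE 0.85) and map it
arch = single_locus_architecture(a=1.0, d=0.0, sigma_e=sigma_e_for_pve(1, 0, 0.85))
f2 = f2_from_inbreds(arch, 200, np.random.default_rng(1))
bulks = make_bulks(f2)                                # top/bottom 15% = 30+30
track = snp_index(bulk_read_counts(f2, bulks, 50.0, np.random.default_rng(2)), arch.mmap)
region = call_candidate(smooth_track(track))[0]
print(region.chrom, region.start_bp, region.end_bp)   # chr3 1 3200000

# 4. verify by the co-segregation standard at the flanking markers
fl = classify_flanks(genotype_calls(f2), "M10", "M12")
res = coseg_test(fl, f2.phenotype_table().means())
model, diag = classify_model(fl, f2.phenotype_table().means())
print(res.status, res.overlap, round(res.pve_f2gp, 3))
# -> verified 0.0 0.882
print(model)                                          # semi-dominant/high/partially-overlapping
```

The candidate region (the padded 3.2 Mb window around the peak
|Δ SNP-index|) contains the true locus at chr3:1,000,001; the verification
separates the homozygous classes perfectly (overlap 0.0) and estimates the
locus explains 88% of this F2's variance, close to the simulated 85%.

The same pipeline is scriptable from the shell (`gradmap design`,
`simulate`, `bsa`, `coseg`, `finemap`, `effects`, `popgen`, `fixtures`);
`gradmap fixtures --seed 1 --out fx/` writes a complete synthetic input
suite, byte-identical for identical seeds.

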