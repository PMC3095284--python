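# corekit

Genetic-distance based core-collection sampling and evaluation for
codominant marker data.

## The problem

Germplasm banks hold thousands of accessions; breeders use few. A *core
collection* is a small subset chosen to represent the genetic diversity of a
larger collection with minimal redundancy — the usual bar being retention of
at least 80% of the collection's distinct alleles in roughly 10–20% of its
size. For a *thematic* collection (accessions pre-filtered for variability in
one target trait, e.g. drought tolerance in upland rice), corekit implements
and evaluates a sampling strategy driven purely by pairwise genetic
distances, alongside the baselines it must be compared with.

## The method

For two diploid accessions genotyped at *L* codominant loci (SSRs), the
proportion of shared alleles is

    Ps = Σ_l s_l / (2 L′)

where `s_l ∈ {0, 1, 2}` counts the allele copies the two accessions share at
locus *l* (sum over alleles of the minimum copy count) and `L′` is the number
of loci typed in both. The shared-allele distance is `Dsa = 1 − Ps` (a
`−ln Ps` transform is also provided; both rank pairs identically). Two
accessions sharing 6 of 10 allele copies over 5 loci sit at distance
`1 − 6/10 = 0.4`.

The distance-maximizing sampler ranks all `n(n−1)/2` pairs by distance,
descending, and walks the list adding both members of each pair until a
nominal size *k* is reached. Ties between equal distances — frequent, since
`Dsa` takes at most `2L+1` values — are shuffled independently in each of
(at least) 100 repetitions; accessions present in *every* repetition form
the **stable set** (100% inclusion). Sweeping *k* and plotting the stable
set's *allele richness* (`100 × alleles retained / total alleles`) gives a
retention curve from which the smallest size clearing the 80% threshold is
chosen.

The evaluation harness supplies everything needed to judge the result:

* diversity statistics — observed heterozygosity `Ho`, gene diversity
  `GD = (2n/(2n−1))(1 − Σ p_i²)`, `PIC`, the inbreeding coefficient
  `f = 1 − H̄o/H̄e`, and Weir–Cockerham `F_IS/F_ST/F_IT`;
* multiallelic linkage disequilibrium (`D′`, `r²`) from EM-estimated
  two-locus haplotype frequencies, with permutation significance and the
  three-class (p < 0.0001 / 0.01 > p > 0.0001 / p ≥ 0.01) map;
* competitor samplers — uniform random cores and a greedy M-strategy allele
  maximizer (fixed-size and full-coverage "cover" modes);
* comparison reports — retained/lost alleles with frequency × group-
  exclusivity classification, accession overlap between methods, paired
  t / Wilcoxon signed-rank tests on per-locus GD, Bartlett's variance test
  on replicated phenotypes;
* a synthetic-data generator (Balding–Nichols divergence, partial selfing,
  SSR-like allele-frequency spectra) so the whole pipeline is testable
  without any external dataset.

## Worked example

`examples/03_retention_curve.py` simulates a 500-accession, 16-locus
collection (two groups, divergence F = 0.15, selfing rate 0.98), computes
all 124,750 pairwise distances and sweeps core sizes 25–300:

```
 size  stable_size  retained_alleles retention_pct mean_GD
   25            0                 0           0.0     NaN
  100            2                30          12.9   0.583
  150           17               110          47.4   0.803
  200           83               173          74.6   0.783
  225          210               204          87.9   0.745
  300          260               209          90.1   0.740

smallest size retaining >= 80%: k = 225 (stable set 210 accessions,
87.9% of alleles) = 42.0% of the collection
```

Reading it: small nominal sizes have empty stable sets (tie shuffling makes
every repetition differ); once the high-distance tie blocks are exhausted
the stable set grows in jumps, and the chosen core retains 87.9% of the 220
alleles. The core's mean gene diversity (0.75 at mid sizes) exceeds the full
collection's (0.68): selecting mutually distant accessions enriches
diversity, which is the point of the method. The other examples cover
simulation and F-statistics (01), a single extraction (02), the four-way
strategy comparison (04) and the LD contrast between a structured
collection and its core (05).

A thin CLI mirrors the library:

```bash
corekit simulate --n-accessions 200 --seed 1 --out-dir sim/
corekit distance --genotypes sim/genotypes.csv --out d.csv
corekit curve --genotypes sim/genotypes.csv --sizes 25:150:25 --threshold 80 --reps 100 --seed 2 --out curve.csv
corekit extract --genotypes sim/genotypes.csv --method corex --size 60 --reps 100 --seed 3 --out-prefix core
```

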