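# Methods

This note records the models, estimators and design choices behind
corekit, the defaults that matter, and what the synthetic benchmarks do
and do not establish.

## Shared-allele distance

For accessions *i*, *j* and locus *l*, let `c_{ia}` be the number of copies
(0, 1 or 2) of allele *a* carried by *i*. The shared-copy count is
`s_l = Σ_a min(c_{ia}, c_{ja})`, which handles heterozygote/homozygote
combinations correctly (a 1/2 vs 2/2 pair shares one copy). With `L′` the
number of loci typed in both accessions,

    Ps = Σ_l s_l / (2 L′),   Dsa = 1 − Ps   or   −ln Ps.

**Missing data** are handled by per-locus pairwise deletion: a locus missing
in either accession contributes to neither numerator nor denominator. This
keeps Ps unbiased under incomplete typing at the cost of pair-to-pair
denominator differences; a pair with no commonly typed locus is an error.

**The −ln transform at Ps = 0** is capped at `−ln ε` with `ε = 1/(4 L n)`
(configurable): fully disjoint pairs stay "maximally distant" yet finite.
Both transforms are strictly decreasing in Ps, so every ranking-based
procedure downstream is transform-invariant (tested); `1 − Ps` is the
default because its values are directly interpretable as a fraction of
unshared copies.

The all-pairs computation is vectorized through the identity
`Σ_a min(c_i, c_j) = (T_i + T_j − ‖c_i − c_j‖₁)/2` on per-allele copy-count
vectors (`T` = total copies at typed loci), with the Manhattan term
delegated to `scipy.spatial.distance.pdist`. 124,750 pairs at n = 500 take
well under a second.

## Maximum-distance core extraction

All unordered pairs are sorted by distance, descending. The ranked list is
walked; both members of each pair are added until exactly *k* accessions
are accumulated. When a full pair would overshoot, one member is chosen
uniformly at random. Because SSR-based distances take at most `2L + 1`
distinct values, ties are massive; they are shuffled independently per
repetition (default 100 repetitions), giving per-accession inclusion
frequencies. The **stable set** — accessions at 100% inclusion — is the
reported core for any repeated run; single-repetition runs report that
repetition. The repetition machinery is what makes the stochastic
tie-breaks interpretable: an accession in the stable set is there because
of its distances, not because of a lucky shuffle.

A consequence worth knowing: the stable set's size is governed by how many
tie blocks the walk fully consumes, so it grows in jumps as *k* increases
and can sit far below *k*. Retention curves built on stable sets (below)
therefore rise in steps, and with an unlucky frequency spectrum a sweep
capped at some maximum size can top out below a retention threshold — the
size-selection routine then raises an explicit "increase size range" error
rather than guessing.

## Competing samplers

* **Random baseline** — independent uniform k-subsets without replacement;
  its reported core is the first repetition, and its mean retention/GD over
  repetitions is what a deliberate method must beat.
* **Greedy M-strategy** — maximizes allelic representation: repeatedly add
  the accession contributing the most not-yet-represented alleles.
  *Cover mode* stops when every allele of the collection is represented
  (ties broken toward higher added gene diversity, then randomly);
  *fixed-size mode* stops at *k* with random tie-breaks over several
  repetitions, reporting the repetition with the most alleles (then highest
  GD). This is a generic greedy set-cover heuristic; no bit-compatibility
  with any specific M-strategy program is claimed, and on tiny instances it
  is checked against exhaustive enumeration instead.

## Size selection

`retention_curve` runs a sampler over a size sweep (classically 25–300 in
steps of 25 for a ~500-accession collection), computes each size's stable
set, and records its allele richness (`100 × retained/total`) and mean
unbiased gene diversity — both computed from the stable set's own allele
frequencies and its own n. `choose_core_size` picks the smallest evaluated
size whose stable set retains at least the threshold (default 80%).

## Diversity statistics

With allele frequencies `p_i` from `n` typed accessions at a locus:

* raw gene diversity `1 − Σ p_i²`; unbiased variant multiplied by
  `2n/(2n − 1)`. The correction inflates — the standard small-sample form.
  (A literal reading of "divide by the factor 2n/(2n−1)" would deflate;
  the sources that define the estimator inflate, so corekit does.)
* `PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²` (Botstein convention).
* `Ho` = fraction of typed accessions with two distinct copies.
* Inbreeding `f = 1 − H̄o/H̄e`, a ratio of across-locus means (more stable
  than a mean of per-locus ratios), with `H̄e` the mean unbiased GD; `f` is
  undefined (error) when every locus is monomorphic.
* `F_IS/F_ST/F_IT` by Weir–Cockerham variance components (a, b, c) summed
  over alleles and loci before forming ratios, so
  `(1 − F_IT) = (1 − F_IS)(1 − F_ST)` holds exactly; per-group-pair F_ST
  restricts the components to the two groups. Loci where a group is
  entirely untyped, or fewer than two groups remain, are skipped.
* Allele classification: rare `f < 0.05`, intermediate `0.05 ≤ f < 0.30`,
  common `f ≥ 0.30` (boundary values go to the higher class; the
  conventional statement uses open intervals and leaves boundaries
  unassigned). An allele is *exclusive* when all its carriers belong to
  one a-priori group.

Across-locus means are unweighted arithmetic means throughout.

## Linkage disequilibrium

Genotypes are unphased, so two-locus haplotype frequencies are fitted by
EM over collapsed genotype classes; only double heterozygotes are
phase-ambiguous, and the no-ambiguity case short-circuits to direct
counting. Convergence: max frequency change < 1e-10 or 1000 iterations;
the log-likelihood is non-decreasing (asserted in tests). From fitted
frequencies `h_ij` with marginals `p_i`, `q_j` and `D_ij = h_ij − p_i q_j`:

    D′ = Σ_ij p_i q_j |D_ij| / Dmax_ij,
    r² = Σ_ij p_i q_j D_ij² / (p_i(1−p_i) q_j(1−q_j)),

frequency-weighted multiallelic forms that reduce to the classic biallelic
definitions. Significance comes from permuting one locus's genotype column
(destroying between-locus association while preserving both single-locus
distributions), `p = (1 + #{r²_perm ≥ r²_obs})/(1 + B)`. The default is
B = 999 shuffles — enough to resolve the 0.01 class boundary while keeping
a 120-pair map affordable; sparse multiallelic tables are why a chi-square
is only offered as a fast alternative, not the default. Per-permutation
EM fits are made cheap by precomputing genotype-category cross-tables and
running the EM in a numba-compiled kernel (a pure-numpy fallback exists).
Pairs monomorphic within the analyzed subset are flagged undefined and
excluded from the significant fraction, not raised.

LD on a core is computed from the core's own genotypes only — that is
precisely how sampling changes the significance map: structure-driven
associations weaken and the smaller n lowers power.

## Synthetic data generator

The generator emulates a large, highly autogamous SSR-genotyped collection
with two a-priori subgroups. Per locus:

1. a pool of ~34 alleles (Normal(34, 3), clipped) gets base frequencies
   shaped like real SSR spectra — 2–4 common alleles (sorted Dirichlet(1)
   weights scaled to 1 − t) plus a near-uniform rare tail of total mass
   `t ~ U(0.20, 0.32)`, i.e. individual rare alleles at roughly 0.005–0.015;
2. group frequencies are Balding–Nichols draws,
   Dirichlet(`p (1 − F)/F`), whose parameter F equals the expected F_ST
   (the closed-form recovery target), default F = 0.15;
3. with probability 0.4 per locus per group, one extra group-private
   allele is injected at a frequency below 0.05, guaranteeing true
   rare-and-exclusive alleles for the classification machinery;
4. individuals are drawn with the partial-selfing equilibrium inbreeding
   `f_eq = s/(2 − s)` (default s = 0.98, so f_eq ≈ 0.961): each locus is
   homozygous-by-descent with probability f_eq, else two independent
   draws. Loci are realized independently — adequate for unlinked markers,
   but it means no genome-wide identity disequilibrium;
5. cells are masked missing at a configurable rate (default 0).

Under the defaults a draw yields ~500 accessions × 16 loci with ≈190–240
distinct alleles, mean GD ≈ 0.58–0.70, F_IS ≈ 0.96 and F_ST ≈ 0.15 — the
regime of a tropical-japonica-like thematic collection. The common/rare
mixture is essential: a flat Dirichlet cannot produce both a high allele
count and GD ≈ 0.67, and it floods the distance distribution with fully
disjoint pairs, which degenerates the stable-set analysis.

Phenotypes (e.g. 100-grain weight in grams) are simulated as accession
means drawn per group (defaults: mean 2.89, SD 0.57) plus replicate noise
(SD 0.125, three replicates), enough to exercise Bartlett's test and the
report tables.

**What passing tests on these data do not show:** the generator has no
mutation model, no linkage, no genome-wide inbreeding correlation, no
admixed individuals, and its groups are clean labels rather than inferred
clusters. Conclusions about estimator correctness and about the *relative*
behavior of samplers transfer to real SSR data; absolute retention
percentages and LD fractions do not.

## Statistical comparisons

Per-locus gene-diversity vectors of two collections are compared with a
paired two-sided Student's t and a Wilcoxon signed-rank test (exact for
≤ 25 loci, normal approximation above; identical vectors are reported as
p = 1 with a degeneracy flag since both statistics are undefined).
Variance homogeneity of replicated phenotypes uses Bartlett's chi-square
(k − 1 degrees of freedom); a zero-variance group is an error. All three
delegate to scipy.stats. Cross-method overlap percentages use the distinct
union of all selected accessions as the denominator; report rounding is
retention 1 d.p., size share 2 d.p., GD 3 d.p.

## Numerical and scale choices

* All stochastic operations take explicit seeds; per-repetition (and
  per-size, per-pair) streams are spawned from the master seed by index,
  so results are order-independent and identical runs are byte-identical.
* Property tests run at small n (≤ 10) against loop-based oracles;
  simulation-based checks use 500 × 16 collections, 100-repetition sweeps,
  and 1000-trial permutation-validity experiments — sizes chosen so the
  whole suite completes in a few minutes on one core while keeping
  binomial bands meaningful.
* The 16-locus Weir–Cockerham F_ST estimate carries ≈ 0.035 locus-sampling
  SD, so generator-recovery assertions bound the across-seed mean at
  ±0.05 and individual seeds only loosely.

## Known limitations

* The ranked-pair walk reconstructs an unpublished selection heuristic
  from its described behavior; tie-handling details of the original are
  unknowable, which is exactly why the stable-set analysis (invariant to
  tie order) is the reported object.
* Stable-set retention curves are step-like; with some frequency spectra
  the 80% threshold is not reachable within a capped size sweep and the
  range must be extended.
* No rarefaction-based allelic richness, no bootstrap CIs on
  F-statistics, no position-aware LD decay, and read-only support for the
  two-column population-genetics text format.
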