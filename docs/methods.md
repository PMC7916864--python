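# Methods

This note records the statistical models implemented in popgenkit, the
defaults and why they were chosen, what the simulators do and do not
emulate, and the numerical conventions that matter when interpreting
results.

## Variant filtering

Sites are retained when minor allele frequency (MAF) is strictly greater
than `min_maf` (default 0.05), the missing-call fraction strictly less than
`max_missing` (default 0.1), and site QUAL strictly greater than `min_qual`
(default 30 phred). MAF and missingness are computed jointly over all
samples: filtering happens once on the combined cohort, and per-group MAF
reported by the diversity module is descriptive recomputation, not a second
filter. Genotype-level qualities (GQ) are not used. Coordinates are
1-based and inclusive, distances in base pairs.

## Inbreeding coefficients

**F_HOM** is the method-of-moments excess-homozygosity form
F = (O_hom − E_hom)/(m − E_hom) over a sample's m non-missing variants,
with E_hom = Σ_j [1 − 2 p_j (1 − p_j) · 2N_j/(2N_j − 1)]. The
2N/(2N − 1) factor is the standard small-sample correction to the expected
heterozygosity; with it, Hardy–Weinberg data give F ≈ 0 in expectation, and
populations with heterozygote excess (common in managed, partly admixed
herds) give F < 0. Reference frequencies p_j default to the full pooled
sample set; when groups are differentiated this induces a Wahlund-type
positive shift in within-group F_HOM, which is a property of the statistic,
not a bug — a per-group frequency mode is available via the
`freq_samples` argument.

**F_PED** is Wright's coefficient, computed as the kinship of the parents
by the recursive tabular (additive-relationship) method with memoisation;
founders and individuals with an unknown parent contribute zero kinship
through that slot. Cycles are detected and rejected. The test suite checks
the recursion against an independent path-counting implementation
(Σ (1/2)^(n₁+n₂+1)(1+F_A) over common ancestors and non-intersecting path
pairs).

**F_ROH** divides the summed length of ROH segments at or above a length
threshold by the callable genome length L. L defaults to the total span of
the analysed scaffolds (first to last observed SNP position), since scaffold
lengths are not generally carried by a VCF; pass the assembly's callable
length when it is known. F_ROH is non-increasing in the threshold by
construction.

## ROH detection

A window of `min_window_snps` consecutive SNPs (default 20) slides one SNP
at a time; a window is homozygous when its heterozygote count is at most
floor(error_rate × window) — zero with the defaults (error rate 0.01),
so a single heterozygote breaks a run. Missing calls are non-informative:
they neither count as heterozygous nor interrupt a run (missingness is
already capped at 10% by filtering). Maximal unions of overlapping
homozygous windows become segments whose coordinates span the first to the
last SNP of the union; runs shorter than the window in SNPs are never
reported. Segment ends are therefore localized only to the nearest flanking
heterozygote: with SNP spacing s and background heterozygosity h the
expected overshoot is about s·(1−h)/h per side. Boundaries are the
outermost SNP positions rather than inter-SNP midpoints — simpler and
conservative. Detection depends on genotypes only through heterozygosity,
so it is invariant to ref/alt relabeling.

## Differentiation

**Nei's standard distance** uses ratio-of-averages normalized identity:
J_A, J_B and J_AB are averaged over loci before forming
I = J_AB/√(J_A·J_B) and D = −ln I. Loci monomorphic in both groups
legitimately contribute identity 1; completely disjoint allele pools give
I = 0, reported as infinite distance.

**Weir–Cockerham θ** uses the standard two-level variance components
(a: among populations, b: among individuals within populations, c: within
individuals) computed from per-group sample sizes, allele frequencies and
observed heterozygote fractions, combined across loci as Σa/Σ(a+b+c)
(ratio of sums, the recommended multi-locus form — more stable than
averaging per-locus ratios). Loci monomorphic across the compared groups
are excluded; they contribute zero to both sums. θ can be slightly
negative for undifferentiated groups.

**AMOVA** decomposes a matrix of squared inter-individual distances into
among-supergroup, among-group-within-supergroup and within-group sums of
squares, then equates mean squares to their expectations with the standard
unequal-sample-size coefficients to obtain variance components. The
pipeline feeds the mean squared dosage difference over shared non-missing
loci; any squared-distance matrix may be supplied instead. Negative
components are reported raw and truncated to zero for the percentage
breakdown (the usual convention). Significance is by permutation — whole
groups across supergroups for the top level, samples across groups within
supergroups for the middle level — with the (count+1)/(n+1) correction and
999 permutations by default. A design with a single supergroup reports the
top stratum as undefined; the among-group level is then the top of the
hierarchy.

## Composite LD and Ne

With unphased genotypes the gametic disequilibrium D is estimated by the
Burrows composite estimator,

    D̂ = [N/(N−1)] · ( ΣXY/(2N) − 2 p̂_A p̂_B ),

equivalently the sample covariance of the two dosage vectors divided by
two. It sums the gametic and non-gametic components of disequilibrium and
is unbiased for gametic D under random mating. r² = D̂²/(p̂_A p̂_a p̂_B p̂_b)
is then corrected for sample size, r²_corr = (r² − 1/n)/(1 − 1/n) with
n = 2N sampled haplotypes, and clamped to [0, 1]: the correction can
produce small negatives at low true LD, and negative mass would bias the
Sved inversion upward. One known property worth stating plainly: on tables
without double heterozygotes (phase effectively known), the composite
estimator equals 2N/(N−1) times the haplotype-count D̂ exactly — the
non-gametic joint distribution then coincides with the gametic one — so
composite r² intentionally does not reduce to haplotype r² on such tables;
the unit tests pin down this exact algebraic relation.

Pairs are restricted to one scaffold. Decay curves assign pairs to
half-open distance bins [k·bin, (k+1)·bin); the three conventional distance
sets are ≤100 kb / 10 kb bins, ≤1 Mb / 100 kb bins and ≤10 Mb / 1 Mb bins.
A bin's representative distance is the median of its realized pair
distances (midpoint when empty). Before pair formation, SNPs are
subsampled without replacement (default 100,000, seeded) from scaffolds
whose observed span reaches `min_scaffold_length` (default 10 Mb), keeping
the pair count tractable and the recombination-distance mapping meaningful
on short contigs.

Ne uses Sved's drift expectation E[r²] = 1/(1 + 4·Ne·c), inverted as
Ne = (1/r̄² − 1)/(4c). No additional 1/n term enters the expectation
because the sample-size correction has already been applied to r². Each
requested date t generations ago targets c = 1/(2t) Morgans, converted to
base pairs at the configured recombination rate (default 1 cM/Mb, i.e.
1e-8 Morgans/bp); the bin whose median distance is nearest the target is
used, and its own median distance supplies the c in the inversion. Targets
with no bin within a factor of two are omitted with a warning — at 1 cM/Mb
the t = 5 point needs 10 Mb pairs, which only long scaffolds provide.
Marker-density recommendations are floor(genome size / decay distance),
where the decay distance is the upper edge of the last bin whose mean r²
still meets the threshold (0.2 for genomic selection, 0.3 for GWAS).

## Simulators: what they emulate, and what they do not

**Structured populations.** K ancestral populations at target Fst values
under the Balding–Nichols model: population frequency
~ Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency p drawn
uniformly from the MAF range (default 0.1–0.5, so post-filter loss is
small), with a random choice of which allele is ancestral-minor.
Individuals are binomial draws at q·p_k with per-group admixture vectors q.
Pairwise Weir–Cockerham θ between two independently drawn populations with
parameters F₁ and F₂ recovers (F₁+F₂)/2. Loci are unlinked — genotypes are
independent across loci even though nominal positions are assigned — so
this generator supports frequency-based statistics (Fst, Nei, AMOVA, F_HOM)
but not LD.

**Wright–Fisher.** A forward diploid population of constant size Ne on one
chromosome: each offspring haplotype recombines the two haplotypes of a
random parent with a Poisson(length × rate) crossover count, gametes unite
at random (selfing allowed), and the final sample is drawn without
replacement. Initial haplotypes carry independent loci at frequencies
uniform on (0.1, 0.9), chosen so a workable fraction of loci is still
segregating after a couple of hundred generations of drift. There is no
mutation, so LD at a given scale needs roughly 1/(2c) generations to
equilibrate and very recent dates are estimated from long-distance bins
only. This is the ground truth for LD decay and Ne recovery.

**Planted ROH.** Chosen tracts are forced homozygous: heterozygous and
missing calls become the homozygote of the per-variant major allele;
already-homozygous calls are untouched, keeping site frequencies close to
the original. An optional error rate flips in-tract SNPs back to
heterozygous, emulating genotyping error inside true autozygous runs. The
detection-accuracy fixtures use a strongly heterozygous background so that
the flanking-heterozygote localization error stays below the evaluation
resolution; with realistic heterozygosity the same detector is accurate to
one or two SNP spacings per side.

**Pedigrees.** Designed full-sib, half-sib and parent–offspring matings
carry textbook coefficients (1/4, 1/8, 1/4); `gene_drop` pushes unlinked
Mendelian genotypes through any pedigree to connect F_PED with genomic
homozygosity.

Passing tests on these generators demonstrates estimator correctness under
the stated models; they do not capture real-data complications such as
genotype-calling error correlated with depth, reference bias, assembly
fragmentation beyond what scaffold spans encode, or selection.

## Problem sizes and determinism

The recovery experiments run at deliberately moderate sizes chosen as the
package's own defaults: Fst recovery uses 2 × 50 samples × 20,000 unlinked
loci over 10 seeds; AMOVA null calibration 200 replicates × 199
permutations of 30 samples × 200 loci; Ne recovery 10 Wright–Fisher seeds
(Ne = 100, 10 Mb, 3,000 start loci, 200 generations, 50 sampled diploids);
ROH recovery two 35 Mb scaffolds at 10 kb spacing with six tracts of
0.5–3 Mb. All randomness flows through `numpy.random.default_rng` with
explicit seeds; identical seeds give byte-identical pipeline outputs (the
table header records the package version and a hash of all analysis
parameters, excluding the output path).

## Known limitations

- Scaffold length is approximated by the last observed SNP position where
  the assembly is not consulted; F_ROH denominators and the ≥10 Mb scaffold
  rule inherit this approximation.
- The composite r² clamp at zero makes very-low-LD bin means slightly
  upward biased, which in turn makes extremely large Ne (weak drift signal)
  under-estimated; at the Ne and distances of interest here the effect is
  negligible against sampling noise.
- The AMOVA top level has S − 1 degrees of freedom; with two supergroups
  its permutation test has little power and its component estimate is
  noisy, as the single-degree-of-freedom "among farms" row of any such
  design would be.
- DAPC, k-means cluster selection and ADMIXTURE-style model-based ancestry
  estimation are out of scope; published tools do those well, and this
  package's PCA-free statistics do not depend on them.
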