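# Methods

This note documents the models and procedures implemented in `strainkin`,
the parameters that matter, and the design choices made where the method
left room for choice.

## Genotype model and calling rule

All genotype semantics are diploid: a call is an unordered pair of
nucleotides, `hom` (equal), `het` (distinct) or missing.  Calls are made
per strain against the reference from per-site allele read depths with two
thresholds:

| parameter      | default | meaning |
|----------------|---------|---------|
| `min_coverage` | 10 reads | below this total depth the site is missing |
| `min_var_freq` | 0.30    | minimum read fraction for an allele to enter the genotype |

Both comparisons are **inclusive** (≥); the boundary behaviour is pinned by
tests (e.g. 12 alt reads of 40 total, frequency 0.30, yields a het call;
12 of 41 does not).  When more than two alleles qualify the two
highest-frequency alleles are retained (ties broken lexicographically) and
the site is flagged multi-allelic, because identity-by-state is defined on
diploid genotypes.  Polyploid strains are still called as diploid
genotypes; dosage is handled exclusively by the coverage module.  The
matrix keeps loci that are variant in at least one strain and missing in
fewer than `max_missing = 2` strains.

## Sliding windows

One grid convention serves heterozygosity, IBS and coverage tracks:
window starts at multiples of the step; a trailing window shorter than the
step is merged into the previous one, so chromosome ends never produce
spuriously small windows.  Defaults are 10 kb / 5 kb for heterozygosity
and coverage and 50 kb / 25 kb for IBS; the coarser 50 kb / 25 kb grid is
also the plotting preset for genome-overview heterozygosity figures.

## Homozygosity and LOH

A strain is classed homozygous when the 0.75 quantile of its per-window
heterozygous-SNP counts equals zero.  The quantile uses **lower-value
interpolation** so the rule is well defined on integer counts (a track
with exactly 75% zero-het windows classifies as homozygous).  The
deliberately forgiving quantile absorbs sporadic false-positive het
calls.  Windows with no SNP calls at all carry no information and are
excluded; an all-empty track is an error.

LOH segments are maximal runs of at least `min_run_windows = 4`
consecutive zero-het windows (≈ 25 kb at the default grid) within a
non-homozygous strain, never crossing chromosome boundaries, reported
with the mean het percentage of up to two flanking windows per side.  The
run length default is a pragmatic floor — short enough to catch focal
events, long enough that a single SNP-free window does not qualify — and
is exposed as a flag.  For a globally homozygous strain LOH is undefined
and an empty list is returned with a warning.

## IBS, equivalence and grouping

The per-locus IBS state is the multiset intersection of the two diploid
genotypes (2 shared alleles → IBS2, 1 → IBS1, 0 → IBS0; AT:AT is IBS2,
AC:AT is IBS1).  Windowed percentages are computed over compared
(non-missing in both strains) sites; windows with fewer than 20 compared
sites (configurable) are marked no-data and excluded from state summaries
so that near-empty windows cannot dictate a state.

Equivalence uses ratios with the IBS2 count as denominator:
`IBS0:IBS2 ≤ 0.05%` and `IBS1:IBS2 ≤ 1%`.  Groups are **connected
components** of the equivalence graph, not cliques: components are
order-independent and reproducible, whereas clique closure depends on
enumeration order near the threshold.  Chains in which two members pass
only via an intermediate are surfaced by per-group maximum-internal-ratio
diagnostics rather than split.  Grouping can be run over any strain
subset (e.g. excluding a large near-clonal clade); the choice of subset
is the caller's.

## Coverage, hybrids and the pan-genome

Depth tracks are re-windowed by overlap-weighted means, masked where the
estimated read count (mean depth × window / 100 bp read length) is below
`min_reads = 10`, and normalized to the mean of qualifying
**focal-species chromosome** windows.  Restricting the normalization
constant to focal chromosomes (accessory loci and donor genomes excluded)
prevents a large second genome or strain-variable accessory content from
deflating the focal dosage scale.  All downstream calls are invariant
under uniform depth rescaling.

A window counts as *covered* at normalized depth ≥ `presence_depth =
0.125`.  The smallest dosage of interest is a single chromosome copy in a
tetraploid background, which sits at normalized depth 0.25 exactly; a
threshold placed *at* that dosage would straddle the signal under any
symmetric depth noise and cover only half of such a chromosome's windows.
The default therefore sits midway between the zero noise floor and that
dosage, recovering the single-copy chromosome at breadth ≈ 1 while still
rejecting low-level cross-mapping background.

A donor species is called when the covered fraction of at least one of
its chromosomes **exceeds** 10% (strict, an extent-of-chromosome rule
over breadth rather than mean depth); all donor chromosomes > 90% covered
marks a near-complete second genome; a donor whose genome-wide covered
fraction stays below 25% is flagged *minor* (the third-species signature
of some lager and fortified-wine hybrids) rather than suppressed.
Copy-number output stays per-window and relative; no genome-wide integer
ploidy is inferred.

Accessory loci are scored present at coverage breadth ≥ 0.5 (inclusive);
the biological loci are represented as named intervals, not sequences.

## Consensus, core columns and trees

Consensus sequences patch a reference with hom-alt bases and two-allele
IUPAC codes, masking sub-coverage positions (and missing calls) as N.
The core alignment keeps columns with no N in any strain; a
`variant_only` flag additionally drops monomorphic columns for users who
want a SNP matrix.  Pairwise distance treats every symbol as a diploid
genotype and scores `1 − shared_alleles/2` per column, so a base matching
one allele of an ambiguity code counts half a difference.  Neighbor
joining (scikit-bio) runs on ids sorted lexicographically, making the
tree invariant to input order; it is a deterministic surrogate used for
topology checks, not a substitute for model-based phylogenetics.

## The simulator: what it does and does not emulate

Genotypes are simulated at SNP sites only, over a shared site registry
placed by a per-chromosome Poisson process.  Defaults (chosen once as the
study conditions): SNP density 0.005/bp, founder heterozygosity rate
0.30, homozygous-alt rate 0.30, one crossover per chromosome per meiosis
(Poisson), clone divergence 0–29 planted mutations, sequencing depth 50×
with window-level multiplicative Gamma noise of CV 0.15 and site-level
Poisson/Binomial read sampling.  Depth 50× reflects typical small-genome
Illumina resequencing; the clone-divergence bound matches the scale of
called differences between commercial re-isolates of one strain.

Deliberately **not** emulated: base-calling errors (false heterozygous
calls arise in real data and motivate the forgiving homozygosity
quantile; here only depth sampling noise exists), mapping ambiguity and
cross-species mismapping, GC bias, structural variation, indels,
selection and drift.  Passing tests therefore demonstrate the
correctness of the statistics and their thresholds under clean pedigree
structure, not robustness to alignment artifacts.  Interspecific donor
content exists only in depth tracks — the focal-species VCF never sees
it — matching the fact that SNP-level analyses are focal-species only.
Emission is a pure function of (pedigree, seed); coordinates are 0-based
half-open internally, converted to 1-based only on VCF write.

## Problem sizes

The test suite and the acceptance script run on deliberately small
panels: 30 strains × ~12,000 sites (4 × 500 kb chromosomes) for
clone-family recovery, 61 strains for parent–progeny signatures, 100
replicates of a 400-kb chromosome for LOH boundary recovery, a 3-species
× 16 × 60-kb panel for hybrid calls, and 2 × 30 kb references for
consensus algebra.  All recovery statements (equivalence precision and
recall 1.0, LOH boundary error ≤ 1 window in ≥ 95% of replicates, exact
hybrid donor-chromosome sets, single-copy dosage within [0.20, 0.30])
are computed by the tests and `scripts/acceptance.py` at run time.

## Known limitations

* Equivalence thresholds assume accurate genotypes; with real base-error
  rates the IBS1:IBS2 ratio of true clone pairs rises toward the 1% band,
  which is why the thresholds were originally calibrated on known
  re-isolate pairs.
* The 10% hybrid rule is interpreted as breadth of coverage; a
  mean-depth reading would differ for highly fragmented contributions.
* Window grids are fixed-span, not recombination- or mappability-aware.
* Connected-component grouping can chain near-threshold pairs into one
  group; inspect the per-group diagnostics when ratios crowd the
  threshold.
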