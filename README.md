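# strainkin

Strain relatedness from reference-aligned yeast genome panels.

Commercial *Saccharomyces cerevisiae* wine and brewing starters are a
genetically narrow, heavily inbred group: many products sold under
different names are re-isolates or trivial derivatives of one progenitor
strain.  `strainkin` implements the comparative-genomic toolkit used to
map that redundancy from short-read resequencing data aligned to a
concatenated multi-species reference:

* **Genotype calling** from per-sample allele depths with a
  frequency/coverage rule (site callable at depth ≥ 10; an allele enters
  the diploid genotype at read frequency ≥ 30%), and a strains × sites
  matrix restricted to loci that are variant in ≥ 1 strain and missing in
  < 2 strains.
* **Windowed heterozygosity and LOH** — per-strain het/hom SNP counts in
  10-kb sliding windows (5-kb step); a strain is *homozygous* ("genome
  renewal" by sporulation and selfing) when the 0.75 quantile of its
  per-window het counts is zero; loss-of-heterozygosity segments are
  maximal runs of ≥ 4 consecutive zero-het windows inside an otherwise
  heterozygous genome.
* **Pairwise identity-by-state (IBS)** — for each pair of strains and each
  locus the shared-allele count: IBS2 (identical genotypes, e.g. AA:AA,
  AT:AT), IBS1 (one shared allele, e.g. AA:AT), IBS0 (none, e.g. AA:TT).
  50-kb windows (25-kb step) are classified as IBS2 (< 5% IBS1, < 1%
  IBS0), IBS2|1 (≥ 5%, < 1%), IBS2|1|0 (≥ 5%, ≥ 1%) or IBS2|0 (< 5%,
  ≥ 1%); parent–progeny pairs show genome-wide IBS2|1 with zero IBS0.
* **Genetic equivalence** — a pair is equivalent when
  IBS0:IBS2 ≤ 0.05% **and** IBS1:IBS2 ≤ 1%; equivalence *groups* are
  connected components of the equivalence graph.
* **Coverage-based calls** — depth in 10-kb/5-kb windows, masked below 10
  reads and normalized to the focal-genome mean, yields per-chromosome
  dosage; an interspecific hybrid is called when > 10% of at least one
  chromosome of another *sensu stricto* species is covered; accessory
  (pan-genome) loci such as the wine-circle, *RTM1*-cluster, *MPR1*,
  *BIO1*/*BIO6* and the aryl-alcohol cluster are scored present by
  coverage breadth ≥ 0.5.
* **Consensus and phylogeny** — per-strain coverage-masked consensus
  sequences (hom-alt → alt base, het → IUPAC code, low coverage → N),
  extraction of the core columns callable in every strain, and a
  deterministic neighbor-joining tree for topology checks.

Because real strain panels are large downloads, the package ships a
**diploid pedigree simulator**: founders, clones with a bounded number of
planted mutations, selfed (fully homozygous) derivatives, F1 crosses,
interspecific hybrids with donor chromosomes at chosen copy numbers, and
strain-variable accessory content — emitted as VCF (with AD/DP), BedGraph
depth tracks and machine-readable truth tables, so every stage is
verifiable against planted truth.

## Worked example

```python
import strainkin as sk

cfg = sk.RunConfig(seed=7)           # 19-strain synthetic demo panel
report = sk.run_pipeline(cfg, "demo_run")
print(open("demo_run/report.md").read())
```

prints

```
# strainkin summary

- strains analyzed: 19
- pairwise comparisons: 171
- strains with an equivalence partner: 11
- equivalence groups: 4
- homozygous strains: 2
- interspecific hybrids: 2

## Equivalence groups

- group 1 (n=4): C1_1, C1_2, C1_3, F01
- group 2 (n=3): C2_1, C2_2, F02
- group 3 (n=2): F05, HYB_FULL
- group 4 (n=2): F06, HYB_ONE_CHROM
...
```

The demo pedigree plants two clone families seeded by founders F01 and
F02, and two hybrids cloned from F05/F06 — exactly the four groups
recovered.  The two homozygous strains are the planted selfed
derivatives, and the two hybrids are the strains carrying donor-species
chromosomes in their depth tracks.  Pairwise detail is in
`demo_run/pairs.tsv`; for the planted clone pair F01/C1_1:

```
strain_a strain_b  n_ibs0  n_ibs1  n_ibs2  ibs0_to_ibs2  ibs1_to_ibs2  equivalent
     F01     C1_1       0      28    6061           0.0       0.00462        True
```

— its 28 planted mutations sit well inside the 1% IBS1:IBS2 equivalence
band, while zero IBS0 rules out a true outcross.

The same stages are exposed on the command line:

```bash
strainkin simulate --out panel/            # VCF + depth tracks + truth
strainkin genotype panel/strains.vcf --out matrix.tsv
strainkin ibs matrix.tsv --out pairs.tsv
strainkin report --out run/                # full pipeline + report.md
```

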