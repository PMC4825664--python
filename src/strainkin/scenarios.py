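"""Canned synthetic study designs with planted truth.

Each builder assembles a :class:`~strainkin.simulate.Population` whose
pedigree plants exactly the structure a downstream stage must recover:
clone families for equivalence grouping, parent–F1 pairs for the IBS2|1
signature, selfed derivatives for genome-renewal classification, zero-het
blocks for LOH detection, and donor-genome configurations for hybrid
calling.  Defaults are the study conditions used by the acceptance checks.
"""

from __future__ import annotations

import numpy as np

from .layout import make_layout
from .simulate import (PedigreeRecord, Population, as_rng, simulate_founders)


def clone_family_population(seed=None,
                            families: tuple[int, ...] = (6, 6, 2),
                            n_strains: int = 30,
                            max_mutations: int = 29,
                            n_chromosomes: int = 4,
                            chrom_length: int = 500_000,
                            snp_density: float = 0.006,
                            het_rate: float = 0.30) -> Population:
    """Population with planted equivalence families among unrelated strains.

    Each family is one founder plus clones carrying 0..``max_mutations``
    single-allele differences.  The remaining strains are unrelated
    founders, selfed derivatives and F1 crosses — none of which must pass
    the equivalence test.  ~12k variant sites at the defaults.
    """
    rng = as_rng(seed)
    n_family = sum(families)
    n_clones = n_family - len(families)
    n_selfed, n_crosses = 3, 3
    n_founders = n_strains - n_clones - n_selfed - n_crosses
    if n_founders < len(families) + 2 * n_crosses:
        raise ValueError("n_strains too small for the requested families")
    layouts = make_layout(n_chromosomes, chrom_length)
    pop = simulate_founders(layouts, n_founders, snp_density, het_rate, rng)
    founders = pop.strains

    for fam, size in enumerate(families):
        seed_strain = founders[fam]
        for k in range(size - 1):
            pop.derive(PedigreeRecord(
                f"C{fam + 1}_{k + 1}", "clone", (seed_strain,),
                n_mutations=int(rng.integers(0, max_mutations + 1))), rng)
    free = founders[len(families):]
    for k in range(n_selfed):
        pop.derive(PedigreeRecord(f"S{k + 1}", "self", (free[k],)), rng)
    for k in range(n_crosses):
        a, b = free[n_selfed + 2 * k], free[n_selfed + 2 * k + 1]
        pop.derive(PedigreeRecord(f"X{k + 1}", "cross", (a, b)), rng)
    return pop


def parent_progeny_population(seed=None, n_pairs: int = 20,
                              n_chromosomes: int = 4,
                              chrom_length: int = 500_000,
                              snp_density: float = 0.005,
                              het_rate: float = 0.30) -> Population:
    """Founder pairs plus one F1 per pair, and one clone pair for contrast.

    The F1s carry no mutations, so IBS0 against either parent is exactly
    zero; the planted clone pair bounds the background IBS2|1 window rate.
    """
    rng = as_rng(seed)
    layouts = make_layout(n_chromosomes, chrom_length)
    pop = simulate_founders(layouts, 2 * n_pairs, snp_density, het_rate, rng)
    founders = pop.strains
    for k in range(n_pairs):
        a, b = founders[2 * k], founders[2 * k + 1]
        pop.derive(PedigreeRecord(f"F1_{k + 1}", "cross", (a, b)), rng)
    pop.derive(PedigreeRecord("CLONE_1", "clone", (founders[0],),
                              n_mutations=29), rng)
    return pop


def loh_population(seed=None,
                   chrom_length: int = 400_000,
                   block_length: int = 50_000,
                   snp_density: float = 0.004,
                   het_rate: float = 0.80) -> tuple[Population,
                                                    tuple[str, int, int]]:
    """One heterozygous founder plus a derivative with a planted LOH block.

    The het-site density at the defaults is ~1.6 per kb, comfortably above
    one per kb, so zero-het windows outside the block are rare.  Returns
    the population and the planted (chrom, start, end) block.
    """
    rng = as_rng(seed)
    layouts = make_layout(1, chrom_length)
    pop = simulate_founders(layouts, 1, snp_density, het_rate, rng,
                            alt_hom_rate=0.0)
    chrom = layouts[0].chromosomes[0].name
    start = int(rng.integers(0, chrom_length - block_length))
    block = (chrom, start, start + block_length)
    pop.derive(PedigreeRecord("LOH_1", "clone", (pop.strains[0],),
                              n_mutations=0, loh_intervals=(block,)), rng)
    return pop, block


def hybrid_trio_population(seed=None,
                           n_chromosomes: int = 16,
                           chrom_length: int = 60_000,
                           n_species: int = 3,
                           n_accessory: int = 5) -> Population:
    """Three hybrid archetypes over a focal + two-donor reference panel.

    * ``HYB_FULL`` — diploid focal genome plus a complete second genome
      (two copies of every donor chromosome), the VIN7/S6U configuration;
    * ``HYB_ONE_CHROM`` — tetraploid focal genome plus a single copy of
      one donor chromosome (chrXIII), the NT50 configuration: donor
      normalized dosage 0.25;
    * ``HYB_THREE_SPECIES`` — diploid focal plus a complete second genome
      plus ~10% of a third species' genome (two chromosomes at one copy).
    """
    rng = as_rng(seed)
    layouts = make_layout(n_chromosomes, chrom_length, n_species=n_species,
                          n_accessory=n_accessory)
    donor1, donor2 = layouts[1].species_id, layouts[2].species_id
    chroms = [c.name for c in layouts[0].chromosomes]
    pop = simulate_founders(layouts, 2, seed=rng)
    base = pop.strains[0]
    pop.derive(PedigreeRecord(
        "HYB_FULL", "interspecific_hybrid", (base,),
        donor_chrom_copies={donor1: {c: 2 for c in chroms}}), rng)
    pop.derive(PedigreeRecord(
        "HYB_ONE_CHROM", "interspecific_hybrid", (base,),
        donor_chrom_copies={donor1: {"chrXIII": 1}}, ploidy=4), rng)
    pop.derive(PedigreeRecord(
        "HYB_THREE_SPECIES", "interspecific_hybrid", (base,),
        donor_chrom_copies={donor1: {c: 2 for c in chroms},
                            donor2: {chroms[0]: 1, chroms[1]: 1}}), rng)
    return pop


def demo_population(seed=None,
                    n_chromosomes: int = 4,
                    chrom_length: int = 300_000,
                    n_species: int = 3,
                    n_accessory: int = 5,
                    snp_density: float = 0.005,
                    het_rate: float = 0.30) -> Population:
    """A small end-to-end panel exercising every pipeline stage.

    Contains two clone families (one of them accessory-variable), selfed
    genome-renewal derivatives, F1 crosses, a VIN7-like and an NT50-like
    hybrid, plus wine-like and brewing-like accessory marker patterns.
    """
    rng = as_rng(seed)
    layouts = make_layout(n_chromosomes, chrom_length, n_species=n_species,
                          n_accessory=n_accessory)
    wine = {"wine_circle": 2, "RTM1_cluster": 0, "MPR1": 2, "BIO1_BIO6": 0,
            "aryl_alcohol": 0}
    brew = {"wine_circle": 0, "RTM1_cluster": 2, "MPR1": 0, "BIO1_BIO6": 0,
            "aryl_alcohol": 0}
    pop = simulate_founders(layouts, 8, snp_density, het_rate, rng)
    founders = pop.strains
    for i, f in enumerate(founders):
        pop.records[f].accessory_content = dict(wine if i < 6 else brew)

    donor1 = layouts[1].species_id
    chroms = [c.name for c in layouts[0].chromosomes]
    for k in range(3):  # family 1: wine-like, one member lost a locus
        acc = dict(wine)
        if k == 2:
            acc["MPR1"] = 0
        pop.derive(PedigreeRecord(
            f"C1_{k + 1}", "clone", (founders[0],),
            n_mutations=int(rng.integers(0, 30)), accessory_content=acc), rng)
    for k in range(2):  # family 2
        pop.derive(PedigreeRecord(
            f"C2_{k + 1}", "clone", (founders[1],),
            n_mutations=int(rng.integers(0, 30))), rng)
    pop.derive(PedigreeRecord("S1", "self", (founders[2],)), rng)
    pop.derive(PedigreeRecord("S2", "self", (founders[3],)), rng)
    pop.derive(PedigreeRecord("X1", "cross", (founders[2], founders[3])), rng)
    pop.derive(PedigreeRecord("X2", "interclade_cross",
                              (founders[5], founders[6])), rng)
    pop.derive(PedigreeRecord(
        "HYB_FULL", "interspecific_hybrid", (founders[4],),
        donor_chrom_copies={donor1: {c: 2 for c in chroms}}), rng)
    pop.derive(PedigreeRecord(
        "HYB_ONE_CHROM", "interspecific_hybrid", (founders[5],),
        donor_chrom_copies={donor1: {chroms[-1]: 1}}, ploidy=4), rng)
    return pop


def demo_clades(pop: Population) -> dict[str, str]:
    """Clade labels for :func:`demo_population` (user metadata downstream)."""
    labels = {}
    for s in pop.strains:
        root = s
        while pop.records[root].parents:
            root = pop.records[root].parents[0]
        idx = int(root[1:]) - 1 if root.startswith("F") else 0
        labels[s] = "wine" if idx < 6 else "brew"
    return labels
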