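"""Diploid pedigree simulator with known truth.

Simulates a population of diploid yeast strains over a multi-species
reference layout so that every downstream stage (genotype calling, IBS,
LOH, hybrid and pan-genome calls) can be verified against planted truth.
Only SNP sites are simulated — each strain is a pair of allele vectors over
a shared site registry — except for consensus export, which patches a
generated random reference.

Supported origins
-----------------
founder
    Independent diploid drawn site-by-site (heterozygous with probability
    ``het_rate``, otherwise homozygous alt with probability ``alt_hom_rate``).
clone
    Copy of the parent plus exactly ``n_mutations`` single-allele changes,
    placed at brand-new sites (mimicking divergence accumulated during
    independent isolation and passaging of one commercial strain).
self
    One meiotic haploid product of the parent (Poisson crossovers), doubled:
    a fully homozygous "genome renewal" derivative.
cross / interclade_cross
    One gamete from each parent; shares at least one allele with each
    parent at every site.
interspecific_hybrid
    Focal genome copied from the *S. cerevisiae* parent; donor chromosomes
    are carried at stated copy numbers and affect only depth emission (the
    focal-species VCF never sees them).

All randomness flows through one :class:`numpy.random.Generator` passed
explicitly; emission is a pure function of (pedigree, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import GenomeLayout, contig_name, contig_table, layouts_to_json

BASES = "ACGT"

ORIGIN_KINDS = ("founder", "clone", "self", "cross", "interclade_cross",
                "interspecific_hybrid")


def as_rng(seed) -> np.random.Generator:
    """Pass a Generator through, or seed a fresh PCG64."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class PedigreeRecord:
    """How one strain arises from the strains before it.

    ``parents`` is empty for founders, one id for clone/self/hybrid, two for
    crosses.  ``donor_chrom_copies`` maps donor species → chromosome name →
    copy number and is only meaningful for interspecific hybrids.
    ``accessory_content`` maps accessory-locus name → copy number; when left
    empty it is inherited from the first parent (founders default to two
    copies of every locus).  ``loh_intervals`` are (chrom, start, end)
    blocks in which the second haplotype is overwritten by the first.
    """

    strain_id: str
    origin: str
    parents: tuple[str, ...] = ()
    n_mutations: int = 0
    donor_chrom_copies: dict[str, dict[str, int]] = field(default_factory=dict)
    accessory_content: dict[str, int] = field(default_factory=dict)
    ploidy: int = 2
    loh_intervals: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.origin not in ORIGIN_KINDS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        n_par = {"founder": 0, "clone": 1, "self": 1,
                 "interspecific_hybrid": 1, "cross": 2,
                 "interclade_cross": 2}[self.origin]
        if len(self.parents) != n_par:
            raise ValueError(f"origin {self.origin!r} needs {n_par} parent(s),"
                             f" got {len(self.parents)}")
        if any(c < 0 for v in self.donor_chrom_copies.values()
               for c in v.values()):
            raise ValueError("donor chromosome copies must be >= 0")
        if any(c < 0 for c in self.accessory_content.values()):
            raise ValueError("accessory copy numbers must be >= 0")


class _Registry:
    """Growing per-chromosome SNP site registry of the focal species."""

    def __init__(self, focal: GenomeLayout):
        self.chroms = [c.name for c in focal.chromosomes]
        self.lengths = {c.name: c.length for c in focal.chromosomes}
        self.positions: dict[str, list[int]] = {c: [] for c in self.chroms}
        self.ref: dict[str, list[int]] = {c: [] for c in self.chroms}
        self.alt: dict[str, list[int]] = {c: [] for c in self.chroms}
        self._used: dict[str, set[int]] = {c: set() for c in self.chroms}

    def n_sites(self, chrom: str) -> int:
        return len(self.positions[chrom])

    @property
    def total_sites(self) -> int:
        return sum(len(v) for v in self.positions.values())

    def add_site(self, chrom: str, pos: int, ref: int, alt: int) -> int:
        if pos in self._used[chrom]:
            raise ValueError(f"site {chrom}:{pos} already exists")
        self._used[chrom].add(pos)
        self.positions[chrom].append(pos)
        self.ref[chrom].append(ref)
        self.alt[chrom].append(alt)
        return len(self.positions[chrom]) - 1

    def has(self, chrom: str, pos: int) -> bool:
        return pos in self._used[chrom]

    def pos_array(self, chrom: str) -> np.ndarray:
        return np.asarray(self.positions[chrom], dtype=np.int64)


class DiploidGenome:
    """Two allele vectors per chromosome, aligned to the registry prefix
    that existed when the genome was created (later sites are implicitly
    homozygous reference)."""

    def __init__(self, haps: dict[str, np.ndarray]):
        self.haps = haps  # chrom -> int8 array of shape (2, k)

    def padded(self, registry: _Registry, chrom: str) -> np.ndarray:
        """Haplotypes padded with the reference allele to registry width."""
        h = self.haps[chrom]
        n = registry.n_sites(chrom)
        if h.shape[1] == n:
            return h
        pad_ref = np.asarray(registry.ref[chrom][h.shape[1]:], dtype=np.int8)
        pad = np.tile(pad_ref, (2, 1))
        return np.concatenate([h, pad], axis=1)

    def copy(self) -> "DiploidGenome":
        return DiploidGenome({c: h.copy() for c, h in self.haps.items()})

    def het_count(self) -> int:
        return int(sum((h[0] != h[1]).sum() for h in self.haps.values()))


@dataclass
class Population:
    """Layouts, the shared site registry and the simulated genomes."""

    layouts: list[GenomeLayout]
    registry: _Registry
    genomes: dict[str, DiploidGenome] = field(default_factory=dict)
    records: dict[str, PedigreeRecord] = field(default_factory=dict)
    order: list[str] = field(default_factory=list)
    crossover_rate: float = 1.0

    @property
    def focal(self) -> GenomeLayout:
        return self.layouts[0]

    @property
    def strains(self) -> list[str]:
        return list(self.order)

    def _add(self, record: PedigreeRecord, genome: DiploidGenome) -> None:
        if record.strain_id in self.records:
            raise ValueError(f"duplicate strain id {record.strain_id!r}")
        self.records[record.strain_id] = record
        self.genomes[record.strain_id] = genome
        self.order.append(record.strain_id)

    def derive(self, record: PedigreeRecord, seed=None) -> DiploidGenome:
        """Derive a strain from existing ones; see :func:`derive_strain`."""
        genome = derive_strain(record, self, seed)
        self._add(record, genome)
        return genome

    def accessory_content(self, strain: str) -> dict[str, int]:
        """Per-locus copy number, inherited along the pedigree when a
        record leaves it unspecified."""
        rec = self.records[strain]
        if rec.accessory_content:
            return dict(rec.accessory_content)
        if rec.parents:
            return self.accessory_content(rec.parents[0])
        return {a.name: 2 for a in self.focal.accessory_loci}

    def donor_content(self, strain: str) -> dict[str, dict[str, int]]:
        return {sp: dict(ch) for sp, ch in
                self.records[strain].donor_chrom_copies.items()}


def simulate_founders(layouts: list[GenomeLayout] | GenomeLayout,
                      n_founders: int,
                      snp_density: float = 0.005,
                      het_rate: float = 0.30,
                      seed=None,
                      *,
                      alt_hom_rate: float = 0.30,
                      ids: list[str] | None = None,
                      crossover_rate: float = 1.0) -> Population:
    """Place SNP sites by a Poisson process and draw unrelated founders.

    Each chromosome receives ``Poisson(snp_density * length)`` variant
    sites at distinct uniform positions.  Each founder is heterozygous
    (ref/alt) at a site with probability ``het_rate``; otherwise it is
    homozygous alt with probability ``alt_hom_rate``, else homozygous ref.
    """
    if isinstance(layouts, GenomeLayout):
        layouts = [layouts]
    if not 0 <= het_rate <= 1:
        raise ValueError("het_rate must be in [0, 1]")
    if not 0 <= snp_density <= 1:
        raise ValueError("snp_density must be in [0, 1]")
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    rng = as_rng(seed)
    registry = _Registry(layouts[0])

    for chrom in registry.chroms:
        length = registry.lengths[chrom]
        n = int(rng.poisson(snp_density * length))
        n = min(n, length)
        if n == 0:
            warnings.warn(f"no variant sites placed on {chrom} "
                          f"(density {snp_density}, length {length})")
            continue
        pos = np.sort(rng.choice(length, size=n, replace=False))
        ref = rng.integers(0, 4, size=n)
        alt = (ref + rng.integers(1, 4, size=n)) % 4
        for p, r, a in zip(pos, ref, alt):
            registry.add_site(chrom, int(p), int(r), int(a))

    pop = Population(layouts, registry, crossover_rate=crossover_rate)
    names = ids or [f"F{i + 1:02d}" for i in range(n_founders)]
    if len(names) != n_founders:
        raise ValueError("ids must match n_founders")
    for name in names:
        haps = {}
        for chrom in registry.chroms:
            n = registry.n_sites(chrom)
            ref = np.asarray(registry.ref[chrom], dtype=np.int8)
            alt = np.asarray(registry.alt[chrom], dtype=np.int8)
            h = np.tile(ref, (2, 1))
            u = rng.random(n)
            het = u < het_rate
            hom_alt = (~het) & (rng.random(n) < alt_hom_rate)
            which = rng.integers(0, 2, size=n)  # which haplotype gets alt
            h[0, het & (which == 0)] = alt[het & (which == 0)]
            h[1, het & (which == 1)] = alt[het & (which == 1)]
            h[:, hom_alt] = alt[hom_alt]
            haps[chrom] = h
        pop._add(PedigreeRecord(name, "founder"), DiploidGenome(haps))
    return pop


def _gamete(genome: DiploidGenome, pop: Population,
            rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One recombinant haploid product (per-chromosome Poisson crossovers)."""
    out = {}
    reg = pop.registry
    for chrom in reg.chroms:
        h = genome.padded(reg, chrom)
        pos = reg.pos_array(chrom)
        k = rng.poisson(pop.crossover_rate)
        start = rng.integers(0, 2)
        if k == 0 or pos.size == 0:
            out[chrom] = h[start].copy()
            continue
        bps = np.sort(rng.integers(1, reg.lengths[chrom], size=k))
        phase = (start + np.searchsorted(bps, pos, side="right")) % 2
        out[chrom] = h[phase, np.arange(pos.size)]
    return out


def apply_loh(genome: DiploidGenome, pop: Population,
              chrom: str, start: int, end: int) -> None:
    """Overwrite haplotype 2 by haplotype 1 inside ``[start, end)``."""
    reg = pop.registry
    h = genome.padded(reg, chrom)
    pos = reg.pos_array(chrom)
    mask = (pos >= start) & (pos < end)
    h = h.copy()
    h[1, mask] = h[0, mask]
    genome.haps[chrom] = h


def derive_strain(record: PedigreeRecord, pop: Population,
                  seed=None) -> DiploidGenome:
    """Materialize one pedigree record into a diploid genome.

    Does not register the genome with the population; use
    :meth:`Population.derive` for that.  Mutates the site registry when a
    clone plants mutations at new sites.
    """
    rng = as_rng(seed)
    reg = pop.registry
    for p in record.parents:
        if p not in pop.genomes:
            raise KeyError(f"parent {p!r} of {record.strain_id!r} not "
                           "simulated yet")

    if record.origin == "founder":
        raise ValueError("founders are created by simulate_founders")

    if record.origin in ("clone", "interspecific_hybrid"):
        parent = pop.genomes[record.parents[0]]
        haps = {c: parent.padded(reg, c).copy() for c in reg.chroms}
        genome = DiploidGenome(haps)
        if record.origin == "interspecific_hybrid":
            donors = {l.species_id: l for l in pop.layouts[1:]}
            for sp, chroms in record.donor_chrom_copies.items():
                if sp not in donors:
                    raise KeyError(f"unknown donor species {sp!r}")
                for ch in chroms:
                    donors[sp].chromosome(ch)  # raises on bad name
        else:
            _plant_mutations(genome, pop, record.n_mutations, rng)
    elif record.origin == "self":
        parent_rec = pop.records[record.parents[0]]
        if parent_rec.ploidy != 2:
            raise ValueError("selfing requires a diploid parent "
                             f"({record.parents[0]} has ploidy "
                             f"{parent_rec.ploidy})")
        g = _gamete(pop.genomes[record.parents[0]], pop, rng)
        genome = DiploidGenome({c: np.stack([v, v.copy()]) for c, v
                                in g.items()})
    elif record.origin in ("cross", "interclade_cross"):
        ga = _gamete(pop.genomes[record.parents[0]], pop, rng)
        gb = _gamete(pop.genomes[record.parents[1]], pop, rng)
        genome = DiploidGenome({c: np.stack([ga[c], gb[c]])
                                for c in reg.chroms})
    else:  # pragma: no cover - guarded by PedigreeRecord validation
        raise ValueError(record.origin)

    for chrom, start, end in record.loh_intervals:
        apply_loh(genome, pop, chrom, start, end)
    return genome


def _plant_mutations(genome: DiploidGenome, pop: Population,
                     n_mutations: int, rng: np.random.Generator) -> None:
    """Plant exactly ``n_mutations`` single-allele changes at new sites."""
    reg = pop.registry
    # pad to current registry width first so appended columns line up
    for chrom in reg.chroms:
        genome.haps[chrom] = genome.padded(reg, chrom).copy()
    lengths = np.array([reg.lengths[c] for c in reg.chroms], dtype=float)
    probs = lengths / lengths.sum()
    new_cols: dict[str, list[tuple[int, int]]] = {c: [] for c in reg.chroms}
    for _ in range(n_mutations):
        chrom = reg.chroms[rng.choice(len(reg.chroms), p=probs)]
        while True:
            p = int(rng.integers(0, reg.lengths[chrom]))
            if not reg.has(chrom, p):
                break
        ref = int(rng.integers(0, 4))
        alt = (ref + int(rng.integers(1, 4))) % 4
        reg.add_site(chrom, p, ref, alt)
        new_cols[chrom].append((ref, alt))
    for chrom, cols in new_cols.items():
        if not cols:
            continue
        add = np.array(cols, dtype=np.int8).T  # (2, m): ref on hap1, alt hap2
        genome.haps[chrom] = np.concatenate([genome.haps[chrom], add], axis=1)


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Planted truth for the acceptance oracle, symmetric over pairs."""

    strains: list[str]
    clone_families: list[set[str]]
    pair_labels: dict[tuple[str, str], str]
    homozygous: dict[str, bool]
    hybrid_composition: dict[str, dict[str, dict[str, int]]]
    accessory_presence: dict[str, dict[str, bool]]
    loh_intervals: dict[str, list[tuple[str, int, int]]]

    def label(self, a: str, b: str) -> str:
        return self.pair_labels[tuple(sorted((a, b)))]

    def expected_equivalent(self, a: str, b: str) -> bool:
        return self.label(a, b) == "clonal"

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, lab) for (a, b), lab in sorted(self.pair_labels.items())]
        return pd.DataFrame(rows, columns=["strain_a", "strain_b", "label"])


def build_truth(pop: Population) -> TruthTable:
    """Derive the truth table from the pedigree (and planted genomes)."""
    import networkx as nx

    strains = pop.strains
    g = nx.Graph()
    g.add_nodes_from(strains)
    parent_edges = set()
    for s in strains:
        rec = pop.records[s]
        if rec.origin in ("clone", "interspecific_hybrid"):
            g.add_edge(s, rec.parents[0])
        elif rec.origin in ("self", "cross", "interclade_cross"):
            for p in rec.parents:
                parent_edges.add(tuple(sorted((s, p))))
    comps = [set(c) for c in nx.connected_components(g)]
    family_of = {s: i for i, c in enumerate(comps) for s in c}

    labels = {}
    for i, a in enumerate(strains):
        for b in strains[i + 1:]:
            key = tuple(sorted((a, b)))
            if family_of[a] == family_of[b]:
                labels[key] = "clonal"
            elif key in parent_edges:
                labels[key] = "parent_progeny"
            else:
                labels[key] = "unrelated"

    return TruthTable(
        strains=strains,
        clone_families=[c for c in comps if len(c) >= 2],
        pair_labels=labels,
        homozygous={s: pop.genomes[s].het_count() == 0 for s in strains},
        hybrid_composition={s: pop.donor_content(s) for s in strains},
        accessory_presence={s: {k: v > 0 for k, v in
                                pop.accessory_content(s).items()}
                            for s in strains},
        loh_intervals={s: list(pop.records[s].loh_intervals)
                       for s in strains},
    )


# ---------------------------------------------------------------------------
# emission: depth tracks and VCF
# ---------------------------------------------------------------------------

def depth_profiles(pop: Population,
                   mean_depth: float = 50.0,
                   depth_noise: float = 0.15,
                   seed=None,
                   bin_size: int = 5_000) -> dict[str, pd.DataFrame]:
    """Per-strain binned depth over every contig of the panel.

    The per-copy depth is ``mean_depth / ploidy``; focal chromosomes carry
    ``ploidy`` copies (so their expected depth is ``mean_depth``), donor
    chromosomes and accessory loci carry their stated copy numbers, and
    absent segments are emitted at depth 0.  ``depth_noise`` is the
    coefficient of variation of multiplicative Gamma noise per bin
    (0 disables noise entirely).
    """
    if mean_depth < 10:
        raise ValueError("mean_depth must be >= 10 so the caller's "
                         "coverage floor is satisfiable")
    rng = as_rng(seed)
    ct = contig_table(pop.layouts)
    out = {}
    for strain in pop.strains:
        rec = pop.records[strain]
        acc = pop.accessory_content(strain)
        donors = pop.donor_content(strain)
        per_copy = mean_depth / rec.ploidy
        rows = []
        for _, r in ct.iterrows():
            if r["kind"] == "accessory":
                copies = acc.get(r["name"], 0)
            elif r["focal"]:
                copies = rec.ploidy
            else:
                copies = donors.get(r["species"], {}).get(r["name"], 0)
            mu = per_copy * copies
            edges = list(range(0, r["length"], bin_size)) + [r["length"]]
            for s, e in zip(edges[:-1], edges[1:]):
                if mu == 0:
                    d = 0.0
                elif depth_noise == 0:
                    d = mu
                else:
                    shape = 1.0 / depth_noise ** 2
                    d = mu * rng.gamma(shape, 1.0 / shape)
                rows.append((r["contig"], s, e, d))
        out[strain] = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                  "depth"])
    return out


def _sorted_sites(pop: Population):
    """Yield (chrom, order) with positions sorted per chromosome."""
    reg = pop.registry
    for chrom in reg.chroms:
        pos = reg.pos_array(chrom)
        order = np.argsort(pos, kind="stable")
        yield chrom, pos, order


def write_vcf(pop: Population, path: str | Path,
              mean_depth: float = 50.0, depth_noise: float = 0.15,
              seed=None) -> Path:
    """Write a VCF 4.2 with GT:DP:AD for every strain at every variant site.

    Sites where no strain carries a non-reference allele are skipped (they
    are not SNPs).  With ``depth_noise == 0`` depths are deterministic
    (DP = round(mean_depth), heterozygous reads split as evenly as
    possible), otherwise DP is Poisson and the alt read count Binomial.
    """
    rng = as_rng(seed)
    reg = pop.registry
    strains = pop.strains
    path = Path(path)
    focal = pop.focal

    padded = {s: {c: pop.genomes[s].padded(reg, c) for c in reg.chroms}
              for s in strains}

    lines = ["##fileformat=VCFv4.2",
             "##source=strainkin-simulator"]
    for c in focal.chromosomes:
        lines.append(f"##contig=<ID={contig_name(focal.species_id, c.name)},"
                     f"length={c.length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allele read depths (ref first)">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(strains))

    dp_fixed = int(round(mean_depth))
    for chrom, pos, order in _sorted_sites(pop):
        ref_arr = np.asarray(reg.ref[chrom])
        contig = contig_name(focal.species_id, chrom)
        for idx in order:
            ref = int(ref_arr[idx])
            genos = [(int(padded[s][chrom][0, idx]),
                      int(padded[s][chrom][1, idx])) for s in strains]
            alts = sorted({a for g in genos for a in g if a != ref})
            if not alts:
                continue
            allele_index = {ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
            fields = [contig, str(int(pos[idx]) + 1), ".", BASES[ref],
                      ",".join(BASES[a] for a in alts), ".", "PASS", ".",
                      "GT:DP:AD"]
            for g in genos:
                i1, i2 = sorted(allele_index[a] for a in g)
                if depth_noise == 0:
                    dp = dp_fixed
                else:
                    dp = int(rng.poisson(mean_depth))
                ad = [0] * (len(alts) + 1)
                if i1 == i2:
                    ad[i1] = dp
                else:
                    n2 = dp // 2 if depth_noise == 0 else int(
                        rng.binomial(dp, 0.5))
                    ad[i2] = n2
                    ad[i1] = dp - n2
                fields.append(f"{i1}/{i2}:{dp}:" + ",".join(map(str, ad)))
            lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass
class Observables:
    vcf: Path
    depth: dict[str, pd.DataFrame]
    truth: TruthTable
    outdir: Path


def emit_observables(pop: Population, outdir: str | Path,
                     mean_depth: float = 50.0,
                     depth_noise: float = 0.15,
                     seed=None,
                     bin_size: int = 5_000) -> Observables:
    """Write VCF + depth tracks + truth tables + layout to ``outdir``."""
    rng = as_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf = write_vcf(pop, outdir / "strains.vcf", mean_depth, depth_noise, rng)
    depth = depth_profiles(pop, mean_depth, depth_noise, rng,
                           bin_size=bin_size)
    ddir = outdir / "depth"
    ddir.mkdir(exist_ok=True)
    for strain, df in depth.items():
        df.to_csv(ddir / f"{strain}.bedgraph", sep="\t", header=False,
                  index=False, float_format="%.4f")
    truth = build_truth(pop)
    truth.to_frame().to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
    per_strain = pd.DataFrame(
        {"strain": truth.strains,
         "homozygous": [truth.homozygous[s] for s in truth.strains],
         "origin": [pop.records[s].origin for s in truth.strains]})
    per_strain.to_csv(outdir / "truth_strains.tsv", sep="\t", index=False)
    layouts_to_json(pop.layouts, outdir / "layout.json")
    return Observables(vcf=vcf, depth=depth, truth=truth, outdir=outdir)
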