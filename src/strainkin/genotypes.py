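"""Frequency/coverage genotype calling and the strains × sites matrix.

The calling rule mirrors a Varscan-style per-strain protocol: a site needs
at least ``min_coverage`` reads to be callable, and an allele needs a read
frequency of at least ``min_var_freq`` (default 30%) to enter the genotype.
One qualifying allele gives a homozygous call, two give a heterozygous
call; both threshold comparisons are inclusive (pinned by tests).

Sites enter the matrix only if a SNP was recorded in at least one strain
and data were missing in fewer than ``max_missing`` strains (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

BASES = "ACGT"
CODE = {b: i for i, b in enumerate(BASES)}
MISSING = np.int8(-1)


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid call: allele pair (lexicographically sorted) or missing."""

    alleles: tuple[str, str] | None
    zygosity: str  # 'hom' | 'het' | 'missing'
    depth: int
    variant_frequency: float
    multi_allelic: bool = False


def call_site(ref_depth: int,
              alt_depths,
              min_coverage: int = 10,
              min_var_freq: float = 0.30,
              alleles: list[str] | None = None) -> GenotypeCall:
    """Call one site of one strain from allele read depths.

    Parameters
    ----------
    ref_depth, alt_depths
        Reads supporting the reference allele and each alternate allele
        (``alt_depths`` may be a single int).
    alleles
        Allele labels, reference first.  Defaults to ``["0", "1", ...]``
        (VCF-style indices) when only zygosity matters.

    Sites with more than two alleles at or above ``min_var_freq`` are kept
    with the two highest-frequency alleles (ties broken lexicographically)
    and flagged ``multi_allelic``.
    """
    if np.isscalar(alt_depths):
        alt_depths = [alt_depths]
    depths = [int(ref_depth)] + [int(d) for d in alt_depths]
    if any(d < 0 for d in depths):
        raise ValueError("read depths must be >= 0")
    labels = alleles if alleles is not None else [str(i) for i
                                                 in range(len(depths))]
    if len(labels) != len(depths):
        raise ValueError("need one allele label per depth")
    total = sum(depths)
    if total < min_coverage:
        return GenotypeCall(None, "missing", total, float("nan"))
    freqs = [d / total for d in depths]
    vf = 1.0 - freqs[0]  # total non-reference read fraction
    qualifying = [(f, l) for f, l in zip(freqs, labels) if f >= min_var_freq]
    if not qualifying:
        # no allele reaches the frequency floor: uncallable
        return GenotypeCall(None, "missing", total, vf)
    multi = len(qualifying) > 2
    top = sorted(qualifying, key=lambda t: (-t[0], t[1]))[:2]
    if len(top) == 1:
        a = top[0][1]
        return GenotypeCall((a, a), "hom", total, vf, multi)
    pair = tuple(sorted(l for _, l in top))
    return GenotypeCall(pair, "het", total, vf, multi)


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for ``strains`` at filtered SNP ``sites``.

    ``geno`` has shape (n_sites, n_strains, 2) with allele codes
    0..3 = A,C,G,T sorted within each cell and -1,-1 for missing.
    ``chrom_lengths`` (contig → bp) carries the coordinate frame for
    windowed analyses.
    """

    strains: list[str]
    sites: pd.DataFrame  # columns: chrom, pos (0-based), ref
    geno: np.ndarray
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if self.geno.shape != (len(self.sites), len(self.strains), 2):
            raise ValueError("genotype grid shape mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise KeyError(f"strain {strain!r} not in matrix") from None

    def chrom_rows(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.sites["chrom"].to_numpy() == chrom)

    def missing_per_site(self) -> np.ndarray:
        return (self.geno[:, :, 0] == MISSING).sum(axis=1)

    def genotype(self, strain: str, row: int) -> tuple[str, str] | None:
        g = self.geno[row, self.strain_index(strain)]
        if g[0] == MISSING:
            return None
        return (BASES[g[0]], BASES[g[1]])

    # -- persistence --------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Site rows, strain columns, genotypes as ``A/T`` (``./.`` missing)."""
        cols = {"chrom": self.sites["chrom"],
                "pos": self.sites["pos"],
                "ref": self.sites["ref"]}
        for j, s in enumerate(self.strains):
            g = self.geno[:, j]
            cols[s] = ["./." if a == MISSING else f"{BASES[a]}/{BASES[b]}"
                       for a, b in g]
        header = "#lengths\t" + ";".join(f"{c}={l}" for c, l
                                         in self.chrom_lengths.items())
        with open(path, "w") as fh:
            fh.write(header + "\n")
            pd.DataFrame(cols).to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            lengths = {}
            if header.startswith("#lengths"):
                spec = header.split("\t", 1)[1] if "\t" in header else ""
                for item in filter(None, spec.split(";")):
                    c, l = item.split("=")
                    lengths[c] = int(l)
            df = pd.read_csv(fh, sep="\t")
        strains = [c for c in df.columns if c not in ("chrom", "pos", "ref")]
        geno = np.full((len(df), len(strains), 2), MISSING, dtype=np.int8)
        for j, s in enumerate(strains):
            for i, val in enumerate(df[s]):
                if val != "./.":
                    a, b = val.split("/")
                    geno[i, j] = sorted((CODE[a], CODE[b]))
        return cls(strains, df[["chrom", "pos", "ref"]].copy(), geno, lengths)


def build_matrix(vcf_path: str | Path,
                 strains: list[str] | None = None,
                 max_missing: int = 2,
                 min_coverage: int = 10,
                 min_var_freq: float = 0.30) -> GenotypeMatrix:
    """Read per-sample allele depths from a VCF and assemble the matrix.

    Genotypes are (re)called from AD, not taken from GT, so the matrix
    reflects the frequency/coverage rule regardless of upstream calls.
    Retained sites are variant in at least one strain and missing in fewer
    than ``max_missing`` of the requested strains; rows are sorted into
    genomic order using the VCF header contig order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if strains is None:
        strains = samples
    else:
        absent = [s for s in strains if s not in samples]
        if absent:
            raise KeyError("strains absent from VCF header: "
                           + ", ".join(absent))
    col = [samples.index(s) for s in strains]
    contig_rank = {c: i for i, c in enumerate(vcf.seqnames)}
    chrom_lengths = dict(zip(vcf.seqnames, vcf.seqlens))

    rows, keys, genos = [], [], []
    for v in vcf:
        alleles = [v.REF] + list(v.ALT)
        if any(len(a) != 1 or a not in BASES for a in alleles):
            continue  # SNPs only
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"VCF record {v.CHROM}:{v.POS} lacks AD")
        cell = np.full((len(col), 2), MISSING, dtype=np.int8)
        n_missing = 0
        variant = False
        for k, j in enumerate(col):
            depths = [int(d) if d >= 0 else 0 for d in ad[j]]
            call = call_site(depths[0], depths[1:], min_coverage,
                             min_var_freq, alleles=alleles)
            if call.zygosity == "missing":
                n_missing += 1
                continue
            a, b = call.alleles
            cell[k] = sorted((CODE[a], CODE[b]))
            if call.zygosity == "het" or a != v.REF:
                variant = True
        if not variant or n_missing >= max_missing:
            continue
        rows.append((v.CHROM, v.POS - 1, v.REF))
        keys.append((contig_rank[v.CHROM], v.POS - 1))
        genos.append(cell)

    order = np.argsort(np.array(keys, dtype=[("c", int), ("p", int)]),
                       order=("c", "p")) if keys else np.array([], dtype=int)
    sites = pd.DataFrame([rows[i] for i in order],
                         columns=["chrom", "pos", "ref"])
    geno = (np.stack([genos[i] for i in order])
            if len(order) else np.empty((0, len(strains), 2), dtype=np.int8))
    return GenotypeMatrix(list(strains), sites, geno, chrom_lengths)


def matrix_from_population(pop, strains: list[str] | None = None
                           ) -> GenotypeMatrix:
    """Planted-truth genotype matrix straight from simulated genomes.

    Applies the same "variant in >= 1 strain" filter as :func:`build_matrix`
    (there are no missing cells in truth), so site sets are comparable.
    """
    from .layout import contig_name
    from .simulate import _sorted_sites

    strains = strains or pop.strains
    reg = pop.registry
    sp = pop.focal.species_id
    rows, geno_chunks = [], []
    for chrom, pos, order in _sorted_sites(pop):
        if pos.size == 0:
            continue
        ref = np.asarray(reg.ref[chrom], dtype=np.int8)[order]
        # (n_strains, 2, n_sites) -> sorted allele pairs per cell
        stack = np.stack([pop.genomes[s].padded(reg, chrom)[:, order]
                          for s in strains])
        stack = np.sort(stack, axis=1)
        cells = stack.transpose(2, 0, 1)  # (n_sites, n_strains, 2)
        variant = (cells != ref[:, None, None]).any(axis=(1, 2))
        idx = np.flatnonzero(variant)
        contig = contig_name(sp, chrom)
        rows.extend((contig, int(pos[order][i]), BASES[ref[i]]) for i in idx)
        geno_chunks.append(cells[idx])
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref"])
    geno = (np.concatenate(geno_chunks) if geno_chunks
            else np.empty((0, len(strains), 2), dtype=np.int8))
    return GenotypeMatrix(list(strains), sites, geno,
                          pop.focal.chrom_lengths())
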