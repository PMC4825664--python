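"""Coverage-masked consensus sequences, core columns and NJ trees.

Each strain's consensus starts from the reference, replaces homozygous-alt
positions with the alt base, encodes heterozygous positions as the
two-allele IUPAC ambiguity code, and masks positions below the coverage
floor (or inside an explicit mask) as N.  Columns callable in *every*
strain form the core alignment; a neighbor-joining tree over pairwise
column differences serves as the topology check on synthetic panels.

Distances treat every symbol as a diploid genotype (a plain base is a
homozygote, an ambiguity code a heterozygote): the per-column distance is
``1 - shared_alleles / 2``, so base vs. ambiguity-containing-it scores a
half difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .genotypes import BASES, MISSING, GenotypeMatrix
from .layout import GenomeLayout, contig_name

IUPAC = {frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
         frozenset("T"): "T",
         frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
         frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K"}
_ALLELES = {code: fs for fs, code in IUPAC.items()}


def random_reference(layout: GenomeLayout, seed=None,
                     sites=None) -> dict[str, str]:
    """Random nucleotide reference for the focal chromosomes.

    ``sites`` (e.g. ``GenotypeMatrix.sites``, with chrom/pos/ref columns)
    pins the reference base at known variant positions so the sequence is
    consistent with the genome the calls were made against.
    """
    from .simulate import as_rng

    rng = as_rng(seed)
    seqs = {contig_name(layout.species_id, c.name):
            bytearray("".join(np.array(list(BASES))[
                rng.integers(0, 4, c.length)]), "ascii")
            for c in layout.chromosomes}
    if sites is not None:
        rows = (sites.itertuples(index=False)
                if hasattr(sites, "itertuples") else sites)
        for contig, pos, ref in rows:
            seqs[contig][pos] = ord(ref)
    return {c: s.decode("ascii") for c, s in seqs.items()}


@dataclass
class ConsensusSequence:
    strain: str
    sequences: dict[str, str]  # contig -> nucleotide string

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig, seq in self.sequences.items():
                fh.write(f">{self.strain}|{contig}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")


def patch_consensus(reference: dict[str, str],
                    calls,
                    mask: dict[str, list[tuple[int, int]]] | None = None,
                    ) -> ConsensusSequence:
    """Patch reference with calls and apply a low-coverage mask.

    Parameters
    ----------
    calls
        Iterable of ``(contig, pos, (allele_a, allele_b))`` diploid calls
        (0-based positions), or ``(contig, pos, None)`` for a missing call
        (masked as N).  Homozygous-reference calls leave the base intact.
    mask
        Per-contig list of half-open sub-coverage intervals; masked
        positions become N regardless of calls.
    """
    if isinstance(calls, tuple) and len(calls) == 2:  # (matrix, strain)
        calls = _matrix_calls(*calls)
    seqs = {c: bytearray(s, "ascii") for c, s in reference.items()}
    for contig, pos, alleles in calls:
        if contig not in seqs:
            raise KeyError(f"contig {contig!r} not in reference")
        if alleles is None:
            seqs[contig][pos] = ord("N")
            continue
        a, b = alleles
        if a not in BASES or b not in BASES:
            raise ValueError(f"allele not a nucleotide: {alleles!r}")
        seqs[contig][pos] = ord(IUPAC[frozenset((a, b))])
    for contig, intervals in (mask or {}).items():
        if contig not in seqs:
            raise KeyError(f"mask contig {contig!r} not in reference")
        for start, end in intervals:
            seqs[contig][start:end] = b"N" * (end - start)
    return ConsensusSequence("consensus",
                             {c: s.decode("ascii") for c, s in seqs.items()})


def _matrix_calls(matrix: GenotypeMatrix, strain: str):
    j = matrix.strain_index(strain)
    for i, (contig, pos) in enumerate(zip(matrix.sites["chrom"],
                                          matrix.sites["pos"])):
        g = matrix.geno[i, j]
        if g[0] == MISSING:
            yield contig, int(pos), None
        else:
            yield contig, int(pos), (BASES[g[0]], BASES[g[1]])


def consensus_from_matrix(reference: dict[str, str],
                          matrix: GenotypeMatrix, strain: str,
                          mask: dict[str, list[tuple[int, int]]] | None = None
                          ) -> ConsensusSequence:
    """Consensus for one strain of a genotype matrix (missing cells → N)."""
    cons = patch_consensus(reference, _matrix_calls(matrix, strain), mask)
    cons.strain = strain
    return cons


@dataclass
class CoreAlignment:
    """Columns callable (non-N) in every strain."""

    strains: list[str]
    coords: list[tuple[str, int]]  # (contig, 0-based position) per column
    columns: np.ndarray  # (n_strains, n_columns) of single-byte chars

    @property
    def length(self) -> int:
        return self.columns.shape[1]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, s in enumerate(self.strains):
                fh.write(f">{s}\n")
                seq = self.columns[i].tobytes().decode("ascii")
                for k in range(0, len(seq), 80):
                    fh.write(seq[k:k + 80] + "\n")


def extract_core(consensuses: list[ConsensusSequence],
                 variant_only: bool = False) -> CoreAlignment:
    """Drop every column that is N in any strain.

    With ``variant_only`` additionally drop columns identical across all
    strains.  Raises when the strains disagree on the reference frame or
    when no column survives.
    """
    if len(consensuses) < 2:
        raise ValueError("need at least 2 strains")
    first = consensuses[0]
    contigs = list(first.sequences)
    for c in consensuses[1:]:
        if (list(c.sequences) != contigs
                or any(len(c.sequences[k]) != len(first.sequences[k])
                       for k in contigs)):
            raise ValueError("consensus sequences are not on one reference")
    strains = [c.strain for c in consensuses]
    col_chunks, coord_chunks = [], []
    for contig in contigs:
        block = np.vstack([np.frombuffer(c.sequences[contig].encode(),
                                         dtype="S1")
                           for c in consensuses])
        keep = ~(block == b"N").any(axis=0)
        if variant_only:
            keep &= (block != block[0]).any(axis=0)
        idx = np.flatnonzero(keep)
        col_chunks.append(block[:, idx])
        coord_chunks.extend((contig, int(p)) for p in idx)
    columns = np.hstack(col_chunks) if col_chunks else np.empty((len(strains),
                                                                 0), "S1")
    if columns.shape[1] == 0:
        raise ValueError("no column is callable in every strain")
    return CoreAlignment(strains, coord_chunks, columns)


def _pair_distance_table() -> dict[tuple[bytes, bytes], float]:
    # every symbol is a diploid multiset: plain base X -> (X,X),
    # ambiguity {a,b} -> (a,b); distance = 1 - multiset_intersection / 2
    from collections import Counter

    table = {}
    codes = list(IUPAC.values())
    for x in codes:
        for y in codes:
            ma = Counter(sorted(_ALLELES[x]) * (2 // len(_ALLELES[x])))
            mb = Counter(sorted(_ALLELES[y]) * (2 // len(_ALLELES[y])))
            shared = sum((ma & mb).values())
            table[(x.encode(), y.encode())] = 1.0 - shared / 2.0
    return table


_DIST = _pair_distance_table()


def distance_matrix(core: CoreAlignment) -> DistanceMatrix:
    """Mean per-column difference with half-weight ambiguity handling."""
    n = len(core.strains)
    # map bytes to small ints once, then look distances up in a 10x10 grid
    codes = sorted({c for c, _ in _DIST})
    code_of = {c: i for i, c in enumerate(codes)}
    grid = np.zeros((len(codes), len(codes)))
    for (x, y), d in _DIST.items():
        grid[code_of[x], code_of[y]] = d
    enc = np.zeros((n, core.length), dtype=np.intp)
    for i in range(n):
        col = core.columns[i]
        enc[i] = [code_of[c] for c in col]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = grid[enc[i], enc[j]].mean()
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=core.strains)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Deterministic neighbor-joining tree (ids sorted before joining)."""
    if len(dm.ids) < 3:
        raise ValueError("need at least 3 strains for a tree")
    ordered = sorted(dm.ids)
    return nj(dm.filter(ordered))


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
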