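"""Pairwise identity-by-state: counts, windowed states, equivalence groups.

For each pair of diploid genotypes the number of shared alleles (multiset
intersection) defines the IBS state: IBS2 for identical genotypes (AA:AA,
AT:AT), IBS1 when exactly one allele is shared (AA:AT, AC:AT), IBS0 when
none is (AA:TT, AT:CG).  Sites missing in either strain are skipped.

Windowed IBS percentages (default 50-kb window, 25-kb step) classify each
window into one of four genomic states:

============  ===========  ===========
state         pct IBS1     pct IBS0
============  ===========  ===========
IBS2          < 5          < 1
IBS2|1        >= 5         < 1
IBS2|1|0      >= 5         >= 1
IBS2|0        < 5          >= 1
============  ===========  ===========

Two strains are *genetically equivalent* — re-isolates or trivial
derivatives of one strain — when IBS0:IBS2 <= 0.05% and IBS1:IBS2 <= 1%.
Equivalence groups are connected components of the equivalence graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

from ._windows import count_in_windows, window_grid
from .genotypes import GenotypeMatrix, MISSING

STATES = ("IBS2", "IBS2|1", "IBS2|1|0", "IBS2|0")
NO_DATA = "no-data"


def ibs_state(genotype_a, genotype_b) -> str:
    """IBS state of two unordered diploid genotypes ('skip' on missing)."""
    if genotype_a is None or genotype_b is None:
        return "skip"
    x1, x2 = sorted(genotype_a)
    y1, y2 = sorted(genotype_b)
    if (x1, x2) == (y1, y2):
        return "IBS2"
    if x1 == y1 or x1 == y2 or x2 == y1 or x2 == y2:
        return "IBS1"
    return "IBS0"


def _shared_alleles(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Vectorized multiset-intersection size for (n, 2) genotype arrays."""
    shared = np.zeros(ga.shape[0], dtype=np.int8)
    for base in range(4):
        ca = (ga[:, 0] == base).astype(np.int8) + (ga[:, 1] == base)
        cb = (gb[:, 0] == base).astype(np.int8) + (gb[:, 1] == base)
        shared += np.minimum(ca, cb)
    return shared


def classify_window(pct_ibs1: float, pct_ibs0: float) -> str:
    """Map within-window IBS1/IBS0 percentages to the four-state table."""
    if not (0 <= pct_ibs1 <= 100 and 0 <= pct_ibs0 <= 100):
        raise ValueError("percentages must be in [0, 100]")
    hi1 = pct_ibs1 >= 5.0
    hi0 = pct_ibs0 >= 1.0
    if hi1 and hi0:
        return "IBS2|1|0"
    if hi1:
        return "IBS2|1"
    if hi0:
        return "IBS2|0"
    return "IBS2"


@dataclass
class PairwiseIBS:
    """Genome-wide IBS counts and windowed states for one strain pair."""

    strain_a: str
    strain_b: str
    n_ibs0: int
    n_ibs1: int
    n_ibs2: int
    windows: pd.DataFrame | None = None  # chrom,start,end,n_sites,pct_*,state

    @property
    def n_compared(self) -> int:
        return self.n_ibs0 + self.n_ibs1 + self.n_ibs2

    @property
    def ibs0_to_ibs2(self) -> float:
        return self.n_ibs0 / self.n_ibs2 if self.n_ibs2 else float("inf")

    @property
    def ibs1_to_ibs2(self) -> float:
        return self.n_ibs1 / self.n_ibs2 if self.n_ibs2 else float("inf")

    def state_fractions(self) -> dict[str, float]:
        """Fraction of data windows in each genomic state."""
        if self.windows is None:
            raise ValueError("pair was computed without windows")
        data = self.windows[self.windows["state"] != NO_DATA]
        if len(data) == 0:
            return {s: float("nan") for s in STATES}
        counts = data["state"].value_counts()
        return {s: counts.get(s, 0) / len(data) for s in STATES}


def pairwise_ibs(matrix: GenotypeMatrix, a: str, b: str,
                 window: int = 50_000, step: int = 25_000,
                 min_window_sites: int = 20,
                 with_windows: bool = True) -> PairwiseIBS:
    """Accumulate IBS0/1/2 over all sites called in both strains.

    Windows with fewer than ``min_window_sites`` compared sites carry the
    ``no-data`` state and are excluded from state summaries (a handful of
    sites should not dictate a 50-kb state).  Raises if the pair shares no
    comparable site at all.
    """
    ia, ib = matrix.strain_index(a), matrix.strain_index(b)
    ga, gb = matrix.geno[:, ia], matrix.geno[:, ib]
    ok = (ga[:, 0] != MISSING) & (gb[:, 0] != MISSING)
    if not ok.any():
        raise ValueError(f"strains {a!r} and {b!r} share no compared sites")
    shared = _shared_alleles(ga[ok], gb[ok])
    n0 = int((shared == 0).sum())
    n1 = int((shared == 1).sum())
    n2 = int((shared == 2).sum())

    wins = None
    if with_windows:
        chroms = matrix.sites["chrom"].to_numpy()[ok]
        pos = matrix.sites["pos"].to_numpy()[ok]
        rows = []
        for chrom, length in matrix.chrom_lengths.items():
            grid = window_grid(length, window, step)
            sel = chroms == chrom
            p = pos[sel]
            order = np.argsort(p, kind="stable")
            p = p[order]
            s_chrom = shared[sel][order]
            n_sites = count_in_windows(p, grid)
            c0 = count_in_windows(p, grid, (s_chrom == 0).astype(float))
            c1 = count_in_windows(p, grid, (s_chrom == 1).astype(float))
            for (ws, we), ns, k0, k1 in zip(grid, n_sites, c0, c1):
                if ns < min_window_sites:
                    rows.append((chrom, ws, we, int(ns), np.nan, np.nan,
                                 NO_DATA))
                else:
                    p1, p0 = 100.0 * k1 / ns, 100.0 * k0 / ns
                    rows.append((chrom, ws, we, int(ns), p1, p0,
                                 classify_window(p1, p0)))
        wins = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "n_sites", "pct_ibs1",
                                           "pct_ibs0", "state"])
    return PairwiseIBS(a, b, n0, n1, n2, wins)


def is_equivalent(pair: PairwiseIBS,
                  max_ibs0_ratio: float = 0.0005,
                  max_ibs1_ratio: float = 0.01) -> bool:
    """Genetic-equivalence test on IBS0:IBS2 and IBS1:IBS2 ratios."""
    if pair.n_ibs2 == 0:
        raise ValueError(f"pair ({pair.strain_a}, {pair.strain_b}) has no "
                         "IBS2 sites; equivalence ratios are undefined")
    return (pair.ibs0_to_ibs2 <= max_ibs0_ratio
            and pair.ibs1_to_ibs2 <= max_ibs1_ratio)


def all_pairwise(matrix: GenotypeMatrix, strains: list[str] | None = None,
                 with_windows: bool = False,
                 **kwargs) -> Iterator[PairwiseIBS]:
    """Yield :func:`pairwise_ibs` for every unordered strain pair."""
    strains = strains or matrix.strains
    for a, b in combinations(strains, 2):
        yield pairwise_ibs(matrix, a, b, with_windows=with_windows, **kwargs)


@dataclass
class EquivalenceGraph:
    """Equivalence edges and their connected components (size >= 2)."""

    graph: nx.Graph
    groups: list[list[str]]
    diagnostics: pd.DataFrame  # per group: size, max internal ratios

    @property
    def grouped_strains(self) -> list[str]:
        return sorted(s for g in self.groups for s in g)


def equivalence_groups(pairs: Iterable[PairwiseIBS],
                       max_ibs0_ratio: float = 0.0005,
                       max_ibs1_ratio: float = 0.01) -> EquivalenceGraph:
    """Group strains by connected components over equivalence edges.

    Components (not cliques) are used: they are order-independent and
    reproducible; near-threshold chains are surfaced by the per-group
    maximum internal ratio diagnostics instead of being split.
    """
    g = nx.Graph()
    ratios: dict[tuple[str, str], tuple[float, float]] = {}
    for p in pairs:
        g.add_node(p.strain_a)
        g.add_node(p.strain_b)
        ratios[tuple(sorted((p.strain_a, p.strain_b)))] = (p.ibs0_to_ibs2,
                                                           p.ibs1_to_ibs2)
        if is_equivalent(p, max_ibs0_ratio, max_ibs1_ratio):
            g.add_edge(p.strain_a, p.strain_b)
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), c[0]))
    diag = []
    for i, comp in enumerate(comps):
        internal = [ratios[tuple(sorted(p))] for p in combinations(comp, 2)
                    if tuple(sorted(p)) in ratios]
        diag.append((i, len(comp),
                     max((r0 for r0, _ in internal), default=np.nan),
                     max((r1 for _, r1 in internal), default=np.nan)))
    diagnostics = pd.DataFrame(diag, columns=["group", "size",
                                              "max_internal_ibs0_ratio",
                                              "max_internal_ibs1_ratio"])
    return EquivalenceGraph(g, comps, diagnostics)


def pair_count(n_strains: int) -> int:
    """Number of unordered strain pairs, n(n-1)/2."""
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    return n_strains * (n_strains - 1) // 2


def pairs_to_frame(pairs: Iterable[PairwiseIBS],
                   max_ibs0_ratio: float = 0.0005,
                   max_ibs1_ratio: float = 0.01) -> pd.DataFrame:
    """Summary table: one row per pair with counts, ratios, equivalence."""
    rows = []
    for p in pairs:
        rows.append((p.strain_a, p.strain_b, p.n_ibs0, p.n_ibs1, p.n_ibs2,
                     p.ibs0_to_ibs2, p.ibs1_to_ibs2,
                     is_equivalent(p, max_ibs0_ratio, max_ibs1_ratio)))
    return pd.DataFrame(rows, columns=["strain_a", "strain_b", "n_ibs0",
                                       "n_ibs1", "n_ibs2", "ibs0_to_ibs2",
                                       "ibs1_to_ibs2", "equivalent"])
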