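"""Depth normalization, species contributions, hybrid and accessory calls.

Raw depth tracks (BedGraph bins or samtools-depth per-base TSV) are
re-windowed onto a sliding grid (default 10-kb window, 5-kb step), masked
where a window holds fewer than ``min_reads`` reads, and normalized to the
mean of the qualifying focal-species chromosome windows — so a strain's
euploid focal genome sits at 1.0 and dosage reads off directly (a single
donor chromosome copy in a tetraploid background sits at 0.25).

Downstream calls:

* species contribution — per (species, chromosome) coverage breadth and
  mean normalized depth;
* interspecific hybrids — a donor species is called when more than 10% of
  at least one of its chromosomes is covered (strict inequality, matching
  an extent-of-chromosome rule); a donor with all chromosomes >90% covered
  marks a near-complete second genome;
* accessory (pan-genome) loci — present when coverage breadth over the
  locus reaches ``min_breadth`` (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._windows import window_grid
from .layout import GenomeLayout, contig_table

#: Normalized-depth floor for counting a window as covered.  Sits midway
#: between the zero noise floor and the smallest dosage of interest (a
#: single chromosome copy in a tetraploid background, 0.25), so that such
#: a chromosome is covered across ~all of its windows under depth noise.
PRESENCE_DEPTH = 0.125


def read_depth_track(path: str | Path) -> pd.DataFrame:
    """Load a depth track: 4-column BedGraph or samtools-depth TSV.

    samtools-depth rows (chrom, 1-based pos, depth) are converted to
    single-base half-open bins.
    """
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] == 4:
        df.columns = ["chrom", "start", "end", "depth"]
        return df
    if df.shape[1] == 3:
        out = pd.DataFrame({"chrom": df[0], "start": df[1] - 1,
                            "end": df[1], "depth": df[2]})
        return out
    raise ValueError(f"unrecognized depth track format in {path} "
                     f"({df.shape[1]} columns)")


@dataclass
class CoverageProfile:
    """Normalized windowed depth across every contig of the panel."""

    strain: str
    frame: pd.DataFrame  # contig,species,kind,start,end,depth,reads,norm,masked
    norm_constant: float
    window: int
    step: int

    def contig_frame(self, contig: str) -> pd.DataFrame:
        sub = self.frame[self.frame["contig"] == contig]
        if sub.empty:
            raise KeyError(f"contig {contig!r} not in profile")
        return sub

    def to_bedgraph(self, path) -> None:
        out = self.frame[["contig", "start", "end", "norm"]].copy()
        out["norm"] = out["norm"].fillna(-1.0)
        out.to_csv(path, sep="\t", header=False, index=False,
                   float_format="%.4f")


def _window_means(bins: pd.DataFrame, length: int,
                  grid: list[tuple[int, int]]) -> np.ndarray:
    """Overlap-weighted mean depth per window from non-overlapping bins."""
    if bins.empty:
        return np.zeros(len(grid))
    b = bins.sort_values("start")
    s = b["start"].to_numpy(dtype=float)
    e = b["end"].to_numpy(dtype=float)
    d = b["depth"].to_numpy(dtype=float)
    # prefix sums of depth*bp let each window query in O(log n)
    cum = np.concatenate([[0.0], np.cumsum(d * (e - s))])
    means = np.empty(len(grid))
    for i, (ws, we) in enumerate(grid):
        lo = np.searchsorted(e, ws, side="right")
        hi = np.searchsorted(s, we, side="left")
        total = cum[hi] - cum[lo]
        if lo < hi:  # trim partial overlap at both edges
            total -= d[lo] * max(0.0, ws - s[lo])
            total -= d[hi - 1] * max(0.0, e[hi - 1] - we)
        means[i] = total / (we - ws)
    return means


def normalize_windows(depth: pd.DataFrame | str | Path,
                      layouts: list[GenomeLayout],
                      window: int = 10_000, step: int = 5_000,
                      min_reads: int = 10, read_length: int = 100,
                      strain: str = "strain") -> CoverageProfile:
    """Window, mask and normalize one strain's depth track.

    A window qualifies when it holds at least ``min_reads`` reads
    (estimated as ``mean_depth * window_bp / read_length``); sub-threshold
    windows are masked.  The normalization constant is the mean depth of
    qualifying focal-species *chromosome* windows (accessory loci and donor
    genomes are excluded so that strain-variable content cannot deflate
    the focal dosage scale).
    """
    if not isinstance(depth, pd.DataFrame):
        depth = read_depth_track(depth)
    if (depth["depth"] < 0).any():
        raise ValueError("depth values must be >= 0")
    ct = contig_table(layouts)
    rows = []
    for _, r in ct.iterrows():
        grid = window_grid(r["length"], window, step)
        bins = depth[depth["chrom"] == r["contig"]]
        means = _window_means(bins, r["length"], grid)
        for (ws, we), m in zip(grid, means):
            reads = m * (we - ws) / read_length
            rows.append((r["contig"], r["species"], r["kind"], ws, we,
                         m, reads, reads < min_reads))
    frame = pd.DataFrame(rows, columns=["contig", "species", "kind", "start",
                                        "end", "depth", "reads", "masked"])
    focal_sp = layouts[0].species_id
    qual = frame[(frame["species"] == focal_sp)
                 & (frame["kind"] == "chromosome") & ~frame["masked"]]
    if qual.empty:
        raise ValueError("no qualifying focal-species window; cannot "
                         "normalize")
    norm_const = float(qual["depth"].mean())
    frame["norm"] = np.where(frame["masked"], np.nan,
                             frame["depth"] / norm_const)
    return CoverageProfile(strain, frame, norm_const, window, step)


@dataclass
class SpeciesContribution:
    """Per-chromosome coverage breadth and dosage for every species."""

    strain: str
    frame: pd.DataFrame  # species, chrom, n_windows, covered_fraction,
    #                      mean_norm_depth
    presence_depth: float

    def species_frame(self, species: str) -> pd.DataFrame:
        return self.frame[self.frame["species"] == species]


def species_contribution(profile: CoverageProfile,
                         presence_depth: float = PRESENCE_DEPTH
                         ) -> SpeciesContribution:
    """Coverage breadth per chromosome of every species in the panel.

    A window counts as covered when its normalized depth is at least
    ``presence_depth``; masked windows count as uncovered.  The mean
    normalized depth over covered windows estimates copy dosage.
    """
    chrom = profile.frame[profile.frame["kind"] == "chromosome"]
    rows = []
    for (sp, contig), sub in chrom.groupby(["species", "contig"],
                                           sort=False):
        covered = sub["norm"].to_numpy() >= presence_depth
        covered = np.where(np.isnan(sub["norm"].to_numpy()), False, covered)
        frac = covered.mean() if len(sub) else 0.0
        mean_depth = (float(sub["norm"].to_numpy()[covered].mean())
                      if covered.any() else 0.0)
        name = contig.split(f"{sp}_", 1)[1]
        rows.append((sp, name, len(sub), float(frac), mean_depth))
    frame = pd.DataFrame(rows, columns=["species", "chrom", "n_windows",
                                        "covered_fraction",
                                        "mean_norm_depth"])
    return SpeciesContribution(profile.strain, frame, presence_depth)


@dataclass
class DonorCall:
    species: str
    chromosomes: dict[str, tuple[float, float]]  # chrom -> (fraction, depth)
    genome_fraction: float
    minor: bool


@dataclass
class HybridCall:
    strain: str
    donors: list[DonorCall]
    classification: str  # non-hybrid | partial | near-complete second genome

    @property
    def donor_species(self) -> list[str]:
        return [d.species for d in self.donors]

    def donor_chromosomes(self, species: str) -> set[str]:
        for d in self.donors:
            if d.species == species:
                return set(d.chromosomes)
        return set()


def call_hybrid(contribution: SpeciesContribution,
                focal_species: str | None = None,
                min_chrom_fraction: float = 0.10,
                near_complete_fraction: float = 0.90,
                minor_genome_fraction: float = 0.25) -> HybridCall:
    """Call interspecific hybrids from per-chromosome coverage breadth.

    A donor species is listed when the covered fraction of at least one of
    its chromosomes exceeds ``min_chrom_fraction`` (strictly).  Donors
    whose genome-wide covered fraction stays below
    ``minor_genome_fraction`` are flagged minor rather than suppressed.
    """
    frame = contribution.frame
    focal = focal_species or frame["species"].iloc[0]
    donors = []
    for sp, sub in frame.groupby("species", sort=False):
        if sp == focal:
            continue
        hit = sub[sub["covered_fraction"] > min_chrom_fraction]
        if hit.empty:
            continue
        chroms = {r["chrom"]: (float(r["covered_fraction"]),
                               float(r["mean_norm_depth"]))
                  for _, r in hit.iterrows()}
        genome_fraction = float(sub["covered_fraction"].mean())
        donors.append(DonorCall(sp, chroms, genome_fraction,
                                genome_fraction < minor_genome_fraction))
    if not donors:
        cls = "non-hybrid"
    elif any((sub := frame[frame["species"] == d.species])
             ["covered_fraction"].min() > near_complete_fraction
             for d in donors):
        cls = "near-complete second genome"
    else:
        cls = "partial"
    return HybridCall(contribution.strain, donors, cls)


@dataclass
class AccessoryCall:
    strain: str
    locus: str
    present: bool
    breadth: float
    mean_norm_depth: float


def call_accessory(profile: CoverageProfile, locus: str,
                   min_breadth: float = 0.5,
                   presence_depth: float = PRESENCE_DEPTH) -> AccessoryCall:
    """Presence/absence of one accessory locus by coverage breadth."""
    sub = profile.frame[(profile.frame["kind"] == "accessory")
                        & (profile.frame["contig"].str.endswith(
                            f"_acc_{locus}"))]
    if sub.empty:
        raise KeyError(f"accessory locus {locus!r} not in profile")
    norm = sub["norm"].to_numpy()
    covered = np.where(np.isnan(norm), False, norm >= presence_depth)
    breadth = float(covered.mean())
    mean_depth = float(norm[covered].mean()) if covered.any() else 0.0
    return AccessoryCall(profile.strain, locus, breadth >= min_breadth,
                         breadth, mean_depth)


def call_accessories(profile: CoverageProfile, layout: GenomeLayout,
                     min_breadth: float = 0.5,
                     presence_depth: float = PRESENCE_DEPTH) -> pd.DataFrame:
    """One row per accessory locus of the focal layout."""
    rows = []
    for a in layout.accessory_loci:
        c = call_accessory(profile, a.name, min_breadth, presence_depth)
        rows.append((c.strain, c.locus, c.present, c.breadth,
                     c.mean_norm_depth))
    return pd.DataFrame(rows, columns=["strain", "locus", "present",
                                       "breadth", "mean_norm_depth"])


def marker_profile(accessory_calls: pd.DataFrame,
                   marker_loci: list[str],
                   clade_of: dict[str, str] | None = None,
                   clade: str | None = None) -> dict:
    """Marker presence vectors and clade co-occurrence counts.

    ``accessory_calls`` is a concatenation of :func:`call_accessories`
    frames over strains.  Returns a dict with a boolean ``presence`` matrix
    (strains × marker loci), a per-marker ``co_occurrence`` table of
    carriers inside/outside ``clade`` (when clade labels are supplied), and
    the list of strains carrying *all* the markers (interclade-marker
    carriers when the markers tag different clades).
    """
    if not marker_loci:
        return {"presence": pd.DataFrame(), "co_occurrence": pd.DataFrame(),
                "carriers_of_all": []}
    sub = accessory_calls[accessory_calls["locus"].isin(marker_loci)]
    presence = (sub.pivot_table(index="strain", columns="locus",
                                values="present", aggfunc="first")
                .reindex(columns=marker_loci).fillna(False).astype(bool))
    rows = []
    if clade_of is not None and clade is not None:
        for locus in marker_loci:
            carriers = presence.index[presence[locus]].tolist()
            inside = sum(clade_of.get(s) == clade for s in carriers)
            rows.append((locus, len(carriers), inside,
                         len(carriers) - inside))
    co = pd.DataFrame(rows, columns=["locus", "n_carriers",
                                     "carriers_in_clade",
                                     "carriers_out_clade"])
    all_markers = presence.index[presence.all(axis=1)].tolist()
    return {"presence": presence, "co_occurrence": co,
            "carriers_of_all": all_markers}
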