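"""Windowed heterozygosity, homozygosity classification and LOH detection.

Heterozygosity is summarized per strain in sliding windows (default 10 kb
window, 5 kb step).  A strain is classed as homozygous when the 0.75
quantile of its per-window heterozygous-SNP counts is zero — a deliberately
forgiving rule that tolerates sporadic false-positive het calls.  Loss of
heterozygosity (LOH) is reported as maximal runs of consecutive zero-het
windows inside an otherwise heterozygous genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._windows import count_in_windows, window_grid
from .genotypes import GenotypeMatrix, MISSING

#: Window/step used by genome-overview plots (coarser than the default).
PLOT_PRESET = {"window": 50_000, "step": 25_000}


@dataclass
class WindowTrack:
    """Per-window values for one strain on one sliding-window grid."""

    strain: str
    frame: pd.DataFrame  # chrom, start, end, het, hom, n_sites, pct_het, empty
    window: int
    step: int

    def to_bedgraph(self, path, value: str = "pct_het") -> None:
        self.frame[["chrom", "start", "end", value]].to_csv(
            path, sep="\t", header=False, index=False)


@dataclass
class LOHSegment:
    chrom: str
    start: int
    end: int
    n_windows: int
    mean_het: float
    flank_pct_het: float


def het_windows(matrix: GenotypeMatrix, strain: str,
                window: int = 10_000, step: int = 5_000) -> WindowTrack:
    """Count heterozygous and homozygous-variant calls per window.

    A call is heterozygous when its two alleles differ, homozygous when it
    is a non-reference homozygote (an all-reference cell is not a SNP in
    this strain).  ``pct_het`` is ``100 * het / (het + hom)``; windows with
    no calls at all are flagged ``empty`` and carry 0.
    """
    j = matrix.strain_index(strain)
    ref_codes = matrix.sites["ref"].map({"A": 0, "C": 1, "G": 2,
                                         "T": 3}).to_numpy(dtype=np.int8)
    g = matrix.geno[:, j]
    called = g[:, 0] != MISSING
    het = called & (g[:, 0] != g[:, 1])
    hom = called & (g[:, 0] == g[:, 1]) & (g[:, 0] != ref_codes)

    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    rows = []
    for chrom, length in matrix.chrom_lengths.items():
        grid = window_grid(length, window, step)
        sel = chroms == chrom
        p = pos[sel]
        order = np.argsort(p, kind="stable")
        p = p[order]
        n_het = count_in_windows(p, grid, het[sel][order].astype(float))
        n_hom = count_in_windows(p, grid, hom[sel][order].astype(float))
        for (s, e), h, o in zip(grid, n_het, n_hom):
            rows.append((chrom, s, e, int(h), int(o)))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "het",
                                        "hom"])
    frame["n_sites"] = frame["het"] + frame["hom"]
    frame["empty"] = frame["n_sites"] == 0
    with np.errstate(invalid="ignore"):
        frame["pct_het"] = np.where(frame["empty"], 0.0,
                                    100.0 * frame["het"]
                                    / frame["n_sites"].replace(0, 1))
    return WindowTrack(strain, frame, window, step)


def classify_homozygous(track: WindowTrack, quantile: float = 0.75) -> bool:
    """True iff the ``quantile`` quantile of per-window het counts is zero.

    The quantile uses lower-value interpolation so that the rule is well
    defined on integer counts (e.g. a track with exactly 75% zero-het
    windows classifies as homozygous at the default).  Empty windows carry
    no information and are excluded; an all-empty track raises.
    """
    counts = track.frame.loc[~track.frame["empty"], "het"].to_numpy()
    if counts.size == 0:
        raise ValueError(f"strain {track.strain!r}: no windows with data")
    return float(np.quantile(counts, quantile, method="lower")) == 0.0


def detect_loh(track: WindowTrack, min_run_windows: int = 4,
               quantile: float = 0.75) -> list[LOHSegment]:
    """Maximal runs of >= ``min_run_windows`` consecutive zero-het windows.

    Runs never cross chromosome boundaries; overlapping windows inside a
    run merge into one segment spanning the first window start to the last
    window end.  For a globally homozygous strain LOH is undefined: an
    empty list is returned with a warning.
    """
    if classify_homozygous(track, quantile):
        warnings.warn(f"strain {track.strain!r} is globally homozygous; "
                      "LOH is undefined", stacklevel=2)
        return []
    segments: list[LOHSegment] = []
    for chrom, sub in track.frame.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        zero = (sub["het"] == 0).to_numpy()
        i = 0
        while i < len(zero):
            if not zero[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(zero) and zero[j + 1]:
                j += 1
            if j - i + 1 >= min_run_windows:
                flank_idx = [k for k in (i - 2, i - 1, j + 1, j + 2)
                             if 0 <= k < len(sub) and not sub["empty"][k]]
                flank = (float(sub["pct_het"].iloc[flank_idx].mean())
                         if flank_idx else float("nan"))
                segments.append(LOHSegment(
                    chrom=chrom,
                    start=int(sub["start"][i]),
                    end=int(sub["end"][j]),
                    n_windows=j - i + 1,
                    mean_het=0.0,
                    flank_pct_het=flank))
            i = j + 1
    return segments


def loh_to_bed(segments: list[LOHSegment], path) -> None:
    pd.DataFrame([(s.chrom, s.start, s.end,
                   f"LOH_{s.n_windows}w", s.flank_pct_het)
                  for s in segments],
                 columns=["chrom", "start", "end", "name", "flank_pct_het"]
                 ).to_csv(path, sep="\t", header=False, index=False)
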