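"""Reference layout: the coordinate frame shared by every track.

A reference panel is an ordered list of :class:`GenomeLayout` objects, one
per species with the focal species first, mirroring the concatenated
multi-species reference used for competitive read mapping in *Saccharomyces*
surveys (the focal *S. cerevisiae* genome, its *sensu stricto* relatives,
plus a set of strain-variable accessory loci attached to the focal species
only).

Coordinates are 0-based and half-open throughout the package; conversion to
1-based happens only on VCF write.  Contig identifiers embed the species
(``Scer_chrI``, ``Scer_acc_wine_circle``) so that depth tracks spanning
several species never collide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

FOCAL_SPECIES = "Scer"

#: Default species identifiers, focal species first (the remaining six echo
#: the composition of an extended sensu-stricto reference panel).
SENSU_STRICTO = ("Scer", "Spar", "Smik", "Skud", "Suva", "Seub", "Sarb")

#: Canonical names for the first few accessory loci; further loci are
#: numbered ``segment_06`` and so on.
NAMED_ACCESSORY = ("wine_circle", "RTM1_cluster", "MPR1", "BIO1_BIO6",
                   "aryl_alcohol")

_ROMAN = ("I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI"
          " XVII XVIII XIX XX").split()


def roman_chrom(i: int) -> str:
    """Yeast-style chromosome name for 1-based index ``i`` (``chrI`` ...)."""
    if 1 <= i <= len(_ROMAN):
        return f"chr{_ROMAN[i - 1]}"
    return f"chr{i}"


def contig_name(species: str, name: str, accessory: bool = False) -> str:
    """Global contig identifier for a chromosome or accessory locus."""
    return f"{species}_acc_{name}" if accessory else f"{species}_{name}"


@dataclass(frozen=True)
class Locus:
    """A named contiguous segment (chromosome or accessory locus)."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"locus {self.name!r}: length must be > 0, "
                             f"got {self.length}")


@dataclass
class GenomeLayout:
    """Ordered chromosomes (and accessory loci) of one species."""

    species_id: str
    chromosomes: list[Locus]
    accessory_loci: list[Locus] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate chromosome names in {self.species_id}")
        acc = [a.name for a in self.accessory_loci]
        if len(set(acc)) != len(acc):
            raise ValueError(f"duplicate accessory names in {self.species_id}")

    @property
    def genome_length(self) -> int:
        """Total chromosome length, accessory loci excluded."""
        return sum(c.length for c in self.chromosomes)

    @property
    def total_length(self) -> int:
        return self.genome_length + sum(a.length for a in self.accessory_loci)

    def chrom_lengths(self) -> dict[str, int]:
        """Contig-id → length for this species' chromosomes."""
        return {contig_name(self.species_id, c.name): c.length
                for c in self.chromosomes}

    def chromosome(self, name: str) -> Locus:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"{self.species_id} has no chromosome {name!r}")

    def accessory(self, name: str) -> Locus:
        for a in self.accessory_loci:
            if a.name == name:
                return a
        raise KeyError(f"{self.species_id} has no accessory locus {name!r}")


def make_layout(n_chromosomes: int,
                chrom_length: int,
                n_species: int = 1,
                n_accessory: int = 0,
                accessory_length: int = 30_000) -> list[GenomeLayout]:
    """Build a multi-species reference layout.

    Every species carries ``n_chromosomes`` chromosomes of ``chrom_length``
    bp; ``n_accessory`` accessory loci of ``accessory_length`` bp are
    attached to the focal (first) species only.

    Raises
    ------
    ValueError
        If any count or size is non-positive (``n_accessory`` may be 0).
    """
    if n_chromosomes < 1 or n_species < 1:
        raise ValueError("n_chromosomes and n_species must be >= 1")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be > 0")
    if n_accessory < 0:
        raise ValueError("n_accessory must be >= 0")
    if n_accessory > 0 and accessory_length <= 0:
        raise ValueError("accessory_length must be > 0")

    species_ids = list(SENSU_STRICTO[:n_species])
    species_ids += [f"sp{i + 1}" for i in range(len(species_ids), n_species)]

    acc_names = list(NAMED_ACCESSORY[:n_accessory])
    acc_names += [f"segment_{i + 1:02d}" for i in range(len(acc_names),
                                                        n_accessory)]

    layouts = []
    for si, sp in enumerate(species_ids):
        chroms = [Locus(roman_chrom(i + 1), chrom_length)
                  for i in range(n_chromosomes)]
        acc = ([Locus(n, accessory_length) for n in acc_names]
               if si == 0 else [])
        layouts.append(GenomeLayout(sp, chroms, acc))
    return layouts


def contig_table(layouts: list[GenomeLayout]) -> pd.DataFrame:
    """One row per contig across the whole panel.

    Columns: contig, species, name, kind ('chromosome'|'accessory'),
    length, focal (bool).  Row order is the on-disk emission order.
    """
    rows = []
    focal_id = layouts[0].species_id
    for lay in layouts:
        for c in lay.chromosomes:
            rows.append((contig_name(lay.species_id, c.name),
                         lay.species_id, c.name, "chromosome", c.length,
                         lay.species_id == focal_id))
        for a in lay.accessory_loci:
            rows.append((contig_name(lay.species_id, a.name, accessory=True),
                         lay.species_id, a.name, "accessory", a.length,
                         lay.species_id == focal_id))
    return pd.DataFrame(rows, columns=["contig", "species", "name", "kind",
                                       "length", "focal"])


def layouts_to_json(layouts: list[GenomeLayout], path: str | Path) -> None:
    data = [{"species_id": l.species_id,
             "chromosomes": [[c.name, c.length] for c in l.chromosomes],
             "accessory_loci": [[a.name, a.length] for a in l.accessory_loci]}
            for l in layouts]
    Path(path).write_text(json.dumps(data, indent=1))


def layouts_from_json(path: str | Path) -> list[GenomeLayout]:
    data = json.loads(Path(path).read_text())
    return [GenomeLayout(d["species_id"],
                         [Locus(n, ln) for n, ln in d["chromosomes"]],
                         [Locus(n, ln) for n, ln in d["accessory_loci"]])
            for d in data]
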