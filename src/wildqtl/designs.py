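"""Crossing designs M1-M9 that turn wild individuals into mapping populations.

Each *entry* of a mapping population descends from one selected wild
individual.  A design first builds the entry's pre-testcross genome — the
individual that is genotyped for the association scan — carrying exactly one
randomly chosen offspring per intermediate generation, and then crosses it to
a common tester to produce the testcross progeny whose mean performance is the
entry's trait value:

====  ==============================  expected wild genome in progeny
M1    wild                            50%
M2    self(wild)                      50%
M3    DH(wild)                        50%
M4    wild x elite F1                 25%
M5    self(F1)                        25%
M6    DH(F1)                          25%
M7    B1 = F1 x elite                 12.5%
M8    self(B1)                        12.5%
M9    DH(B1)                          12.5%
====  ==============================  ================================

Scan genotypes are origin-blind 0/1/2 dosages of the pre-testcross genome and
never reference the tester (genotyping happens before the testcross).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genmap import GeneticMap
from .genome import DiploidGenome, cross, make_dh, self_

__all__ = [
    "DESIGN_IDS",
    "MappingEntry",
    "MappingPopulation",
    "UnknownDesignError",
    "build_entry",
    "build_mapping_population",
    "pre_testcross_genome",
]

DESIGN_IDS = tuple(f"M{i}" for i in range(1, 10))


class UnknownDesignError(ValueError):
    """Raised for design ids outside M1-M9."""


@dataclass
class MappingEntry:
    """One entry: scan genotype, testcross progeny, and trait values."""

    wild_parent_id: str
    pre_testcross: DiploidGenome
    scan_genotype: np.ndarray  # (M,) 0/1/2 dosage of the pre-testcross genome
    progeny: list[DiploidGenome] = field(default_factory=list)
    n_progeny: int = 0
    genotypic_value: float | None = None
    phenotype: float | None = None


@dataclass
class MappingPopulation:
    design: str
    entries: list[MappingEntry]
    gmap: GeneticMap

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    def scan_matrix(self) -> np.ndarray:
        """(n_entries, M) dosage matrix used for kinship and the scan."""
        return np.vstack([e.scan_genotype for e in self.entries])


def pre_testcross_genome(
    design: str,
    wild: DiploidGenome,
    elite: DiploidGenome,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> DiploidGenome:
    """Run the material-development steps of ``design`` for one wild parent."""
    if design == "M1":
        return wild
    if design == "M2":
        return self_(wild, gmap, rng)
    if design == "M3":
        return make_dh(wild, gmap, rng)
    f1 = None
    if design in ("M4", "M5", "M6"):
        f1 = cross(wild, elite, gmap, rng)
        if design == "M4":
            return f1
        if design == "M5":
            return self_(f1, gmap, rng)
        return make_dh(f1, gmap, rng)
    if design in ("M7", "M8", "M9"):
        b1 = cross(cross(wild, elite, gmap, rng), elite, gmap, rng)
        if design == "M7":
            return b1
        if design == "M8":
            return self_(b1, gmap, rng)
        return make_dh(b1, gmap, rng)
    raise UnknownDesignError(f"unknown crossing design {design!r}")


def build_entry(
    design: str,
    wild: DiploidGenome,
    elite: DiploidGenome,
    tester: DiploidGenome,
    n_offspring: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    wild_parent_id: str = "",
    keep_progeny: bool = True,
) -> MappingEntry:
    """Build one mapping-population entry (default 594 testcross progeny).

    With ``keep_progeny=False`` the progeny list is left empty (the caller is
    expected to stream progeny itself); ``n_progeny`` still records the
    configured count.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    pre = pre_testcross_genome(design, wild, elite, gmap, rng)
    progeny = (
        [cross(pre, tester, gmap, rng) for _ in range(n_offspring)]
        if keep_progeny
        else []
    )
    return MappingEntry(
        wild_parent_id=wild_parent_id,
        pre_testcross=pre,
        scan_genotype=pre.dosage(),
        progeny=progeny,
        n_progeny=n_offspring,
    )


def build_mapping_population(
    design: str,
    selected_wilds: list[DiploidGenome],
    elite: DiploidGenome,
    tester: DiploidGenome,
    n_offspring: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    keep_progeny: bool = True,
) -> MappingPopulation:
    """One entry per selected wild individual."""
    if not selected_wilds:
        raise ValueError("selected_wilds must be nonempty")
    if design not in DESIGN_IDS:
        raise UnknownDesignError(f"unknown crossing design {design!r}")
    entries = [
        build_entry(
            design,
            wild,
            elite,
            tester,
            n_offspring,
            gmap,
            rng,
            wild_parent_id=f"w{i}",
            keep_progeny=keep_progeny,
        )
        for i, wild in enumerate(selected_wilds)
    ]
    return MappingPopulation(design, entries, gmap)
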