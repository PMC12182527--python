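"""Origin-tagged diploid genomes and the meiosis/cross/self/DH primitives.

Every genome carries, per allele copy, an integer *origin id* identifying the
founder haplotype it descends from.  Ids ``>= 0`` are wild founder haplotypes
(id ``2*f + s`` for founder ``f``, strand ``s``); ids ``< 0`` belong to the
elite breeding pool.  Origin ids are copied verbatim through meiosis, which is
what lets the simulator measure wild-genome content and wild-haplotype
representation of any derived individual, while the association scan itself
stays origin-blind (a SNP array cannot tell identical-by-state wild and elite
alleles apart).

Recombination follows the Haldane model: per chromosome the crossover count is
Poisson(L/100) for map length L in cM, crossover positions are uniform, and
there is no interference or obligate chiasma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .genmap import GeneticMap

__all__ = [
    "DiploidGenome",
    "Gamete",
    "GenomeShapeError",
    "OriginTag",
    "cross",
    "decode_origin",
    "elite_origin_id",
    "gamete_batch",
    "make_dh",
    "meiosis",
    "self_",
    "wild_genome_fraction",
    "wild_haplotype_coverage",
    "wild_origin_id",
]


class GenomeShapeError(ValueError):
    """Raised when genome and map widths disagree."""


@dataclass(frozen=True)
class OriginTag:
    """Decoded identity of one founder haplotype."""

    source_class: str  # "wild" or "elite"
    founder_id: int
    founder_strand: int


def wild_origin_id(founder_id: int, strand: int) -> int:
    return 2 * founder_id + strand


def elite_origin_id(founder_id: int, strand: int) -> int:
    return -(2 * founder_id + strand + 1)


def decode_origin(origin_id: int) -> OriginTag:
    if origin_id >= 0:
        return OriginTag("wild", origin_id // 2, origin_id % 2)
    k = -origin_id - 1
    return OriginTag("elite", k // 2, k % 2)


class Gamete(NamedTuple):
    """One recombined haplotype: alleles plus inherited origin ids."""

    alleles: np.ndarray  # (M,) uint8
    origins: np.ndarray  # (M,) int32


@dataclass
class DiploidGenome:
    """Two phased haplotypes over a shared marker index.

    ``alleles`` has shape (2, M) with biallelic codes {0, 1}; ``origins`` has
    the same shape and holds founder-haplotype ids.
    """

    alleles: np.ndarray
    origins: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.origins = np.asarray(self.origins, dtype=np.int32)
        if self.alleles.ndim != 2 or self.alleles.shape[0] != 2:
            raise GenomeShapeError("alleles must have shape (2, n_markers)")
        if self.origins.shape != self.alleles.shape:
            raise GenomeShapeError("origins must match alleles in shape")

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def dosage(self) -> np.ndarray:
        """Origin-blind 0/1/2 dosage of the '1' allele, as scored by an array."""
        return self.alleles.sum(axis=0, dtype=np.int16)

    def heterozygosity(self) -> float:
        """Fraction of markers with two different alleles."""
        return float(np.mean(self.alleles[0] != self.alleles[1]))

    def haplotype(self, strand: int) -> Gamete:
        return Gamete(self.alleles[strand].copy(), self.origins[strand].copy())


def _check_width(g: DiploidGenome, gmap: GeneticMap) -> None:
    if g.n_markers != gmap.n_markers:
        raise GenomeShapeError(
            f"genome width {g.n_markers} != map width {gmap.n_markers}"
        )


def meiosis(parent: DiploidGenome, gmap: GeneticMap, rng: np.random.Generator) -> Gamete:
    """Draw one gamete from ``parent`` under the Haldane crossover model.

    Each chromosome starts on a random parental strand and switches strand at
    every crossover; both the allele and the origin id at each marker are
    copied from the active strand.
    """
    _check_width(parent, gmap)
    out_a = np.empty(parent.n_markers, dtype=np.uint8)
    out_o = np.empty(parent.n_markers, dtype=np.int32)
    for c in range(gmap.n_chromosomes):
        sl = gmap.chrom_slice(c)
        length = gmap.chrom_length(c)
        start = int(rng.integers(2))
        n_co = int(rng.poisson(length / 100.0)) if length > 0 else 0
        if n_co:
            origin0 = gmap.pos[sl.start]
            cuts = np.sort(rng.uniform(0.0, length, n_co))
            crossed = np.searchsorted(cuts, gmap.pos[sl] - origin0, side="right")
            strand = (start + crossed) % 2
        else:
            strand = np.full(sl.stop - sl.start, start)
        idx = np.arange(sl.start, sl.stop)
        out_a[sl] = parent.alleles[strand, idx]
        out_o[sl] = parent.origins[strand, idx]
    return Gamete(out_a, out_o)


def gamete_batch(
    parent: DiploidGenome, gmap: GeneticMap, rng: np.random.Generator, n: int
) -> Gamete:
    """Draw ``n`` independent gametes from ``parent`` at once.

    Same crossover model as :func:`meiosis`, vectorized over gametes: all
    Poisson counts, crossover positions and start strands for one chromosome
    are drawn in single batched calls.  Returns a :class:`Gamete` whose
    arrays have shape (n, M).  Used for testcross progeny simulation, where
    hundreds of gametes come from the same pre-testcross genome.
    """
    _check_width(parent, gmap)
    out_a = np.empty((n, parent.n_markers), dtype=np.uint8)
    out_o = np.empty((n, parent.n_markers), dtype=np.int32)
    for c in range(gmap.n_chromosomes):
        sl = gmap.chrom_slice(c)
        length = gmap.chrom_length(c)
        pos_rel = gmap.pos[sl] - gmap.pos[sl.start]
        start = rng.integers(0, 2, size=n)
        n_co = rng.poisson(length / 100.0, size=n) if length > 0 else np.zeros(n, int)
        kmax = int(n_co.max())
        if kmax == 0:
            strand = np.broadcast_to(start[:, None], (n, pos_rel.size))
        else:
            total = int(n_co.sum())
            u = rng.uniform(0.0, length, total)
            rows = np.repeat(np.arange(n), n_co)
            cols = np.arange(total) - np.repeat(np.cumsum(n_co) - n_co, n_co)
            cuts = np.full((n, kmax), np.inf)
            cuts[rows, cols] = u
            cuts.sort(axis=1)
            crossed = (cuts[:, :, None] <= pos_rel[None, None, :]).sum(axis=1)
            strand = (start[:, None] + crossed) % 2
        pick1 = strand == 1
        out_a[:, sl] = np.where(pick1, parent.alleles[1, sl], parent.alleles[0, sl])
        out_o[:, sl] = np.where(pick1, parent.origins[1, sl], parent.origins[0, sl])
    return Gamete(out_a, out_o)


def cross(
    a: DiploidGenome, b: DiploidGenome, gmap: GeneticMap, rng: np.random.Generator
) -> DiploidGenome:
    """Offspring of ``a`` x ``b``: one independent gamete from each parent."""
    ga = meiosis(a, gmap, rng)
    gb = meiosis(b, gmap, rng)
    return DiploidGenome(
        np.stack([ga.alleles, gb.alleles]), np.stack([ga.origins, gb.origins])
    )


def self_(a: DiploidGenome, gmap: GeneticMap, rng: np.random.Generator) -> DiploidGenome:
    """Self-fertilization: two independent gametes from the same parent."""
    return cross(a, a, gmap, rng)


def make_dh(a: DiploidGenome, gmap: GeneticMap, rng: np.random.Generator) -> DiploidGenome:
    """Doubled haploid: a single gamete duplicated onto both strands."""
    g = meiosis(a, gmap, rng)
    return DiploidGenome(
        np.stack([g.alleles, g.alleles.copy()]),
        np.stack([g.origins, g.origins.copy()]),
    )


def wild_genome_fraction(g: DiploidGenome) -> float:
    """Fraction of all allele copies that are of wild origin (in [0, 1])."""
    return float(np.mean(g.origins >= 0))


def wild_haplotype_coverage(g: DiploidGenome) -> float:
    """Mean per-locus count of *distinct* wild founder haplotypes (in [0, 2]).

    A wild individual itself scores 2 (two distinct founder haplotypes at
    every locus); its doubled haploid scores 1; a backcross-derived DH scores
    0.25 in expectation.
    """
    o0, o1 = g.origins
    w0 = o0 >= 0
    w1 = o1 >= 0
    distinct = w0.astype(np.int8) + w1.astype(np.int8)
    distinct -= (w0 & w1 & (o0 == o1)).astype(np.int8)
    return float(distinct.mean())
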