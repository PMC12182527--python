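"""Synthetic founder material: wild populations, an elite line, a tester.

The generator emulates the statistical fingerprint of genotyped natural
populations of an outcrossing crop wild relative: an L-shaped minor-allele
frequency spectrum, per-individual heterozygosity far below the outbred
maximum, and linkage disequilibrium that is strong between tightly linked
markers but decays within a few cM.

Per-marker allele frequencies are drawn from a Beta law calibrated to the
requested mean MAF and heterozygosity; founder haplotypes start in linkage
equilibrium and LD is then built by a random-mating burn-in at a reduced
effective size, so that r^2 between markers decays with map distance roughly
as drift-recombination equilibrium predicts (r^2 ~ 1/(1 + 8*Ne*c)).  Because
drift during the burn-in erodes diversity, the initial Beta law is inflated
and re-calibrated in a short loop until the realized population statistics
meet the requested targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genmap import GeneticMap
from .genome import DiploidGenome, cross, elite_origin_id, wild_origin_id

__all__ = [
    "CalibrationError",
    "FounderPopulation",
    "PopulationSpec",
    "generate_elite_line",
    "generate_tester",
    "generate_wild_population",
]

_MAX_BETA_CONCENTRATION = 50.0
_CALIBRATION_TOL = 0.015
_MAX_CALIBRATION_ROUNDS = 4


class CalibrationError(ValueError):
    """Raised when the requested population statistics are unattainable."""


@dataclass(frozen=True)
class PopulationSpec:
    """Target statistics and size of one synthetic wild population.

    ``burn_in_size`` is the effective (census) size during the random-mating
    burn-in; the final ``n_individuals`` are produced by one further round of
    random mating among the burn-in survivors.  A small burn-in size is what
    creates haploblock sharing and usable marker-QTL LD.
    """

    n_individuals: int = 1000
    n_markers: int = 16076
    n_chromosomes: int = 9
    total_map_length: float = 625.0
    target_heterozygosity: float = 0.14
    maf_mean: float = 0.105
    burn_in_generations: int = 60
    burn_in_size: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < self.n_chromosomes or self.n_chromosomes < 1:
            raise CalibrationError("need n_markers >= n_chromosomes >= 1")
        if self.total_map_length <= 0:
            raise CalibrationError("total_map_length must be positive")
        if not 0 < self.maf_mean <= 0.5:
            raise CalibrationError("maf_mean must lie in (0, 0.5]")
        if not 0 <= self.target_heterozygosity <= 1:
            raise CalibrationError("target_heterozygosity must lie in [0, 1]")
        if self.n_individuals < 2 or self.burn_in_size < 2:
            raise CalibrationError("population sizes must be at least 2")
        if self.burn_in_generations < 0:
            raise CalibrationError("burn_in_generations must be >= 0")
        hmax = 2 * self.maf_mean * (1 - self.maf_mean) * 1.05
        if self.target_heterozygosity > hmax:
            raise CalibrationError(
                f"target heterozygosity {self.target_heterozygosity:.3f} exceeds "
                f"the maximum ~{hmax:.3f} attainable at mean MAF {self.maf_mean:.3f}"
            )
        # under Hardy-Weinberg, 2q(1-q) >= q for q <= 1/2, so the mean
        # per-individual heterozygosity cannot fall below the mean MAF
        if self.target_heterozygosity < self.maf_mean * 0.95:
            raise CalibrationError(
                f"target heterozygosity {self.target_heterozygosity:.3f} lies below "
                f"the Hardy-Weinberg lower bound (~mean MAF {self.maf_mean:.3f})"
            )


@dataclass
class FounderPopulation:
    """An ordered collection of phased, origin-tagged diploid genomes."""

    genomes: list[DiploidGenome]
    gmap: GeneticMap
    population_id: str = "pop"

    def __post_init__(self) -> None:
        widths = {g.n_markers for g in self.genomes}
        if widths and widths != {self.gmap.n_markers}:
            raise ValueError("all genomes must match the map width")

    @property
    def n_individuals(self) -> int:
        return len(self.genomes)

    def haplotype_matrix(self) -> np.ndarray:
        """(2N, M) matrix of phased haplotype alleles."""
        return np.vstack([g.alleles for g in self.genomes])

    def dosage_matrix(self) -> np.ndarray:
        """(N, M) matrix of 0/1/2 dosages."""
        return np.vstack([g.dosage() for g in self.genomes])

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the '1' allele per marker."""
        return self.haplotype_matrix().mean(axis=0)

    def mean_heterozygosity(self) -> float:
        return float(np.mean([g.heterozygosity() for g in self.genomes]))

    def mean_maf(self) -> float:
        p = self.allele_frequency()
        return float(np.minimum(p, 1 - p).mean())

    def subset(self, indices, population_id: str | None = None) -> "FounderPopulation":
        return FounderPopulation(
            [self.genomes[i] for i in indices],
            self.gmap,
            population_id or self.population_id,
        )


def _beta_params(mean_maf: float, mean_het: float) -> tuple[float, float]:
    """Solve Beta(a, b) on [0, 1] for MAF = x/2 hitting the two means.

    With x ~ Beta(a, b), mu = E[x] = 2*mean_maf and the expected
    Hardy-Weinberg heterozygosity E[2q(1-q)] for q = x/2 equals
    mu - mu^2/2 - mu(1-mu)/(2(s+1)) where s = a + b, which pins down s.
    """
    mu = min(2 * mean_maf, 0.999)
    hmax = mu - mu * mu / 2
    gap = hmax - mean_het
    if gap <= hmax / (_MAX_BETA_CONCENTRATION + 1):
        s = _MAX_BETA_CONCENTRATION
    else:
        s = max(mu * (1 - mu) / (2 * gap) - 1, 0.02)
    return mu * s, (1 - mu) * s


def _random_mating(
    parents: list[DiploidGenome],
    n_children: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> list[DiploidGenome]:
    n = len(parents)
    children = []
    for _ in range(n_children):
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        if j >= i:  # outcrossing: no selfing during burn-in
            j += 1
        children.append(cross(parents[i], parents[j], gmap, rng))
    return children


def _simulate_population(
    spec: PopulationSpec, gmap: GeneticMap, p: np.ndarray, rng: np.random.Generator
) -> list[DiploidGenome]:
    n_e = min(spec.burn_in_size, spec.n_individuals) if spec.burn_in_generations else spec.n_individuals
    zeros = np.zeros((2, spec.n_markers), dtype=np.int32)
    pop = [
        DiploidGenome((rng.random((2, spec.n_markers)) < p).astype(np.uint8), zeros)
        for _ in range(n_e)
    ]
    for _ in range(spec.burn_in_generations):
        pop = _random_mating(pop, n_e, gmap, rng)
    if n_e != spec.n_individuals:
        pop = _random_mating(pop, spec.n_individuals, gmap, rng)
    return pop


def generate_wild_population(
    spec: PopulationSpec, gmap: GeneticMap, population_id: str = "wild"
) -> FounderPopulation:
    """Generate one wild population matching ``spec`` on ``gmap``.

    The realized mean per-individual heterozygosity is required to fall within
    3 percentage points of the target; the generator re-calibrates its initial
    allele-frequency law (up to a few regenerations) to get there, because the
    burn-in's genetic drift removes diversity in a way that depends on the
    whole frequency spectrum.  Deterministic for a fixed ``spec.seed``.
    """
    if gmap.n_markers != spec.n_markers:
        raise CalibrationError(
            f"map width {gmap.n_markers} != spec.n_markers {spec.n_markers}"
        )
    rng = np.random.default_rng(spec.seed)

    # expected survival of heterozygosity through drift, used as the starting
    # inflation of the initial frequency law
    n_e = min(spec.burn_in_size, spec.n_individuals)
    decay = (1 - 1 / (2 * n_e)) ** (spec.burn_in_generations + 1) if spec.burn_in_generations else 1.0
    het_work = min(spec.target_heterozygosity / decay, 0.45)
    maf_work = min(spec.maf_mean * (1 + (1 - decay)), 0.5)

    best: tuple[float, list[DiploidGenome]] | None = None
    for _ in range(_MAX_CALIBRATION_ROUNDS):
        a, b = _beta_params(maf_work, het_work)
        q = 0.5 * rng.beta(a, b, spec.n_markers)
        flip = rng.random(spec.n_markers) < 0.5
        p = np.where(flip, q, 1 - q)
        pop = _simulate_population(spec, gmap, p, rng)

        haps = np.array([g.alleles for g in pop])  # (N, 2, M)
        het = float(np.mean(haps[:, 0, :] != haps[:, 1, :]))
        freq = haps.reshape(-1, spec.n_markers).mean(axis=0)
        maf = float(np.minimum(freq, 1 - freq).mean())
        err = max(
            abs(het - spec.target_heterozygosity), abs(maf - spec.maf_mean)
        )
        if best is None or err < best[0]:
            best = (err, pop)
        if err <= _CALIBRATION_TOL:
            break
        if het > 1e-9:
            het_work = min(max(het_work * spec.target_heterozygosity / het, 1e-4), 0.45)
        if maf > 1e-9:
            maf_work = min(max(maf_work * spec.maf_mean / maf, 1e-4), 0.5)

    assert best is not None
    err, pop = best
    if err > 0.03:
        raise CalibrationError(
            f"could not calibrate population statistics (residual error {err:.3f}); "
            "the requested heterozygosity/MAF combination may be unattainable "
            "under the configured burn-in"
        )

    genomes = [
        DiploidGenome(
            g.alleles,
            np.stack(
                [
                    np.full(spec.n_markers, wild_origin_id(i, 0), dtype=np.int32),
                    np.full(spec.n_markers, wild_origin_id(i, 1), dtype=np.int32),
                ]
            ),
        )
        for i, g in enumerate(pop)
    ]
    return FounderPopulation(genomes, gmap, population_id)


def generate_elite_line(
    gmap: GeneticMap,
    het_fraction: float = 0.01,
    seed: int | None = None,
    allele_freq: np.ndarray | float | None = None,
    founder_id: int = 0,
) -> DiploidGenome:
    """An almost fully inbred elite line (default <= 1% heterozygous markers).

    Alleles are drawn marker-wise with probability ``allele_freq`` (default
    0.5; pass the wild population's allele frequencies to make the elite line
    carry mostly population-major alleles).  Exactly
    ``floor(het_fraction * M)`` randomly chosen markers are made heterozygous
    (floor, so the realized fraction never exceeds the bound).  All origin
    tags are elite.
    """
    if not 0 <= het_fraction <= 1:
        raise ValueError("het_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    p = 0.5 if allele_freq is None else allele_freq
    hap = (rng.random(m) < p).astype(np.uint8)
    hap2 = hap.copy()
    n_het = int(np.floor(het_fraction * m))
    if n_het:
        loci = rng.choice(m, size=n_het, replace=False)
        hap2[loci] ^= 1
    origins = np.stack(
        [
            np.full(m, elite_origin_id(founder_id, 0), dtype=np.int32),
            np.full(m, elite_origin_id(founder_id, 1), dtype=np.int32),
        ]
    )
    return DiploidGenome(np.stack([hap, hap2]), origins)


def generate_tester(
    gmap: GeneticMap,
    elite: DiploidGenome,
    divergence: float = 0.2444,
    seed: int | None = None,
) -> DiploidGenome:
    """A two-way hybrid tester from the elite pool.

    Modelled as the F1 of two homozygous within-pool lines: one strand copies
    the elite line's first haplotype, the other differs from it at exactly
    ``round(divergence * M)`` randomly chosen markers, so the tester's
    heterozygosity equals ``divergence`` (default 24.44%).  Both strands carry
    elite origin tags (the tester contributes no wild genome).
    """
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    hap_a = elite.alleles[0].copy()
    hap_b = hap_a.copy()
    n_diff = int(round(divergence * m))
    if n_diff:
        loci = rng.choice(m, size=n_diff, replace=False)
        hap_b[loci] ^= 1
    origins = np.stack(
        [
            np.full(m, elite_origin_id(1, 0), dtype=np.int32),
            np.full(m, elite_origin_id(2, 0), dtype=np.int32),
        ]
    )
    return DiploidGenome(np.stack([hap_a, hap_b]), origins)
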