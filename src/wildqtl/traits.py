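"""Quantitative trait architecture: QTL, wild background, elite infinitesimal.

Effects are additive, non-negative and attach to individual allele *copies*
according to their origin class:

* **wild QTL** — ``n_qtl`` markers drawn at random from those polymorphic in
  the selected wild subset; one of the two alleles (chosen uniformly) carries
  an effect, the other 0.  Effects follow a geometric series
  ``e_i = emax * (1/2)**(i-1)`` with ``emax`` defaulting to 5% of the elite
  positive-effect total.
* **wild background** — the remaining wild performance: a total of
  ``E/2 - sum(QTL effects)`` spread equally over all non-QTL markers,
  attached to wild-origin copies of either allele.
* **elite infinitesimal** — every marker carries ``E/M`` on elite-origin
  copies of either allele, so a fully elite haplotype sums to ``E``.

``E`` is the haploid elite total (100 arbitrary trait units by default); the
haploid wild total is exactly ``E/2``, i.e. elite material performs twice as
well as wild material.  Phenotypes are entry means plus one Gaussian noise
draw per entry, with the noise variance set from the realized genetic
variance and the chosen broad-sense heritability h^2 = v_g / (v_g + v_e).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .designs import MappingEntry, MappingPopulation
from .genmap import GeneticMap
from .genome import DiploidGenome

__all__ = [
    "DegenerateVarianceError",
    "EffectTable",
    "PhenotypeModel",
    "QTLConfig",
    "TraitArchitectureError",
    "assign_elite_effects",
    "assign_qtl_effects",
    "assign_wild_background",
    "build_effect_table",
    "entry_value_and_phenotype",
    "gamete_values",
    "genotypic_value",
    "qtl_allele_frequencies",
    "simulate_phenotypes",
    "value_entries",
]

DEFAULT_ELITE_TOTAL = 100.0
DEFAULT_EMAX_PERCENT = 5.0


class TraitArchitectureError(ValueError):
    """Raised for inconsistent effect architectures."""


class DegenerateVarianceError(ValueError):
    """Raised when the realized genetic variance is zero."""


@dataclass(frozen=True)
class QTLConfig:
    """Ground truth of the simulated QTL."""

    qtl_markers: np.ndarray  # (n_qtl,) global marker indices, effect-size order
    qtl_alleles: np.ndarray  # (n_qtl,) allele in {0,1} carrying the effect
    effects: np.ndarray  # (n_qtl,) trait units, geometric series
    emax_percent: float

    @property
    def n_qtl(self) -> int:
        return self.qtl_markers.size

    def effect_percents(self, elite_total: float) -> np.ndarray:
        """Effects as percent of the elite positive-effect total."""
        return 100.0 * self.effects / elite_total


@dataclass
class EffectTable:
    """Per-marker, per-(allele, origin-class) additive effects.

    ``wild`` and ``elite`` have shape (2, M): row ``a`` is the effect carried
    by a copy of allele ``a`` of that origin class.
    """

    wild: np.ndarray
    elite: np.ndarray
    elite_total: float

    @property
    def n_markers(self) -> int:
        return self.wild.shape[1]

    def to_frame(self, gmap: GeneticMap):
        """Long-format audit table (marker, allele, origin, effect)."""
        import pandas as pd

        names = gmap.marker_names
        rows = []
        for origin, eff in (("wild", self.wild), ("elite", self.elite)):
            for a in (0, 1):
                nz = np.nonzero(eff[a])[0]
                rows.append(
                    pd.DataFrame(
                        {
                            "marker_id": [names[j] for j in nz],
                            "allele": a,
                            "origin": origin,
                            "effect": eff[a, nz],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class PhenotypeModel:
    """Broad-sense heritability and the variance components it implies."""

    h2: float
    v_g: float
    v_e: float

    @classmethod
    def from_genetic_variance(cls, h2: float, v_g: float) -> "PhenotypeModel":
        if not 0 < h2 <= 1:
            raise ValueError("h2 must lie in (0, 1]")
        if v_g <= 0:
            raise DegenerateVarianceError(
                "genetic variance across entries is zero; phenotype scaling undefined"
            )
        return cls(h2=h2, v_g=v_g, v_e=v_g * (1 - h2) / h2)


def assign_elite_effects(gmap: GeneticMap, elite_total: float = DEFAULT_ELITE_TOTAL) -> np.ndarray:
    """Infinitesimal elite effects: ``E/M`` per marker, either allele; (2, M)."""
    if elite_total <= 0:
        raise TraitArchitectureError("elite_total must be positive")
    return np.full((2, gmap.n_markers), elite_total / gmap.n_markers)


def assign_qtl_effects(
    wild_subset_dosages: np.ndarray,
    n_qtl: int,
    rng: np.random.Generator,
    emax_percent: float = DEFAULT_EMAX_PERCENT,
    elite_total: float = DEFAULT_ELITE_TOTAL,
) -> QTLConfig:
    """Draw QTL markers, effect alleles and geometric effects.

    ``wild_subset_dosages`` is the (N, M) dosage matrix of the selected wild
    individuals; QTL markers are drawn (distinct, without replacement) from
    markers polymorphic there, and the effect allele is chosen uniformly from
    the two alleles present.
    """
    freq = wild_subset_dosages.mean(axis=0) / 2.0
    polymorphic = np.nonzero((freq > 0) & (freq < 1))[0]
    if polymorphic.size < n_qtl:
        raise TraitArchitectureError(
            f"only {polymorphic.size} polymorphic markers for {n_qtl} QTL"
        )
    markers = rng.choice(polymorphic, size=n_qtl, replace=False)
    alleles = rng.integers(0, 2, size=n_qtl)
    emax = emax_percent / 100.0 * elite_total
    effects = emax * 0.5 ** np.arange(n_qtl)
    return QTLConfig(
        qtl_markers=np.asarray(markers),
        qtl_alleles=np.asarray(alleles, dtype=np.int8),
        effects=effects,
        emax_percent=emax_percent,
    )


def assign_wild_background(
    gmap: GeneticMap, qtl: QTLConfig, elite_total: float = DEFAULT_ELITE_TOTAL
) -> np.ndarray:
    """Background effect per non-QTL marker (scalar array (M,), either allele).

    The background total is ``E/2 - sum(QTL effects)``; QTL markers carry no
    background.
    """
    qtl_sum = float(qtl.effects.sum())
    if qtl_sum >= elite_total / 2:
        raise TraitArchitectureError(
            f"QTL effects ({qtl_sum}) exhaust the wild total ({elite_total / 2})"
        )
    n_bg = gmap.n_markers - qtl.n_qtl
    if n_bg == 0:
        raise TraitArchitectureError("no non-QTL markers left for background")
    bg = np.full(gmap.n_markers, (elite_total / 2 - qtl_sum) / n_bg)
    bg[qtl.qtl_markers] = 0.0
    return bg


def build_effect_table(
    gmap: GeneticMap,
    wild_subset_dosages: np.ndarray,
    n_qtl: int,
    rng: np.random.Generator,
    emax_percent: float = DEFAULT_EMAX_PERCENT,
    elite_total: float = DEFAULT_ELITE_TOTAL,
) -> tuple[EffectTable, QTLConfig]:
    """Combine the three effect files into one table (redrawn per run)."""
    qtl = assign_qtl_effects(
        wild_subset_dosages, n_qtl, rng, emax_percent=emax_percent, elite_total=elite_total
    )
    bg = assign_wild_background(gmap, qtl, elite_total)
    wild = np.broadcast_to(bg, (2, gmap.n_markers)).copy()
    wild[qtl.qtl_alleles, qtl.qtl_markers] += qtl.effects
    wild[1 - qtl.qtl_alleles, qtl.qtl_markers] = 0.0
    elite = assign_elite_effects(gmap, elite_total)
    return EffectTable(wild=wild, elite=elite, elite_total=elite_total), qtl


def gamete_values(
    alleles: np.ndarray, origins: np.ndarray, effects: EffectTable
) -> np.ndarray:
    """Haploid value of each gamete in a batch: sum of per-copy effects.

    ``alleles``/``origins`` have shape (n, M).  Genotypic values are additive
    over allele copies, so a diploid's value is the sum of its two gametes'
    values; this is what makes streaming testcross valuation cheap.
    """
    idx = np.arange(alleles.shape[1])
    wild_v = effects.wild[alleles, idx]
    elite_v = effects.elite[alleles, idx]
    return np.where(origins >= 0, wild_v, elite_v).sum(axis=1)


def genotypic_value(g: DiploidGenome, effects: EffectTable) -> float:
    """Sum of per-copy effects over both haplotypes and all markers."""
    if g.n_markers != effects.n_markers:
        raise TraitArchitectureError("genome and effect table widths differ")
    idx = np.arange(g.n_markers)
    total = 0.0
    for s in (0, 1):
        wild_mask = g.origins[s] >= 0
        alleles = g.alleles[s]
        total += float(
            np.where(wild_mask, effects.wild[alleles, idx], effects.elite[alleles, idx]).sum()
        )
    return total


def value_entries(mpop: MappingPopulation, effects: EffectTable) -> np.ndarray:
    """Fill each entry's genotypic value (mean over its testcross progeny)."""
    values = np.empty(mpop.n_entries)
    for i, entry in enumerate(mpop.entries):
        if not entry.progeny:
            raise TraitArchitectureError(
                f"entry {entry.wild_parent_id} has no progeny to average over"
            )
        vals = [genotypic_value(p, effects) for p in entry.progeny]
        entry.genotypic_value = float(np.mean(vals))
        values[i] = entry.genotypic_value
    return values


def entry_value_and_phenotype(
    entry: MappingEntry,
    effects: EffectTable,
    model: PhenotypeModel,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Entry-mean genotypic value plus one noise draw at the model's v_e."""
    if not entry.progeny:
        raise TraitArchitectureError("entry has no progeny")
    value = float(np.mean([genotypic_value(p, effects) for p in entry.progeny]))
    phenotype = value + rng.normal(0.0, np.sqrt(model.v_e)) if model.v_e > 0 else value
    entry.genotypic_value = value
    entry.phenotype = float(phenotype)
    return value, float(phenotype)


def simulate_phenotypes(
    mpop: MappingPopulation,
    h2: float,
    rng: np.random.Generator,
    values: np.ndarray | None = None,
) -> tuple[np.ndarray, PhenotypeModel]:
    """Phenotypes for every entry at heritability ``h2``.

    ``v_g`` is the realized variance of entry genotypic values across the
    mapping population (recomputed per run per design); ``v_e`` follows from
    h^2 = v_g / (v_g + v_e).  One independent noise draw per entry.
    """
    if values is None:
        if any(e.genotypic_value is None for e in mpop.entries):
            raise TraitArchitectureError("entries have no genotypic values yet")
        values = np.array([e.genotypic_value for e in mpop.entries], dtype=float)
    v_g = float(np.var(values, ddof=1))
    model = PhenotypeModel.from_genetic_variance(h2, v_g)
    noise = rng.normal(0.0, np.sqrt(model.v_e), size=values.size) if model.v_e > 0 else 0.0
    phenotypes = values + noise
    for e, y in zip(mpop.entries, phenotypes):
        e.phenotype = float(y)
    return phenotypes, model


def qtl_allele_frequencies(qtl: QTLConfig, wild_subset_dosages: np.ndarray) -> np.ndarray:
    """Frequency of each QTL's effect allele among the selected wilds."""
    freq1 = wild_subset_dosages[:, qtl.qtl_markers].mean(axis=0) / 2.0
    return np.where(qtl.qtl_alleles == 1, freq1, 1 - freq1)
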