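"""Factorial experiment orchestration: designs x h2 x n_QTL x replicates.

One *run* is a single genetic realization: QTL are drawn fresh, the mapping
population for one crossing design is built from the selected wild subset,
entry genotypic values are computed, and then for every heritability on the
grid an independent noise draw produces phenotypes that are scanned and
evaluated.  Sharing the genetic realization across the h2 grid isolates the
heritability effect; everything else is independent between runs.

Sub-seeds are derived deterministically from the master seed and the run
coordinates (population, design, n_qtl, replicate), so results are invariant
to execution order and reproducible end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .assoc import fit_polygenic, kinship_from_genotypes, scan
from .designs import DESIGN_IDS, MappingEntry, MappingPopulation, pre_testcross_genome
from .genome import gamete_batch
from .evaluate import (
    DEFAULT_NEGLOG10_THRESHOLD,
    adjust_fdr,
    call_qtl_regions,
    call_significant,
    evaluate,
)
from .genmap import GeneticMap, generate_genetic_map
from .genome import DiploidGenome
from .subset import build_catalog, select_diverse_subset
from .synthetic import (
    FounderPopulation,
    PopulationSpec,
    generate_elite_line,
    generate_tester,
    generate_wild_population,
)
from .traits import (
    DEFAULT_ELITE_TOTAL,
    DEFAULT_EMAX_PERCENT,
    build_effect_table,
    gamete_values,
    qtl_allele_frequencies,
    simulate_phenotypes,
)

__all__ = [
    "ExperimentConfig",
    "aggregate",
    "aggregate_by_allele_frequency",
    "prepare_population",
    "run_experiment",
    "scan_table",
]

logger = logging.getLogger("wildqtl")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full factorial experiment definition.

    ``population_specs`` describes synthetic populations; alternatively
    pre-built :class:`FounderPopulation` objects (e.g. read from VCF) can be
    passed directly to :func:`run_experiment`.
    """

    population_specs: tuple[PopulationSpec, ...] = (PopulationSpec(),)
    n_select: int = 300
    n_seed_select: int = 25
    designs: tuple[str, ...] = DESIGN_IDS
    h2_grid: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)
    n_qtl_grid: tuple[int, ...] = (1, 2, 5)
    n_reps: int = 50
    n_offspring: int = 594
    emax_percent: float = DEFAULT_EMAX_PERCENT
    elite_total: float = DEFAULT_ELITE_TOTAL
    elite_het_fraction: float = 0.01
    tester_divergence: float = 0.2444
    threshold_neglog10: float = DEFAULT_NEGLOG10_THRESHOLD
    threshold_on_raw_p: bool = False
    kinship_method: str = "freq"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.designs and self.h2_grid and self.n_qtl_grid):
            raise ValueError("designs, h2_grid and n_qtl_grid must be nonempty")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        unknown = set(self.designs) - set(DESIGN_IDS)
        if unknown:
            raise ValueError(f"unknown designs: {sorted(unknown)}")


def _sub_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=tuple(key))


def prepare_population(
    config: ExperimentConfig,
    pop_index: int,
    population: FounderPopulation | None = None,
) -> tuple[FounderPopulation, list[DiploidGenome], DiploidGenome, DiploidGenome]:
    """Generate/select one population and its elite and tester genotypes."""
    spec = config.population_specs[pop_index % len(config.population_specs)]
    if population is None:
        seed_int = int(_sub_seed(config.seed, 0, pop_index).generate_state(1)[0] % 2**31)
        spec = replace(spec, seed=seed_int)
        population = generate_wild_population(spec, _map_for(spec), f"pop{pop_index}")
    gmap = population.gmap
    n_select = min(config.n_select, population.n_individuals)
    catalog = build_catalog(population)
    selected = select_diverse_subset(
        population, catalog, n_total=n_select, n_seed=config.n_seed_select
    )
    wilds = [population.genomes[i] for i in selected]
    elite_seed = int(_sub_seed(config.seed, 1, pop_index).generate_state(1)[0] % 2**31)
    tester_seed = int(_sub_seed(config.seed, 2, pop_index).generate_state(1)[0] % 2**31)
    freq = population.allele_frequency()
    elite = generate_elite_line(
        gmap, config.elite_het_fraction, seed=elite_seed, allele_freq=freq
    )
    tester = generate_tester(gmap, elite, config.tester_divergence, seed=tester_seed)
    return population, wilds, elite, tester


def _map_for(spec: PopulationSpec) -> GeneticMap:
    return generate_genetic_map(
        spec.n_markers, spec.n_chromosomes, spec.total_map_length, "even"
    )


def _build_valued_population(
    design: str,
    wilds: list[DiploidGenome],
    elite: DiploidGenome,
    tester: DiploidGenome,
    n_offspring: int,
    gmap: GeneticMap,
    effects,
    rng: np.random.Generator,
) -> MappingPopulation:
    """Build entries, valuing testcross progeny in a streaming batch.

    Genotypic values are additive over allele copies, so each progeny's
    value is the sum of its two gamete values; progeny genomes are never
    retained (at full scale they would not fit in memory).
    """
    entries = []
    for i, wild in enumerate(wilds):
        pre = pre_testcross_genome(design, wild, elite, gmap, rng)
        g_pre = gamete_batch(pre, gmap, rng, n_offspring)
        g_tes = gamete_batch(tester, gmap, rng, n_offspring)
        values = gamete_values(g_pre.alleles, g_pre.origins, effects) + gamete_values(
            g_tes.alleles, g_tes.origins, effects
        )
        entries.append(
            MappingEntry(
                wild_parent_id=f"w{i}",
                pre_testcross=pre,
                scan_genotype=pre.dosage(),
                progeny=[],
                n_progeny=n_offspring,
                genotypic_value=float(values.mean()),
            )
        )
    return MappingPopulation(design, entries, gmap)


def run_experiment(
    config: ExperimentConfig,
    populations: list[FounderPopulation] | None = None,
) -> pd.DataFrame:
    """Run the full factorial experiment and return one row per run x h2.

    Any failure inside a run (e.g. degenerate genetic variance) is logged with
    its coordinates and recorded as a failed row with TPR 0 and FD 1, matching
    the 100%-FD convention for runs without detection.
    """
    n_pops = len(populations) if populations is not None else len(config.population_specs)
    rows: list[dict] = []
    for pop_idx in range(n_pops):
        pop_given = populations[pop_idx] if populations is not None else None
        population, wilds, elite, tester = prepare_population(config, pop_idx, pop_given)
        gmap = population.gmap
        subset_dosages = np.vstack([w.dosage() for w in wilds])
        for design in config.designs:
            d_idx = DESIGN_IDS.index(design)
            for n_qtl in config.n_qtl_grid:
                for rep in range(config.n_reps):
                    rows.extend(
                        _run_one(
                            config, population.population_id, pop_idx, design,
                            d_idx, n_qtl, rep, wilds, subset_dosages, elite,
                            tester, gmap,
                        )
                    )
    return pd.DataFrame(rows)


def _run_one(
    config, pop_id, pop_idx, design, d_idx, n_qtl, rep,
    wilds, subset_dosages, elite, tester, gmap,
) -> list[dict]:
    base = {
        "population": pop_id,
        "design": design,
        "n_qtl": n_qtl,
        "rep": rep,
    }
    rows = []
    try:
        ss = _sub_seed(config.seed, 3, pop_idx, d_idx, n_qtl, rep)
        rng_qtl, rng_build = [np.random.default_rng(s) for s in ss.spawn(2)]
        effects, qtl = build_effect_table(
            gmap, subset_dosages, n_qtl, rng_qtl,
            emax_percent=config.emax_percent, elite_total=config.elite_total,
        )
        qtl_freq = qtl_allele_frequencies(qtl, subset_dosages)
        mpop = _build_valued_population(
            design, wilds, elite, tester, config.n_offspring, gmap, effects, rng_build
        )
        scan_g = mpop.scan_matrix()
        kinship = kinship_from_genotypes(scan_g, method=config.kinship_method)
        values = np.array([e.genotypic_value for e in mpop.entries])
        qtl_chrom = gmap.chrom[qtl.qtl_markers]
        qtl_pos = gmap.pos[qtl.qtl_markers]
        for h2_idx, h2 in enumerate(config.h2_grid):
            row = dict(base, h2=h2, failed=False)
            try:
                rng_noise = np.random.default_rng(
                    _sub_seed(config.seed, 4, pop_idx, d_idx, n_qtl, rep, h2_idx)
                )
                phenotypes, model = simulate_phenotypes(mpop, h2, rng_noise, values)
                fit = fit_polygenic(phenotypes, kinship)
                result = scan(scan_g, fit, exclude_markers=qtl.qtl_markers)
                p_for_threshold = (
                    result.p_value if config.threshold_on_raw_p else adjust_fdr(result.p_value)
                )
                sig = call_significant(p_for_threshold, config.threshold_neglog10)
                regions = call_qtl_regions(sig, gmap, adjusted_p=p_for_threshold)
                ev = evaluate(regions, qtl_chrom, qtl_pos)
                row.update(
                    tpr=ev.tpr,
                    fd=ev.fd,
                    n_regions=ev.n_regions,
                    v_g=model.v_g,
                    fitted_heritability=fit.heritability_ratio,
                    qtl_detected=";".join(str(int(d)) for d in ev.detected),
                )
            except Exception:
                logger.exception(
                    "run failed: pop=%s design=%s n_qtl=%d rep=%d h2=%.2f",
                    pop_id, design, n_qtl, rep, h2,
                )
                row.update(
                    tpr=0.0, fd=1.0, n_regions=0, v_g=np.nan,
                    fitted_heritability=np.nan,
                    qtl_detected=";".join("0" * n_qtl), failed=True,
                )
            row.update(
                qtl_freq=";".join(f"{f:.6f}" for f in qtl_freq),
                qtl_effect_percent=";".join(
                    f"{e:.6f}" for e in qtl.effect_percents(config.elite_total)
                ),
            )
            rows.append(row)
    except Exception:
        logger.exception(
            "run failed before scanning: pop=%s design=%s n_qtl=%d rep=%d",
            pop_id, design, n_qtl, rep,
        )
        for h2 in config.h2_grid:
            rows.append(
                dict(
                    base, h2=h2, failed=True, tpr=0.0, fd=1.0, n_regions=0,
                    v_g=np.nan, fitted_heritability=np.nan,
                    qtl_detected=";".join("0" * n_qtl), qtl_freq="", qtl_effect_percent="",
                )
            )
    return rows


def aggregate(table: pd.DataFrame, by: list[str] | tuple[str, ...] = ("design", "h2")) -> pd.DataFrame:
    """Mean TPR/FD (and run count) per group."""
    if table.empty:
        raise ValueError("result table is empty")
    out = (
        table.groupby(list(by), as_index=False)
        .agg(tpr=("tpr", "mean"), fd=("fd", "mean"), n_runs=("tpr", "size"))
    )
    return out


def _explode_qtl(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, r in table.iterrows():
        if not r["qtl_freq"]:
            continue
        freqs = [float(x) for x in str(r["qtl_freq"]).split(";")]
        det = [bool(int(x)) for x in str(r["qtl_detected"]).split(";")]
        effs = [float(x) for x in str(r["qtl_effect_percent"]).split(";")]
        for f, d, e in zip(freqs, det, effs):
            rows.append(
                {
                    "population": r["population"], "design": r["design"],
                    "h2": r["h2"], "n_qtl": r["n_qtl"],
                    "qtl_freq": f, "detected": d, "effect_percent": e,
                }
            )
    return pd.DataFrame(rows)


def aggregate_by_allele_frequency(table: pd.DataFrame, n_select: int) -> pd.DataFrame:
    """Per-QTL detection rate by allele-frequency class.

    Classes are multiples of 1/(2N) for N selected individuals: a QTL allele
    present as k copies among the selected wilds falls in class k/(2N),
    reported in percent.
    """
    long = _explode_qtl(table)
    if long.empty:
        raise ValueError("no per-QTL rows to aggregate")
    two_n = 2 * n_select
    long["freq_class_percent"] = np.round(long["qtl_freq"] * two_n) / two_n * 100.0
    return (
        long.groupby(["design", "h2", "n_qtl", "freq_class_percent"], as_index=False)
        .agg(tpr=("detected", "mean"), n=("detected", "size"))
    )


def scan_table(result, gmap: GeneticMap, adjusted_p: np.ndarray | None = None) -> pd.DataFrame:
    """Serializable per-marker scan table (TSV-friendly)."""
    df = pd.DataFrame(
        {
            "marker_id": gmap.marker_names,
            "chromosome": gmap.chrom + 1,
            "position_cM": gmap.pos,
            "statistic": result.statistic,
            "p": result.p_value,
        }
    )
    df["p_adjusted"] = adjusted_p if adjusted_p is not None else adjust_fdr(result.p_value)
    return df
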