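"""Phased-VCF and genetic-map TSV input/output.

Synthetic populations are written as plain-text phased VCF (GT with ``|``)
plus a three-column genetic map (marker_id, chromosome, position_cM), and real
data in the same two formats can replace them transparently.  VCF POS is an
integer, so cM positions are stored on a 1e4 pseudo-basepair grid in the VCF;
the map TSV keeps the exact cM values and is the authoritative source of
positions when reading.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genmap import GeneticMap
from .genome import DiploidGenome, elite_origin_id, wild_origin_id
from .synthetic import FounderPopulation

__all__ = [
    "read_genetic_map_tsv",
    "read_population_vcf",
    "write_genetic_map_tsv",
    "write_population_vcf",
]

_CM_SCALE = 10_000  # pseudo-bp per cM in VCF POS


def write_genetic_map_tsv(path: str | os.PathLike, gmap: GeneticMap) -> None:
    df = pd.DataFrame(
        {
            "marker_id": gmap.marker_names,
            "chromosome": gmap.chrom + 1,
            "position_cM": gmap.pos,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_genetic_map_tsv(path: str | os.PathLike) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    order = np.lexsort((df["position_cM"].to_numpy(), df["chromosome"].to_numpy()))
    df = df.iloc[order]
    chrom_codes = pd.factorize(df["chromosome"], sort=True)[0]
    return GeneticMap(chrom_codes, df["position_cM"].to_numpy())


def _vcf_positions(gmap: GeneticMap) -> np.ndarray:
    pos = np.empty(gmap.n_markers, dtype=np.int64)
    for c in range(gmap.n_chromosomes):
        sl = gmap.chrom_slice(c)
        p = np.round(gmap.pos[sl] * _CM_SCALE).astype(np.int64) + 1
        p = np.maximum.accumulate(p)  # enforce strictly increasing integers
        while np.any(np.diff(p) <= 0):
            dup = np.where(np.diff(p) <= 0)[0] + 1
            p[dup] = p[dup - 1] + 1
        pos[sl] = p
    return pos


def write_population_vcf(
    path: str | os.PathLike,
    pop: FounderPopulation,
    sample_prefix: str | None = None,
) -> None:
    """Write a plain-text phased VCF (one contig per chromosome)."""
    gmap = pop.gmap
    prefix = sample_prefix or pop.population_id
    samples = [f"{prefix}_{i:04d}" for i in range(pop.n_individuals)]
    names = gmap.marker_names
    pos = _vcf_positions(gmap)
    haps = np.array([g.alleles for g in pop.genomes])  # (N, 2, M)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=wildqtl\n")
        for c in range(gmap.n_chromosomes):
            sl = gmap.chrom_slice(c)
            fh.write(f"##contig=<ID=chr{c + 1},length={int(pos[sl.stop - 1]) + 1}>\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Position in cM">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in range(gmap.n_markers):
            gts = "\t".join(f"{haps[i, 0, j]}|{haps[i, 1, j]}" for i in range(len(samples)))
            fh.write(
                f"chr{int(gmap.chrom[j]) + 1}\t{pos[j]}\t{names[j]}\tA\tT\t.\t.\t"
                f"CM={gmap.pos[j]:.6f}\tGT\t{gts}\n"
            )


def read_population_vcf(
    vcf_path: str | os.PathLike,
    map_path: str | os.PathLike,
    population_id: str = "pop",
    source_class: str = "wild",
) -> FounderPopulation:
    """Read a phased VCF plus its map TSV into a founder population.

    Fresh origin tags are assigned (each individual's two strands become
    distinct founder haplotypes of ``source_class``).
    """
    gmap = read_genetic_map_tsv(map_path)
    vcf = VCF(str(vcf_path))
    n = len(vcf.samples)
    hap0 = []
    hap1 = []
    for variant in vcf:
        g = np.asarray(variant.genotypes, dtype=np.int32)
        if g.shape[1] >= 3 and not np.all(g[:, 2]):
            raise ValueError(f"unphased genotype at {variant.ID}: phased input required")
        hap0.append(g[:, 0])
        hap1.append(g[:, 1])
    vcf.close()
    a0 = np.array(hap0, dtype=np.uint8).T  # (N, M)
    a1 = np.array(hap1, dtype=np.uint8).T
    if a0.shape[1] != gmap.n_markers:
        raise ValueError(
            f"VCF has {a0.shape[1]} markers but map has {gmap.n_markers}"
        )
    make_id = wild_origin_id if source_class == "wild" else elite_origin_id
    genomes = []
    for i in range(n):
        origins = np.stack(
            [
                np.full(gmap.n_markers, make_id(i, 0), dtype=np.int32),
                np.full(gmap.n_markers, make_id(i, 1), dtype=np.int32),
            ]
        )
        genomes.append(DiploidGenome(np.stack([a0[i], a1[i]]), origins))
    return FounderPopulation(genomes, gmap, population_id)
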