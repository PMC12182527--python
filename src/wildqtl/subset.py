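"""Diversity-maximizing subset selection via haploblock rarity and coverage.

A mapping population cannot use every genotyped wild individual, so a subset
(N = 300 in the reference workflow) is chosen to cover as much of the
population's haplotype variation as possible.  Haplotypes are summarized as
*haploblocks*: consecutive non-overlapping windows of ``window_size`` markers
(default 5) that never span chromosome boundaries; a trailing short block at a
chromosome end is kept.  Selection is two-stage:

1. the ``n_seed`` individuals with the highest *rarity score* — the sum over
   both haplotypes and all blocks of 1/(population count of the block
   haplotype) — enter first;
2. the rest are added greedily, each step taking the individual contributing
   the most block haplotypes not yet represented, counting only block
   haplotypes that occur at least twice in the population (singletons are
   likely genotyping/phasing artefacts and never contribute coverage).

Ties are broken by lowest individual index so the selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import FounderPopulation

__all__ = ["HaploblockCatalog", "build_catalog", "rarity_score", "select_diverse_subset"]


@dataclass
class HaploblockCatalog:
    """Per-block haplotype classes and their population counts.

    ``labels[b]`` assigns every one of the 2N haplotypes a class index within
    block ``b`` (offset by ``offsets[b]`` to get a globally unique class id);
    ``counts`` holds the population count of every global class.
    """

    block_slices: list[slice]
    labels: np.ndarray  # (n_blocks, 2N) int32, within-block class index
    offsets: np.ndarray  # (n_blocks,) int64, global id offset per block
    counts: np.ndarray  # (n_classes,) int64
    n_individuals: int
    window_size: int

    @property
    def n_blocks(self) -> int:
        return len(self.block_slices)

    def individual_classes(self, i: int) -> np.ndarray:
        """Sorted unique global class ids carried by individual ``i``."""
        ids = np.concatenate(
            [
                self.labels[:, 2 * i] + self.offsets,
                self.labels[:, 2 * i + 1] + self.offsets,
            ]
        )
        return np.unique(ids)


def build_catalog(pop: FounderPopulation, window_size: int = 5) -> HaploblockCatalog:
    """Tally every block haplotype over all 2N phased haplotypes."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    gmap = pop.gmap
    haps = pop.haplotype_matrix()  # (2N, M)
    block_slices: list[slice] = []
    for c in range(gmap.n_chromosomes):
        sl = gmap.chrom_slice(c)
        for start in range(sl.start, sl.stop, window_size):
            block_slices.append(slice(start, min(start + window_size, sl.stop)))

    labels = np.empty((len(block_slices), haps.shape[0]), dtype=np.int32)
    offsets = np.empty(len(block_slices), dtype=np.int64)
    counts_parts = []
    total = 0
    for b, sl in enumerate(block_slices):
        _, inv, cnt = np.unique(
            haps[:, sl], axis=0, return_inverse=True, return_counts=True
        )
        labels[b] = inv.ravel()
        offsets[b] = total
        counts_parts.append(cnt)
        total += cnt.size
    return HaploblockCatalog(
        block_slices,
        labels,
        offsets,
        np.concatenate(counts_parts),
        pop.n_individuals,
        window_size,
    )


def rarity_score(individual: int, catalog: HaploblockCatalog) -> float:
    """Sum of 1/occurrences over both haplotypes and all blocks."""
    c0 = catalog.counts[catalog.labels[:, 2 * individual] + catalog.offsets]
    c1 = catalog.counts[catalog.labels[:, 2 * individual + 1] + catalog.offsets]
    return float((1.0 / c0).sum() + (1.0 / c1).sum())


def select_diverse_subset(
    pop: FounderPopulation,
    catalog: HaploblockCatalog | None = None,
    n_total: int = 300,
    n_seed: int = 25,
    window_size: int = 5,
) -> list[int]:
    """Choose ``n_total`` individuals: rarity seeds, then greedy coverage.

    Returns individual indices in selection order.  The greedy stage maximizes
    at each step the number of not-yet-covered block haplotypes with
    population count >= 2 carried by the candidate.
    """
    if catalog is None:
        catalog = build_catalog(pop, window_size)
    n = pop.n_individuals
    if not 0 < n_total <= n:
        raise ValueError(f"n_total must lie in [1, {n}]")
    n_seed = min(n_seed, n_total)

    scores = np.array([rarity_score(i, catalog) for i in range(n)])
    # highest rarity first; ties by lowest index (lexsort is stable)
    order = np.lexsort((np.arange(n), -scores))
    selected = list(order[:n_seed])

    if n_total == n:
        remaining_sorted = [i for i in range(n) if i not in set(selected)]
        return selected + remaining_sorted

    eligible = catalog.counts >= 2
    member_classes = [catalog.individual_classes(i) for i in range(n)]
    covered = np.zeros(catalog.counts.size, dtype=bool)
    for i in selected:
        covered[member_classes[i]] = True

    chosen = np.zeros(n, dtype=bool)
    chosen[selected] = True
    while len(selected) < n_total:
        best_i = -1
        best_gain = -1
        for i in range(n):
            if chosen[i]:
                continue
            cls = member_classes[i]
            gain = int(np.count_nonzero(eligible[cls] & ~covered[cls]))
            if gain > best_gain:
                best_gain = gain
                best_i = i
        selected.append(best_i)
        chosen[best_i] = True
        covered[member_classes[best_i]] = True
    return selected
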