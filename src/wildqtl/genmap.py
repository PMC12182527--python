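"""Genetic maps in centimorgans.

A :class:`GeneticMap` holds marker positions partitioned over chromosomes.
Positions are genetic distances (cM), not physical coordinates; they drive
crossover placement during meiosis and the clustering of significant markers
into QTL regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneticMap", "MapSpecError", "generate_genetic_map"]


class MapSpecError(ValueError):
    """Raised for structurally invalid map specifications."""


@dataclass
class GeneticMap:
    """Chromosome-partitioned marker positions.

    Parameters
    ----------
    chrom
        Integer chromosome index per marker (0-based), non-decreasing.
    pos
        Position in cM per marker, strictly increasing within each chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    _offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        self.pos = np.asarray(self.pos, dtype=np.float64)
        if self.chrom.shape != self.pos.shape or self.chrom.ndim != 1:
            raise MapSpecError("chrom and pos must be 1-D arrays of equal length")
        if self.chrom.size == 0:
            raise MapSpecError("a map needs at least one marker")
        if np.any(np.diff(self.chrom) < 0):
            raise MapSpecError("markers must be grouped by chromosome in order")
        n_chrom = int(self.chrom[-1]) + 1
        starts = np.searchsorted(self.chrom, np.arange(n_chrom))
        self._offsets = np.append(starts, self.chrom.size)
        for c in range(n_chrom):
            p = self.pos[self._offsets[c] : self._offsets[c + 1]]
            if p.size and np.any(np.diff(p) <= 0):
                raise MapSpecError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    @property
    def n_markers(self) -> int:
        return self.pos.size

    @property
    def n_chromosomes(self) -> int:
        return self._offsets.size - 1

    def chrom_slice(self, c: int) -> slice:
        """Global marker index range of chromosome ``c``."""
        return slice(int(self._offsets[c]), int(self._offsets[c + 1]))

    def chrom_length(self, c: int) -> float:
        """Map length of chromosome ``c`` in cM (position of its last marker)."""
        s = self.chrom_slice(c)
        return float(self.pos[s.stop - 1] - self.pos[s.start])

    @property
    def chrom_lengths(self) -> np.ndarray:
        return np.array([self.chrom_length(c) for c in range(self.n_chromosomes)])

    @property
    def marker_names(self) -> list[str]:
        """Synthetic marker identifiers, stable across the package's writers."""
        return [
            f"c{c + 1}m{i - self._offsets[c] + 1}"
            for c, i in zip(self.chrom, range(self.n_markers))
        ]

    def mean_adjacent_spacing(self) -> float:
        """Mean cM distance between adjacent markers within chromosomes.

        Returns 0.0 when no within-chromosome adjacent pair exists (e.g. one
        marker per chromosome).
        """
        total = 0.0
        pairs = 0
        for c in range(self.n_chromosomes):
            p = self.pos[self.chrom_slice(c)]
            if p.size > 1:
                total += float(p[-1] - p[0])
                pairs += p.size - 1
        return total / pairs if pairs else 0.0


def generate_genetic_map(
    n_markers: int,
    n_chromosomes: int,
    total_length: float,
    spacing_mode: str = "even",
    seed: int | None = None,
) -> GeneticMap:
    """Build a synthetic map of ``n_markers`` over equally long chromosomes.

    Markers are partitioned across chromosomes as evenly as the counts allow
    (the first ``n_markers % n_chromosomes`` chromosomes receive one extra).
    Within a chromosome the first marker sits at 0 cM and the last at the
    chromosome end; ``spacing_mode='even'`` places the rest on a regular grid
    while ``'uniform_random'`` draws interior positions uniformly.
    """
    if n_chromosomes < 1:
        raise MapSpecError("need at least one chromosome")
    if n_markers < n_chromosomes:
        raise MapSpecError(
            f"cannot place {n_markers} markers on {n_chromosomes} chromosomes"
        )
    if total_length <= 0:
        raise MapSpecError("total map length must be positive")
    if spacing_mode not in ("even", "uniform_random"):
        raise MapSpecError(f"unknown spacing mode {spacing_mode!r}")

    rng = np.random.default_rng(seed)
    chrom_len = total_length / n_chromosomes
    counts = np.full(n_chromosomes, n_markers // n_chromosomes, dtype=int)
    counts[: n_markers % n_chromosomes] += 1

    chrom_parts: list[np.ndarray] = []
    pos_parts: list[np.ndarray] = []
    for c, m in enumerate(counts):
        if m == 1:
            p = np.array([0.0])
        elif spacing_mode == "even":
            p = np.linspace(0.0, chrom_len, m)
        else:
            interior = np.sort(rng.uniform(0.0, chrom_len, m - 2))
            p = np.concatenate([[0.0], interior, [chrom_len]])
            # uniform draws can (rarely) collide in float; nudge onto a grid
            while np.any(np.diff(p) <= 0):
                dup = np.where(np.diff(p) <= 0)[0] + 1
                p[dup] = np.nextafter(p[dup - 1], np.inf)
        chrom_parts.append(np.full(m, c))
        pos_parts.append(p)
    return GeneticMap(np.concatenate(chrom_parts), np.concatenate(pos_parts))
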