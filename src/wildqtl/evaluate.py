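"""QTL-region calling and TPR/FD evaluation against the simulated truth.

P-values are Benjamini-Hochberg adjusted; a marker is *significant* when
-log10(adjusted p) exceeds 3 (strictly).  Per chromosome, significant markers
are split into clusters wherever consecutive significant markers are >= 5 cM
apart; a cluster is called a QTL region when some 5 cM window (anchored at a
member marker) contains at least 5 of its markers.

A simulated QTL counts as detected when any called region overlaps the
window +-2.5 cM around its position.  TPR = detected / simulated.  A region
overlapping no QTL window is false; FD = false regions / all regions, set to
100% by convention when QTL were simulated but nothing was detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .genmap import GeneticMap

__all__ = [
    "EvaluationResult",
    "QTLRegion",
    "adjust_fdr",
    "call_qtl_regions",
    "call_significant",
    "evaluate",
]

DEFAULT_NEGLOG10_THRESHOLD = 3.0
REGION_MIN_MARKERS = 5
REGION_WINDOW_CM = 5.0
REGION_GAP_CM = 5.0
DETECTION_WINDOW_CM = 2.5


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN entries pass through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any(ok):
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_significant(
    adjusted_p: np.ndarray, threshold_neglog10: float = DEFAULT_NEGLOG10_THRESHOLD
) -> np.ndarray:
    """Boolean mask: -log10(adjusted p) strictly above the threshold."""
    p = np.asarray(adjusted_p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(np.isnan(p), False, -np.log10(p) > threshold_neglog10)


@dataclass
class QTLRegion:
    """A called region: contiguous cluster of significant markers."""

    chromosome: int
    start_cM: float
    end_cM: float
    markers: np.ndarray  # global marker indices of the cluster
    min_adjusted_p: float


def call_qtl_regions(
    significant: np.ndarray,
    gmap: GeneticMap,
    adjusted_p: np.ndarray | None = None,
    min_markers: int = REGION_MIN_MARKERS,
    window_cm: float = REGION_WINDOW_CM,
    gap_cm: float = REGION_GAP_CM,
) -> list[QTLRegion]:
    """Cluster significant markers per chromosome and apply the density rule."""
    sig_idx = np.nonzero(np.asarray(significant, dtype=bool))[0]
    regions: list[QTLRegion] = []
    for c in range(gmap.n_chromosomes):
        sl = gmap.chrom_slice(c)
        on_c = sig_idx[(sig_idx >= sl.start) & (sig_idx < sl.stop)]
        if on_c.size == 0:
            continue
        pos = gmap.pos[on_c]
        # split into clusters at gaps >= gap_cm
        breaks = np.nonzero(np.diff(pos) >= gap_cm)[0] + 1
        for cluster in np.split(on_c, breaks):
            cpos = gmap.pos[cluster]
            # density rule: some window of window_cm anchored at a member
            # marker must contain >= min_markers of the cluster's markers
            counts = np.searchsorted(cpos, cpos + window_cm, side="right") - np.arange(
                cpos.size
            )
            if cpos.size >= min_markers and counts.max() >= min_markers:
                min_p = (
                    float(np.nanmin(adjusted_p[cluster]))
                    if adjusted_p is not None
                    else float("nan")
                )
                regions.append(
                    QTLRegion(
                        chromosome=c,
                        start_cM=float(cpos[0]),
                        end_cM=float(cpos[-1]),
                        markers=cluster,
                        min_adjusted_p=min_p,
                    )
                )
    return regions


@dataclass
class EvaluationResult:
    """TPR/FD of one scan against the simulated QTL."""

    tpr: float
    fd: float
    detected: np.ndarray  # bool per simulated QTL
    n_regions: int
    n_false_regions: int
    region_is_false: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


def evaluate(
    regions: list[QTLRegion],
    qtl_chromosomes: np.ndarray,
    qtl_positions: np.ndarray,
    window_cm: float = DETECTION_WINDOW_CM,
) -> EvaluationResult:
    """Match called regions to true QTL windows and compute TPR/FD.

    A region overlapping several QTL windows counts each of them as detected
    and is not false.  With no regions at all, FD is 1 by convention.
    """
    qc = np.atleast_1d(np.asarray(qtl_chromosomes, dtype=int))
    qp = np.atleast_1d(np.asarray(qtl_positions, dtype=float))
    n_sim = qp.size
    if n_sim < 1:
        raise ValueError("need at least one simulated QTL")
    detected = np.zeros(n_sim, dtype=bool)
    region_false = np.ones(len(regions), dtype=bool)
    for r_i, region in enumerate(regions):
        for q_i in range(n_sim):
            if region.chromosome != qc[q_i]:
                continue
            if region.start_cM <= qp[q_i] + window_cm and region.end_cM >= qp[q_i] - window_cm:
                detected[q_i] = True
                region_false[r_i] = False
    n_regions = len(regions)
    n_false = int(region_false.sum())
    fd = (n_false / n_regions) if n_regions else 1.0
    return EvaluationResult(
        tpr=float(detected.mean()),
        fd=float(fd),
        detected=detected,
        n_regions=n_regions,
        n_false_regions=n_false,
        region_is_false=region_false,
    )
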