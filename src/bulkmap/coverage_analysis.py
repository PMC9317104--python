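"""Coverage-derived structural signals: ZCRs and gene-level PAVs.

A zero-coverage region (ZCR) is a run of fixed 200 bp windows in which no
read aligned in *either* pool — typically a deletion shared by both
parents, where no variants can be called and dARC intervals would
otherwise split.  A presence-absence variation (PAV) is a gene with no or
extremely low coverage in one pool but substantially higher, normalized
coverage in the other — the footprint of a deletion carried by one parent
whose haplotype was driven to a high frequency in one phenotype tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import CoverageTrack, GeneModel


@dataclass(frozen=True)
class ZeroCoverageRegion:
    """Merged run of 200 bp windows with zero depth in both pools."""

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    n_windows: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_zcrs(
    cov_high: CoverageTrack,
    cov_low: CoverageTrack,
    window: int = 200,
) -> list[ZeroCoverageRegion]:
    """Scan non-overlapping windows tiled from position 1 for zero coverage.

    A window qualifies only if *every* base has depth 0 in *both* pools;
    adjacent qualifying windows are merged.  A trailing partial window is
    not evaluated.
    """
    if len(cov_high) != len(cov_low):
        raise ValueError("coverage tracks differ in length")
    n_win = len(cov_high) // window
    if n_win == 0:
        return []
    hi = cov_high.depth[: n_win * window].reshape(n_win, window)
    lo = cov_low.depth[: n_win * window].reshape(n_win, window)
    zero = (hi.max(axis=1) == 0) & (lo.max(axis=1) == 0)

    regions: list[ZeroCoverageRegion] = []
    run_start = None
    for i, z in enumerate(np.append(zero, False)):
        if z and run_start is None:
            run_start = i
        elif not z and run_start is not None:
            regions.append(
                ZeroCoverageRegion(
                    chrom=cov_high.chrom,
                    start=run_start * window + 1,
                    end=i * window,
                    n_windows=i - run_start,
                )
            )
            run_start = None
    return regions


def gene_mean_coverage(track: CoverageTrack, gene: GeneModel) -> float:
    """Arithmetic mean depth over the gene body [start, end]."""
    if gene.chrom != track.chrom:
        raise ValueError(f"gene {gene.gene_id} is on {gene.chrom}, track on {track.chrom}")
    if gene.end > len(track):
        raise ValueError(f"gene {gene.gene_id} extends past the coverage track")
    return float(track.depth[gene.start - 1 : gene.end].mean())


@dataclass(frozen=True)
class PavCall:
    """A gene with a presence-absence coverage contrast between pools."""

    gene_id: str
    chrom: str
    start: int
    end: int
    raw_cov_high: float
    raw_cov_low: float
    norm_cov_high: float
    norm_cov_low: float
    ratio: float      # larger normalized coverage / smaller; inf when smaller is 0
    direction: str    # which pool is depleted: "high" or "low"


def _as_track_map(cov) -> Mapping[str, CoverageTrack]:
    if isinstance(cov, CoverageTrack):
        return {cov.chrom: cov}
    return cov


def pool_mean_depth(cov: Mapping[str, CoverageTrack] | CoverageTrack) -> float:
    """Genome-wide mean depth of a pool (base-weighted over chromosomes)."""
    tracks = _as_track_map(cov)
    total = sum(int(t.depth.sum()) for t in tracks.values())
    bases = sum(len(t) for t in tracks.values())
    return total / bases if bases else 0.0


def detect_pavs(
    genes: Sequence[GeneModel],
    cov_high: Mapping[str, CoverageTrack] | CoverageTrack,
    cov_low: Mapping[str, CoverageTrack] | CoverageTrack,
    mincov: float = 10.0,
    ratio_min: float = 2.0,
) -> list[PavCall]:
    """Call gene-level PAVs from the two pools' coverage tracks.

    Per gene the mean depth in each pool is normalized by that pool's
    genome-wide mean depth.  A PAV requires the depleted pool's *raw* mean
    below ``mincov`` and a normalized larger/smaller ratio of at least
    ``ratio_min`` (an F2 deletion haplotype swept to a 3/4-vs-1/4 contrast
    gives an expected ratio of ~3).  Calls are ranked by descending ratio.
    Genes on chromosomes without coverage tracks are skipped (e.g. genes on
    unanchored scaffolds excluded upstream).
    """
    high = _as_track_map(cov_high)
    low = _as_track_map(cov_low)
    mean_h = pool_mean_depth(high)
    mean_l = pool_mean_depth(low)
    calls: list[PavCall] = []
    for gene in genes:
        if gene.chrom not in high or gene.chrom not in low:
            continue
        raw_h = gene_mean_coverage(high[gene.chrom], gene)
        raw_l = gene_mean_coverage(low[gene.chrom], gene)
        norm_h = raw_h / mean_h if mean_h > 0 else 0.0
        norm_l = raw_l / mean_l if mean_l > 0 else 0.0
        small, big = sorted((norm_h, norm_l))
        if big == 0:  # no coverage anywhere: ZCR territory, not a PAV
            continue
        ratio = math.inf if small == 0 else big / small
        if min(raw_h, raw_l) < mincov and ratio >= ratio_min:
            calls.append(
                PavCall(
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    start=gene.start,
                    end=gene.end,
                    raw_cov_high=raw_h,
                    raw_cov_low=raw_l,
                    norm_cov_high=norm_h,
                    norm_cov_low=norm_l,
                    ratio=ratio,
                    direction="high" if norm_h < norm_l else "low",
                )
            )
    calls.sort(key=lambda c: (-c.ratio, c.chrom, c.start))
    return calls
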