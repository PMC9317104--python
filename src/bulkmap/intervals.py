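"""Clustering dARCs into trait-associated genomic intervals.

The interval rules: (I) an interval needs at least 4 dARCs; (II) at least
3 of its dARCs must be spread out, pairwise more than 1 kbp apart, so that
a burst of variants from a single DNA fragment cannot seed an interval;
(III) adjacent dARCs within an interval must be less than 50 kbp apart
(strict), splitting stretches without a constantly high dARC density.
Zero-coverage regions are allowed to bridge splits: two clusters merge
when ZCRs cover at least half of the gap between them, because a shared
deletion suppresses variant calls without breaking the underlying linkage
signal.  Final intervals are ranked by their dARC count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .coverage_analysis import ZeroCoverageRegion


@dataclass
class GenomicInterval:
    """A dARC cluster reported as a candidate trait locus.

    ``start``/``end`` are the first and last member dARC positions; the
    reported size is ``end - start`` (the spanned distance in bp).
    """

    interval_id: str
    chrom: str
    start: int
    end: int
    n_darcs: int
    rank: int = 0

    @property
    def size(self) -> int:
        return self.end - self.start


def cluster_darcs(
    positions: Sequence[int], max_gap: int = 50_000
) -> list[list[int]]:
    """Chain sorted dARC positions into maximal runs with adjacent gaps
    strictly below ``max_gap``; a gap of exactly ``max_gap`` splits."""
    positions = list(positions)
    if positions != sorted(positions):
        raise ValueError("dARC positions must be sorted ascending")
    clusters: list[list[int]] = []
    current: list[int] = []
    for pos in positions:
        if current and pos - current[-1] >= max_gap:
            clusters.append(current)
            current = []
        current.append(pos)
    if current:
        clusters.append(current)
    return clusters


def validate_cluster(
    cluster: Sequence[int],
    min_darcs: int = 4,
    spread_count: int = 3,
    spread_dist: int = 1_000,
    spread_mode: str = "pairwise",
) -> bool:
    """Check the seeding rules for one cluster.

    ``pairwise`` mode (default) requires a subset of at least
    ``spread_count`` dARCs that are pairwise more than ``spread_dist``
    apart; greedy left-to-right selection (keep a dARC when it is more
    than ``spread_dist`` from the last kept one) maximizes that subset on
    sorted positions.  ``span`` mode is the looser alternative reading:
    the cluster span alone must exceed ``spread_dist``.
    """
    if len(cluster) < min_darcs:
        return False
    if spread_mode == "span":
        return cluster[-1] - cluster[0] > spread_dist
    if spread_mode != "pairwise":
        raise ValueError(f"unknown spread_mode {spread_mode!r}")
    kept = 1
    last = cluster[0]
    for pos in cluster[1:]:
        if pos - last > spread_dist:
            kept += 1
            last = pos
            if kept >= spread_count:
                return True
    return kept >= spread_count


def _zcr_overlap(gap_start: int, gap_end: int, zcrs: Sequence[ZeroCoverageRegion]) -> int:
    covered = 0
    for z in zcrs:
        lo = max(gap_start, z.start)
        hi = min(gap_end, z.end)
        if hi >= lo:
            covered += hi - lo + 1
    return covered


def merge_across_zcrs(
    clusters: Sequence[Sequence[int]],
    zcrs: Sequence[ZeroCoverageRegion],
    zcr_gap_fraction: float = 0.5,
) -> list[list[int]]:
    """Merge adjacent clusters whose separating gap is mostly ZCR.

    The gap between a cluster's last dARC and the next cluster's first
    dARC is intersected with the ZCRs; if the covered fraction reaches
    ``zcr_gap_fraction`` the clusters merge regardless of gap length.
    Merging iterates to a fixed point.
    """
    merged = [list(c) for c in clusters]
    if not zcrs:
        return merged
    changed = True
    while changed:
        changed = False
        out: list[list[int]] = []
        for cluster in merged:
            if out:
                gap_start = out[-1][-1] + 1
                gap_end = cluster[0] - 1
                gap_len = gap_end - gap_start + 1
                if gap_len <= 0 or (
                    _zcr_overlap(gap_start, gap_end, zcrs) / gap_len
                    >= zcr_gap_fraction
                ):
                    out[-1].extend(cluster)
                    changed = True
                    continue
            out.append(cluster)
        merged = out
    return merged


def _short_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


def rank_and_threshold(
    candidates: Sequence[tuple[str, Sequence[int]]],
    min_darc_cutoff: int = 4,
    trait_label: str = "TRAIT",
) -> list[GenomicInterval]:
    """Apply the downstream dARC-count cutoff, assign IDs and ranks.

    ``candidates`` are (chrom, member positions) pairs of validated
    clusters.  IDs number intervals per chromosome by ascending start
    (``<chrom-short>_<trait>_<k>``); ranks order all intervals by
    descending dARC count, ties broken by larger size then smaller start.
    Returned in rank order.
    """
    intervals = [
        GenomicInterval(
            interval_id="",
            chrom=chrom,
            start=min(pos),
            end=max(pos),
            n_darcs=len(pos),
        )
        for chrom, pos in candidates
        if len(pos) >= min_darc_cutoff
    ]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start)):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        for k, iv in enumerate(ivs, start=1):
            iv.interval_id = f"{_short_chrom(chrom)}_{trait_label}_{k}"
    intervals.sort(key=lambda iv: (-iv.n_darcs, -iv.size, iv.chrom, iv.start))
    for rank, iv in enumerate(intervals, start=1):
        iv.rank = rank
    return intervals


def detect_intervals(
    darc_positions: Mapping[str, Sequence[int]],
    zcrs: Sequence[ZeroCoverageRegion] = (),
    max_gap: int = 50_000,
    min_darcs: int = 4,
    spread_count: int = 3,
    spread_dist: int = 1_000,
    spread_mode: str = "pairwise",
    zcr_gap_fraction: float = 0.5,
    min_darc_cutoff: int = 4,
    trait_label: str = "TRAIT",
) -> list[GenomicInterval]:
    """Full interval detection: chain, ZCR-merge, validate, rank.

    ``darc_positions`` maps chromosome -> sorted dARC positions; ``zcrs``
    may span several chromosomes.  ``min_darc_cutoff`` is the
    trait-specific downstream threshold (100 for the GSL analysis, 65 for
    SPC in the original study design).
    """
    candidates: list[tuple[str, Sequence[int]]] = []
    for chrom in sorted(darc_positions):
        clusters = cluster_darcs(sorted(darc_positions[chrom]), max_gap=max_gap)
        chrom_zcrs = [z for z in zcrs if z.chrom == chrom]
        clusters = merge_across_zcrs(clusters, chrom_zcrs, zcr_gap_fraction)
        for cluster in clusters:
            if validate_cluster(
                cluster, min_darcs, spread_count, spread_dist, spread_mode
            ):
                candidates.append((chrom, cluster))
    return rank_and_threshold(candidates, min_darc_cutoff, trait_label)
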