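"""End-to-end orchestration: parents + pools -> gold standard -> dAF ->
dARCs -> genomic intervals.

This is the composition the individual modules are designed around; it
operates on in-memory variant lists so the same path serves files read
through :mod:`bulkmap.io_formats` and simulations from
:mod:`bulkmap.synthetic_data`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .coverage_analysis import ZeroCoverageRegion
from .darc import DarcRecord, call_darcs
from .gold_standard import GoldStandardSet, build_gold_standard
from .intervals import GenomicInterval, detect_intervals
from .io_formats import PoolVariant
from .pool_stats import AlleleFrequencyRecord, filter_pool_variants, join_pools


@dataclass
class PipelineResult:
    gold: GoldStandardSet
    af_records: list[AlleleFrequencyRecord]
    darcs: list[DarcRecord]
    intervals: list[GenomicInterval]
    n_alt_mismatch: int = 0

    @property
    def darc_positions(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for d in self.darcs:
            if d.is_darc:
                out.setdefault(d.chrom, []).append(d.pos)
        for positions in out.values():
            positions.sort()
        return out

    @property
    def n_darcs(self) -> int:
        return sum(d.is_darc for d in self.darcs)


def run_mbs(
    p1_variants: Sequence[PoolVariant],
    p2_variants: Sequence[PoolVariant],
    high_pool: Sequence[PoolVariant],
    low_pool: Sequence[PoolVariant],
    zcrs: Sequence[ZeroCoverageRegion] = (),
    *,
    min_cov: int = 10,
    max_cov: int = 60,
    af_lo: float = 0.2,
    af_hi: float = 0.8,
    pool_lo_factor: float = 0.75,
    pool_hi_factor: float = 1.5,
    alpha: float = 0.05,
    correction: str = "benjamini-hochberg",
    max_gap: int = 50_000,
    min_darcs: int = 4,
    spread_count: int = 3,
    spread_dist: int = 1_000,
    min_darc_cutoff: int = 4,
    trait_label: str = "TRAIT",
) -> PipelineResult:
    """Run the full mapping-by-sequencing analysis on variant calls.

    ``min_darc_cutoff`` is the trait-specific downstream threshold; the
    default keeps every validated interval, which suits simulated single
    locus experiments (the original study used 100/65 after manual
    inspection of the dARC counts).
    """
    gold = build_gold_standard(
        p1_variants, p2_variants,
        min_cov=min_cov, max_cov=max_cov, af_lo=af_lo, af_hi=af_hi,
    )
    high_f = filter_pool_variants(high_pool, gold, pool_lo_factor, pool_hi_factor)
    low_f = filter_pool_variants(low_pool, gold, pool_lo_factor, pool_hi_factor)
    joined = join_pools(high_f, low_f)
    darcs = call_darcs(joined.records, alpha=alpha, method=correction)

    positions: dict[str, list[int]] = {}
    for d in darcs:
        if d.is_darc:
            positions.setdefault(d.chrom, []).append(d.pos)
    intervals = detect_intervals(
        positions,
        zcrs=zcrs,
        max_gap=max_gap,
        min_darcs=min_darcs,
        spread_count=spread_count,
        spread_dist=spread_dist,
        min_darc_cutoff=min_darc_cutoff,
        trait_label=trait_label,
    )
    return PipelineResult(
        gold=gold,
        af_records=joined.records,
        darcs=darcs,
        intervals=intervals,
        n_alt_mismatch=joined.n_alt_mismatch,
    )
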