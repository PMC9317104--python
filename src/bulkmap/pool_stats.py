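"""Pool-level allele frequencies and delta allele frequencies (dAF).

For each phenotype pool the raw variant calls are restricted to
gold-standard sites and to a per-pool coverage band around the pool's
median depth (default 0.75x to 1.5x the median), then the high and low
pools are joined site-wise and the dAF — the absolute difference of the
alternate-allele read fractions — is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .gold_standard import GoldStandardSet
from .io_formats import PoolVariant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlleleFrequencyRecord:
    """Joined high/low pool allele counts and frequencies at one site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_high: int
    alt_high: int
    ref_low: int
    alt_low: int

    @property
    def af_high(self) -> float:
        return self.alt_high / (self.ref_high + self.alt_high)

    @property
    def af_low(self) -> float:
        return self.alt_low / (self.ref_low + self.alt_low)

    @property
    def daf(self) -> float:
        return delta_af(self.af_high, self.af_low)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.ref_high, self.alt_high, self.ref_low, self.alt_low)


def pool_median_coverage(variants: Sequence[PoolVariant]) -> float:
    """Median per-site total depth of a pool (mean of the central pair
    for an even number of sites)."""
    if not variants:
        raise ValueError("cannot take the median coverage of an empty pool")
    return float(np.median([v.depth for v in variants]))


def filter_pool_variants(
    pool: Iterable[PoolVariant],
    gold: GoldStandardSet,
    lo_factor: float = 0.75,
    hi_factor: float = 1.5,
) -> list[PoolVariant]:
    """Restrict a pool to gold-standard SNVs within the coverage band.

    The band is ``[lo_factor * M, hi_factor * M]`` (inclusive) where M is
    the pool's median depth over its gold-standard SNV sites; sites with
    too low a depth give noisy frequencies, sites with too high a depth are
    suspect for copy-number inflation.
    """
    candidates = [
        v for v in pool if v.is_snv and (v.chrom, v.pos) in gold
    ]
    if not candidates:
        return []
    m = pool_median_coverage(candidates)
    lo, hi = lo_factor * m, hi_factor * m
    kept = [v for v in candidates if lo <= v.depth <= hi]
    logger.info(
        "pool filter: %d gold-standard SNVs, median depth %.1f, %d inside [%.1f, %.1f]",
        len(candidates), m, len(kept), lo, hi,
    )
    return kept


def delta_af(af_high: float, af_low: float) -> float:
    """Delta allele frequency: |af_high - af_low|.

    Orientation-free by construction, so no parent-of-origin polarization
    is needed.
    """
    if not (0.0 <= af_high <= 1.0 and 0.0 <= af_low <= 1.0):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return abs(af_high - af_low)


@dataclass
class JoinResult:
    """Site-wise join of the two filtered pools."""

    records: list[AlleleFrequencyRecord] = field(default_factory=list)
    n_alt_mismatch: int = 0

    def __iter__(self) -> Iterator[AlleleFrequencyRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, idx):
        return self.records[idx]


def join_pools(
    high: Sequence[PoolVariant], low: Sequence[PoolVariant]
) -> JoinResult:
    """Inner-join the pools on (chrom, pos) requiring an identical ALT.

    Only sites that are biallelic in both pools with the same alternate
    allele produce a record; ALT mismatches are excluded and counted.
    Sites with zero depth in either pool are dropped (no frequency is
    defined there).  Output is sorted by (chrom, pos) and duplicate-free.
    """
    mh = {(v.chrom, v.pos): v for v in high}
    ml = {(v.chrom, v.pos): v for v in low}
    res = JoinResult()
    for key in sorted(set(mh) & set(ml)):
        vh, vl = mh[key], ml[key]
        if vh.alt != vl.alt:
            res.n_alt_mismatch += 1
            continue
        if vh.depth == 0 or vl.depth == 0:
            continue
        res.records.append(
            AlleleFrequencyRecord(
                chrom=vh.chrom,
                pos=vh.pos,
                ref=vh.ref,
                alt=vh.alt,
                ref_high=vh.ref_count,
                alt_high=vh.alt_count,
                ref_low=vl.ref_count,
                alt_low=vl.alt_count,
            )
        )
    return res
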