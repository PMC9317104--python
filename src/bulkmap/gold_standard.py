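"""Build the gold-standard SNV set used to whitelist pool variants.

A marker is trusted for bulk-segregant contrasts only if it is (a) a
homozygous, coverage-bounded SNV in one parent, (b) contrasting between the
two parents (present in exactly one, or dropped as triallelic when the
parents carry different ALT alleles at the same site), and (c) behaves as a
heterozygous site in a "reconstituted F1" — the merged parental read set —
with an alternate-allele frequency inside a configurable band (default
0.2-0.8).  Sites failing the F1 band are typically affected by copy-number
differences or collapsed paralogs and would distort pool allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .io_formats import HOM_ALT, MISSING, PoolVariant

#: fallback homozygosity call when the caller genotype is absent
_HOM_ALT_FRACTION = 0.9


@dataclass(frozen=True)
class GoldEntry:
    """Parental alleles at one gold-standard site."""

    ref: str
    alt: str
    carrier: str  # "P1" or "P2": which parent is homozygous for ALT

    @property
    def parent1_allele(self) -> str:
        return self.alt if self.carrier == "P1" else self.ref

    @property
    def parent2_allele(self) -> str:
        return self.alt if self.carrier == "P2" else self.ref


@dataclass
class GoldStandardCounters:
    n_input_p1: int = 0
    n_input_p2: int = 0
    n_filtered_p1: int = 0
    n_filtered_p2: int = 0
    n_shared_dropped: int = 0
    n_triallelic_dropped: int = 0
    n_after_contrast: int = 0
    n_missing_f1: int = 0
    n_final: int = 0


@dataclass
class GoldStandardSet:
    """Map from (chrom, pos) to the contrasting parental alleles."""

    entries: dict[tuple[str, int], GoldEntry] = field(default_factory=dict)
    counters: GoldStandardCounters = field(default_factory=GoldStandardCounters)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.entries)


def is_homozygous_alt(variant: PoolVariant) -> bool:
    """Caller GT when present; otherwise an ALT read fraction >= 0.9."""
    if variant.genotype != MISSING:
        return variant.genotype == HOM_ALT
    return variant.depth > 0 and variant.alt_fraction >= _HOM_ALT_FRACTION


def filter_parental_variants(
    variants: Iterable[PoolVariant],
    min_cov: int = 10,
    max_cov: int = 60,
) -> list[PoolVariant]:
    """Keep homozygous-ALT, single-ALT SNVs with depth in [min_cov, max_cov].

    The default ceiling of 60 is about twice the modal depth of a ~30x
    parental run and discards sites inflated by copy-number variation.
    """
    return [
        v
        for v in variants
        if v.is_snv
        and is_homozygous_alt(v)
        and min_cov <= v.depth <= max_cov
    ]


@dataclass
class ContrastingResult:
    sites: dict[tuple[str, int], GoldEntry] = field(default_factory=dict)
    n_shared: int = 0
    n_triallelic: int = 0

    def __len__(self) -> int:
        return len(self.sites)


def combine_parental_sets(
    p1: Sequence[PoolVariant], p2: Sequence[PoolVariant]
) -> ContrastingResult:
    """Combine the filtered parental sets into contrasting sites.

    A site is kept when exactly one parent is homozygous for an ALT allele
    (the other implicitly matches the reference).  Sites where both parents
    carry the same ALT are not contrasting and are dropped; sites where the
    parents carry different ALT alleles are triallelic and dropped.
    """
    m1 = {(v.chrom, v.pos): v for v in p1}
    m2 = {(v.chrom, v.pos): v for v in p2}
    res = ContrastingResult()
    for key in sorted(set(m1) | set(m2)):
        v1, v2 = m1.get(key), m2.get(key)
        if v1 is not None and v2 is not None:
            if v1.alt == v2.alt:
                res.n_shared += 1
            else:
                res.n_triallelic += 1
            continue
        v = v1 if v1 is not None else v2
        res.sites[key] = GoldEntry(
            ref=v.ref, alt=v.alt, carrier="P1" if v1 is not None else "P2"
        )
    return res


def reconstitute_f1(
    parent_sets: Sequence[Sequence[PoolVariant]],
    positions: Iterable[tuple[str, int]] | None = None,
) -> dict[tuple[str, int], float]:
    """Alternate-allele frequency of the pooled parental read sets.

    Summing ref/alt read counts of both parents at each site emulates
    sequencing a true F1 heterozygote.  Additional read sets (e.g. the
    pools) may be appended to ``parent_sets``.  A site contributes only if
    every supplied set carries a record there, since an absent record
    leaves that sample's reference depth unknown.
    """
    maps = [{(v.chrom, v.pos): v for v in s} for s in parent_sets]
    keys = set(maps[0])
    for m in maps[1:]:
        keys &= set(m)
    if positions is not None:
        keys &= set(positions)
    af: dict[tuple[str, int], float] = {}
    for key in keys:
        ref = sum(m[key].ref_count for m in maps)
        alt = sum(m[key].alt_count for m in maps)
        if ref + alt > 0:
            af[key] = alt / (ref + alt)
    return af


def filter_f1_heterozygous(
    contrasting: ContrastingResult | Mapping[tuple[str, int], GoldEntry],
    f1_af: Mapping[tuple[str, int], float],
    lo: float = 0.2,
    hi: float = 0.8,
) -> GoldStandardSet:
    """Keep contrasting sites whose F1 allele frequency lies in [lo, hi].

    Bounds are inclusive.  Sites absent from the F1 frequency map are
    dropped and counted.
    """
    sites = contrasting.sites if isinstance(contrasting, ContrastingResult) else contrasting
    gold = GoldStandardSet()
    for key, entry in sites.items():
        if key not in f1_af:
            gold.counters.n_missing_f1 += 1
            continue
        if lo <= f1_af[key] <= hi:
            gold.entries[key] = entry
    gold.counters.n_after_contrast = len(sites)
    gold.counters.n_final = len(gold)
    return gold


def build_gold_standard(
    p1_variants: Sequence[PoolVariant],
    p2_variants: Sequence[PoolVariant],
    min_cov: int = 10,
    max_cov: int = 60,
    af_lo: float = 0.2,
    af_hi: float = 0.8,
    extra_read_sets: Sequence[Sequence[PoolVariant]] = (),
) -> GoldStandardSet:
    """Run the full gold-standard construction from raw parental variants.

    ``extra_read_sets`` optionally adds further read sets (e.g. the pools)
    to the reconstituted F1; the default uses the parents only.
    """
    f1_p1 = filter_parental_variants(p1_variants, min_cov, max_cov)
    f1_p2 = filter_parental_variants(p2_variants, min_cov, max_cov)
    contrasting = combine_parental_sets(f1_p1, f1_p2)
    f1_af = reconstitute_f1(
        [list(p1_variants), list(p2_variants), *map(list, extra_read_sets)],
        positions=contrasting.sites,
    )
    gold = filter_f1_heterozygous(contrasting, f1_af, af_lo, af_hi)
    c = gold.counters
    c.n_input_p1 = len(p1_variants)
    c.n_input_p2 = len(p2_variants)
    c.n_filtered_p1 = len(f1_p1)
    c.n_filtered_p2 = len(f1_p2)
    c.n_shared_dropped = contrasting.n_shared
    c.n_triallelic_dropped = contrasting.n_triallelic
    return gold
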