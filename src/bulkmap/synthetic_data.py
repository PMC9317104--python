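"""Synthetic F2 bulk-segregant experiments with a machine-readable truth.

The generator emulates the study design the pipeline targets: two fully
homozygous parents contrasting at biallelic SNVs, a large F2 population
derived from their cross, phenotype pools drawn from the distribution
tails, short-read allele counts sampled binomially at Poisson depth, and
large deletions that surface as zero-coverage regions (shared deletions)
or depleted coverage ratios (single-parent deletions).

Model choices: crossovers follow a Haldane (no-interference) process so
linkage decay has the closed form r = (1 - exp(-2d/100)) / 2; the
phenotype is additive over causal loci with Gaussian residual noise
scaled from the heritability (an optional pairwise epistasis term can be
added); sequencing error is off by default but a per-read allele-flip
probability is available to stress the exact test.  Deletion regions
carry no SNVs (deleted DNA yields no variant calls in the carrier).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .io_formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    CoverageTrack,
    GeneModel,
    PoolVariant,
    write_coverage,
    write_gff3,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CausalLocus:
    chrom: str
    pos: int
    effect: float  # additive effect per allele of the high parent (P2)


@dataclass(frozen=True)
class Deletion:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    carrier: str  # "P1", "P2" or "both"


@dataclass(frozen=True)
class EpistaticPair:
    """Optional pairwise interaction between two causal loci."""

    locus_a: int  # indices into causal_loci
    locus_b: int
    effect: float


@dataclass
class SimulationConfig:
    """Study-design parameters of one synthetic experiment.

    Defaults describe a single 20 Mbp chromosome carrying one SNV per
    2 kbp, an F2 of 1,000 plants pooled from the 5% phenotype tails, one
    causal locus explaining half of the phenotypic variance, and 50x mean
    pool coverage — a desk-scale rendition of a winter-rapeseed F2
    mapping design.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000}
    )
    snv_density: float = 1 / 2_000          # expected SNVs per bp
    n_f2: int = 1_000
    tail_fractions: tuple[float, float] = (0.05, 0.05)  # (low, high)
    causal_loci: list[CausalLocus] = field(
        default_factory=lambda: [CausalLocus("chr1", 10_000_000, 1.0)]
    )
    heritability: float = 0.5
    residual_sd: float | None = None        # overrides heritability when set
    mean_depth: float = 50.0
    cm_per_mb: float = 2.0
    deletions: list[Deletion] = field(default_factory=list)
    epistatic_pairs: list[EpistaticPair] = field(default_factory=list)
    error_rate: float = 0.0                 # per-read allele flip probability
    gene_spacing: int = 20_000
    gene_length: int = 5_000
    emit_coverage: bool | None = None       # default: only when deletions exist
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tail_fractions
        if not (0 < lo < 0.5 and 0 < hi < 0.5):
            raise ValueError("tail fractions must lie in (0, 0.5)")
        if lo * self.n_f2 < 1 or hi * self.n_f2 < 1:
            raise ValueError("tail smaller than one individual")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        for locus in self.causal_loci:
            if locus.chrom not in self.chrom_lengths:
                raise ValueError(f"causal locus on unknown chromosome {locus.chrom}")
            if not (1 <= locus.pos <= self.chrom_lengths[locus.chrom]):
                raise ValueError("causal locus outside chromosome bounds")
        for d in self.deletions:
            if d.chrom not in self.chrom_lengths:
                raise ValueError(f"deletion on unknown chromosome {d.chrom}")
            if not (1 <= d.start <= d.end <= self.chrom_lengths[d.chrom]):
                raise ValueError("deletion outside chromosome bounds")
            if d.carrier not in ("P1", "P2", "both"):
                raise ValueError("deletion carrier must be P1, P2 or both")


@dataclass
class ChromTruth:
    """Per-site ground truth on one chromosome."""

    positions: np.ndarray        # SNV positions, sorted
    carrier: np.ndarray          # "P1"/"P2": which parent carries ALT
    af_high: np.ndarray          # true ALT frequency in the high pool
    af_low: np.ndarray


@dataclass
class TruthTable:
    sites: dict[str, ChromTruth]
    causal_loci: list[CausalLocus]        # snapped to SNV positions
    deletions: list[Deletion]
    deletion_freq_high: list[float]       # deletion-haplotype pool frequencies
    deletion_freq_low: list[float]
    phenotypes: np.ndarray
    low_pool_idx: np.ndarray
    high_pool_idx: np.ndarray

    def causal_daf(self, k: int = 0) -> float:
        """True dAF at the k-th causal locus."""
        locus = self.causal_loci[k]
        t = self.sites[locus.chrom]
        i = int(np.searchsorted(t.positions, locus.pos))
        return float(abs(t.af_high[i] - t.af_low[i]))


@dataclass
class SimulationResult:
    config: SimulationConfig
    truth: TruthTable
    parent_variants: dict[str, list[PoolVariant]]   # "P1", "P2"
    pool_variants: dict[str, list[PoolVariant]]     # "high", "low"
    coverage: dict[str, dict[str, CoverageTrack]] | None  # pool -> chrom -> track
    genes: list[GeneModel]

    def write_outputs(self, outdir: str | Path) -> dict[str, Path]:
        """Emit VCFs, coverage TSVs, GFF3 gene models and the truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["parents_vcf"] = outdir / "parents.vcf"
        _write_vcf(
            paths["parents_vcf"],
            {"P1": self.parent_variants["P1"], "P2": self.parent_variants["P2"]},
            self.config.chrom_lengths,
        )
        paths["pools_vcf"] = outdir / "pools.vcf"
        _write_vcf(
            paths["pools_vcf"],
            {"HIGH": self.pool_variants["high"], "LOW": self.pool_variants["low"]},
            self.config.chrom_lengths,
        )
        paths["genes_gff3"] = outdir / "genes.gff3"
        write_gff3(self.genes, paths["genes_gff3"])
        if self.coverage is not None:
            for pool, tracks in self.coverage.items():
                for chrom, track in tracks.items():
                    p = outdir / f"coverage_{pool}_{chrom}.tsv"
                    write_coverage(track, p)
                    paths[f"coverage_{pool}_{chrom}"] = p
        paths["truth_json"] = outdir / "truth.json"
        with open(paths["truth_json"], "w") as fh:
            json.dump(_truth_to_json(self.truth), fh, indent=1)
        return paths


def _truth_to_json(truth: TruthTable) -> dict:
    return {
        "causal_loci": [asdict(c) for c in truth.causal_loci],
        "deletions": [asdict(d) for d in truth.deletions],
        "deletion_freq_high": truth.deletion_freq_high,
        "deletion_freq_low": truth.deletion_freq_low,
        "sites": {
            chrom: {
                "positions": t.positions.tolist(),
                "carrier": t.carrier.tolist(),
                "af_high": np.round(t.af_high, 6).tolist(),
                "af_low": np.round(t.af_low, 6).tolist(),
            }
            for chrom, t in truth.sites.items()
        },
    }


def _haldane_gametes(
    rng: np.random.Generator,
    n_gametes: int,
    chrom_length: int,
    morgans: float,
    marker_pos: np.ndarray,
) -> np.ndarray:
    """Parental origin (0 = P1, 1 = P2) of each gamete at each marker."""
    origins = np.empty((n_gametes, len(marker_pos)), dtype=np.int8)
    n_x = rng.poisson(morgans, size=n_gametes)
    starts = rng.integers(0, 2, size=n_gametes)
    for g in range(n_gametes):
        if n_x[g]:
            breaks = np.sort(rng.uniform(0, chrom_length, size=n_x[g]))
            origins[g] = (np.searchsorted(breaks, marker_pos) + starts[g]) % 2
        else:
            origins[g] = starts[g]
    return origins


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref], _BASES[alt]


def simulate_f2(
    config: SimulationConfig, seed: int | None = None
) -> SimulationResult:
    """Run one synthetic experiment; fully reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m_per_bp = config.cm_per_mb / 100 / 1e6

    # --- markers: SNV positions, carriers, alleles per chromosome -------
    site_pos: dict[str, np.ndarray] = {}
    site_carrier: dict[str, np.ndarray] = {}
    site_ref: dict[str, np.ndarray] = {}
    site_alt: dict[str, np.ndarray] = {}
    causal_snapped: list[CausalLocus] = []
    for chrom, length in config.chrom_lengths.items():
        n_snv = int(round(length * config.snv_density))
        pos = np.sort(rng.choice(length, size=n_snv, replace=False)) + 1
        keep = np.ones(len(pos), dtype=bool)
        for d in config.deletions:
            if d.chrom == chrom:
                keep &= (pos < d.start) | (pos > d.end)
        pos = pos[keep]
        carrier = rng.integers(0, 2, size=len(pos)).astype(np.int8)  # 1 = P2
        for locus in config.causal_loci:
            if locus.chrom == chrom:
                i = int(np.argmin(np.abs(pos.astype(np.int64) - locus.pos)))
                carrier[i] = 1  # the high parent contributes the raising allele
                causal_snapped.append(CausalLocus(chrom, int(pos[i]), locus.effect))
        ref, alt = _random_alleles(rng, len(pos))
        site_pos[chrom] = pos
        site_carrier[chrom] = carrier
        site_ref[chrom] = ref
        site_alt[chrom] = alt

    # --- gametes and F2 dosages of the P2 haplotype ---------------------
    # dosage[chrom] has shape (n_f2, n_sites + n_deletions_on_chrom): the
    # deletions ride along as pseudo-markers at their midpoints
    n_f2 = config.n_f2
    dosage: dict[str, np.ndarray] = {}
    del_cols: dict[int, tuple[str, int]] = {}
    for chrom, length in config.chrom_lengths.items():
        markers = site_pos[chrom].astype(np.float64)
        extra = []
        for j, d in enumerate(config.deletions):
            if d.chrom == chrom:
                del_cols[j] = (chrom, len(markers) + len(extra))
                extra.append((d.start + d.end) / 2)
        all_markers = np.concatenate([markers, np.array(extra)]) if extra else markers
        origins = _haldane_gametes(
            rng, 2 * n_f2, length, length * m_per_bp, all_markers
        )
        dosage[chrom] = (origins[0::2] + origins[1::2]).astype(np.int8)

    # --- phenotype: additive (optionally epistatic) + Gaussian noise ----
    causal_dosage = np.empty((n_f2, len(causal_snapped)))
    for k, locus in enumerate(causal_snapped):
        i = int(np.searchsorted(site_pos[locus.chrom], locus.pos))
        causal_dosage[:, k] = dosage[locus.chrom][:, i]
    genetic = (causal_dosage - 1) @ np.array([c.effect for c in causal_snapped])
    for pair in config.epistatic_pairs:
        genetic = genetic + pair.effect * (
            (causal_dosage[:, pair.locus_a] - 1)
            * (causal_dosage[:, pair.locus_b] - 1)
        )
    var_g = sum(c.effect**2 / 2 for c in causal_snapped)
    if config.residual_sd is not None:
        sd_e = config.residual_sd
    else:
        h2 = config.heritability
        sd_e = math.sqrt(var_g * (1 - h2) / h2) if causal_snapped else 1.0
    phenotypes = genetic + rng.normal(0.0, sd_e, size=n_f2)

    # --- phenotype tails become the pools --------------------------------
    n_low = int(round(config.tail_fractions[0] * n_f2))
    n_high = int(round(config.tail_fractions[1] * n_f2))
    order = np.argsort(phenotypes, kind="stable")
    low_idx = order[:n_low]
    high_idx = order[-n_high:]

    # --- truth: pool allele frequencies ----------------------------------
    sites: dict[str, ChromTruth] = {}
    for chrom in config.chrom_lengths:
        n_sites = len(site_pos[chrom])
        q_high = dosage[chrom][high_idx, :n_sites].mean(axis=0) / 2
        q_low = dosage[chrom][low_idx, :n_sites].mean(axis=0) / 2
        carrier = site_carrier[chrom]
        sites[chrom] = ChromTruth(
            positions=site_pos[chrom].astype(np.int64),
            carrier=np.where(carrier == 1, "P2", "P1"),
            af_high=np.where(carrier == 1, q_high, 1 - q_high),
            af_low=np.where(carrier == 1, q_low, 1 - q_low),
        )

    del_freq_high: list[float] = []
    del_freq_low: list[float] = []
    for j, d in enumerate(config.deletions):
        if d.carrier == "both":
            del_freq_high.append(1.0)
            del_freq_low.append(1.0)
            continue
        chrom, col = del_cols[j]
        q_h = dosage[chrom][high_idx, col].mean() / 2  # P2-haplotype freq
        q_l = dosage[chrom][low_idx, col].mean() / 2
        if d.carrier == "P2":
            del_freq_high.append(float(q_h))
            del_freq_low.append(float(q_l))
        else:
            del_freq_high.append(float(1 - q_h))
            del_freq_low.append(float(1 - q_l))

    # --- read sampling ----------------------------------------------------
    def _sample_reads(af: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        depth = rng.poisson(config.mean_depth, size=len(af))
        p = af
        if config.error_rate > 0:
            e = config.error_rate
            p = p * (1 - e) + (1 - p) * e
        alt = rng.binomial(depth, p)
        return depth, alt

    parent_variants: dict[str, list[PoolVariant]] = {"P1": [], "P2": []}
    pool_variants: dict[str, list[PoolVariant]] = {"high": [], "low": []}
    for chrom in config.chrom_lengths:
        t = sites[chrom]
        ref_al, alt_al = site_ref[chrom], site_alt[chrom]
        for parent in ("P1", "P2"):
            hom = t.carrier == parent
            depth, alt = _sample_reads(hom.astype(float))
            gt = np.where(hom, HOM_ALT, HOM_REF)
            parent_variants[parent].extend(
                PoolVariant(
                    chrom=chrom, pos=int(p), ref=str(r), alt=str(a),
                    ref_count=int(d - x), alt_count=int(x), genotype=str(g),
                )
                for p, r, a, d, x, g in zip(
                    t.positions, ref_al, alt_al, depth, alt, gt
                )
            )
        for pool, af in (("high", t.af_high), ("low", t.af_low)):
            depth, alt = _sample_reads(af)
            with np.errstate(invalid="ignore"):
                frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.5)
            gt = np.where(frac == 0, HOM_REF, np.where(frac == 1, HOM_ALT, HET))
            pool_variants[pool].extend(
                PoolVariant(
                    chrom=chrom, pos=int(p), ref=str(r), alt=str(a),
                    ref_count=int(d - x), alt_count=int(x), genotype=str(g),
                )
                for p, r, a, d, x, g in zip(
                    t.positions, ref_al, alt_al, depth, alt, gt
                )
            )

    # --- coverage tracks --------------------------------------------------
    emit_cov = (
        config.emit_coverage
        if config.emit_coverage is not None
        else bool(config.deletions)
    )
    coverage: dict[str, dict[str, CoverageTrack]] | None = None
    if emit_cov:
        coverage = {"high": {}, "low": {}}
        for pool, freqs in (("high", del_freq_high), ("low", del_freq_low)):
            for chrom, length in config.chrom_lengths.items():
                rate = np.full(length, config.mean_depth)
                for j, d in enumerate(config.deletions):
                    if d.chrom == chrom:
                        rate[d.start - 1 : d.end] = config.mean_depth * (1 - freqs[j])
                coverage[pool][chrom] = CoverageTrack(
                    chrom=chrom,
                    depth=rng.poisson(rate).astype(np.int32),
                    pool_id=pool,
                )

    # --- toy gene models tiled across each chromosome --------------------
    genes: list[GeneModel] = []
    for chrom, length in config.chrom_lengths.items():
        k = 0
        start = 1
        while start + config.gene_length - 1 <= length:
            genes.append(
                GeneModel(
                    gene_id=f"{chrom}_g{k:05d}",
                    chrom=chrom,
                    start=start,
                    end=start + config.gene_length - 1,
                )
            )
            k += 1
            start += config.gene_spacing

    truth = TruthTable(
        sites=sites,
        causal_loci=causal_snapped,
        deletions=list(config.deletions),
        deletion_freq_high=del_freq_high,
        deletion_freq_low=del_freq_low,
        phenotypes=phenotypes,
        low_pool_idx=low_idx,
        high_pool_idx=high_idx,
    )
    return SimulationResult(
        config=config,
        truth=truth,
        parent_variants=parent_variants,
        pool_variants=pool_variants,
        coverage=coverage,
        genes=genes,
    )


# ----------------------------------------------------------------------
# closed-form expectations

def expected_causal_pool_af(
    tail_fraction: float = 0.05, heritability: float = 0.5
) -> float:
    """Expected frequency of the trait-raising allele in the selected tail.

    Single additive biallelic locus in an F2 (dosage ~ Binomial(2, 1/2)),
    Gaussian residual with variance set by the heritability; the pool is
    the upper ``tail_fraction`` of the phenotype distribution.
    """
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail fraction must lie in (0, 0.5)")
    sd_e = math.sqrt((1 - heritability) / (2 * heritability))
    sd_p = math.sqrt(0.5 + sd_e**2)
    threshold = sd_p * norm.ppf(1 - tail_fraction)
    probs = np.array([0.25, 0.5, 0.25])       # dosage 0, 1, 2
    means = np.array([-1.0, 0.0, 1.0])
    p_sel = norm.sf((threshold - means) / sd_e)
    weights = probs * p_sel
    return float((weights * np.array([0.0, 0.5, 1.0])).sum() / weights.sum())


def haldane_recombination(distance_cm: float) -> float:
    """Recombination fraction at a Haldane genetic distance in cM."""
    if distance_cm < 0:
        raise ValueError("distance must be non-negative")
    return 0.5 * (1 - math.exp(-2 * distance_cm / 100))


def expected_pool_af(
    distance_cm: float,
    tail_fraction: float = 0.05,
    causal_pool_af: float | None = None,
    heritability: float = 0.5,
) -> float:
    """Expected selected-pool allele frequency at a linked neutral marker.

    The frequency skew decays with the recombination fraction r toward
    the free-recombination limit of 0.5:
    ``q(d) = 0.5 + (q0 - 0.5) * (1 - 2 r(d))``
    where q0 is the causal-locus pool frequency (computed from the tail
    fraction and heritability unless given explicitly).
    """
    if causal_pool_af is None:
        causal_pool_af = expected_causal_pool_af(tail_fraction, heritability)
    r = haldane_recombination(distance_cm)
    return 0.5 + (causal_pool_af - 0.5) * (1 - 2 * r)


def distance_for_pool_af(
    target_af: float,
    tail_fraction: float = 0.05,
    causal_pool_af: float | None = None,
    heritability: float = 0.5,
) -> float:
    """Genetic distance (cM) at which the expected pool AF decays to target."""
    if causal_pool_af is None:
        causal_pool_af = expected_causal_pool_af(tail_fraction, heritability)
    shrink = (target_af - 0.5) / (causal_pool_af - 0.5)
    if not 0 < shrink <= 1:
        raise ValueError("target frequency not reachable from the causal frequency")
    return -50.0 * math.log(shrink)


def structural_variant_demo_config(seed: int = 0) -> SimulationConfig:
    """Study conditions for the structural-variant fixtures.

    One 20 Mbp chromosome at 30x pool coverage with (a) a 10 kbp deletion
    shared by both parents (a ZCR: exactly zero coverage in both pools,
    window-aligned boundaries) and (b) a 60 kbp deletion private to the
    high parent P2, placed at the genetic distance where the expected
    deletion-haplotype tail frequencies are 0.75/0.25 — the depleted
    pool then shows ~1/4 of the background coverage against ~3/4 in the
    other pool, i.e. the characteristic ~3-fold normalized PAV ratio of
    an imperfectly sorted (polygenic-like) background.  30x keeps the
    depleted pool's raw mean under the mincov=10 call threshold.
    """
    causal_pos = 2_500_000
    cm_per_mb = 2.0
    d_cm = distance_for_pool_af(0.75, tail_fraction=0.05, heritability=0.5)
    offset_bp = int(round(d_cm / cm_per_mb * 1e6))
    del_start = causal_pos + offset_bp
    del_start = (del_start // 200) * 200 + 1  # align to the ZCR window grid
    return SimulationConfig(
        chrom_lengths={"chr1": 20_000_000},
        causal_loci=[CausalLocus("chr1", causal_pos, 1.0)],
        mean_depth=30.0,
        cm_per_mb=cm_per_mb,
        deletions=[
            Deletion("chr1", 5_000_001, 5_010_000, "both"),
            Deletion("chr1", del_start, del_start + 60_000 - 1, "P2"),
        ],
        seed=seed,
    )


# ----------------------------------------------------------------------
# VCF emission

def _write_vcf(
    path: Path,
    samples: Mapping[str, Sequence[PoolVariant]],
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write one joint VCF with AD/DP/GT for the given sample columns.

    All sample variant lists must cover the same sites in the same order
    (true for simulator output).
    """
    import pysam

    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allele read depths")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    names = list(samples)
    for name in names:
        header.add_sample(name)

    gt_code = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}
    per_sample = [samples[n] for n in names]
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in zip(*per_sample):
            v0 = row[0]
            rec = vcf.new_record(
                contig=v0.chrom, start=v0.pos - 1, stop=v0.pos,
                alleles=(v0.ref, v0.alt),
            )
            for name, v in zip(names, row):
                rec.samples[name]["GT"] = gt_code.get(v.genotype, (None, None))
                rec.samples[name]["AD"] = (v.ref_count, v.alt_count)
                rec.samples[name]["DP"] = v.depth
            vcf.write(rec)
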