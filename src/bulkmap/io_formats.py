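"""Readers and writers for the standard formats the pipeline touches.

VCF files (with per-sample allele depths), per-base coverage tables, GFF3
gene annotation, BED exports and TSV interval reports are translated into
the internal data model here.  All coordinates inside the pipeline are
1-based inclusive (the VCF/GFF3 convention); only the BED export converts
to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOM_REF = "hom-ref"
HET = "het"
HOM_ALT = "hom-alt"
MISSING = "missing"

_GT_CODE = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}


@dataclass(frozen=True)
class PoolVariant:
    """One biallelic variant site in one sample or pool.

    ``ref_count``/``alt_count`` are the allele-specific read depths (the AD
    field of the caller).  ``genotype`` is the caller's diploid genotype
    label; for a sequenced pool it is merely descriptive.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_count: int
    alt_count: int
    filter_status: str = "PASS"
    genotype: str = MISSING

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def alt_fraction(self) -> float:
        """Alternate-allele read fraction; NaN at zero depth."""
        d = self.depth
        return self.alt_count / d if d > 0 else float("nan")


@dataclass
class VcfReadResult:
    """Variants read for one sample, plus the skip counters."""

    variants: list[PoolVariant] = field(default_factory=list)
    n_multiallelic: int = 0
    n_missing_ad: int = 0
    n_malformed: int = 0

    def __iter__(self) -> Iterator[PoolVariant]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __getitem__(self, idx):
        return self.variants[idx]


def read_vcf(path: str | Path, sample: str) -> VcfReadResult:
    """Read per-sample biallelic variants with allele depths from a VCF.

    Multiallelic records are rejected (not split) and counted: triallelic
    sites are not contrasting between two homozygous parents, so downstream
    consumers only ever see single-ALT records.  Records without an AD entry
    for the sample are skipped and counted.  InDels are retained; SNV-only
    consumers filter on :attr:`PoolVariant.is_snv`.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    if sample not in vcf.samples:
        raise ValueError(f"sample {sample!r} not in VCF header ({vcf.samples})")
    si = vcf.samples.index(sample)

    result = VcfReadResult()
    for rec in vcf:
        try:
            alts = rec.ALT
            if len(alts) != 1:
                result.n_multiallelic += 1
                continue
            ad = rec.format("AD")
            if ad is None:
                result.n_missing_ad += 1
                continue
            ref_c, alt_c = int(ad[si][0]), int(ad[si][1])
            if ref_c < 0 or alt_c < 0:  # cyvcf2 encodes missing AD as negative
                result.n_missing_ad += 1
                continue
            result.variants.append(
                PoolVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alts[0],
                    ref_count=ref_c,
                    alt_count=alt_c,
                    filter_status=rec.FILTER or "PASS",
                    genotype=_GT_CODE.get(rec.gt_types[si], MISSING),
                )
            )
        except (ValueError, TypeError, IndexError) as exc:
            result.n_malformed += 1
            logger.warning("skipping malformed VCF record: %s", exc)
    if result.n_multiallelic or result.n_missing_ad or result.n_malformed:
        logger.info(
            "read_vcf(%s, %s): %d kept, %d multiallelic rejected, %d missing AD, %d malformed",
            path.name, sample, len(result), result.n_multiallelic,
            result.n_missing_ad, result.n_malformed,
        )
    return result


@dataclass
class CoverageTrack:
    """Per-base read depth of one pool on one chromosome.

    ``depth[i]`` is the depth at 1-based position ``i + 1``.
    """

    chrom: str
    depth: np.ndarray
    pool_id: str = ""

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.depth)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0


def read_coverage(
    path: str | Path,
    length: int | None = None,
    chrom: str | None = None,
    pool_id: str = "",
) -> CoverageTrack:
    """Read a 3-column coverage TSV (chromosome, 1-based position, depth).

    The file may be sparse; positions absent from the file get depth 0.
    Positions must be strictly increasing within the chromosome.  ``length``
    pins the chromosome length (defaults to the last listed position).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "pos", "depth"], comment="#",
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "pos", "depth"])
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    elif not df.empty:
        chroms = df["chrom"].unique()
        if len(chroms) > 1:
            raise ValueError(
                f"coverage file holds {len(chroms)} chromosomes; pass chrom="
            )
        chrom = chroms[0]
    if chrom is None:
        chrom = ""
    pos = df["pos"].to_numpy(dtype=np.int64)
    if len(pos) and (np.diff(pos) <= 0).any():
        raise ValueError(f"non-monotone positions in coverage file {path}")
    if length is None:
        if not len(pos):
            raise ValueError("empty coverage file needs an explicit length")
        length = int(pos[-1])
    dense = np.zeros(length, dtype=np.int32)
    if len(pos):
        if pos[-1] > length:
            raise ValueError("coverage positions exceed declared length")
        dense[pos - 1] = df["depth"].to_numpy(dtype=np.int32)
    return CoverageTrack(chrom=chrom, depth=dense, pool_id=pool_id)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write the dense track as 3-column TSV (every position, zeros included)."""
    df = pd.DataFrame({
        "chrom": track.chrom,
        "pos": np.arange(1, len(track) + 1),
        "depth": track.depth,
    })
    df.to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class GeneModel:
    """A gene feature with 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Read gene features from a GFF3 file into GeneModel records.

    Only ``gene`` features are returned (mRNA/exon children are ignored);
    features with end < start are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        if feat.end < feat.start:
            logger.warning("skipping gene %s with end < start", feat.id)
            continue
        note = feat.attributes.get("Note") or feat.attributes.get("description") or []
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                annotation="; ".join(note),
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.annotation:
                attrs += f";Note={g.annotation}"
            fh.write(
                f"{g.chrom}\tbulkmap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


INTERVAL_COLUMNS = ["Interval ID", "Chromosome", "Size [bp]", "Start [bp]", "End [bp]"]


def write_interval_table(intervals: Sequence, path: str | Path) -> None:
    """Write genomic intervals as a TSV report.

    Columns: Interval ID, Chromosome, Size [bp], Start [bp], End [bp];
    the size column equals end - start (the span between the first and
    last member variant).
    """
    rows = [
        {
            "Interval ID": iv.interval_id,
            "Chromosome": iv.chrom,
            "Size [bp]": iv.end - iv.start,
            "Start [bp]": iv.start,
            "End [bp]": iv.end,
        }
        for iv in intervals
    ]
    pd.DataFrame(rows, columns=INTERVAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_interval_table(path: str | Path) -> list:
    """Read an interval report TSV back into GenomicInterval records."""
    from .intervals import GenomicInterval

    df = pd.read_csv(path, sep="\t")
    out = []
    for rank, row in enumerate(df.itertuples(index=False), start=1):
        out.append(
            GenomicInterval(
                interval_id=str(row[0]),
                chrom=str(row[1]),
                start=int(row[3]),
                end=int(row[4]),
                n_darcs=0,
                rank=rank,
            )
        )
    return out


def write_bed(regions: Sequence, path: str | Path) -> None:
    """Export regions (anything with chrom/start/end, 1-based inclusive) as BED.

    BED is 0-based half-open, so start shifts by -1 and end stays.
    """
    with open(path, "w") as fh:
        for r in regions:
            name = getattr(r, "interval_id", None) or getattr(r, "gene_id", ".")
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")
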