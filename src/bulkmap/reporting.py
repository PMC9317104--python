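"""Smoothed dAF tracks, dARC densities, candidate genes and impact reports.

Window tracks support the genome-wide visualization of the mapping
signal: a median-smoothed dAF track (sliding window of 100 variants,
stepped by 5 variants), the normalized dARC density (dARCs per SNV in
100 kbp windows stepped by 30 kbp), and per-window mean coverage
normalized to the chromosome maximum.  Candidate genes are extracted
within +/- 5 kbp of interval borders, and effect-annotated variants are
filtered down to the four high-impact classes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, GeneModel
from .intervals import GenomicInterval
from .pool_stats import AlleleFrequencyRecord

logger = logging.getLogger(__name__)


@dataclass
class WindowTrack:
    """One value per window position on one chromosome."""

    chrom: str
    starts: np.ndarray  # 1-based start coordinate of each window
    values: np.ndarray  # NaN marks a window with no defined value
    kind: str

    def __len__(self) -> int:
        return len(self.values)


def smooth_daf(
    records: Sequence[AlleleFrequencyRecord],
    window: int = 100,
    step: int = 5,
) -> list[WindowTrack]:
    """Median-smooth the dAF signal in sliding variant-count windows.

    Windows contain ``window`` consecutive variants and advance by
    ``step`` variants; the trailing partial window is dropped.  Returns
    one track per chromosome (empty with a warning when a chromosome has
    fewer than ``window`` variants).  The window position is the genomic
    coordinate of its first variant.
    """
    tracks: list[WindowTrack] = []
    by_chrom: dict[str, list[AlleleFrequencyRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, recs in sorted(by_chrom.items()):
        recs.sort(key=lambda r: r.pos)
        dafs = np.array([r.daf for r in recs])
        pos = np.array([r.pos for r in recs])
        if len(recs) < window:
            logger.warning(
                "chromosome %s has %d < %d variants; empty smoothed track",
                chrom, len(recs), window,
            )
            tracks.append(WindowTrack(chrom, np.array([], dtype=int),
                                      np.array([]), "smoothed_daf"))
            continue
        offsets = np.arange(0, len(recs) - window + 1, step)
        values = np.array([np.median(dafs[o : o + window]) for o in offsets])
        tracks.append(WindowTrack(chrom, pos[offsets], values, "smoothed_daf"))
    return tracks


def _window_starts(length: int, window: int, step: int) -> np.ndarray:
    """Full windows anchored at position 1 with a fixed step."""
    last_start = length - window + 1
    if last_start < 1:
        return np.array([], dtype=np.int64)
    return np.arange(1, last_start + 1, step, dtype=np.int64)


def darc_density(
    darc_positions: Sequence[int],
    snv_positions: Sequence[int],
    chrom: str = "",
    chrom_length: int | None = None,
    window: int = 100_000,
    step: int = 30_000,
) -> WindowTrack:
    """Normalized dARC density: dARCs per SNV in each sliding window.

    Windows with zero SNVs yield NaN (a variant desert, visually distinct
    from a significance-free region).  Since dARCs are a subset of the
    SNVs, values lie in [0, 1].
    """
    darcs = np.sort(np.asarray(darc_positions, dtype=np.int64))
    snvs = np.sort(np.asarray(snv_positions, dtype=np.int64))
    if chrom_length is None:
        chrom_length = int(snvs[-1]) if len(snvs) else 0
    starts = _window_starts(chrom_length, window, step)
    ends = starts + window - 1
    n_darc = np.searchsorted(darcs, ends, side="right") - np.searchsorted(
        darcs, starts, side="left"
    )
    n_snv = np.searchsorted(snvs, ends, side="right") - np.searchsorted(
        snvs, starts, side="left"
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_snv > 0, n_darc / np.maximum(n_snv, 1), np.nan)
    return WindowTrack(chrom, starts, values, "darc_density")


def normalized_mean_coverage(
    track: CoverageTrack,
    window: int = 100_000,
    step: int = 30_000,
) -> WindowTrack:
    """Per-window mean depth scaled by the chromosome-wide maximum mean.

    An all-zero chromosome yields all zeros (no division by zero).
    """
    starts = _window_starts(len(track), window, step)
    csum = np.concatenate([[0], np.cumsum(track.depth, dtype=np.int64)])
    means = (csum[starts + window - 1] - csum[starts - 1]) / window
    peak = means.max(initial=0.0)
    values = means / peak if peak > 0 else means
    return WindowTrack(track.chrom, starts, values, "norm_coverage")


def extract_candidate_genes(
    intervals: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    flank: int = 5_000,
) -> dict[str, list[GeneModel]]:
    """Genes located within or spanning over interval borders +/- flank.

    A gene qualifies for an interval when [gene.start, gene.end] overlaps
    [interval.start - flank, interval.end + flank] by at least one base
    (touching the flank boundary counts).
    """
    out: dict[str, list[GeneModel]] = {}
    for iv in intervals:
        lo, hi = iv.start - flank, iv.end + flank
        hits = [
            g for g in genes
            if g.chrom == iv.chrom and g.end >= lo and g.start <= hi
        ]
        hits.sort(key=lambda g: g.start)
        out[iv.interval_id] = hits
    return out


#: the high-impact effect classes reported by this pipeline; other
#: annotation-HIGH classes (e.g. start_lost) are excluded by default
HIGH_IMPACT_CLASSES = {
    "stop_gained": "stop_gained",
    "stop_lost": "stop_lost",
    "frameshift_variant": "frameshift",
    "splice_acceptor_variant": "splice_site",
    "splice_donor_variant": "splice_site",
}


@dataclass(frozen=True)
class ImpactVariant:
    """A high-impact effect prediction at one variant in one gene."""

    chrom: str
    pos: int
    gene_id: str
    effect_class: str  # stop_gained / stop_lost / frameshift / splice_site
    af_high: float = float("nan")
    af_low: float = float("nan")


def filter_high_impact(
    vcf_path: str | Path,
    candidate_genes: Iterable[str] | None = None,
    af_records: Sequence[AlleleFrequencyRecord] | None = None,
    classes: Mapping[str, str] = HIGH_IMPACT_CLASSES,
) -> list[ImpactVariant]:
    """Filter an effect-annotated VCF (ANN fields) to high-impact variants.

    Keeps stop gain/loss, frameshift and splice-site (donor/acceptor)
    predictions.  ``candidate_genes`` restricts the report to the genes
    extracted from the genomic intervals; ``af_records`` attaches the pool
    allele frequencies where the position was jointly genotyped.
    Unparsable ANN entries are skipped with a warning.
    """
    from cyvcf2 import VCF

    gene_filter = set(candidate_genes) if candidate_genes is not None else None
    af_map = (
        {(r.chrom, r.pos): (r.af_high, r.af_low) for r in af_records}
        if af_records
        else {}
    )
    out: list[ImpactVariant] = []
    for rec in VCF(str(vcf_path)):
        ann = rec.INFO.get("ANN")
        if ann is None:
            continue
        for entry in str(ann).split(","):
            fields = entry.split("|")
            if len(fields) < 5:
                logger.warning("unparsable ANN entry at %s:%d", rec.CHROM, rec.POS)
                continue
            terms = fields[1].split("&")
            gene_id = fields[4] or fields[3]
            hit = next((classes[t] for t in terms if t in classes), None)
            if hit is None:
                continue
            if gene_filter is not None and gene_id not in gene_filter:
                continue
            af_h, af_l = af_map.get((rec.CHROM, rec.POS), (float("nan"), float("nan")))
            out.append(
                ImpactVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    gene_id=gene_id,
                    effect_class=hit,
                    af_high=af_h,
                    af_low=af_l,
                )
            )
    return out


@dataclass
class ChromosomeSummary:
    """Interval tally per chromosome plus the grand total."""

    per_chrom: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_chrom.values())

    def __getitem__(self, chrom: str) -> int:
        return self.per_chrom.get(chrom, 0)


def chromosome_summary(intervals: Sequence[GenomicInterval]) -> ChromosomeSummary:
    """Count reported intervals per chromosome."""
    return ChromosomeSummary(per_chrom=dict(Counter(iv.chrom for iv in intervals)))


def window_tracks_to_frame(tracks: Sequence[WindowTrack]) -> pd.DataFrame:
    """Flatten window tracks into a bedGraph-style table."""
    frames = [
        pd.DataFrame(
            {"chrom": t.chrom, "start": t.starts, "value": t.values, "kind": t.kind}
        )
        for t in tracks
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "value", "kind"]
    )


def plot_tracks(
    tracks: Sequence[WindowTrack], path: str | Path, title: str = ""
) -> None:
    """Quick-look plot of window tracks, one panel per track kind."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    kinds = sorted({t.kind for t in tracks})
    fig, axes = plt.subplots(len(kinds), 1, figsize=(10, 2.5 * len(kinds)),
                             sharex=True, squeeze=False)
    for ax, kind in zip(axes[:, 0], kinds):
        for t in tracks:
            if t.kind == kind and len(t):
                ax.plot(t.starts / 1e6, t.values, lw=0.8, label=t.chrom)
        ax.set_ylabel(kind)
        ax.legend(fontsize=6, loc="upper right")
    axes[-1, 0].set_xlabel("position [Mbp]")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
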