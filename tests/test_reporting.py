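"""Window tracks, candidate-gene extraction, impact filtering, summaries."""

import numpy as np
import pytest

from bulkmap import reporting
from bulkmap.io_formats import CoverageTrack, GeneModel
from bulkmap.intervals import GenomicInterval
from bulkmap.pool_stats import AlleleFrequencyRecord
from bulkmap.reference_data import load_reference_intervals

from conftest import make_vcf


def af_rec(pos, daf, chrom="chr1"):
    """Record with af_high = daf, af_low = 0 at depth 100."""
    alt_h = int(round(daf * 100))
    return AlleleFrequencyRecord(chrom, pos, "A", "G", 100 - alt_h, alt_h, 100, 0)


class TestSmoothDaf:
    def test_identical_dafs_single_window(self):
        records = [af_rec(1 + 10 * i, 0.3) for i in range(100)]
        (track,) = reporting.smooth_daf(records)
        assert len(track) == 1 and track.values[0] == pytest.approx(0.3)

    def test_window_count_formula(self):
        records = [af_rec(1 + 10 * i, 0.5) for i in range(105)]
        (track,) = reporting.smooth_daf(records)
        assert len(track) == (105 - 100) // 5 + 1 == 2

    def test_median_robust_to_outlier(self):
        records = [af_rec(1 + i, 0.1) for i in range(99)] + [af_rec(200, 1.0)]
        (track,) = reporting.smooth_daf(records)
        assert track.values[0] == pytest.approx(0.1)

    def test_too_few_variants_empty_track_with_warning(self, caplog):
        records = [af_rec(i + 1, 0.2) for i in range(10)]
        with caplog.at_level("WARNING"):
            (track,) = reporting.smooth_daf(records)
        assert len(track) == 0
        assert "10" in caplog.text


class TestDarcDensity:
    def test_full_and_zero_and_missing_windows(self):
        snvs = list(range(1, 100_001, 2_000))  # 50 SNVs inside window 1
        t_full = reporting.darc_density(snvs, snvs, chrom_length=100_000)
        assert t_full.values[0] == 1.0
        t_zero = reporting.darc_density([], snvs, chrom_length=100_000)
        assert t_zero.values[0] == 0.0
        t_missing = reporting.darc_density([], [], chrom_length=100_000)
        assert np.isnan(t_missing.values[0])

    def test_density_never_exceeds_one(self):
        rng = np.random.default_rng(0)
        snvs = np.sort(rng.choice(1_000_000, 500, replace=False))
        darcs = np.sort(rng.choice(snvs, 200, replace=False))
        track = reporting.darc_density(darcs, snvs, chrom_length=1_000_000)
        vals = track.values[~np.isnan(track.values)]
        assert ((0 <= vals) & (vals <= 1)).all()


class TestNormalizedCoverage:
    def test_constant_depth_all_ones(self):
        track = CoverageTrack("chr1", np.full(300_000, 25), "p")
        out = reporting.normalized_mean_coverage(track)
        assert np.allclose(out.values, 1.0)

    def test_peak_window_normalizes_to_one(self):
        depth = np.full(400_000, 25)
        depth[:100_000] = 50
        out = reporting.normalized_mean_coverage(CoverageTrack("chr1", depth, "p"))
        assert out.values[0] == pytest.approx(1.0)
        assert out.values[-1] == pytest.approx(0.5)

    def test_all_zero_chromosome_yields_zeros(self):
        out = reporting.normalized_mean_coverage(
            CoverageTrack("chr1", np.zeros(200_000, dtype=int), "p")
        )
        assert (out.values == 0).all()


class TestCandidateGenes:
    IV = GenomicInterval("A_1", "chr1", 100_000, 200_000, n_darcs=10, rank=1)

    @pytest.mark.parametrize(
        "start,end,included",
        [
            (94_000, 95_000, True),     # ends exactly at start - 5,000: touching
            (150_000, 155_000, True),   # fully inside
            (93_000, 94_999, False),    # 5,001 bp upstream of the border
            (204_500, 210_000, True),   # spans the downstream flank
            (205_001, 210_000, False),  # just beyond the downstream flank
        ],
    )
    def test_flank_overlap_boundaries(self, start, end, included):
        gene = GeneModel("g", "chr1", start, end)
        hits = reporting.extract_candidate_genes([self.IV], [gene])["A_1"]
        assert (hits == [gene]) is included

    def test_flank_monotonicity(self):
        rng = np.random.default_rng(1)
        genes = [
            GeneModel(f"g{i}", "chr1", int(s), int(s) + 2_000)
            for i, s in enumerate(rng.choice(400_000, 50, replace=False))
        ]
        tight = reporting.extract_candidate_genes([self.IV], genes, flank=0)["A_1"]
        wide = reporting.extract_candidate_genes([self.IV], genes, flank=5_000)["A_1"]
        assert set(g.gene_id for g in tight) <= set(g.gene_id for g in wide)

    def test_other_chromosome_excluded(self):
        gene = GeneModel("g", "chr2", 150_000, 160_000)
        assert reporting.extract_candidate_genes([self.IV], [gene])["A_1"] == []


ANN_BODY = [
    "chrA\t100\t.\tC\tT\t50\tPASS\tANN=T|stop_gained|HIGH|G1|G1|transcript|t1|x\tGT:AD:DP\t0/1:10,10:20",
    "chrA\t200\t.\tC\tT\t50\tPASS\tANN=T|missense_variant|MODERATE|G2|G2|transcript|t2|x\tGT:AD:DP\t0/1:10,10:20",
    "chrA\t300\t.\tCA\tC\t50\tPASS\tANN=C|frameshift_variant|HIGH|G3|G3|transcript|t3|x\tGT:AD:DP\t0/1:10,10:20",
    "chrA\t400\t.\tG\tA\t50\tPASS\tANN=A|splice_donor_variant&intron_variant|HIGH|G4|G4|transcript|t4|x\tGT:AD:DP\t0/1:10,10:20",
    "chrA\t500\t.\tG\tA\t50\tPASS\tANN=A|start_lost|HIGH|G5|G5|transcript|t5|x\tGT:AD:DP\t0/1:10,10:20",
]


class TestHighImpact:
    def test_only_the_four_classes_kept(self, tmp_path):
        path = make_vcf(tmp_path, ANN_BODY, name="ann.vcf")
        hits = reporting.filter_high_impact(path)
        assert [(h.gene_id, h.effect_class) for h in hits] == [
            ("G1", "stop_gained"), ("G3", "frameshift"), ("G4", "splice_site"),
        ]

    def test_candidate_gene_restriction_and_pool_afs(self, tmp_path):
        path = make_vcf(tmp_path, ANN_BODY, name="ann.vcf")
        afs = [AlleleFrequencyRecord("chrA", 300, "CA", "C", 79, 21, 14, 86)]
        hits = reporting.filter_high_impact(
            path, candidate_genes={"G3"}, af_records=afs
        )
        assert len(hits) == 1
        h = hits[0]
        assert h.effect_class == "frameshift"
        assert h.af_high == pytest.approx(0.21)
        assert h.af_low == pytest.approx(0.86)


class TestChromosomeSummary:
    def test_reference_gsl_table_tallies(self):
        summary = reporting.chromosome_summary(load_reference_intervals("GSL"))
        assert summary["chrA09"] == 18
        assert summary.total == 30

    def test_reference_spc_table_tallies(self):
        summary = reporting.chromosome_summary(load_reference_intervals("SPC"))
        assert summary["chrC08"] == 5
        assert summary.total == 15

    def test_empty_interval_list(self):
        summary = reporting.chromosome_summary([])
        assert summary.per_chrom == {} and summary.total == 0

    def test_reference_tables_respect_size_convention(self):
        for trait in ("GSL", "SPC"):
            for iv in load_reference_intervals(trait):
                assert iv.size == iv.end - iv.start


def test_plot_tracks_smoke(tmp_path):
    records = [af_rec(1 + 10 * i, 0.3) for i in range(120)]
    tracks = reporting.smooth_daf(records)
    out = tmp_path / "tracks.png"
    reporting.plot_tracks(tracks, out, title="demo")
    assert out.stat().st_size > 0
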