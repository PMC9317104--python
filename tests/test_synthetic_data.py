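"""The F2 bulk-segregant simulator and its closed-form expectations."""

import numpy as np
import pytest

from bulkmap import io_formats
from bulkmap.synthetic_data import (
    CausalLocus,
    Deletion,
    SimulationConfig,
    distance_for_pool_af,
    expected_causal_pool_af,
    expected_pool_af,
    simulate_f2,
)


class TestConfigValidation:
    def test_infeasible_tail_fatal(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_f2=10, tail_fractions=(0.01, 0.05))

    def test_locus_outside_bounds_fatal(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                chrom_lengths={"chr1": 1_000},
                causal_loci=[CausalLocus("chr1", 2_000, 1.0)],
            )

    def test_unknown_deletion_carrier_fatal(self):
        with pytest.raises(ValueError):
            SimulationConfig(deletions=[Deletion("chr1", 1, 100, "P3")])


class TestReproducibility:
    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(
            chrom_lengths={"chr1": 500_000},
            causal_loci=[CausalLocus("chr1", 250_000, 1.0)],
            n_f2=100,
            seed=5,
        )
        a, b = simulate_f2(cfg), simulate_f2(cfg)
        assert np.array_equal(a.truth.phenotypes, b.truth.phenotypes)
        assert a.pool_variants["high"] == b.pool_variants["high"]
        assert a.parent_variants["P1"] == b.parent_variants["P1"]

    def test_different_seed_differs(self):
        cfg = SimulationConfig(
            chrom_lengths={"chr1": 500_000},
            causal_loci=[CausalLocus("chr1", 250_000, 1.0)],
            n_f2=100,
        )
        a = simulate_f2(cfg, seed=1)
        b = simulate_f2(cfg, seed=2)
        assert not np.array_equal(a.truth.phenotypes, b.truth.phenotypes)


class TestTruthSelfChecks:
    def test_causal_site_pool_frequencies_separate(self, default_sim):
        """Strong effect, small tails: the trait-raising allele reaches
        > 0.8 in the high pool and < 0.2 in the low pool (genotype tally)."""
        truth = default_sim.truth
        locus = truth.causal_loci[0]
        t = truth.sites[locus.chrom]
        i = int(np.searchsorted(t.positions, locus.pos))
        assert t.af_high[i] > 0.8
        assert t.af_low[i] < 0.2

    def test_unlinked_sites_near_half(self):
        """With no causal locus every site is unlinked to the selection:
        pool frequencies stay within binomial noise of 0.5 (s.e. over
        2 * pool_n sampled F2 alleles)."""
        # many short chromosomes give near-independent linkage blocks
        cfg = SimulationConfig(
            chrom_lengths={f"chr{i}": 250_000 for i in range(1, 21)},
            causal_loci=[],
            n_f2=1_000,
            seed=3,
        )
        truth = simulate_f2(cfg).truth
        n_alleles = 2 * len(truth.high_pool_idx)
        bound = 3 * np.sqrt(0.25 / n_alleles)
        devs = np.concatenate(
            [np.abs(t.af_high - 0.5) for t in truth.sites.values()]
        )
        # neighbouring sites are linked to each other, so deviations are
        # correlated within a chromosome; require the large majority of
        # sites inside the 3-sigma band
        assert len(devs) > 1_000
        assert (devs <= bound).mean() > 0.9

    def test_observed_pool_afs_track_truth(self, default_sim):
        truth = default_sim.truth.sites["chr1"]
        obs = np.array(
            [v.alt_fraction for v in default_sim.pool_variants["high"]]
        )
        ok = ~np.isnan(obs)
        # binomial read noise at depth ~50 around the true frequency
        assert np.nanmean(np.abs(obs[ok] - truth.af_high[ok])) < 0.06

    def test_no_snvs_inside_deletions(self, sv_sim):
        positions = sv_sim.truth.sites["chr1"].positions
        for d in sv_sim.config.deletions:
            assert not ((positions >= d.start) & (positions <= d.end)).any()

    def test_shared_deletion_coverage_exactly_zero(self, sv_sim):
        shared = [d for d in sv_sim.config.deletions if d.carrier == "both"]
        assert shared
        for d in shared:
            for pool in ("high", "low"):
                depth = sv_sim.coverage[pool][d.chrom].depth[d.start - 1 : d.end]
                assert depth.max(initial=0) == 0


class TestExpectedPoolAf:
    def test_zero_distance_is_causal_frequency(self):
        q0 = expected_causal_pool_af(0.05, 0.5)
        assert expected_pool_af(0.0) == pytest.approx(q0)

    def test_infinite_distance_reaches_half(self):
        assert expected_pool_af(1e6) == pytest.approx(0.5)

    def test_monotone_decay(self):
        qs = [expected_pool_af(d) for d in (0, 5, 10, 20, 50, 100)]
        assert qs == sorted(qs, reverse=True)

    def test_matches_gamete_class_enumeration(self):
        """10 cM from a locus with pool frequency 0.9: enumerate the four
        gamete classes (causal allele x parental origin at the marker)."""
        q0, d = 0.9, 10.0
        r = 0.5 * (1 - np.exp(-2 * d / 100))
        # marker allele matches the causal allele with probability 1 - r
        expected = q0 * (1 - r) + (1 - q0) * r
        assert expected_pool_af(d, causal_pool_af=q0) == pytest.approx(expected)

    def test_distance_inversion_roundtrip(self):
        q0 = expected_causal_pool_af(0.05, 0.5)
        d = distance_for_pool_af(0.75)
        assert expected_pool_af(d) == pytest.approx(0.75)
        assert 0 < d < 100
        with pytest.raises(ValueError):
            distance_for_pool_af(0.4)  # below the free-recombination floor

    def test_causal_pool_af_increases_with_selection_pressure(self):
        assert expected_causal_pool_af(0.02) > expected_causal_pool_af(0.2)
        assert expected_causal_pool_af(0.05, 0.9) > expected_causal_pool_af(0.05, 0.2)

    def test_mean_observed_daf_matches_expectation(self, default_sim):
        """The truth dAF at the causal site agrees with the closed-form
        two-tail expectation within sampling noise."""
        cfg = default_sim.config
        q0 = expected_causal_pool_af(cfg.tail_fractions[1], cfg.heritability)
        expected_daf = q0 - (1 - q0)
        assert default_sim.truth.causal_daf() == pytest.approx(expected_daf, abs=0.08)


class TestFileEmission:
    def test_written_outputs_roundtrip_through_io(self, small_sim, tmp_path):
        paths = small_sim.write_outputs(tmp_path / "sim")
        p1 = io_formats.read_vcf(paths["parents_vcf"], "P1")
        assert len(p1) == len(small_sim.parent_variants["P1"])
        assert p1.variants == small_sim.parent_variants["P1"]
        high = io_formats.read_vcf(paths["pools_vcf"], "HIGH")
        truth = small_sim.truth.sites["chr1"]
        assert [v.pos for v in high] == truth.positions.tolist()
        track = io_formats.read_coverage(
            paths["coverage_high_chr1"], pool_id="high"
        )
        assert np.array_equal(track.depth, small_sim.coverage["high"]["chr1"].depth)
        genes = io_formats.read_gff3(paths["genes_gff3"])
        assert [g.gene_id for g in genes] == [g.gene_id for g in small_sim.genes]
        assert paths["truth_json"].stat().st_size > 0
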