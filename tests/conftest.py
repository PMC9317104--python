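"""Shared fixtures: tiny hand-written format fixtures and session-scoped
simulations (generated programmatically, nothing read from disk)."""

from __future__ import annotations

import textwrap

import pytest

from bulkmap.synthetic_data import (
    SimulationConfig,
    simulate_f2,
    structural_variant_demo_config,
)

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chrA,length=100000>
    ##contig=<ID=chrB,length=100000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
    ##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
    """
)


def make_vcf(tmp_path, body_lines, name="toy.vcf", header=VCF_HEADER):
    """Write a small plain-text VCF and return its path."""
    path = tmp_path / name
    path.write_text(header + "".join(line + "\n" for line in body_lines))
    return path


@pytest.fixture
def toy_vcf(tmp_path):
    """Three records: a hom-alt SNV, a het SNV, and a multiallelic site."""
    return make_vcf(
        tmp_path,
        [
            "chrA\t100\t.\tA\tG\t50\tPASS\t.\tGT:AD:DP\t1/1:12,30:42",
            "chrA\t200\t.\tC\tT\t50\tPASS\t.\tGT:AD:DP\t0/1:20,21:41",
            "chrA\t300\t.\tG\tA,T\t50\tPASS\t.\tGT:AD:DP\t1/2:2,20,20:42",
        ],
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation (20 Mbp, n_f2=1000, 5% tails, 50x)."""
    return simulate_f2(SimulationConfig(seed=20_260_921))


@pytest.fixture(scope="session")
def sv_sim():
    """The structural-variant demo: shared + single-parent deletions at 30x."""
    return simulate_f2(structural_variant_demo_config(seed=7))


@pytest.fixture(scope="session")
def small_sim():
    """A light simulation for IO round-trips (2 Mbp, 200 F2, sparse SNVs)."""
    from bulkmap.synthetic_data import CausalLocus

    config = SimulationConfig(
        chrom_lengths={"chr1": 2_000_000},
        causal_loci=[CausalLocus("chr1", 1_000_000, 1.0)],
        n_f2=200,
        snv_density=1 / 10_000,
        emit_coverage=True,
        seed=11,
    )
    return simulate_f2(config)
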