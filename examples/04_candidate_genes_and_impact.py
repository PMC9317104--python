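"""From intervals to candidate genes and high-impact variants.

Extracts the genes within +/- 5 kbp of the top interval's borders, then
filters a small effect-annotated VCF (SnpEff-style ANN fields) down to
the four high-impact classes (stop gain/loss, frameshift, splice site)
restricted to those candidates.
"""

import tempfile
import textwrap
from pathlib import Path

from bulkmap.pipeline import run_mbs
from bulkmap.reporting import extract_candidate_genes, filter_high_impact
from bulkmap.synthetic_data import SimulationConfig, simulate_f2

sim = simulate_f2(SimulationConfig(seed=42))
res = run_mbs(
    sim.parent_variants["P1"], sim.parent_variants["P2"],
    sim.pool_variants["high"], sim.pool_variants["low"],
)
top = res.intervals[0]
candidates = extract_candidate_genes([top], sim.genes)[top.interval_id]
print(f"top interval {top.interval_id}: {len(candidates)} candidate genes")

# a toy annotated VCF placing a frameshift in the first candidate gene
gene = candidates[0]
ann_vcf = textwrap.dedent(
    f"""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=20000000>
    ##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
    chr1\t{gene.start + 100}\t.\tCA\tC\t50\tPASS\tANN=C|frameshift_variant|HIGH|{gene.gene_id}|{gene.gene_id}|transcript|t1|x
    chr1\t{gene.start + 200}\t.\tG\tA\t50\tPASS\tANN=A|missense_variant|MODERATE|{gene.gene_id}|{gene.gene_id}|transcript|t1|x
    """
)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "ann.vcf"
    path.write_text(ann_vcf)
    hits = filter_high_impact(
        path, candidate_genes=[g.gene_id for g in candidates],
        af_records=res.af_records,
    )
print("high-impact variants in candidate genes:")
for h in hits:
    print(f"  {h.chrom}:{h.pos:,} {h.gene_id} {h.effect_class}")
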