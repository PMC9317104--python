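# bulkmap

Mapping-by-sequencing (MBS / bulk segregant analysis) for large F2
populations: from parental and pool variant calls plus per-base coverage
tracks to trait-associated genomic intervals, candidate genes and
presence–absence variations (PAVs).

The package is written for geneticists analyzing pooled sequencing of
phenotypic extremes — the design used to map seed quality loci in crops
such as *Brassica napus*, where two homozygous parents are crossed, a
large F2 is phenotyped, and the tails of the phenotype distribution are
pooled and sequenced.

## The method

For each biallelic SNV with pool read counts, the **allele frequency** in
a pool is the alternate-read fraction `AF = alt / (ref + alt)`, and the
**delta allele frequency** between the high and low pools is

```
dAF = |AF_high − AF_low|
```

Raw calls are first whitelisted against a **gold standard**: SNVs that are
homozygous in exactly one parent (coverage 10–60, about twice the modal
depth as a ceiling), contrasting between the parents (shared and
triallelic sites dropped), and heterozygous-looking (AF 0.2–0.8) in a
*reconstituted F1* built by summing the parental read counts. Pool sites
are then kept within 0.75–1.5× the pool's median coverage.

Each surviving site's 2×2 table `[[ref_high, alt_high], [ref_low,
alt_low]]` is tested with a two-sided Fisher exact test; after
Benjamini–Hochberg correction, sites with adjusted p < 0.05 are **dARCs**
(differential allele-specific read counts). dARCs are chained into
**genomic intervals** with three rules: ≥ 4 dARCs per interval, ≥ 3 dARCs
pairwise > 1 kbp apart, and adjacent dARCs < 50 kbp apart; zero-coverage
regions (200 bp windows with no reads in either pool, typically shared
deletions) may bridge splits. Intervals are ranked by dARC count.

Coverage is screened separately for gene-level **PAVs**: a gene whose
depleted pool has a raw mean depth below 10 and whose normalized coverage
ratio between pools is ≥ 2 — a deletion carried by one parent under
opposite tail selection shows the characteristic ~3-fold ("1/3 coverage")
contrast.

A first-class **simulator** generates complete synthetic experiments
(parents, Haldane-model F2 gametes, additive phenotypes, tail pools,
binomial read sampling at Poisson depth, engineered deletions) with a
truth table, so every stage is testable without any sequencing data.

## Worked example

`examples/01_full_pipeline.py` simulates an F2 of 1,000 plants with one
causal locus on chr2 of three 8 Mbp chromosomes, pools the 5% tails at
50× coverage, and runs the full pipeline:

```
causal locus: chr2:4,000,717 (true dAF 0.94)
gold-standard SNVs: 11,125
dARCs: 3,641 of 10,361 joined sites
rank 1: 2_SIM_1 chr2:106-7,996,090 (3463 dARCs, 8.00 Mbp) <- contains causal locus
rank 2: 1_SIM_5 chr1:2,640,276-2,745,438 (7 dARCs, 0.11 Mbp)
...
```

The top-ranked interval carries 3,463 dARCs and brackets the causal
position; unlinked chromosomes only produce small spurious clusters
(≤ 7 dARCs) — the reason a trait-specific dARC-count cutoff (e.g. ≥ 100)
is applied before downstream interpretation. With a 40 cM chromosome and
strong selection, linkage keeps the top interval broad; candidate genes
and high-impact variants (stop gain/loss, frameshift, splice site; see
`examples/04_candidate_genes_and_impact.py`) narrow it to mechanisms.

`examples/02_structural_variants.py` shows the coverage side: a shared
10 kbp deletion is recovered as a ZCR with window-exact boundaries, and a
single-parent 60 kbp deletion as PAV calls with a normalized ratio ≈ 2–3.

The other entry points are the library API (`bulkmap.run_mbs`,
`bulkmap.simulate_f2`, …) and a thin CLI (`bulkmap --help`) with
subcommands `simulate`, `gold-standard`, `daf`, `call-darcs`,
`detect-intervals`, `zcr`, `pav`, `candidates`, `impact` and `tracks`.

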