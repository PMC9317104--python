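# Methods

This note documents the statistical model, the parameter choices and the
numerical conventions behind `bulkmap`, and what the synthetic experiments
do and do not demonstrate.

## Experimental design the package models

A cross of two homozygous parents (P1, P2) yields a large F2 population
segregating for quantitative traits. The phenotypic extremes (tails of
the trait distribution) are pooled and sequenced together with the
parents. At a biallelic SNV, the pooled alternate-read fraction estimates
the allele frequency among the selected individuals; a locus influencing
the trait drags its chromosomal neighbourhood to opposite frequencies in
the two pools, producing a delta-allele-frequency (dAF) peak and a dense
run of statistically significant sites.

## Gold-standard whitelist

Pool frequencies are only interpretable at sites that segregate cleanly
from the parents. The whitelist keeps SNVs that are:

1. **Homozygous-ALT in one parent** with depth in `[min_cov, max_cov]`
   (defaults 10/60; the ceiling is about twice the modal depth of a ~30×
   run and guards against copy-number inflation). Homozygosity comes from
   the caller's GT; when GT is missing the fallback is an ALT read
   fraction ≥ 0.9.
2. **Contrasting**: present in exactly one parent. Sites with the same
   ALT in both parents are not contrasting; sites with different ALT
   alleles are triallelic. Both are dropped and counted. Multiallelic
   VCF records are rejected at parse time (not split) for the same
   reason, with a counter.
3. **Heterozygous in the reconstituted F1**: summing both parents' read
   counts emulates an F1; the site's combined AF must lie in
   `[0.2, 0.8]` (inclusive — the permissive reading of the band, kept as
   a config knob). Additional read sets (e.g. the pools) can be added to
   the reconstitution via `extra_read_sets`; the default is parents-only
   so the unit is self-contained.

## Pool filtering and dAF

Per pool, sites are restricted to the whitelist and to a depth band of
`[0.75, 1.5] × M` (inclusive), where `M` is that pool's median depth over
its whitelisted SNVs — each pool is bounded by its own median; a shared
mean-of-medians is available by passing an explicit band. The pools are
then inner-joined on position, requiring the identical ALT allele
(mismatches counted), and `dAF = |AF_high − AF_low|`. The absolute value
makes the statistic orientation-free, so no parent-of-origin polarization
is needed.

## dARC calling

Each joined site's 2×2 allele-count table is tested with a **two-sided
Fisher exact test**. Genome-scale calling uses a vectorized
hypergeometric enumeration (log-space `gammaln` probabilities; the
two-sided p sums all tables with probability ≤ observed × (1 + 1e−7));
the scalar entry point delegates to `scipy.stats.fisher_exact`, and the
test suite checks both against an independent pure-Python enumeration.
Exact p-values that underflow are floored at the smallest positive float
before correction. Multiple testing uses **Benjamini–Hochberg** by
default (Bonferroni available): the correction method was a genuinely
open choice, and BH is the field standard for genome-wide variant
contrasts. A site is a dARC when adjusted p < 0.05 (strict).

## Interval rules

* **Chaining**: adjacent dARCs < 50 kbp apart (a gap of exactly 50 kbp
  splits) — this caps low-density bridges between dARC-rich regions.
* **Seeding**: ≥ 4 dARCs, of which ≥ 3 pairwise > 1 kbp apart. The
  spread rule's phrasing is ambiguous; it is operationalized as a greedy
  left-to-right selection keeping each dARC strictly more than 1 kbp
  from the last kept one (optimal for the longest such subset on sorted
  positions, verified against quadratic DP). The looser reading — the
  cluster span alone must exceed 1 kbp — is available as
  `spread_mode="span"`.
* **ZCR bridging**: two clusters merge when zero-coverage regions cover
  ≥ 50% of the gap between them, iterated to a fixed point. The
  motivation (shared deletions suppress variant calls and split
  intervals) fixes the mechanism but not a threshold; 0.5 is this
  package's choice and a parameter.
* **Reporting**: interval bounds are the first/last member dARCs, size
  is `end − start`, IDs number intervals per chromosome by ascending
  start, ranks order by descending dARC count (ties: larger size, then
  smaller start). The trait-specific minimum dARC count per reported
  interval (100 for GSL, 65 for SPC in the original design) is
  `min_darc_cutoff`; the pipeline default of 4 keeps every validated
  interval, which suits single-locus simulations.

## Coverage screens

* **ZCRs** scan non-overlapping 200 bp windows tiled from position 1
  (trailing partial window dropped); a window qualifies only when every
  base is zero in *both* pools, and adjacent windows merge. "Extremely
  low" coverage deliberately does not qualify — that is PAV territory.
* **PAVs** (gene mode): per gene, mean depth per pool, normalized by the
  pool's genome-wide mean depth. A call requires the depleted pool's
  *raw* mean below `mincov = 10` and a normalized larger/smaller ratio
  ≥ 2. The ratio threshold is this package's choice: the expected F2
  contrast for a deletion haplotype at 3/4-vs-1/4 tail frequencies is
  (1 − 1/4)/(1 − 3/4) = 3, and 2 admits it with sampling noise. Ranking
  is by descending ratio (a stand-in; the original ranking statistic is
  not specified).

## Window tracks

Smoothed dAF uses sliding windows of 100 *variants* stepped by 5
variants (median per window; trailing partial window dropped; a
chromosome with fewer than 100 variants gives an empty track). dARC
density and normalized coverage use 100 kbp windows stepped by 30 kbp,
anchored at position 1 (the anchor is a convention choice). Density is
dARCs / SNVs per window; a zero-SNV window is *missing* (NaN), not zero,
so variant deserts stay distinguishable from significance-free regions.
Coverage windows are normalized to the per-chromosome maximum window
mean (all-zero chromosomes stay zero).

High-impact filtering keeps exactly four effect classes — stop gain,
stop loss, frameshift, splice donor/acceptor — from SnpEff-style ANN
fields; other HIGH classes (e.g. `start_lost`) are excluded by default
but the class map is a parameter. Candidate genes are genes overlapping
`[interval.start − 5 kbp, interval.end + 5 kbp]` by ≥ 1 bp (overlap, not
containment, so border-spanning genes qualify).

## The simulator

`synthetic_data.simulate_f2` draws SNV positions uniformly at the
configured density (default 1 per 2 kbp), assigns each site's ALT to a
random parent, and forces causal-locus ALT alleles to the high parent.
Gametes follow a **Haldane** crossover process (Poisson crossover count,
uniform positions, no interference) at `cm_per_mb = 2.0` — a realistic
genome-wide average for a rapeseed-like genome — giving the closed-form
linkage decay `r = (1 − exp(−2d/100))/2` used by `expected_pool_af`. The
phenotype is additive over causal loci, `sum(effect · (dosage − 1))`,
plus Gaussian noise scaled so the causal loci explain the configured
heritability (default 0.5, a major-QTL scenario; an optional pairwise
epistasis term exists but is off by default since additive structure
suffices to exercise the pipeline). Pools are the phenotype tails
(default 5% each of an F2 of 1,000 — pool sizes of ~50, matching the
tens-of-genotypes pools typical of this design). Read counts are
`Binomial(depth, AF)` with `depth ~ Poisson(mean_depth)`; sequencing
error is off by default, with a per-read flip knob. Deletion carriers
contribute no reads inside deletions: a shared deletion emits exactly
zero coverage, a single-parent deletion scales the Poisson rate by the
surviving haplotype fraction of each pool. No SNVs are placed inside
deletion regions — deleted DNA yields no variant calls in the carrier.

The parents' VCF contains records (including homozygous-reference AD) at
every segregating site, as a joint caller would emit, which is what the
F1 reconstitution consumes.

**Structural-variant demo** (`structural_variant_demo_config`): one
20 Mbp chromosome at 30× pool coverage with a 10 kbp shared deletion
(window-aligned, for exact ZCR recovery) and a 60 kbp deletion private to
the high parent. The private deletion is placed at the genetic distance
where the closed-form expected deletion-haplotype tail frequencies are
0.75/0.25, so the expected normalized coverage ratio is ≈ 3 — the
"one-third coverage" contrast a polygenic background produces
empirically. A single strong locus with 5% tails sorts almost perfectly
at the causal site itself (tail frequencies ≈ 0.95), so placing the
deletion at a distance is the principled way to model that imperfect
contrast; 30× (a realistic pool depth for this design) keeps the
depleted pool's raw mean (≈ 7.5×) under the `mincov = 10` gate that a
50× experiment would clear.

## What the synthetic experiments do not show

The simulator has no allopolyploid homoeology, no read-mapping or
alignment artifacts, no reference bias, no InDel/complex variants, no
variant-caller genotyping error, and uniform SNV density. Passing
end-to-end tests therefore demonstrates the correctness of the filtering
and statistics on clean segregation signal — not robustness to the
mapping artifacts of a real allopolyploid genome, which the gold
standard and coverage bands are designed to absorb but which are not
emulated here.

## Problem sizes and numerics

Default end-to-end experiments use one 20 Mbp chromosome (~10,000 SNVs),
an F2 of 1,000 and 50 replicate seeds — sizes chosen so a full replicate
set runs in well under a minute per core while leaving pool-composition
noise realistic. All randomness flows through a single
`numpy.random.Generator` seeded from the config, making runs
bit-reproducible. Medians use the mean-of-central-pair convention for
even counts. Coverage bands and the F1 AF band are inclusive on both
ends; the dARC significance and the 50 kbp gap are strict inequalities.
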