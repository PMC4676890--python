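# Methods

## The discovery model and its assumptions

The unit of discovery is a region whose DNA methylation differs among
individuals of one inbred strain, tissue and age.  The design is
deliberately replicate-free: every individual *is* the condition of
interest, so each individual contributes a single WGBS library and the
statistical question at each CpG is heterogeneity of a binomial proportion
across k individuals.

**Per-CpG test.** The 2×k contingency table of (methylated, unmethylated)
read counts is tested with Pearson's chi-squared statistic,
Σ(O−E)²/E, df = k−1, no continuity correction.  Assumptions: reads are
independent Bernoulli draws of the underlying cell-population methylation
fraction (no clonal read duplication, no conversion error), and expected
counts are large enough for the χ² approximation — at the 6-read minimum
this is marginal for CpGs near 0 or 1, which is one reason the caller
never relies on single CpGs.  Tables in which all reads genome-wide at the
site are methylated (or all unmethylated) have a zero row total; they are
returned as statistic 0, p = 1 and flagged degenerate rather than an
error, since fully methylated CpGs are the majority genome background.

**Segmentation.** Informative CpGs (≥ `min_coverage` reads in *every*
calling individual) are scanned left to right per chromosome.  A region
opens at a significant CpG and extends while (a) consecutive member
spacing stays ≤ `max_gap_bp` and (b) the running count of non-significant
members stays within `allowed_nonsignificant(n) = max(1, ⌊n/10⌋)`;
violating either closes the region at the last significant CpG where all
rules held.  Region boundaries are therefore always significant CpGs (no
dangling non-significant tails), and a region needs ≥ `min_cpgs` members.
The budget rule reconciles the two ways the tolerance is usually stated —
"a single CpG" and "10 % of CpGs" — which agree for n ≤ 19.  The
test-suite checks the scan against brute-force enumeration of all windows
satisfying the region predicate (with the budget respected at every
prefix), greedily reduced; on ≤ 15-CpG chromosomes the two are identical.

**Region methylation and range.** Per individual, region methylation is
the coverage-weighted mean of per-CpG fractions, equal to summed
methylated reads over summed total reads.  The range filter
(max − min ≥ `min_range`) is computed over *calling* individuals; the
output table reports weighted methylation for all individuals, including
any excluded from calling (an excluded individual's counts provably do not
affect which regions are called — a permutation test in the suite), and a
separate all-individuals range for reporting.  Regions are flagged
`driven_by_single_individual` when any leave-one-out range falls below the
threshold.

**Error control.** No multiple-testing correction is applied at the CpG
level.  The region rules are the control, and their operating
characteristics are measured by simulation rather than claimed
analytically: on null genomes (≈ 10⁵ informative CpGs, 10 replicates) the
caller's median region count is 0 (< 1 per 10⁵ informative CpGs), while
planted regions of range 0.5 with 8 CpGs at coverage 20 are recovered with
median sensitivity ≥ 0.9 and ≤ 2 false regions per run.  These are the
standing benchmarks in `iidmr.benchmark` and the figures are recomputed by
the test-suite and `scripts/acceptance.py`, not quoted.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `alpha` | 0.05 | — | per-CpG significance level |
| `min_cpgs` | 6 | CpGs | minimum members per region |
| `max_gap_bp` | 500 | bp | maximum spacing between adjacent members |
| `min_range` | 0.20 | methylation fraction | minimum spread between extreme individuals |
| `min_coverage` | 6 | reads | CpG informative only at this depth in every calling individual |
| `allowed_nonsignificant` | max(1, ⌊n/10⌋) | CpGs | tolerated interior non-significant members |

Coverage is required of every calling individual jointly (not
per-individual) because the chi-squared test and the weighted averages
need counts from each compared individual; a per-individual-missing mode
exists behind `coverage_filter(..., mode="any")` but is not the default.

Zygosity thresholds: variant-supporting read fraction > 0.90 →
homozygous-variant (strictly greater; exactly 0.90 is heterozygous),
≥ 0.30 → heterozygous, (0, 0.30) → discarded, 0 → reference.  Mutation-rate
defaults: 4/32 validated de novo candidates, a 985-variant genome-wide
candidate pool, FDR 0.20, FNR 0.23, 2.136 Gbp callable genome, 4
transmitted haploid genomes; the estimator is the explicit product
(v/t)·C·(1−FDR)/(1−FNR)/(callable·G) with every factor a parameter, so any
alternative convention can be evaluated by substitution.

## The synthetic-data generator

`iidmr.simulate` emulates the data regime the method is designed for:

- five individuals, one library each;
- CpG positions from a clustered point process (geometric background at a
  mean 100 bp spacing plus CpG-island clusters every ~50 kb);
- per-CpG coverage ~ NegativeBinomial(mean 15, dispersion 10), under which
  the large majority of CpGs reach 6 reads;
- a per-CpG methylation probability drawn once from Beta(8, 2)
  (mean 0.8, matching a genome whose median 10 kb-window methylation is
  ≈ 80 %) and shared by all individuals — a true null for the
  heterogeneity test;
- planted DMRs in two classes: ERV-like (methylation range ≈ 0.6 ± 0.1
  across individuals) and regulatory-like (≈ 0.25 ± 0.05), each realised
  as n ≥ 6 evenly spaced CpGs whose per-individual Binomial probability is
  the planted target; ERV/tsDMR annotation intervals are emitted over the
  corresponding planted regions.

The variant fixture constructs a genome of plus-strand "gene cassettes"
(5′UTR/CDS exon, intron with canonical GT…AG, CDS/3′UTR exon, flanking
2 kb zones, intergenic spacer) whose CDS is tiled with GCT codons, so
synonymous placements sit at third positions (GCT→GCC, Ala) and
non-synonymous at first positions (GCT→CCT, Ala→Pro) by construction.
Requested (zygosity pattern × genic category) counts are realised exactly
and emitted as VCF/GFF3/FASTA/BED that round-trip through the package's
own readers.

What the generator does **not** model: read-level artefacts (mapping bias,
bisulphite conversion failure, PCR duplication), spatial correlation of
methylation beyond the planted regions, cell-type mixture within a tissue,
linked genetic variation, and real repeat sequence content.  Passing the
recovery benchmarks therefore demonstrates the *statistical* behaviour of
the caller under its own model — power against planted differences and
control of region-level false positives under binomial noise — not
robustness to alignment artefacts or cellular heterogeneity, which on real
tissue data remain confounders exactly as they do for the underlying
method.

## Numerical and design choices

- Coordinates are 0-based half-open internally; 1-based formats (cytosine
  report, VCF, GFF3) convert at the boundary.  Overlap always means ≥ 1 bp
  intersection of half-open intervals; adjacency is not overlap.
- Strand merging keys each CpG to the forward-strand C; an unpaired
  reverse-strand record is re-keyed to position − 1 so all sites refer to
  the dinucleotide's forward C.  A called region's half-open end is the
  last member position + 2, covering the final dinucleotide.
- Windows tile from position 0 per chromosome, last window truncated;
  windows (or individuals) with no informative coverage carry NaN, never 0.
- The range comparison between ERV and non-ERV regions uses Welch's t-test
  by default ("t-test" alone does not pin the variance assumption; Welch
  is the safer default for unequal group sizes); `equal_var=True` gives
  the pooled Student variant.  Clonal comparisons use the pooled Student
  test, the classical choice for small equal-design clone counts; the
  zero-variance-equal-means degenerate case returns t = 0, p = 1.
- The clustered-heterozygote exclusion is per-variant (each member of a
  ≥ 3-call, ≤ 10 kb-spacing heterozygous cluster that itself overlaps a
  segmental duplication or annotated repeat is removed); a region mode
  that removes every call in the cluster span is available by flag.
- Simple-repeat periodicity (< 9) and mapping-quality (< 40) criteria are
  consumed as attributes of pre-annotated intervals; the package does not
  re-detect tandem repeats or recompute mapping quality from alignments.
- Genic category precedence: coding exon (syn/non-syn) > splice junction
  (2 bp intronic, canonical donor/acceptor) > UTR > intronic > upstream
  (2 kb, strand-aware) > downstream > intergenic; a variant upstream of
  one gene and downstream of another is assigned upstream (5′ bias).  With
  several overlapping genes, a non-synonymous coding call outranks a
  synonymous one.
- Homopolymer (> 8 bp) and dinucleotide (> 14 bp, homodimers excluded,
  partial trailing unit counted) masks use strict inequalities and are
  extended 1 bp each side, clipped and merged.

## Problem sizes

Benchmarks default to a 10 Mb single-chromosome genome (~10⁵ CpGs) at
coverage 20 over 10 seeds; the statistical oracles use 10⁴ random tables
and ≥ 250 random ≤ 15-CpG chromosomes.  These sizes give stable medians
while the whole suite and the acceptance script each complete in well
under a minute; all of them scale linearly in genome length and replicate
count through their parameters.

## Known limitations

- The chi-squared approximation is anticonservative for extreme
  methylation fractions at minimal coverage; a beta-binomial or exact
  test would be the upgrade path, but is deliberately out of scope — the
  region rules, not the per-CpG p-value, carry the error control.
- Single-replicate-per-individual design: biological variability within
  an individual is unidentifiable and is not modelled.
- The genic classifier is SNV-only and one transcript per gene; indel
  consequences and isoform resolution are out of scope.
- The variant-table partition requires both individuals classifiable at a
  site; sites with a discarded (0 < fraction < 0.30) class in either
  individual are routed to an indeterminate bin and not counted.
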