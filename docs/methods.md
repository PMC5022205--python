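# Methods

This note documents the models, conventions and numerical choices behind
`regcap`: what each stage computes, which parameters matter, what the
synthetic data emulate, and where genuinely open design choices were made.

## Coordinates and containers

All internal coordinates are 0-based half-open (BED convention); VCF
positions are converted at the I/O boundary. The genome is tiled by a
`BinGrid` of fixed-width bins (100 bp default; the last bin of a chromosome
may be short) addressed by one global integer id, which makes every bin-set
operation a plain integer-set operation. Variants travel as two pandas
frames (sites and per-sample genotype calls); allele counts, links and
reports are plain TSV/JSON.

## Panel design

- **Normalization** divides each bin's assigned reads by the sample's total
  reads. bedGraph records straddling bin boundaries are apportioned by
  bp-overlap fraction — deterministic and mass-conserving; the alternative
  (assigning whole records to the bin of their start) changes nothing on
  data binned at the grid resolution.
- **Ranking** sorts by descending signal with ties broken by genome order
  (chromosome order, then start), so the top-*N* cut is deterministic.
  Zero-signal bins are rankable, so *N* bins are always returned; this only
  matters on sparse toy inputs.
- **Rank-block filtering** compares same-rank strata (blocks of 50,000
  ranks; configurable) between samples of one cell type using the mean
  pairwise |intersection|/block-size. The overlap metric is symmetric in
  samples and bounded in [0, 1]; a min-pairwise variant is available via
  the same code path. Filtering precedes the replicate consensus; a
  single-sample cell type retains all strata.
- **Consensus** keeps bins present in ≥ ceil(m/2) of m ≥ 3 replicates, both
  of 2, or the single sample's set unchanged.
- **Exome subtraction** removes a bin when the union of exome intervals
  covers ≥ 50% of it (union, not per-record sum, so overlapping exome
  records are not double-counted).
- **Sharing level** of a bin = number of cell types whose consensus
  contains it; it is the covariate for all downstream DHS-sharing
  statistics. Merged target intervals coalesce adjacent bins; BED output
  splits runs at sharing-level changes so the annotation round-trips.

Monotonicity properties (raising the overlap floor never adds strata;
raising the exome fraction never shrinks the panel) and equivalence to a
naive fully-materialized set-operation reference on ≤ 10,000-bin genomes
are enforced by tests.

## Capture and enrichment statistics

A lead SNP counts as captured if its own position or any LD-proxy position
(r² > 0.9 proxies are consumed as an input table) lies in a panel interval.
Enrichment against matched random draws uses *n*-bin samples without
replacement from the configured universe; the empirical p uses the add-one
estimator p = (1 + #{null ≥ obs})/(1 + iterations), which is never zero and
is exact for permutation-style nulls. Fisher's exact test (two-sided, via
`scipy.stats.fisher_exact`) is cross-checked against full hypergeometric
enumeration on every 2×2 table with margins ≤ 30. The odds ratio uses the
cross-product convention with an ∞ sentinel for zero denominators.

## Variant QC and annotation

The QC rule is a hard AND over DP ≥ 10, GQ ≥ 70, site MQ ≥ 50; the
allele-balance band [0.10, 0.90] applies to heterozygous calls only —
applying it to homozygous calls would reject essentially all of them, so
the het-only reading is the coherent one. Missing required fields fail the
call; a site survives when at least one genotype call passes. The filter is
idempotent.

Frequency classification matches on (chrom, pos, ref, alt); reference
allele frequencies are folded to MAF before the 1% threshold. A position
known to the reference with a different alternate allele is treated as
novel-at-allele and logged — allele-aware matching is stricter but avoids
misclassifying genuine novel alleles at polymorphic positions. Records
listed only in the known-sites catalogue (no frequency) classify as rare.

The coding-effect annotator translates the codon containing each SNV for
both alleles (gain of stop → stop-gained, other amino-acid change →
non-synonymous); it requires in-frame CDS models and rejects records whose
reference allele disagrees with the genome. It is deliberately minimal —
enough for synthetic gene models — and is validated against an independent
whole-protein translation oracle for every possible SNV in toy genes on
both strands.

Sharing-level enrichment: fold(k) = (numeratorₖ/commonₖ)/(numerator/common
over all DHS bins); levels without common variants are omitted with a
warning. The trend is an unweighted OLS of fold on level with a two-sided
t-test — levels use disjoint variant sets, so the errors are independent,
and the shared all-DHS normalizer rescales all folds equally, leaving the
t-statistic untouched. `fold_span`, exp of the log-fold OLS evaluated
across the level range, estimates the multiplicative enrichment between
least- and most-shared bins and is the estimator used for fold recovery.

Constraint proportions count missing GERP/CADD scores as below threshold in
the denominator (configurable), so classes with patchy annotation are not
silently inflated.

## Motif scanning

Scoring is log₂(p/bg) with pseudocounts of total mass 0.01 distributed by
the background (uniform 0.25 by default) so zero entries stay finite. Every
placement on both strands whose footprint covers the variant position is
evaluated; the best placement's p-value is compared to alpha without
further correction across placements, matching the per-match convention of
standard motif scanners. The Bonferroni divisor is the number of variants
scanned, not variants × PWMs.

P-values are exact tail masses of the score distribution over
background-random w-mers, computed by dynamic programming on an integer
score grid. The grid uses 20,000 steps per motif position: at width 3 a
single w-mer carries probability 4⁻³ ≈ 0.016, so grid-induced rank flips
near a query score must be made vanishingly rare for DP tails to agree with
exhaustive 4^w enumeration within 1e-3; at this resolution the worst
observed disagreement across widths 3–8 is < 1e-3 and the DP cost is still
microseconds. Scanned sequences are scored on the same integer grid, so a
scanned placement's p-value is exactly its discretized tail mass and
p-monotonicity in the score holds by construction.

A variant significant for both alleles gets verdict `none` (the score delta
remains available on the call) — creation and disruption verdicts are
mutually exclusive by definition.

## ASE analysis

Fold difference = max/min of the two haplotype counts; both-zero records
are dropped, single zeros get a +1 pseudocount on both alleles
(configurable to drop). Classes: equal ≤ 1.5 < intermediate < 2 ≤ AI ≤ 9 <
excluded. Excluded records never enter enrichment denominators. Pooling
across individuals uses the median fold per transcript; per-individual
records are analysed unpooled where the question is individual-level
(dose–response, homozygous stratification).

Adjusted AI proportions rescale the raw proportion at each imbalance
cut-off by (grand mean informative-SNP count)/(mean at that cut-off) — a
multiplicative correction for the confounding between genotyping depth,
detectable imbalance and detectable nearby variants. The covariate is
specified; the multiplicative functional form is this package's choice.

Promoter–DHS links are Pearson correlations, across signal datasets, of the
mean promoter-bin signal (TSS ± 500 bp) with each bin within ±1 Mb;
zero-variance vectors are skipped. The AI-enrichment fold is
P(≥1 qualifying variant | AI)/P(≥1 | all tested). For the trend over
correlation thresholds the package reports the OLS slope with its t-test p
(the convention used in figure legends of this literature) *and* an
AI-label permutation p: the folds at nested thresholds share transcripts,
so the 5-point t-test is not calibrated, while permuting the AI labels
respects the dependence exactly. Calibration claims use the permutation p.

Residual variance explained is the OLS R² of log₂(fold difference) on the
rare+novel vicinity variant count over records from individuals homozygous
at the transcript's top common eSNP. No formula for this quantity is
standard; the OLS-R² operationalization is declared here and its parameter
recovery (planted share v recovered within ±0.05 at n = 5,000) is tested.

## Synthetic data

The generators emulate the statistical structure of the real inputs, with
all randomness drawn from named substreams of one master seed (byte-
identical reruns):

- **DNase tracks**: Poisson background (configured total depth spread over
  bins) plus Poisson peak signal at planted peaks; peaks carry explicit
  cell-type sets, replicates add independent noise, and a noise-free mode
  emits expected counts for exact-recovery checks.
- **Variants**: the (rare+novel)/common density ratio rises log-linearly
  with sharing level, ratio(k) = ratio(1)·fold^((k−1)/(K−1)), so the
  configured `enrichment_fold` is the ratio span between level 1 and level
  K and is directly recoverable by the log-fold fit; fold 1 is the null.
  Genotypes are Hardy–Weinberg draws (novel variants get one het carrier);
  depth is 20 + Poisson(30) so planted QC failures (DP = 5 sites) are the
  only QC failures, with het allele balance clipped into the QC band.
- **Motif variants**: creation events place the weakest base at a planted
  consensus site's most informative position as the reference allele, with
  the alternate restoring the consensus; disruption is the mirror image;
  neutral variants land in untouched background ≥ 35 bp from any planted
  site.
- **ASE counts**: beta-binomial with overdispersion ρ ((1−ρ)/ρ
  concentration; ρ = 0 is binomial). Carriers of a planted cis effect have
  expected allelic ratio 2^effect. The residual-variance generator plants
  log₂ ratio = base + β·count + N(0, σ²) with β solved from the target R²
  (σ = 0.3, counts Poisson(2), 2,000 reads so binomial noise is negligible,
  base offset 1 keeping ratios positive so folding preserves the signal).

What the simulations do **not** emulate: mappability and GC structure in
DNase signal, realistic LD between variants, reference-bias in allele
counts, isoform-level expression structure, and real PWM libraries (the
planted PWMs are sharply peaked). Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
models, not robustness to those real-data artefacts.

## Null calibration and problem sizes

With all planted effects at their neutral values, the sharing-slope test,
the motif-proportion Fisher contrast (common vs novel, creation flags at
equal rates) and the AI-trend permutation test each reject at 0.05 ± 0.02
over 500 simulation seeds. The calibration suites use ~2,500 variants per
seed on a 12-level panel, 1,000 variants per class for the Fisher contrast,
and 300 transcripts with 199 permutations for the trend — sizes at which
the normal/discreteness approximations involved are representative while
the full 500-seed sweep remains a few minutes of CPU. The motif-proportion
calibration simulates the per-variant impact flags directly at equal rates
rather than re-scanning sequence per seed: the claim under test is the
calibration of the contrast, while scanner sensitivity/specificity is
measured separately against planted motif truth.

## Known limitations

- The coding annotator handles biallelic SNVs on in-frame single-CDS models
  only (no splice sites, no multi-transcript effect prioritization).
- PWM scanning assumes a 0-order background; higher-order backgrounds and
  indel impacts are out of scope.
- Hi-C links are consumed as BEDPE anchor pairs; no matrix processing.
- The empirical enrichment null draws bins independently, ignoring the
  spatial autocorrelation of real hit sets; with LD-clumped lead SNPs this
  is the standard approximation.
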