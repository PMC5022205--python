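# regcap

Design of regulatory-region capture panels from DNase-I hypersensitivity
maps, and the downstream statistical characterization of the variants such
panels yield in immune cells: frequency classification, enrichment across
open-chromatin sharing levels, transcription-factor motif
creation/disruption, and allele-specific-expression (ASE) based functional
impact of rare regulatory variants.

## Who this is for

Groups running targeted re-sequencing of *cis*-regulatory regions — the
non-coding analogue of whole-exome sequencing — who need a tested,
reproducible implementation of the full analysis chain, plus a synthetic
data generator with planted ground truth so that every stage can be
validated without access to consortium-scale external data.

## The methods at the core

**Panel design.** The genome is tiled into 100-bp bins. Each sample's
DNase-seq signal is normalized to reads-per-bin over total reads, and the
top *N* = 300,000 bins (the top ~1% of the genome) are ranked per sample.
Ranked lists are cut into blocks of 50,000 bins; a rank stratum is dropped
when the mean pairwise overlap between same-cell-type samples falls below
50%. Within each cell type, bins present in ≥50% of replicates are kept
(both of two; all bins for a single sample). Bins with ≥50% overlap with
exome capture targets are subtracted, the union over cell types is merged
into target intervals, and every bin is annotated with its **sharing
level** — the number of cell types (1..K) whose consensus contains it.

**Variant analysis.** Genotype calls pass QC at DP ≥ 10, GQ ≥ 70,
MQ ≥ 50 and, for heterozygotes, reference-allele fraction in [0.10, 0.90];
indels are excluded. SNVs are *common* (reference MAF ≥ 1%), *rare* (known,
MAF < 1%) or *novel* (absent from the frequency reference and the
known-site catalogue). Enrichment across sharing levels is
fold(k) = [rare+novel]ₖ/[common]ₖ normalized by the all-DHS ratio, with an
OLS trend test over k.

**Motif impact.** Both alleles of each SNV are scored within ±15 nt against
PWM libraries by log₂-odds against a 0-order background; p-values are exact
tail probabilities of the discretized score distribution (dynamic
programming over w-mers). At the Bonferroni threshold α = 0.05/#variants
(0.05/351,088 = 1.42e-7 at study scale) a motif is *created* if only the
alternate allele is significant and *disrupted* if only the reference is.

**ASE.** Allelic imbalance is the fold difference max/min of
haplotype-resolved allele counts: equal ≤ 1.5, AI in [2, 9], > 9 excluded
as imprinting/artefacts. The package measures rare-variant enrichment near
AI transcripts (±20 kb vicinity, promoter-correlated DHS bins at Pearson
r thresholds 0.5–0.9, Hi-C-linked regions, TSS-distance profiles with an
80-kb window every 10 kb), a dose–response in the vicinity variant count,
homozygous-eSNP stratification, and the residual variance in log₂
imbalance explained by the rare+novel variant count (OLS R²).

## Worked example

```bash
python examples/03_variant_annotation.py
```

```
QC: 3906/4092 sites pass (186 planted low-depth sites removed)
common    2024
rare      1124
novel      758
rare+novel vs common enrichment: slope 0.096 per sharing level (p = 2.4e-07);
fitted fold span level 1 -> 12: 3.11 (planted: 3.0)
```

The simulation plants a 3-fold excess of rare+novel over common variants in
fully shared DHS bins relative to cell-type-specific ones; the positive
slope (p < 1e-5) detects the trend, and the fitted fold span recovers the
planted value. The other `examples/` scripts cover panel design and exact
recovery of planted peak sharing (`01`), SNP-hit capture fractions and
random-bin enrichment nulls (`02`), motif creation/disruption recall
(`04`), ASE enrichment and residual variance (`05`), and the end-to-end
pipeline with a byte-reproducible manifest (`06`).

A thin CLI wraps the same functions:

```bash
regcap run --config src/regcap/data/smoke.yaml --seed 1 --out out/
regcap design --signals manifest.tsv --chrom-sizes genome.sizes --out panel.bed
```

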