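"""Allelic imbalance and rare-variant enrichment near imbalanced genes.

Simulates beta-binomial allele counts for 200 transcripts in 20 individuals
with a 2-fold cis effect planted in 60 transcripts, classifies allelic
imbalance (AI = fold difference in [2, 9]), and measures (i) the AI
enrichment of transcripts with a rare variant nearby, (ii) the adjusted AI
proportions across imbalance levels, and (iii) the residual variance in
log2 imbalance explained by the rare+novel variant count among individuals
homozygous at the common eSNP.
"""

import numpy as np

from regcap import (
    adjusted_ai_proportions,
    ai_enrichment,
    annotate_records,
    pool_by_transcript,
    residual_variance_explained,
    stratify_homozygous,
)
from regcap.simulate import AseEffectConfig, simulate_ase, simulate_residual_ai

records, esnp_geno, truth = simulate_ase(
    AseEffectConfig(n_transcripts=200, n_affected=60, log2_effect=1.0,
                    carrier_fraction=1.0),
    overdispersion=0.1, n_individuals=20, seed=1)

annotated = annotate_records(records)
per_transcript = pool_by_transcript(annotated)
print(per_transcript["ai_class"].value_counts().to_string())

affected = {e[0] for e in truth.planted_cis_effects}
per_transcript["n_rare"] = per_transcript["transcript"].isin(affected).astype(int)
per_transcript["n_common"] = 1
per_transcript["n_novel"] = 0
per_transcript["n_rare_novel"] = per_transcript["n_rare"]

usable = per_transcript[per_transcript["ai_class"] != "excluded"]
is_ai = (usable["ai_class"] == "ai").to_numpy()
fold = ai_enrichment(is_ai, (usable["n_rare"] >= 1).to_numpy())
print(f"AI transcripts are {fold:.2f}x as likely to carry a nearby rare "
      "variant as all tested transcripts")

props = adjusted_ai_proportions(usable, ai_levels=[1.5, 2.0, 2.5],
                                classes=["rare"])
print(props.to_string(index=False))

hom = stratify_homozygous(annotated, esnp_geno)
print(f"homozygous-eSNP stratum: {len(hom)} records of {len(annotated)}")

resid = simulate_residual_ai(5_000, variance_share=0.14, seed=2)
r2 = residual_variance_explained(resid)
print(f"residual variance explained by rare+novel count: {100 * r2:.1f}% "
      "(planted: 14%)")
# The adjusted proportions rise with the imbalance cut-off because planted
# cis effects push their transcripts into the higher AI bands.
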