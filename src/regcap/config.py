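"""Pipeline configuration: every tunable parameter with its default.

Defaults are the study-standard values: 100-bp bins, top 300,000 bins per
sample, 50,000-bin concordance blocks with a 50% overlap floor, 50%
replicate consensus, 50% exome-overlap subtraction, QC at DP >= 10 /
GQ >= 70 / MQ >= 50 with het allele balance in [0.10, 0.90], MAF 1% for the
common/rare split, a +/-15 nt motif scan window with family alpha 0.05,
+/-20 kb gene vicinity, AI band [2, 9] with "equal" <= 1.5, promoter TSS
+/-500 bp (correlation) and +/-1500 bp (Hi-C), +/-1 Mb correlation window,
an 80-kb TSS sliding window stepping 10 kb, and 1000 random-bin iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # stage toggles
    stages: list = field(default_factory=lambda: [
        "simulate", "design", "enrich", "annotate", "motif", "ase"])
    # panel design
    bin_size: int = 100
    n_top: int = 300_000
    block_size: int = 50_000
    min_block_overlap: float = 0.5
    exome_min_frac: float = 0.5
    # variant QC / classes
    dp_min: float = 10
    gq_min: float = 70
    mq_min: float = 50
    ab_low: float = 0.10
    ab_high: float = 0.90
    maf_threshold: float = 0.01
    # motif scanning
    flank: int = 15
    family_alpha: float = 0.05
    # ASE
    vicinity: int = 20_000
    ai_low: float = 2.0
    ai_high: float = 9.0
    equal_max: float = 1.5
    promoter_halfwidth: int = 500
    hic_promoter_halfwidth: int = 1500
    correlation_window: int = 1_000_000
    tss_window: int = 80_000
    tss_step: int = 10_000
    # empirical nulls
    iterations: int = 1000
    # master seed and simulation scale
    seed: int = 0
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return asdict(self)


# scaled-down simulation defaults used by the bundled smoke configuration;
# thresholds above stay at their standard values, only problem sizes shrink
SMOKE_SIM = {
    "chrom_sizes": {"chr1": 400_000, "chr2": 200_000},
    "cell_types": ["CD4", "CD8", "CD19"],
    "replicates": {"CD4": 3, "CD8": 2, "CD19": 1},
    "n_peaks_shared": 6,
    "n_peaks_specific": 9,
    "peak_reads": 80.0,
    "dhs_depth": 5000.0,
    "n_top": 120,
    "block_size": 30,
    "common_density": 0.6,
    "rare_novel_density": 0.3,
    "enrichment_fold": 3.0,
    "n_samples": 8,
    "n_genes": 40,
    "n_pwms": 3,
    "pwm_width": 12,
    "n_create": 8,
    "n_disrupt": 8,
    "n_neutral": 24,
    "n_transcripts": 120,
    "n_affected": 40,
    "log2_effect": 1.2,
    "carrier_fraction": 1.0,
    "overdispersion": 0.02,
    "n_individuals": 20,
    "iterations": 200,
    "n_hits": 40,
    "hit_in_panel_fraction": 0.6,
}
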