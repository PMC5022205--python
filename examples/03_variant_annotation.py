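"""QC, frequency classification and DHS-sharing enrichment of variants.

Simulates variants on a 12-cell-type panel with a planted 3-fold excess of
rare+novel over common variants in fully shared DHS bins, applies the hard
QC cut-offs (DP >= 10, GQ >= 70, MQ >= 50, het allele balance 10-90%),
classifies variants as common (MAF >= 1%), rare or novel, and fits the
sharing-level enrichment trend.
"""

from regcap import (
    assign_dhs_sharing,
    classify_frequency,
    qc_filter,
    sharing_level_enrichment,
    summary_table,
)
from regcap.intervals import BinGrid
from regcap.panel import CapturePanel
from regcap.simulate import AfSpectrumConfig, simulate_variants

grid = BinGrid({"chr1": 1_000_000}, bin_size=100)
sharing = {}
b = 0
for level in range(1, 13):          # 300 bins at each sharing level 1..12
    for _ in range(300):
        sharing[b] = level
        b += 2
panel = CapturePanel(grid=grid, sharing=sharing,
                     cell_types=[f"ct{i}" for i in range(12)])

sim = simulate_variants(
    panel,
    AfSpectrumConfig(common_density=0.6, rare_novel_density=0.3,
                     low_dp_fraction=0.05),
    enrichment_fold=3.0, n_samples=8, seed=1)

qc = qc_filter(sim.sites, sim.calls)
print(f"QC: {len(qc.sites)}/{len(sim.sites)} sites pass "
      f"({len(sim.sites) - len(qc.sites)} planted low-depth sites removed)")

sites = classify_frequency(qc.sites, sim.freq_ref, sim.known_sites)
sites = assign_dhs_sharing(sites, panel)
print(sites["freq_class"].value_counts().to_string())

res = sharing_level_enrichment(sites, numerator=("rare", "novel"))
print(f"rare+novel vs common enrichment: slope {res.slope:.3f} per sharing "
      f"level (p = {res.p_value:.2g}); fitted fold span level 1 -> 12: "
      f"{res.fold_span:.2f} (planted: 3.0)")

sites["effect"] = "non-coding"       # no gene models in this example
tab = summary_table(sites, qc.calls)
print(tab[["category", "all", "common", "rare", "novel"]].to_string(index=False))
# The positive slope says rare and novel variants concentrate in DHS bins
# shared across many cell types, relative to common variants.
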