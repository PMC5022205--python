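"""Run the full synthetic pipeline end to end and inspect the manifest.

Equivalent to `regcap run --config <yaml> --seed 1 --out out/`: simulate
DNase tracks, design the panel, test hit-set enrichment, annotate
variants, scan motifs and analyse allele-specific expression, with every
output written as a plain-text file plus a manifest of content digests.
"""

import json
import tempfile
from pathlib import Path

from regcap.config import PipelineConfig
from regcap.pipeline import run_pipeline

config = PipelineConfig(sim={
    "chrom_sizes": {"chr1": 200_000},
    "n_top": 60, "block_size": 30,
    "iterations": 100, "n_transcripts": 60, "n_individuals": 10,
})

out_dir = Path(tempfile.mkdtemp(prefix="regcap_example_"))
manifest = run_pipeline(config, out_dir, seed=1)

print(f"stages run: {[s['name'] for s in manifest['stages']]}")
print(f"outputs in {out_dir}:")
for stage in manifest["stages"]:
    for fname in stage["outputs"]:
        print(f"  [{stage['name']}] {fname}")

report = json.loads((out_dir / "ase_report.json").read_text())
print(f"ASE stage: {report['n_ai']} of {report['n_transcripts']} transcripts "
      "show allelic imbalance")
# Re-running with the same config and seed reproduces every file
# byte-for-byte; the manifest digests make that checkable.
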