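"""Run the whole pipeline end to end on a scaled-down cohort.

simulate -> behavior -> group ICA (x2) -> matching -> decoding ->
cluster inference -> brain-behavior regression, with a provenance
manifest; re-running reuses cached stages.  Equivalent CLI:

    conflictstop run --out run --seed 1
"""

import json
from pathlib import Path

from conflictstop.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=1,
    n_subjects=10,
    n_blocks=3,            # 3 x (24 go + 20 stop) = 132 trials per session
    go_per_block=24,
    stop_per_block=20,
    n_sources=2,
    n_perm=500,
    temporal_generalization=False,  # enable for the full train x test maps
)
out = run_pipeline(config, Path("run-example"))

manifest = json.loads((out / "manifest.json").read_text())
for stage, entry in manifest["stages"].items():
    print(f"{stage:>14}: {entry['duration_s']:7.1f} s  "
          f"{', '.join(sorted(entry['files']))[:60]}")

clusters = json.loads((out / "clusters.json").read_text())
print("\nsignificant decoding windows (sample indices):",
      clusters["significant_windows"])
bb = json.loads((out / "brainbehavior.json").read_text())
for pair in bb["pairs"]:
    print(f"pair {pair['pair_id']}: LOO RMSE = {pair['rmse_ms']:.2f} ms")
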