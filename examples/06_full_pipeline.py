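"""Run the whole analysis pipeline and list the report it produces.

Simulates clamp ensembles at four forces, detects steps, clusters the
pooled lengths, reconstructs the kinetic network and runs the pathway test;
every stage writes a machine-readable table into the report directory.
(Scaled down here for speed; raise n_traces/n_replicas for a full run.)
"""

import json
from pathlib import Path

import mechpath as mp

config = mp.PipelineConfig(
    mode="simulate",
    seed=7,
    out_dir="scratch/pipeline_report",
    forces=(20.0, 40.0, 60.0, 80.0),
    n_traces=20,
    duration=10.0,
    n_replicas=200,
    n_mc=500,
)
out = mp.run(config)

print(f"report directory: {out}")
for p in sorted(Path(out).iterdir()):
    print(f"  {p.name}")
log = json.loads((out / "run.json").read_text())
print(f"\nzero-force rate fit: {log['rate_fit']}")
print(f"pathway verdict: {log['pathway_verdict']}")
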