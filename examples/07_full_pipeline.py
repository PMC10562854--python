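"""Run the whole analysis end to end and list what each stage produced.

simulate -> train per dataset -> latent space -> label transfer -> attribution
recovery -> DE -> lncRNA filter -> co-expression -> enrichment -> capped atlas
export, with a manifest that makes the run byte-reproducible.
"""

import json

from crossatlas import PipelineConfig, run_pipeline

config = PipelineConfig(out_dir="scratch/example_run", seed=0)
run_dir = run_pipeline(config)

manifest = json.loads((run_dir / "manifest.json").read_text())
print(f"run directory: {run_dir}\n")
for stage, info in manifest["stages"].items():
    print(f"{stage:>14}: {info}")

print(f"\n{len(manifest['artifacts'])} artifacts hashed in the manifest; "
      "rerunning with the same config reproduces them byte-for-byte.")
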