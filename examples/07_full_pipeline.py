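"""End-to-end pipeline run: simulate -> overlap -> cluster -> de -> score
-> stratify -> classify, with a JSON manifest of seeds and checksums.

The same run is available from the shell as
    pidsle run-all --outdir pipeline_out --seed 1
"""

import json

from pidsle import PipelineConfig, run_pipeline

config = PipelineConfig.from_dict({"seed": 1})
manifest = run_pipeline(config, "pipeline_out")
print(json.dumps({s: v["status"] for s, v in manifest["stages"].items()}, indent=2))
print("outputs:", ", ".join(sorted(manifest["outputs"])))
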