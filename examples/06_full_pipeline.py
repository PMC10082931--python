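"""Run the whole pipeline into an artifact directory.

Equivalent to `ponet run --out out/ --seed 1`: simulation, noise filter,
PO, differential calls, clustering, the inference crowd, Top1 consensus,
threshold scan, map-equation modules, and sequence-feature statistics.
"""
import json
import tempfile
from pathlib import Path

import ponet

outdir = Path(tempfile.mkdtemp(prefix="ponet_"))
manifest = ponet.run_pipeline(ponet.PipelineConfig(seed=1), outdir)

for name, info in manifest["stages"].items():
    counts = ", ".join(f"{k}={v}" for k, v in info.get("counts", {}).items())
    print(f"{name:<10} {info['status']:<7} {counts}")
print(f"\nartifacts in {outdir}:")
print(", ".join(manifest["artifacts"]))
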