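"""Per-gene pooled F_ST between the female and male pools, both tracks.

The flanks of the differentiated region rise above the autosomal
5th-95th percentile band; including the W scaffolds soaks up W-derived
reads and damps the elevation.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "paths", Path(__file__).parent / "00_paths.py"
)
paths = importlib.util.module_from_spec(spec)
spec.loader.exec_module(paths)

for tag in ("withW", "noW"):
    paths.run_cli([
        "fst",
        "--sync", str(paths.SIM / f"pools_{tag}.sync"),
        "--gtf", str(paths.SIM / "genes.gtf"),
        "--autosomes", paths.AUTOSOMES,
        "--out", str(paths.OUT), "--tag", tag,
    ])
print(f"per-gene tables and rolling-median tracks under {paths.OUT}")
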