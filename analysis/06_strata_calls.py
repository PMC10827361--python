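"""Joint classification of Z genes into evolutionary strata.

Joins the coverage (both mapping references), F_ST (both references) and
dS evidence per gene, applies the stratum rules, and segments the Z into
S0/S1/S2 intervals.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "paths", Path(__file__).parent / "00_paths.py"
)
paths = importlib.util.module_from_spec(spec)
spec.loader.exec_module(paths)

paths.run_cli([
    "collect",
    "--gtf", str(paths.SIM / "genes.gtf"),
    "--windows-withw", str(paths.OUT / "windows_withW.tsv"),
    "--windows-now", str(paths.OUT / "windows_noW.tsv"),
    "--fst-withw", str(paths.OUT / "gene_fst_withW.tsv"),
    "--fst-now", str(paths.OUT / "gene_fst_noW.tsv"),
    "--divergence", str(paths.OUT / "divergence.tsv"),
    "--out", str(paths.OUT / "evidence.tsv"),
])
paths.run_cli([
    "strata",
    "--evidence", str(paths.OUT / "evidence.tsv"),
    "--out", str(paths.OUT),
])
print(f"per-gene calls and stratum intervals under {paths.OUT}")
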