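"""Generate the synthetic ZW data set with planted strata.

Writes a diploid genome (3 autosomes + Z, 3 Mb each, 300 genes), W
sequences derived from Z genes at stratum-specific divergence, sexed
depth tracks with and without W scaffolds, pooled allele counts, long
reads, expression tables, and the ground-truth table.
"""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "paths", Path(__file__).parent / "00_paths.py"
)
paths = importlib.util.module_from_spec(spec)
spec.loader.exec_module(paths)

paths.SIM.mkdir(parents=True, exist_ok=True)
paths.run_cli(["simulate", "--seed", str(paths.SEED), "--out", str(paths.SIM)])

truth = (paths.SIM / "truth.tsv").read_text().splitlines()
n_w = sum(1 for line in truth[1:] if line.split("\t")[5] == "True")
print(f"simulated {len(truth) - 1} genes; {n_w} carry a surviving W homolog")
print(f"inputs for the downstream stages are under {paths.SIM}")
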