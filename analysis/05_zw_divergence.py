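"""W-Z homolog pairing and synonymous divergence (NG86 with JC correction).

W transcripts passing the female-specificity filter (female share of
summed head+gonad expression >= 0.9) are paired with Z transcripts by
reciprocal best hit, codon-aligned at the protein level, filtered to
>= 300 aligned nt, and dated by dS.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "paths", Path(__file__).parent / "00_paths.py"
)
paths = importlib.util.module_from_spec(spec)
spec.loader.exec_module(paths)

paths.run_cli([
    "homologs",
    "--w-transcripts", str(paths.SIM / "w_transcripts.fasta"),
    "--transcripts", str(paths.SIM / "transcripts.fasta"),
    "--tpm", str(paths.SIM / "tpm_head.tsv"),
    "--tpm", str(paths.SIM / "tpm_gonad.tsv"),
    "--out", str(paths.OUT),
])
paths.run_cli([
    "divergence",
    "--pairs", str(paths.OUT / "homolog_pairs.tsv"),
    "--w-transcripts", str(paths.SIM / "w_transcripts.fasta"),
    "--transcripts", str(paths.SIM / "transcripts.fasta"),
    "--out", str(paths.OUT),
])
print("dS per Z-W pair written; stratum medians should order S0 > S1 > S2")
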