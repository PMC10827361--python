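"""Classify long reads as W-derived by female-specific k-mer content.

Builds 21-mer sets from the female (Z + autosomes + W) and male
(Z + autosomes) references, subtracts them, and partitions the simulated
long reads at the 20%-or-more female-specific-k-mer rule (mkf 0.2).
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "paths", Path(__file__).parent / "00_paths.py"
)
paths = importlib.util.module_from_spec(spec)
spec.loader.exec_module(paths)

paths.OUT.mkdir(parents=True, exist_ok=True)
wdir = paths.SIM.parent / "wfilter"  # partitioned FASTQ is bulky -> scratch
paths.run_cli([
    "kmer-filter",
    "--female", str(paths.SIM / "genome.fasta"),
    "--female", str(paths.SIM / "w_transcripts.fasta"),
    "--male", str(paths.SIM / "genome.fasta"),
    "--reads", str(paths.SIM / "long_reads.fastq"),
    "--k", "21", "--mkf", "0.2",
    "--out", str(wdir),
])
import shutil

shutil.copy(wdir / "kmer_report.tsv", paths.OUT / "kmer_report.tsv")
print(f"report: {paths.OUT / 'kmer_report.tsv'}")
print("the partitioned FASTQ files mirror the pre-assembly W-read removal step")
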