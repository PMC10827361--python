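"""Shared locations for the analysis scripts.

Bulky simulated inputs (FASTA/FASTQ/sync/depth) live under scratch/;
small result tables land in results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "scratch" / "sim"
OUT = ROOT / "results"
SEED = 0
AUTOSOMES = "A1,A2,A3"


def run_cli(args: list[str]) -> None:
    """Invoke a pipeline subcommand in-process."""
    from zwstrata.cli import main

    main(args, standalone_mode=False)
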