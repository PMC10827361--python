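from __future__ import annotations

import numpy as np
import pytest

from zwstrata.io_core import RunConfig
from zwstrata.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_runs():
    """Twenty full default-scale pipeline runs, one per seed.

    Shared across the acceptance checks that measure stochastic recovery
    rates; extras (genome sequences, raw tracks) are dropped to bound
    memory.
    """
    runs = []
    for seed in range(20):
        res = run_pipeline(RunConfig(), seed=seed)
        res.extras = {}
        runs.append(res)
    return runs


@pytest.fixture(scope="session")
def default_run(default_runs):
    return default_runs[0]


@pytest.fixture(scope="session")
def kmer_setup():
    """Default genome plus sexed k-mer sets and 5,000 noisy long reads."""
    from zwstrata import kmers as km
    from zwstrata import synth
    from zwstrata.pipeline import stage_seed

    genome, w_records, genes, truth = synth.simulate_genome(seed=stage_seed(0, "genome"))
    female = km.build_kmer_set(
        [s for _, s in genome] + [s for _, s in w_records], k=21, min_count=1
    )
    male = km.build_kmer_set([s for _, s in genome], k=21, min_count=1)
    fs = km.female_specific(female, male)
    # class-balanced draw so both per-class rates are estimable: 4,000
    # reads from the Z+autosome assembly, 1,000 from the W sequences
    g_reads, g_truth = synth.simulate_long_reads(
        genome, n_reads=4_000, read_len=1_000, per_base_error=0.01,
        seed=stage_seed(0, "reads"),
    )
    w_reads, w_truth = synth.simulate_long_reads(
        w_records, n_reads=1_000, read_len=1_000, per_base_error=0.01,
        seed=stage_seed(0, "w-reads"),
    )
    w_reads = [(f"w{rid}", seq, q) for rid, seq, q in w_reads]
    w_truth = w_truth.assign(read_id="w" + w_truth["read_id"])
    reads = g_reads + w_reads
    import pandas as pd

    read_truth = pd.concat([g_truth, w_truth], ignore_index=True)
    return {
        "genome": genome,
        "w_records": w_records,
        "truth": truth,
        "fs": fs,
        "male_set": male,
        "reads": reads,
        "read_truth": read_truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
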