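import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zwstrata.io_core import write_fastq
from zwstrata.kmers import (
    KmerSet,
    build_kmer_set,
    canonical,
    classify_read,
    female_specific,
    partition_reads,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)


class TestBuildKmerSet:
    def test_hand_canonicalization(self):
        # ACGTA at k=5: canonical(ACGTA) = min(ACGTA, TACGT) = ACGTA
        ks = build_kmer_set(["ACGTA"], k=5, min_count=1)
        assert ks.member_strings() == {"ACGTA"}

    def test_canonical_collapses_strands(self):
        fwd = build_kmer_set(["ACGTACG"], k=5)
        rev = build_kmer_set(["CGTACGT"], k=5)  # reverse complement
        assert set(fwd.codes) == set(rev.codes)

    def test_min_count_floor(self):
        # ACGTA holds a single 5-mer: kept only when seen twice
        assert len(build_kmer_set(["ACGTA", "ACGTA"], k=5, min_count=2)) == 1
        assert len(build_kmer_set(["ACGTA"], k=5, min_count=2)) == 0

    def test_n_containing_kmers_skipped(self):
        assert len(build_kmer_set(["ACNGT"], k=3)) == 0
        assert len(build_kmer_set(["ACNGTT"], k=3)) == 1  # only GTT valid

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            build_kmer_set(["ACGT"], k=4)


class TestFemaleSpecific:
    def test_set_difference(self):
        f = build_kmer_set(["AAACT", "CCCGT", "GGGAT"], k=5)
        m = build_kmer_set(["CCCGT"], k=5)
        fs = female_specific(f, m)
        assert fs.member_strings() == {
            canonical("AAACT"),
            canonical("GGGAT"),
        }

    def test_identical_sets_and_empty_male(self):
        f = build_kmer_set(["ACGTAGA"], k=5)
        assert len(female_specific(f, f)) == 0
        empty = build_kmer_set([], k=5)
        assert set(female_specific(f, empty).codes) == set(f.codes)

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            female_specific(build_kmer_set(["ACGTA"], 5), build_kmer_set(["ACG"], 3))


class TestClassifyRead:
    def test_kmer_count_arithmetic(self):
        # 23-bp read at k=21 has 3 k-mers; one female-specific -> 1/3 >= 0.2
        read = "A" * 23
        fs_codes = build_kmer_set([read[:21]], k=21).codes
        fs = KmerSet(21, fs_codes)
        cls = classify_read(read, fs, 0.2)
        assert cls.n_kmers == 3
        assert cls.label == "W"

    def test_no_specific_kmers_is_retained(self):
        fs = KmerSet(21, np.empty(0, dtype=np.int64))
        assert classify_read("ACGT" * 10, fs).label == "retained"

    def test_exact_threshold_is_inclusive(self):
        # 5 distinct canonical k-mers, exactly 1 female-specific:
        # fraction 0.2 -> labeled W (the 20%-or-more rule is inclusive)
        read = "AAACCCGGT"  # k=5 -> 5 k-mers, no canonical collisions
        fs = KmerSet(5, build_kmer_set([read[:5]], k=5).codes)
        cls = classify_read(read, fs, mkf_threshold=0.2)
        assert cls.n_kmers == 5 and cls.n_female_specific == 1
        assert cls.fraction == pytest.approx(0.2)
        assert cls.label == "W"

    def test_short_read_defaults_to_retained(self):
        fs = KmerSet(21, np.empty(0, dtype=np.int64))
        cls = classify_read("ACGT", fs)
        assert (cls.n_kmers, cls.label) == (0, "retained")

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(dna, min_size=1, max_size=5), dna)
    def test_raising_threshold_never_adds_w_labels(self, source, read):
        fs = build_kmer_set([s for s in source if len(s) >= 5] or ["ACGTA"], k=5)
        labels = [
            classify_read(read, fs, thr).label == "W"
            for thr in (0.0, 0.2, 0.5, 0.8, 1.0 + 1e-9)
        ]
        # once a read stops being W at some threshold it never comes back
        assert labels == sorted(labels, reverse=True)


class TestPartitionReads:
    def _write(self, tmp_path, reads):
        path = tmp_path / "in.fastq"
        write_fastq([(f"r{i}", s, "I" * len(s)) for i, s in enumerate(reads)], path)
        return path

    def test_construction_oracle_w_only(self, tmp_path, rng):
        # error-free reads from a W-only sequence: every k-mer female-specific
        w = "".join(rng.choice(list("ACGT"), 200))
        fs = build_kmer_set([w], k=21)
        reads = [w[i : i + 50] for i in range(0, 150, 10)]
        rep = partition_reads(
            self._write(tmp_path, reads), fs, tmp_path / "w.fq", tmp_path / "r.fq"
        )
        assert rep["n_W"] == rep["n_total"] == len(reads)
        assert rep["pct_W"] == 100.0

    def test_empty_input(self, tmp_path):
        fs = KmerSet(21, np.empty(0, dtype=np.int64))
        rep = partition_reads(
            self._write(tmp_path, []), fs, tmp_path / "w.fq", tmp_path / "r.fq"
        )
        assert rep == {
            "n_total": 0, "n_W": 0, "n_retained": 0, "pct_W": 0.0,
            "threshold": 0.2, "k": 21,
        }

    def test_partition_exhaustive_and_exclusive(self, tmp_path, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(30)]
        fs = build_kmer_set(seqs[:10], k=21)
        rep = partition_reads(
            self._write(tmp_path, seqs), fs, tmp_path / "w.fq", tmp_path / "r.fq"
        )
        from zwstrata.io_core import iter_fastq

        w_ids = [r[0] for r in iter_fastq(tmp_path / "w.fq")]
        r_ids = [r[0] for r in iter_fastq(tmp_path / "r.fq")]
        assert rep["n_W"] + rep["n_retained"] == rep["n_total"] == 30
        assert sorted(w_ids + r_ids) == sorted(f"r{i}" for i in range(30))
        assert not set(w_ids) & set(r_ids)

    def test_malformed_fastq_reports_index(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r0\nACGT\n+\nIIII\nnot-a-header\nACGT\n+\nIIII\n")
        fs = KmerSet(21, np.empty(0, dtype=np.int64))
        with pytest.raises(ValueError, match="index 1"):
            partition_reads(p, fs, tmp_path / "w.fq", tmp_path / "r.fq")
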