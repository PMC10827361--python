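"""Female-specific k-mer identification and W-read classification.

In a ZW system the W chromosome is carried only by females, so k-mers that
occur in female reads but never in male reads are (up to sampling noise)
W-derived. Long reads whose k-mer content is dominated by such
female-specific k-mers are classified as W reads and can be removed before
assembly to avoid chimeric Z/W contigs.

K-mers are held canonically: each k-mer is represented by the
lexicographic minimum of itself and its reverse complement, 2-bit encoded
into an int64. ``k`` must be odd so no k-mer is its own reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .io_core import iter_fastq, log, write_fastq

_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lowercase
_COMP = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G in 2-bit space


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical 2-bit codes for every N-free k-mer of ``seq`` (order kept)."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (windows >= 0).all(axis=1)
    windows = windows[valid]
    if windows.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = windows @ pow4
    rev = _COMP[windows][:, ::-1] @ pow4
    return np.minimum(fwd, rev)


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def canonical(kmer: str) -> str:
    """Canonical form: lexicographic min of a k-mer and its reverse complement."""
    rc = kmer.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    return min(kmer, rc)


@dataclass
class KmerSet:
    """A set of canonical k-mers, stored as a sorted int64 code array."""

    k: int
    codes: np.ndarray  # sorted unique canonical codes
    min_count: int = 1

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str) -> bool:
        code = _encode_kmers(canonical(kmer), self.k)
        return code.size == 1 and bool(
            np.searchsorted(self.codes, code[0]) < self.codes.size
            and self.codes[np.searchsorted(self.codes, code[0])] == code[0]
        )

    def member_strings(self) -> set[str]:
        """Decode to the canonical k-mer strings (small sets only)."""
        return {_decode(int(c), self.k) for c in self.codes}

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized membership for an array of canonical codes."""
        if self.codes.size == 0:
            return np.zeros(codes.shape, dtype=bool)
        idx = np.searchsorted(self.codes, codes)
        idx_c = np.minimum(idx, self.codes.size - 1)
        return self.codes[idx_c] == codes


@dataclass
class ReadClassification:
    read_id: str
    n_kmers: int
    n_female_specific: int
    fraction: float
    label: str  # "W" or "retained"


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError("k must be odd (even k allows self-complementary k-mers)")
    if not (3 <= k <= 31):
        raise ValueError("k must be within [3, 31]")


def build_kmer_set(reads: Iterable[str], k: int, min_count: int = 1) -> KmerSet:
    """Build the canonical k-mer set of a read collection.

    A k-mer is a member iff its canonical form occurs at least ``min_count``
    times across all reads (occurrences counted with multiplicity); k-mers
    containing N are skipped. Single pass over the reads.
    """
    _check_k(k)
    chunks = [_encode_kmers(r, k) for r in reads]
    if not chunks:
        return KmerSet(k, np.empty(0, dtype=np.int64), min_count)
    allc = np.concatenate(chunks)
    if min_count <= 1:
        return KmerSet(k, np.unique(allc), min_count)
    uniq, counts = np.unique(allc, return_counts=True)
    return KmerSet(k, uniq[counts >= min_count], min_count)


def female_specific(female: KmerSet, male: KmerSet) -> KmerSet:
    """Exact set difference female \\ male (the k-mer subtraction step)."""
    if female.k != male.k:
        raise ValueError(f"k mismatch: {female.k} vs {male.k}")
    keep = ~male.contains_codes(female.codes)
    return KmerSet(female.k, female.codes[keep], female.min_count)


def classify_read(
    read: str, fs: KmerSet, mkf_threshold: float = 0.2, read_id: str = ""
) -> ReadClassification:
    """Classify one read by its fraction of female-specific k-mers (mkf).

    The label is W iff the fraction is at or above ``mkf_threshold``
    (the 20%-or-more rule is inclusive). Reads shorter than k, or with no
    valid k-mer, default to retained.
    """
    codes = _encode_kmers(read, fs.k)
    n = int(codes.size)
    if n == 0:
        return ReadClassification(read_id, 0, 0, 0.0, "retained")
    nfs = int(fs.contains_codes(codes).sum())
    frac = nfs / n
    label = "W" if frac >= mkf_threshold else "retained"
    return ReadClassification(read_id, n, nfs, frac, label)


def partition_reads(
    fastq_in: str | Path,
    fs: KmerSet,
    w_out: str | Path,
    retained_out: str | Path,
    mkf_threshold: float = 0.2,
) -> dict:
    """Split a FASTQ into W and retained reads; returns the count report.

    Every input read appears in exactly one output file.
    """
    n_total = n_w = 0
    with open(w_out, "w") as wfh, open(retained_out, "w") as rfh:
        for rid, seq, qual in iter_fastq(fastq_in):
            n_total += 1
            cls = classify_read(seq, fs, mkf_threshold, rid)
            rec = f"@{rid}\n{seq}\n+\n{qual}\n"
            if cls.label == "W":
                n_w += 1
                wfh.write(rec)
            else:
                rfh.write(rec)
    report = {
        "n_total": n_total,
        "n_W": n_w,
        "n_retained": n_total - n_w,
        "pct_W": (100.0 * n_w / n_total) if n_total else 0.0,
        "threshold": mkf_threshold,
        "k": fs.k,
    }
    log.info(
        "kmer-filter: %d/%d reads labeled W (%.2f%%) at mkf>=%.2g, k=%d",
        n_w, n_total, report["pct_W"], mkf_threshold, fs.k,
    )
    return report


def classify_reads_bulk(
    reads: Iterable[tuple[str, str]], fs: KmerSet, mkf_threshold: float = 0.2
) -> Iterator[ReadClassification]:
    for rid, seq in reads:
        yield classify_read(seq, fs, mkf_threshold, rid)
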