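"""W-Z homolog pairing and Nei-Gojobori (NG86) synonymous divergence.

Putative W transcripts are paired with their Z homologs by reciprocal best
hit (RBH) under a seeded local nucleotide aligner; pairs are kept only when
the W transcript's expression is female-specific (female share of total
expression >= 0.9, as expected for a W-linked gene). Each retained pair is
codon-aligned at the protein level, unreliable columns are dropped, and
synonymous / nonsynonymous divergence is estimated with the NG86 counting
method under the Jukes-Cantor correction:

    dS = -(3/4) ln(1 - (4/3) pS),    pS = Sd / S

with synonymous site counts S averaged between the two sequences and
multi-step codon differences averaged over all minimal mutational pathways
that avoid stop codons. dS is undefined (reported missing) when
pS >= 3/4, outside the Jukes-Cantor domain.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io_core import log

# ---------------------------------------------------------------------------
# genetic code tables

_BASES = "TCAG"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def _codon_list() -> list[str]:
    return ["".join(c) for c in itertools.product("ACGT", repeat=3)]


@lru_cache(maxsize=None)
def _aa_of() -> dict[str, str]:
    table = dict(_STANDARD.forward_table)
    for stop in _STANDARD.stop_codons:
        table[stop] = "*"
    return table


@lru_cache(maxsize=None)
def _syn_sites() -> dict[str, float]:
    """Synonymous sites per codon: sum over positions of (#synonymous
    one-step changes)/3, so every codon contributes 3 sites total."""
    aa = _aa_of()
    out = {}
    for codon in _codon_list():
        if aa[codon] == "*":
            continue
        s = 0.0
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if aa[mut] == aa[codon]:
                    s += 1.0 / 3.0
        out[codon] = s
    return out


@lru_cache(maxsize=None)
def _pair_differences() -> dict[tuple[str, str], tuple[float, float]]:
    """Pathway-averaged (Sd, Nd) for every ordered pair of non-stop codons.

    Pathways through stop codons are excluded; if every ordering of the
    substitutions is blocked, the exclusion is waived for that pair so the
    pair still contributes its differences.
    """
    aa = _aa_of()
    codons = [c for c in _codon_list() if aa[c] != "*"]
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for c1 in codons:
        for c2 in codons:
            diff = [i for i in range(3) if c1[i] != c2[i]]
            if not diff:
                out[(c1, c2)] = (0.0, 0.0)
                continue
            paths = []
            for order in itertools.permutations(diff):
                cur = c1
                sd = nd = 0.0
                blocked = False
                for pos in order:
                    nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                    if aa[nxt] == "*" and nxt != c2:
                        blocked = True
                    if aa[nxt] == aa[cur]:
                        sd += 1.0
                    else:
                        nd += 1.0
                    cur = nxt
                paths.append((sd, nd, blocked))
            valid = [(s, n) for s, n, b in paths if not b]
            if not valid:
                valid = [(s, n) for s, n, _ in paths]
            sd = sum(s for s, _ in valid) / len(valid)
            nd = sum(n for _, n in valid) / len(valid)
            out[(c1, c2)] = (sd, nd)
    return out


_CODON_INDEX = {c: i for i, c in enumerate(_codon_list())}


@lru_cache(maxsize=None)
def _ng_arrays() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(S_sites[64], Sd[64,64], Nd[64,64]) with NaN rows/cols for stops."""
    sites = np.full(64, np.nan)
    for codon, s in _syn_sites().items():
        sites[_CODON_INDEX[codon]] = s
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for (c1, c2), (s, n) in _pair_differences().items():
        sd[_CODON_INDEX[c1], _CODON_INDEX[c2]] = s
        nd[_CODON_INDEX[c1], _CODON_INDEX[c2]] = n
    return sites, sd, nd


_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _codon_codes(seq: str) -> np.ndarray:
    """Codon indices for an in-frame sequence; -1 where the codon contains
    a non-ACGT symbol."""
    n = len(seq) // 3
    out = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        cod = seq[3 * i : 3 * i + 3]
        try:
            out[i] = (
                _NT_CODE[cod[0]] * 16 + _NT_CODE[cod[1]] * 4 + _NT_CODE[cod[2]]
            )
        except KeyError:
            pass
    return out


@dataclass
class DivergenceEstimate:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # NaN when pS >= 3/4
    dN: float
    n_codons: int


def _jc(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    if p <= 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng_dnds(cds1: str, cds2: str) -> DivergenceEstimate:
    """NG86 divergence for an aligned, filtered codon pair.

    Codons containing ambiguity symbols, and codon columns where either
    codon is a stop, are dropped before counting.
    """
    if len(cds1) != len(cds2) or len(cds1) % 3 != 0:
        raise ValueError("sequences must be aligned and a multiple of 3")
    if len(cds1) == 0:
        raise ValueError("empty alignment")
    sites, sd_tab, nd_tab = _ng_arrays()
    a = _codon_codes(cds1.upper())
    b = _codon_codes(cds2.upper())
    ok = (a >= 0) & (b >= 0)
    ok &= ~np.isnan(sites[np.where(ok, a, 0)]) & ~np.isnan(sites[np.where(ok, b, 0)])
    a, b = a[ok], b[ok]
    if a.size == 0:
        raise ValueError("no countable codons after dropping ambiguous/stop codons")
    S = 0.5 * (sites[a].sum() + sites[b].sum())
    N = 3.0 * a.size - S
    Sd = float(sd_tab[a, b].sum())
    Nd = float(nd_tab[a, b].sum())
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return DivergenceEstimate(
        float(S), float(N), Sd, Nd, pS, pN, _jc(pS), _jc(pN), int(a.size)
    )


# ---------------------------------------------------------------------------
# seeded local alignment and reciprocal best hits


@dataclass
class Hit:
    query_id: str
    target_id: str
    score: float
    strand: str  # "+" or "-"


@dataclass
class HomologPair:
    w_id: str
    z_id: str
    score: float
    aligned_len_nt: int = 0


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _fwd_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Strand-specific 2-bit codes of every N-free k-mer (order kept)."""
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
        lut[b + 32] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.size < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    windows = windows[(windows >= 0).all(axis=1)]
    if windows.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows @ pow4


class _SeedIndex:
    """Sorted-array seed index over both strands of a target set.

    Stores the unique k-mer codes of every (target, strand) variant in one
    sorted array with parallel owner ids, so per-query shared-seed counting
    is a pair of searchsorted calls plus a gather.
    """

    def __init__(self, targets: list[tuple[str, str]], seed_len: int) -> None:
        self.seed_len = seed_len
        codes_parts: list[np.ndarray] = []
        owner_parts: list[np.ndarray] = []
        for ti, (_, tseq) in enumerate(targets):
            for si, seq in enumerate((tseq, _revcomp(tseq))):
                u = np.unique(_fwd_kmer_codes(seq, seed_len))
                codes_parts.append(u)
                owner_parts.append(np.full(u.size, 2 * ti + si, dtype=np.int64))
        if codes_parts:
            codes = np.concatenate(codes_parts)
            owners = np.concatenate(owner_parts)
        else:
            codes = np.empty(0, dtype=np.int64)
            owners = np.empty(0, dtype=np.int64)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.owners = owners[order]

    def counts(self, qseq: str) -> dict[tuple[int, str], int]:
        """Shared-seed occurrence counts per (target index, strand)."""
        q = _fwd_kmer_codes(qseq, self.seed_len)
        if q.size == 0 or self.codes.size == 0:
            return {}
        lo = np.searchsorted(self.codes, q, side="left")
        hi = np.searchsorted(self.codes, q, side="right")
        lens = hi - lo
        m = lens > 0
        if not m.any():
            return {}
        lo, lens = lo[m], lens[m]
        # gather all matched owner slots (multi-arange)
        total = int(lens.sum())
        starts = np.repeat(lo, lens)
        offsets = np.arange(total) - np.repeat(
            np.cumsum(lens) - lens, lens
        )
        matched = self.owners[starts + offsets]
        owner_ids, counts = np.unique(matched, return_counts=True)
        return {
            (int(o) // 2, "+" if int(o) % 2 == 0 else "-"): int(c)
            for o, c in zip(owner_ids, counts)
        }


def best_hits(
    queries: list[tuple[str, str]],
    targets: list[tuple[str, str]],
    seed_len: int = 11,
    min_seed_hits: int = 1,
) -> dict[str, list[Hit]]:
    """Ranked local-alignment hits per query, seeded on exact shared k-mers.

    A (query, target, strand) triple is aligned only when it shares at least
    ``min_seed_hits`` exact ``seed_len``-mers; hits are ranked by score with
    ties broken by the lexicographically lower target id. Both strands of
    each target are searched.
    """
    index = _SeedIndex(targets, seed_len)
    target_variants = [
        {"+": tseq, "-": _revcomp(tseq)} for _, tseq in targets
    ]
    aligner = _local_aligner()
    out: dict[str, list[Hit]] = {}
    for qid, qseq in queries:
        hits = []
        for (ti, strand), c in index.counts(qseq).items():
            if c < min_seed_hits:
                continue
            tid = targets[ti][0]
            score = aligner.score(qseq, target_variants[ti][strand])
            hits.append(Hit(qid, tid, float(score), strand))
        hits.sort(key=lambda h: (-h.score, h.target_id))
        out[qid] = hits
    return out


def rbh_pairs(
    queries: list[tuple[str, str]],
    targets: list[tuple[str, str]],
    seed_len: int = 11,
    min_seed_hits: int = 1,
) -> list[HomologPair]:
    """Reciprocal best hits computed from a single pass of pair scores.

    Candidate (query, target, strand) triples come from shared exact seeds
    counted on the query side; each candidate pair is aligned once (the
    local-alignment score is symmetric in the pair) and both directions'
    best hits are derived from the same scores. Equivalent to running
    :func:`best_hits` both ways at half the cost.
    """
    index = _SeedIndex(targets, seed_len)
    target_variants = [{"+": tseq, "-": _revcomp(tseq)} for _, tseq in targets]
    aligner = _local_aligner()
    best_q: dict[str, tuple[float, str]] = {}
    best_t: dict[str, tuple[float, str]] = {}
    for qid, qseq in queries:
        for (ti, strand), c in index.counts(qseq).items():
            if c < min_seed_hits:
                continue
            tid = targets[ti][0]
            score = float(aligner.score(qseq, target_variants[ti][strand]))
            # higher score wins; ties prefer the lower partner id
            if qid not in best_q or score > best_q[qid][0] or (
                score == best_q[qid][0] and tid < best_q[qid][1]
            ):
                best_q[qid] = (score, tid)
            if tid not in best_t or score > best_t[tid][0] or (
                score == best_t[tid][0] and qid < best_t[tid][1]
            ):
                best_t[tid] = (score, qid)
    pairs = []
    for qid in sorted(best_q):
        score, tid = best_q[qid]
        if best_t.get(tid, (None, None))[1] == qid:
            pairs.append(HomologPair(qid, tid, score))
    return pairs


def reciprocal_best(
    hits_fwd: dict[str, list[Hit]], hits_rev: dict[str, list[Hit]]
) -> list[HomologPair]:
    """Pairs (w, z) where z is w's top hit and w is z's top hit."""
    top_rev = {qid: h[0].target_id for qid, h in hits_rev.items() if h}
    pairs = []
    for wid, hits in sorted(hits_fwd.items()):
        if not hits:
            continue
        zid = hits[0].target_id
        if top_rev.get(zid) == wid:
            pairs.append(HomologPair(wid, zid, hits[0].score))
    return pairs


# ---------------------------------------------------------------------------
# expression specificity


@dataclass
class SpecificityRecord:
    transcript_id: str
    f_head: float
    f_gonad: float
    m_head: float
    m_gonad: float

    @property
    def specificity(self) -> float:
        f = self.f_head + self.f_gonad
        m = self.m_head + self.m_gonad
        if f + m <= 0:
            return float("nan")
        return f / (f + m)


def specificity_filter(
    records: list[SpecificityRecord], cutoff: float = 0.9
) -> list[str]:
    """Transcripts whose female share of summed expression is >= cutoff.

    Zero total expression drops the transcript (with a warning); negative
    expression is an input error.
    """
    kept = []
    for r in records:
        vals = (r.f_head, r.f_gonad, r.m_head, r.m_gonad)
        if any(v < 0 for v in vals):
            raise ValueError(f"negative expression for {r.transcript_id}")
        s = r.specificity
        if math.isnan(s):
            log.warning(
                "specificity_filter: %s has zero expression, dropped", r.transcript_id
            )
            continue
        if s >= cutoff:
            kept.append(r.transcript_id)
    return kept


# ---------------------------------------------------------------------------
# codon alignment


def _global_protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # stiff gaps: at high divergence cheap gap pairs shift the reading
    # frame between them and inflate the divergence estimate
    aligner.open_gap_score = -15
    aligner.extend_gap_score = -2
    return aligner


def codon_align(cds_w: str, cds_z: str) -> tuple[str, str]:
    """Protein-guided codon alignment with unreliable-column removal.

    The two coding sequences are translated (trailing partial codon
    trimmed), globally aligned at the protein level, and back-translated to
    codons; codon columns containing a gap, an N, or a stop codon in either
    sequence are removed. Returned sequences have equal length, a multiple
    of 3.
    """
    cds_w = cds_w.upper()[: len(cds_w) - len(cds_w) % 3]
    cds_z = cds_z.upper()[: len(cds_z) - len(cds_z) % 3]
    if len(cds_w) < 3 or len(cds_z) < 3:
        raise ValueError("coding sequence shorter than one codon")
    prot_w = str(Seq(cds_w).translate())
    prot_z = str(Seq(cds_z).translate())
    if not prot_w or not prot_z:
        raise ValueError("empty translation")
    aln = _global_protein_aligner().align(prot_w, prot_z)[0]
    aligned_w, aligned_z = str(aln[0]), str(aln[1])
    stops = set(_STANDARD.stop_codons)
    out_w, out_z = [], []
    iw = iz = 0
    for aw, az in zip(aligned_w, aligned_z):
        cw = cds_w[3 * iw : 3 * iw + 3] if aw != "-" else None
        cz = cds_z[3 * iz : 3 * iz + 3] if az != "-" else None
        if aw != "-":
            iw += 1
        if az != "-":
            iz += 1
        if cw is None or cz is None:
            continue
        if "N" in cw or "N" in cz or cw in stops or cz in stops:
            continue
        if set(cw) - set("ACGT") or set(cz) - set("ACGT"):
            continue
        out_w.append(cw)
        out_z.append(cz)
    return "".join(out_w), "".join(out_z)


def length_filter(pairs: list[HomologPair], min_nt: int = 300) -> list[HomologPair]:
    """Drop pairs whose filtered codon alignment is shorter than ``min_nt``."""
    return [p for p in pairs if p.aligned_len_nt >= min_nt]


# ---------------------------------------------------------------------------
# stage driver


def divergence_table(
    pairs: list[HomologPair],
    w_seqs: dict[str, str],
    z_seqs: dict[str, str],
    min_nt: int = 300,
):
    """Codon-align each pair, apply the length filter, and estimate NG86
    divergence. Returns a pandas DataFrame (one row per surviving pair)."""
    import pandas as pd

    rows = []
    for p in pairs:
        aln_w, aln_z = codon_align(w_seqs[p.w_id], z_seqs[p.z_id])
        p.aligned_len_nt = len(aln_w)
        if p.aligned_len_nt < min_nt:
            continue
        est = ng_dnds(aln_w, aln_z)
        rows.append(
            {
                "w_id": p.w_id,
                "z_id": p.z_id,
                "aligned_len": p.aligned_len_nt,
                "S": est.S,
                "N": est.N,
                "Sd": est.Sd,
                "Nd": est.Nd,
                "dS": est.dS,
                "dN": est.dN,
            }
        )
    return pd.DataFrame(
        rows, columns=["w_id", "z_id", "aligned_len", "S", "N", "Sd", "Nd", "dS", "dN"]
    )
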