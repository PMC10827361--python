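"""Independent brute-force oracles used to check the implementations.

Each oracle recomputes a quantity from first principles (enumeration,
pair counting, exhaustive pathways) without sharing code with the package
path it checks.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq


# --- region detection -------------------------------------------------------


def regions_oracle(values, threshold):
    """Group adjacent below-threshold windows by testing each independently."""
    hits = [
        i
        for i, v in enumerate(values)
        if not math.isnan(v) and v < threshold
    ]
    runs = []
    for i in hits:
        if runs and runs[-1][1] == i - 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    return [tuple(r) for r in runs]


# --- pooled F_ST ------------------------------------------------------------


def site_fst_oracle(a1: int, b1: int, a2: int, b2: int):
    """Site F_ST from enumerated read counts via pair counting.

    Within-pool heterozygosity is the fraction of distinct read pairs that
    differ; total uses the mean of the two pool frequencies with the
    smaller pool's pair correction. Returns NaN for a monomorphic site.
    """
    c1, c2 = a1 + b1, a2 + b2
    het1 = 2.0 * a1 * b1 / (c1 * (c1 - 1))
    het2 = 2.0 * a2 * b2 / (c2 * (c2 - 1))
    pi_within = (het1 + het2) / 2.0
    pbar = (a1 / c1 + a2 / c2) / 2.0
    cmin = min(c1, c2)
    pi_total = 2.0 * pbar * (1.0 - pbar) * cmin / (cmin - 1)
    if pi_total <= 0:
        return float("nan")
    return (pi_total - pi_within) / pi_total


# --- NG86 -------------------------------------------------------------------


@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


@lru_cache(maxsize=None)
def _codon_syn_sites(codon: str) -> float:
    s = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if _aa(mut) == _aa(codon):
                s += 1.0
    return s / 3.0


@lru_cache(maxsize=None)
def _codon_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-enumerated (synonymous, nonsynonymous) differences."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    all_paths = []
    clean_paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*" and nxt != c2:
                through_stop = True
            if _aa(nxt) == _aa(cur):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        all_paths.append((sd, nd))
        if not through_stop:
            clean_paths.append((sd, nd))
    paths = clean_paths or all_paths
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def ng_oracle(cds1: str, cds2: str):
    """NG86 (S, N, Sd, Nd, dS, dN) by per-codon enumeration.

    Codons containing non-ACGT symbols or a stop in either sequence are
    skipped, matching the estimator's stated input contract.
    """
    assert len(cds1) == len(cds2) and len(cds1) % 3 == 0
    S = Sd = Nd = 0.0
    n = 0
    for i in range(0, len(cds1), 3):
        ca, cb = cds1[i : i + 3], cds2[i : i + 3]
        if set(ca + cb) - set("ACGT"):
            continue
        if _aa(ca) == "*" or _aa(cb) == "*":
            continue
        S += (_codon_syn_sites(ca) + _codon_syn_sites(cb)) / 2.0
        sd, nd = _codon_pair_diffs(ca, cb)
        Sd += sd
        Nd += nd
        n += 1
    N = 3.0 * n - S
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return S, N, Sd, Nd, jc(pS), jc(pN)


# --- rank-sum test ----------------------------------------------------------


def rank_sum_oracle(a, b):
    """Exact two-sided p via full enumeration of group assignments,
    using the rank-sum statistic W (equivalent to U up to a shift)."""
    from scipy.stats import rankdata

    a = list(a)
    b = list(b)
    na = len(a)
    pooled = np.asarray(a + b, dtype=float)
    ranks = rankdata(pooled)
    w_obs = ranks[:na].sum()
    mean_w = na * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - mean_w)
    total = extreme = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= dev - 1e-12:
            extreme += 1
    return extreme / total
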