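"""Evolutionary strata calls from joint coverage, F_ST and dS evidence.

The three strata of a differentiating ZW pair leave distinct joint
signatures across the two mapping references (with and without the W
scaffolds):

* S0 (ancestral): female coverage fully halved in both analyses (the W is
  lost or unmappable), no F_ST elevation (no W reads in the female pool),
  high dS where a W homolog survives at all.
* S1 (intermediate): full coverage drop when W scaffolds soak up the W
  reads, partial drop without them, and F_ST elevated only without the W.
* S2 (young): no coverage drop either way, F_ST elevated in both, very
  low dS.

Units matching none of the patterns are `undiff` (no drop, no elevation)
or `ambiguous`; the per-unit call is a pure function of the evidence and
thresholds. All cut-offs are this pipeline's operationalization of those
verbal definitions and live in :class:`StrataThresholds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import GenomeCoords, log

CALLS = ("S0", "S1", "S2", "undiff", "ambiguous")


@dataclass
class EvidenceVector:
    """Per-gene (or per-region) evidence feeding the stratum call.

    The two optional ``*_med`` fields carry a purely regional F_ST
    summary (rolling median): rules that demand the *absence* of
    elevation test it instead of the per-gene value, so that one gene's
    sampling noise cannot veto a call its whole neighbourhood supports.
    When absent, the main value is used for both directions.
    """

    unit_id: str
    cov_withW: float = math.nan  # smoothed log2(F/M), W scaffolds included
    cov_noW: float = math.nan
    fst_withW: float = math.nan
    fst_noW: float = math.nan
    dS: float = math.nan
    fst_withW_med: float = math.nan
    fst_noW_med: float = math.nan

    def __post_init__(self) -> None:
        for name in ("cov_withW", "cov_noW"):
            v = getattr(self, name)
            if not math.isnan(v) and not (-10.0 <= v <= 10.0):
                raise ValueError(f"{self.unit_id}: {name}={v} outside [-10, 10]")
        for name in ("fst_withW", "fst_noW", "fst_withW_med", "fst_noW_med"):
            v = getattr(self, name)
            if not math.isnan(v) and not (-1.0 <= v <= 1.0):
                raise ValueError(f"{self.unit_id}: {name}={v} outside [-1, 1]")
        if math.isnan(self.fst_withW_med):
            self.fst_withW_med = self.fst_withW
        if math.isnan(self.fst_noW_med):
            self.fst_noW_med = self.fst_noW


@dataclass
class StrataThresholds:
    """Numeric cut-offs for the verbal stratum definitions.

    ``full_drop``/``partial_drop`` partition the smoothed log2(F/M) axis
    (full: <= -0.75; partial: (-0.75, -0.25]); ``fst_elevated`` is the
    autosomal 95th-percentile band edge; ``ds_split`` separates high from
    low dS (defaulting to the median dS over all ZW pairs).
    """

    full_drop: float = -0.75
    partial_drop: float = -0.25
    slight_drop: float = -0.1
    fst_elevated: float = 0.1
    ds_split: float = 0.15

    def __post_init__(self) -> None:
        if not (self.full_drop < self.partial_drop < self.slight_drop < 0):
            raise ValueError("need full_drop < partial_drop < slight_drop < 0")

    def header(self) -> str:
        return (
            f"# thresholds: full_drop<={self.full_drop} "
            f"partial_drop<={self.partial_drop} fst_elevated>{self.fst_elevated} "
            f"ds_split>={self.ds_split}"
        )


def _drop_class(v: float, t: StrataThresholds) -> str:
    """Coverage drop category: full (lost W dose), partial (partially
    cross-mapping W), slight (a W-read deficit well below the detection
    threshold but clearly off the autosomal baseline), or none."""
    if math.isnan(v):
        return "missing"
    if v <= t.full_drop:
        return "full"
    if v <= t.partial_drop:
        return "partial"
    if v <= t.slight_drop:
        return "slight"
    return "none"


def _elevated(v: float, t: StrataThresholds) -> bool | None:
    if math.isnan(v):
        return None
    return v > t.fst_elevated


def classify_unit(e: EvidenceVector, t: StrataThresholds) -> str:
    """Stratum call for one evidence vector (pure function).

    dS is a soft criterion: a missing dS never blocks a call, since genes
    whose W copy is lost (typical of S0) have no dS at all.
    """
    if all(
        math.isnan(v)
        for v in (e.cov_withW, e.cov_noW, e.fst_withW, e.fst_noW, e.dS)
    ):
        raise ValueError(f"{e.unit_id}: all evidence missing")
    dw = _drop_class(e.cov_withW, t)
    dn = _drop_class(e.cov_noW, t)
    ew = _elevated(e.fst_withW, t)
    en = _elevated(e.fst_noW, t)
    # absence-of-elevation is judged on the regional median
    ew_quiet = _elevated(e.fst_withW_med, t)
    en_quiet = _elevated(e.fst_noW_med, t)
    ds_high = None if math.isnan(e.dS) else e.dS >= t.ds_split

    if dw == "full" and dn == "full" and ds_high is not False and en_quiet is not True:
        return "S0"
    if dw == "full" and dn == "partial" and en is True and ew_quiet is not True:
        return "S1"
    if (
        dw in ("none", "slight")
        and dn in ("none", "slight")
        and ew is True
        and en is True
        and ds_high is not True
    ):
        return "S2"
    if dw == "none" and dn == "none" and ew_quiet is not True and en_quiet is not True:
        return "undiff"
    return "ambiguous"


def classify_table(
    evidence: pd.DataFrame, t: StrataThresholds
) -> pd.DataFrame:
    """Apply :func:`classify_unit` to an evidence table.

    Expects columns unit_id, cov_withW, cov_noW, fst_withW, fst_noW, dS.
    """
    has_med = "fst_withW_med" in evidence.columns
    calls = []
    n_blank = 0
    for row in evidence.itertuples():
        e = EvidenceVector(
            row.unit_id,
            float(row.cov_withW),
            float(row.cov_noW),
            float(row.fst_withW),
            float(row.fst_noW),
            float(row.dS),
            float(row.fst_withW_med) if has_med else math.nan,
            float(row.fst_noW_med) if has_med else math.nan,
        )
        try:
            calls.append(classify_unit(e, t))
        except ValueError:
            # evidence-free units (e.g. smoothing edges) stay unclassified
            calls.append("ambiguous")
            n_blank += 1
    if n_blank:
        log.info("strata: %d unit(s) without evidence left ambiguous", n_blank)
    out = evidence.copy()
    out["call"] = calls
    return out


def coverage_fallback(evidence_calls: pd.DataFrame, t: StrataThresholds) -> pd.DataFrame:
    """Resolve ambiguous calls whose coverage signature is unambiguous.

    A consistent full drop in both mapping references is produced only by
    an ancestral (S0) region, and a full drop with the W scaffolds but a
    partial one without them only by an intermediate (S1) region — no
    other class of the model yields those dosage patterns. Genes left
    ambiguous because their own F_ST carries no information (typically
    because their W copy is lost) are therefore assigned by coverage
    alone. Expects columns cov_withW, cov_noW and call.
    """
    out = evidence_calls.copy()
    for idx, row in out.iterrows():
        if row["call"] != "ambiguous":
            continue
        dw = _drop_class(float(row["cov_withW"]), t)
        dn = _drop_class(float(row["cov_noW"]), t)
        if dw == "full" and dn == "full":
            out.loc[idx, "call"] = "S0"
        elif dw == "full" and dn == "partial":
            out.loc[idx, "call"] = "S1"
    return out


def smooth_calls(calls: list[str], vote_window: int = 5) -> list[str]:
    """Majority vote in a centered window; absorbs isolated disagreements.

    ``ambiguous`` entries abstain: they are non-calls, not competing
    votes, so a window's decided calls settle the outcome. Conversion
    needs a strict majority of at least two voters; otherwise the
    original call is kept. The vote is repeated until the calls are
    stable (a chance call whose neighbours were initially undecided is
    outvoted once those neighbours resolve).
    """
    n = len(calls)
    half = vote_window // 2
    current = list(calls)
    for _ in range(10):
        out = []
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            voters = [c for c in current[lo:hi] if c != "ambiguous"]
            best, best_n = current[i], 0
            for c in set(voters):
                k = voters.count(c)
                if k > best_n or (k == best_n and c == current[i]):
                    best, best_n = c, k
            ok = best_n >= 2 and best_n > len(voters) // 2
            out.append(best if ok else current[i])
        if out == current:
            break
        current = out
    return current


def demote_short_runs(calls: list[str], min_run: int = 3) -> list[str]:
    """Isolated stratum-call runs shorter than ``min_run`` become ambiguous.

    An evolutionary stratum is a contiguous multi-gene region: one or two
    stratum-like calls surrounded by undifferentiated neighbours are
    noise, not a stratum. A short run bordering another stratum run is
    kept — it is part of a larger differentiated block, not isolated.
    """
    strata = ("S0", "S1", "S2")
    out = list(calls)
    n = len(out)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and out[j + 1] == out[i]:
            j += 1
        if out[i] in strata and j - i + 1 < min_run:
            left = calls[i - 1] if i > 0 else None
            right = calls[j + 1] if j + 1 < n else None
            if left not in strata and right not in strata:
                for k in range(i, j + 1):
                    out[k] = "ambiguous"
        i = j + 1
    return out


def _coverage_compatible(call: str, dw: str, dn: str) -> bool:
    """Whether a coverage-drop signature can belong to the given class."""
    if call == "S0":
        return dw == "full" and dn == "full"
    if call == "S1":
        return dw == "full" and dn == "partial"
    if call == "S2":
        return dw in ("none", "slight") and dn in ("none", "slight")
    if call == "undiff":
        return dw == "none" and dn == "none"
    return False


def absorb_boundary_ambiguous(
    calls: pd.DataFrame, col: str, t: StrataThresholds
) -> pd.DataFrame:
    """Assign leftover ambiguous genes at run boundaries by coverage.

    A gene the vote could not settle (typically tied between the two
    flanking runs) joins the neighbouring class its own coverage-drop
    signature is compatible with, provided exactly one side qualifies.
    Needs columns cov_withW and cov_noW alongside the call column.
    """
    out = calls.reset_index(drop=True).copy()
    seq = list(out[col])
    n = len(seq)
    for i, call in enumerate(seq):
        if call != "ambiguous":
            continue
        dw = _drop_class(float(out.loc[i, "cov_withW"]), t)
        dn = _drop_class(float(out.loc[i, "cov_noW"]), t)
        sides = set()
        for j in range(i - 1, -1, -1):
            if seq[j] != "ambiguous":
                sides.add(seq[j])
                break
        for j in range(i + 1, n):
            if seq[j] != "ambiguous":
                sides.add(seq[j])
                break
        fits = [c for c in sides if _coverage_compatible(c, dw, dn)]
        if len(fits) == 1:
            out.loc[i, col] = fits[0]
    return out


@dataclass
class StratumInterval:
    name: str
    coords: GenomeCoords
    first_gene: str
    last_gene: str
    n_genes: int


def segment_strata(
    calls: pd.DataFrame,
    vote_window: int = 5,
    thresholds: StrataThresholds | None = None,
) -> tuple[pd.DataFrame, list[StratumInterval]]:
    """Group per-gene calls (ordered along the Z) into stratum intervals.

    Isolated single-gene disagreements are absorbed by majority vote in a
    ``vote_window``-gene centered window before run grouping, short
    isolated stratum runs are demoted, and (when thresholds and coverage
    columns are available) boundary-tied ambiguous genes are assigned by
    their coverage signature. Undiff and ambiguous runs produce no
    interval. Expects columns gene_id (or unit_id), chrom, start, end,
    call, ordered by position.
    """
    id_col = "gene_id" if "gene_id" in calls.columns else "unit_id"
    smoothed = demote_short_runs(smooth_calls(list(calls["call"]), vote_window))
    out = calls.reset_index(drop=True).copy()
    out["call_smoothed"] = smoothed
    if thresholds is not None and "cov_withW" in out.columns:
        out = absorb_boundary_ambiguous(out, "call_smoothed", thresholds)
    intervals: list[StratumInterval] = []
    i = 0
    rows = out.reset_index(drop=True)
    n = len(rows)
    while i < n:
        call = rows.loc[i, "call_smoothed"]
        j = i
        while j + 1 < n and rows.loc[j + 1, "call_smoothed"] == call:
            j += 1
        if call in ("S0", "S1", "S2"):
            intervals.append(
                StratumInterval(
                    call,
                    GenomeCoords(
                        rows.loc[i, "chrom"],
                        int(rows.loc[i, "start"]),
                        int(rows.loc[j, "end"]),
                    ),
                    rows.loc[i, id_col],
                    rows.loc[j, id_col],
                    j - i + 1,
                )
            )
        i = j + 1
    log.info("strata: %d stratum interval(s)", len(intervals))
    return out, intervals
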