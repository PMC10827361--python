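"""Dosage-compensation assessment: Z-versus-autosome expression contrasts.

In a female, genes in the differentiated region of the Z are present in a
single dose; without compensation their expression should sit ~1 log2 unit
below autosomal genes (and below their own male level). The analysis
quantile-normalizes TPM per tissue, filters genes expressed above a TPM
cutoff in both sexes, and compares the log2 expression of Z-differentiated
versus autosomal genes with Wilcoxon rank-sum tests per tissue and sex,
plus per-gene log2(female/male) ratio panels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import log


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across the samples (columns) of one tissue.

    Each sample's sorted values are replaced by the cross-sample means of
    the order statistics; ties within a sample receive the mean of their
    rank-mean block, so tied input values stay tied. With a single sample
    the input is returned unchanged (warning).
    """
    if matrix.shape[1] < 2:
        log.warning("quantile_normalize: single sample, returning input unchanged")
        return matrix.copy()
    vals = matrix.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)  # rank means
    out = np.empty_like(vals)
    ranks_axis = np.arange(1, vals.shape[0] + 1, dtype=float)
    for j in range(vals.shape[1]):
        r = stats.rankdata(vals[:, j], method="average")  # midranks
        out[:, j] = np.interp(r, ranks_axis, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def sample_columns(matrix: pd.DataFrame, tissue: str, sex: str) -> list[str]:
    return [c for c in matrix.columns if c.startswith(f"{tissue}_{sex}_")]


def filter_and_average(
    matrix: pd.DataFrame, tissue: str, cutoff: float = 0.5
) -> pd.DataFrame:
    """Per-sex replicate means for genes passing the cutoff in BOTH sexes.

    A gene is retained iff its mean-over-replicates TPM is >= cutoff for
    both sexes of the tissue (inclusive). Returns columns mean_M, mean_F.
    """
    m_cols = sample_columns(matrix, tissue, "M")
    f_cols = sample_columns(matrix, tissue, "F")
    if not m_cols or not f_cols:
        raise ValueError(f"no samples for tissue {tissue!r}")
    mean_m = matrix[m_cols].mean(axis=1)
    mean_f = matrix[f_cols].mean(axis=1)
    keep = (mean_m >= cutoff) & (mean_f >= cutoff)
    return pd.DataFrame({"mean_M": mean_m[keep], "mean_F": mean_f[keep]})


def _exact_rank_sum_p(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration (midrank ties)."""
    na, nb = len(values_a), len(values_b)
    pooled = np.concatenate([values_a, values_b])
    ranks = stats.rankdata(pooled, method="average")
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mean_u = na * nb / 2.0
    dev = abs(u_obs - mean_u)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(na + nb), na):
        u = float(ranks[list(combo)].sum() - na * (na + 1) / 2.0)
        total += 1
        if abs(u - mean_u) >= dev - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def rank_sum_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U with midrank ties).

    Uses full enumeration when min(n_A, n_B) < 8, and the tie-corrected
    normal approximation with continuity correction otherwise.
    Returns (U statistic of group A, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group in rank-sum test")
    if min(a.size, b.size) < 8:
        return _exact_rank_sum_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class CompensationReport:
    """Fig-3-style per-tissue comparisons at one TPM cutoff."""

    tissue: str
    cutoff: float
    n_autosomal: int = 0
    n_z_diff: int = 0
    tests: dict = field(default_factory=dict)  # (sex) -> (U, p) or None
    log2_fm: pd.DataFrame | None = None  # per-gene log2(F/M) with region label
    median_log2_fm_z: float = math.nan
    median_log2_fm_auto: float = math.nan


def compare_regions(
    means: pd.DataFrame,
    region_of: dict[str, str],
    tissue: str,
    cutoff: float,
) -> CompensationReport:
    """Z-differentiated versus autosomal expression for one tissue.

    ``means`` holds per-sex mean TPM for retained genes; ``region_of``
    maps gene_id to {"autosome", "Z_diff"} (genes not in the map are
    ignored, e.g. W transcripts and undifferentiated Z genes). Rank-sum
    tests compare log2(mean TPM), per sex; log2(F/M) ratios are computed
    for genes with positive means in both sexes, with all counts reported.
    """
    rep = CompensationReport(tissue, cutoff)
    sub = means[means.index.isin(region_of)]
    labels = pd.Series([region_of[g] for g in sub.index], index=sub.index)
    auto = sub[labels == "autosome"]
    zdiff = sub[labels == "Z_diff"]
    rep.n_autosomal = len(auto)
    rep.n_z_diff = len(zdiff)
    if len(zdiff) == 0:
        log.warning("compare_regions: no Z_diff genes retained at cutoff %g", cutoff)
        rep.tests = {"M": None, "F": None}
        return rep
    for sex, col in (("M", "mean_M"), ("F", "mean_F")):
        a = np.log2(auto[col][auto[col] > 0])
        z = np.log2(zdiff[col][zdiff[col] > 0])
        rep.tests[sex] = rank_sum_test(z, a) if len(z) and len(a) else None
    ok = (sub["mean_M"] > 0) & (sub["mean_F"] > 0)
    ratios = pd.DataFrame(
        {
            "log2_fm": np.log2(sub.loc[ok, "mean_F"] / sub.loc[ok, "mean_M"]),
            "region": labels[ok],
        }
    )
    rep.log2_fm = ratios
    z_r = ratios.loc[ratios["region"] == "Z_diff", "log2_fm"]
    a_r = ratios.loc[ratios["region"] == "autosome", "log2_fm"]
    rep.median_log2_fm_z = float(z_r.median()) if len(z_r) else math.nan
    rep.median_log2_fm_auto = float(a_r.median()) if len(a_r) else math.nan
    return rep


def dosage_analysis(
    matrices: dict[str, pd.DataFrame],
    region_of: dict[str, str],
    cutoffs=(0.0, 0.5, 1.0),
    genes: list[str] | None = None,
) -> list[CompensationReport]:
    """Normalize, filter and compare for every tissue and TPM cutoff.

    ``genes`` restricts the matrices to the annotated gene set before
    normalization; quantile normalization assumes every sample shares one
    underlying expression distribution, which sex-limited transcripts
    (e.g. W-linked, female-only) violate by construction, so they must not
    enter the normalization reference.
    """
    reports = []
    for tissue, mat in matrices.items():
        if genes is not None:
            mat = mat[mat.index.isin(genes)]
        norm = quantile_normalize(mat)
        for cutoff in cutoffs:
            means = filter_and_average(norm, tissue, cutoff)
            rep = compare_regions(means, region_of, tissue, cutoff)
            for sex, res in rep.tests.items():
                if res is not None:
                    log.info(
                        "dosage: %s %s cutoff %g: n_auto=%d n_Z=%d U=%.1f p=%.3g",
                        tissue, sex, cutoff, rep.n_autosomal, rep.n_z_diff,
                        res[0], res[1],
                    )
            reports.append(rep)
    return reports


def report_table(reports: list[CompensationReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for sex in ("M", "F"):
            res = r.tests.get(sex)
            rows.append(
                {
                    "tissue": r.tissue,
                    "cutoff": r.cutoff,
                    "sex": sex,
                    "n_autosomal": r.n_autosomal,
                    "n_z_diff": r.n_z_diff,
                    "U": res[0] if res else math.nan,
                    "p": res[1] if res else math.nan,
                    "median_log2_fm_z": r.median_log2_fm_z,
                    "median_log2_fm_auto": r.median_log2_fm_auto,
                }
            )
    return pd.DataFrame(rows)
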