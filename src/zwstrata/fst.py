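"""Pooled two-population F_ST per site and per gene.

The estimator is the classical pooled one: per-site nucleotide diversity
within each pool pi_k = 2 p_k (1 - p_k) * C_k / (C_k - 1) (the C/(C-1)
factor is the finite-pool-size correction), diversity of the pooled
frequencies pi_total = 2 p_bar (1 - p_bar) * C_min / (C_min - 1) with
p_bar = (p_1 + p_2) / 2, and

    F_ST = (pi_total - mean pi_within) / pi_total .

Per gene, the statistic is a ratio of sums over the gene's passing sites,
not a mean of ratios. Pool order is (female, male) throughout the
pipeline; the statistic itself is symmetric in the two pools.

Input counts may come from DNA or pooled RNA reads; with RNA the allele
frequencies are expression-weighted, which is how the pooled transcriptome
design works and is simply inherited here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import GeneModel, SyncSite, log

_BASES = "ATCG"  # sync column order


@dataclass
class SiteFilterResult:
    passed: bool
    alleles: tuple[int, int] | None = None  # indices into ATCG
    freqs: tuple[float, float] | None = None  # frequency of alleles[0] per pool
    coverages: tuple[int, int] | None = None


@dataclass
class GeneFst:
    gene_id: str
    chrom: str
    midpoint: int
    n_sites_used: int
    fst: float  # NaN = missing
    pi_total_sum: float
    pi_within_sum: float


def site_filter(
    site: SyncSite,
    min_count: int = 2,
    min_coverage: int = 10,
    max_coverage: int = 500,
) -> SiteFilterResult:
    """Coverage and biallelicity filter for one sync site.

    Alleles whose combined count across pools is below ``min_count`` are
    masked; the site passes iff both pools are within the coverage bounds
    and exactly two alleles remain (more than two alleles after masking
    fails the biallelic requirement).
    """
    counts = np.array(site.pools, dtype=float)  # 2 x 4
    cov = counts.sum(axis=1)
    if np.any(cov < min_coverage) or np.any(cov > max_coverage):
        return SiteFilterResult(False)
    combined = counts.sum(axis=0)
    alleles = np.nonzero(combined >= min_count)[0]
    if alleles.size != 2:
        return SiteFilterResult(False)
    a, b = int(alleles[0]), int(alleles[1])
    # coverage restricted to the two retained alleles
    c1 = counts[0, a] + counts[0, b]
    c2 = counts[1, a] + counts[1, b]
    if c1 < 2 or c2 < 2:
        return SiteFilterResult(False)
    p1 = counts[0, a] / c1
    p2 = counts[1, a] / c2
    return SiteFilterResult(True, (a, b), (p1, p2), (int(c1), int(c2)))


def site_pi_components(
    p1: float, c1: int, p2: float, c2: int
) -> tuple[float, float]:
    """(mean within-pool pi, total pi) for one biallelic site."""
    if c1 < 2 or c2 < 2:
        raise ValueError("pool coverage must be >= 2")
    pi1 = 2.0 * p1 * (1.0 - p1) * c1 / (c1 - 1)
    pi2 = 2.0 * p2 * (1.0 - p2) * c2 / (c2 - 1)
    pbar = 0.5 * (p1 + p2)
    cmin = min(c1, c2)
    pi_total = 2.0 * pbar * (1.0 - pbar) * cmin / (cmin - 1)
    return 0.5 * (pi1 + pi2), pi_total


def site_fst(p1: float, c1: int, p2: float, c2: int) -> float:
    """Single-site F_ST; NaN when the site is monomorphic overall."""
    pi_w, pi_t = site_pi_components(p1, c1, p2, c2)
    if pi_t <= 0:
        return float("nan")
    return (pi_t - pi_w) / pi_t


def gene_fst(
    gene: GeneModel,
    sites: list[SyncSite],
    min_count: int = 2,
    min_coverage: int = 10,
    max_coverage: int = 500,
) -> GeneFst:
    """Ratio-of-sums F_ST over the passing sites falling in the gene's exons."""
    pi_w_sum = pi_t_sum = 0.0
    n_used = 0
    for site in sites:
        if site.chrom != gene.coords.chrom:
            continue
        if not any(e.contains_point(site.pos) for e in gene.exons):
            continue
        res = site_filter(site, min_count, min_coverage, max_coverage)
        if not res.passed:
            continue
        p1, p2 = res.freqs
        c1, c2 = res.coverages
        pi_w, pi_t = site_pi_components(p1, c1, p2, c2)
        pi_w_sum += pi_w
        pi_t_sum += pi_t
        n_used += 1
    fst = (pi_t_sum - pi_w_sum) / pi_t_sum if pi_t_sum > 0 else float("nan")
    return GeneFst(
        gene.gene_id,
        gene.coords.chrom,
        gene.coords.midpoint,
        n_used,
        fst,
        pi_t_sum,
        pi_w_sum,
    )


def genewise_fst(
    genes: list[GeneModel],
    sites: list[SyncSite],
    min_count: int = 2,
    min_coverage: int = 10,
    max_coverage: int = 500,
) -> pd.DataFrame:
    """Per-gene F_ST table; sites in overlapping genes count for each gene."""
    by_chrom: dict[str, list[SyncSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    rows = []
    for g in genes:
        gf = gene_fst(
            g, by_chrom.get(g.coords.chrom, []), min_count, min_coverage, max_coverage
        )
        rows.append(
            {
                "gene_id": gf.gene_id,
                "chrom": gf.chrom,
                "midpoint": gf.midpoint,
                "n_sites": gf.n_sites_used,
                "fst": gf.fst,
            }
        )
    return pd.DataFrame(rows)


def rolling_gene_median(values: np.ndarray, span: int = 10) -> np.ndarray:
    """Centered rolling median over genes ordered by midpoint (NaN-aware).

    Same edge/missing conventions as the window-coverage smoother.
    """
    from .coverage import WindowSeries, rolling_median

    series = WindowSeries("genes", 1, np.asarray(values, dtype=float), role="log2")
    return rolling_median(series, span).values


def autosomal_band(
    fst_values: np.ndarray, lo: float = 5.0, hi: float = 95.0
) -> tuple[float, float]:
    """Empirical (lo, hi) percentiles of autosomal gene F_ST.

    Linear-interpolation convention (numpy's default), so 100 values 1..100
    give (5.95, 95.05).
    """
    vals = np.asarray(fst_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 20:
        raise ValueError(f"need >= 20 autosomal F_ST values, got {vals.size}")
    p = np.percentile(vals, [lo, hi], method="linear")
    log.info("fst: autosomal band p%g=%.4f p%g=%.4f (n=%d)", lo, p[0], hi, p[1], vals.size)
    return float(p[0]), float(p[1])
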