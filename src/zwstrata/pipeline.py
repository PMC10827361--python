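"""End-to-end drivers: evidence collection and the full synthetic run.

The full pipeline on synthetic data is:

1. simulate a ZW genome with planted strata (``synth.simulate_genome``);
2. sexed depth tracks with and without W scaffolds -> coverage analysis
   (log2 F/M ratio, rolling medians, differentiated-region detection);
3. pooled allele counts per track -> per-gene F_ST and the autosomal
   percentile band;
4. W transcripts -> female-specificity filter -> reciprocal best hits
   against the rest of the transcriptome -> codon alignment -> NG86 dS;
5. join everything per gene into an evidence table -> stratum calls ->
   stratum intervals along the Z;
6. expression tables -> dosage-compensation comparisons.

Each stage draws from its own seeded RNG stream derived from the run seed,
so stages are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coverage as cov
from . import dosage as dos
from . import fst as fstmod
from . import homology as hom
from . import strata as strat
from . import synth
from .io_core import GeneModel, RunConfig, log


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = 2166136261
    for ch in f"{stage}:{seed}":
        h = ((h ^ ord(ch)) * 16777619) & 0xFFFFFFFF
    return h % (2**31)


# ---------------------------------------------------------------------------
# evidence collection


def gene_window_value(series: cov.WindowSeries, midpoint: int) -> float:
    i = midpoint // series.window_size
    if 0 <= i < series.n_windows:
        return float(series.values[i])
    return math.nan


def collect_evidence(
    genes: pd.DataFrame,
    smoothed_withw: dict[str, cov.WindowSeries],
    smoothed_now: dict[str, cov.WindowSeries],
    fst_withw: pd.DataFrame,
    fst_now: pd.DataFrame,
    ds_by_gene: dict[str, float],
    fst_withw_med: pd.DataFrame | None = None,
    fst_now_med: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join coverage, F_ST and dS evidence per gene.

    ``genes`` needs columns gene_id, chrom, start, end; F_ST tables are the
    per-gene outputs of the fst stage. The optional ``*_med`` tables carry
    the purely regional F_ST medians used by absence-of-elevation checks.
    """
    fst_w = dict(zip(fst_withw["gene_id"], fst_withw["fst"]))
    fst_n = dict(zip(fst_now["gene_id"], fst_now["fst"]))
    med_w = (
        dict(zip(fst_withw_med["gene_id"], fst_withw_med["fst"]))
        if fst_withw_med is not None
        else fst_w
    )
    med_n = (
        dict(zip(fst_now_med["gene_id"], fst_now_med["fst"]))
        if fst_now_med is not None
        else fst_n
    )
    rows = []
    for r in genes.itertuples():
        mid = (r.start + r.end) // 2
        cw = (
            gene_window_value(smoothed_withw[r.chrom], mid)
            if r.chrom in smoothed_withw
            else math.nan
        )
        cn = (
            gene_window_value(smoothed_now[r.chrom], mid)
            if r.chrom in smoothed_now
            else math.nan
        )
        rows.append(
            {
                "unit_id": r.gene_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "cov_withW": cw,
                "cov_noW": cn,
                "fst_withW": fst_w.get(r.gene_id, math.nan),
                "fst_noW": fst_n.get(r.gene_id, math.nan),
                "dS": ds_by_gene.get(r.gene_id, math.nan),
                "fst_withW_med": med_w.get(r.gene_id, math.nan),
                "fst_noW_med": med_n.get(r.gene_id, math.nan),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full synthetic run


@dataclass
class PipelineResult:
    truth: synth.SimulatedTruth
    genes: list[GeneModel]
    coverage_withw: dict
    coverage_now: dict
    fst_withw: pd.DataFrame
    fst_now: pd.DataFrame
    band_withw: tuple[float, float]
    band_now: tuple[float, float]
    pairs: pd.DataFrame  # divergence table
    evidence: pd.DataFrame
    calls: pd.DataFrame
    intervals: list
    thresholds: strat.StrataThresholds
    extras: dict = field(default_factory=dict)


def depth_tracks(
    truth: synth.SimulatedTruth, config: RunConfig, seed: int
) -> dict[tuple[str, bool], pd.DataFrame]:
    """(sex, include_w) -> window depth table, independent RNG per track."""
    out = {}
    for sex in ("female", "male"):
        for include_w in (True, False):
            s = stage_seed(seed, f"depth:{sex}:{include_w}")
            out[(sex, include_w)] = synth.simulate_depth(
                truth,
                sex,
                config.mean_depth,
                include_w=include_w,
                seed=s,
                window_size=config.window_size,
            )
    return out


def coverage_stage(
    truth: synth.SimulatedTruth,
    tracks: dict,
    config: RunConfig,
    include_w: bool,
) -> dict:
    female = cov.read_window_tsv_frame(tracks[("female", include_w)], config.window_size)
    male = cov.read_window_tsv_frame(tracks[("male", include_w)], config.window_size)
    return cov.coverage_analysis(
        female,
        male,
        truth.autosomes,
        truth.z_chrom,
        span=config.smoothing_windows,
        drop_delta=config.drop_delta,
        depth_floor=config.depth_floor,
        normalize=config.normalize_by_autosomal_depth,
        detect_on_smoothed=config.detect_on_smoothed,
        absolute_threshold=config.absolute_threshold,
        max_gap=config.merge_max_gap,
    )


def fst_stage(
    truth: synth.SimulatedTruth,
    genes: list[GeneModel],
    config: RunConfig,
    include_w: bool,
    seed: int,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    sites = synth.simulate_sync(
        truth,
        sites_per_gene=config.sites_per_gene,
        pool_depth=config.pool_depth,
        include_w=include_w,
        seed=stage_seed(seed, f"sync:{include_w}"),
    )
    table = fstmod.genewise_fst(
        genes,
        sites,
        min_count=config.fst_min_count,
        min_coverage=config.fst_min_coverage,
        max_coverage=config.fst_max_coverage,
    )
    auto_mask = table["chrom"].isin(truth.autosomes)
    band = fstmod.autosomal_band(
        table.loc[auto_mask, "fst"].to_numpy(), *config.percentile_band
    )
    return table, band


def smooth_gene_fst(table: pd.DataFrame, span: int) -> pd.DataFrame:
    """Rolling gene-median F_ST per chromosome (genes ordered by midpoint)."""
    out = table.sort_values(["chrom", "midpoint"]).copy()
    out["fst"] = np.concatenate(
        [
            fstmod.rolling_gene_median(sub["fst"].to_numpy(), span)
            for _, sub in out.groupby("chrom", sort=False)
        ]
    )
    return out


def blend_gene_fst(table: pd.DataFrame, span: int) -> pd.DataFrame:
    """Per-gene F_ST evidence: max of the raw value and the rolling median."""
    out = smooth_gene_fst(table, span)
    raw = table.sort_values(["chrom", "midpoint"])["fst"].to_numpy()
    out["fst"] = np.fmax(out["fst"].to_numpy(), raw)
    return out


def divergence_stage(
    truth: synth.SimulatedTruth,
    genome: list[tuple[str, str]],
    w_records: list[tuple[str, str]],
    genes: list[GeneModel],
    expression: dict[str, pd.DataFrame],
    config: RunConfig,
    min_seed_hits: int = 6,
) -> pd.DataFrame:
    """Specificity filter -> RBH -> codon alignment -> NG86 divergence."""
    if not w_records:
        return pd.DataFrame(
            columns=["w_id", "z_id", "aligned_len", "S", "N", "Sd", "Nd", "dS", "dN"]
        )
    # female-specificity of W transcripts from mean head/gonad expression
    recs = []
    for wid, _ in w_records:
        vals = {}
        for tissue in expression:
            mat = expression[tissue]
            if wid not in mat.index:
                continue
            for sex in ("F", "M"):
                cols = dos.sample_columns(mat, tissue, sex)
                vals[(tissue, sex)] = float(mat.loc[wid, cols].mean())
        recs.append(
            hom.SpecificityRecord(
                wid,
                vals.get(("head", "F"), 0.0),
                vals.get(("gonad", "F"), 0.0),
                vals.get(("head", "M"), 0.0),
                vals.get(("gonad", "M"), 0.0),
            )
        )
    kept = set(hom.specificity_filter(recs, config.specificity_cutoff))
    w_seqs = [(wid, seq) for wid, seq in w_records if wid in kept]
    if not w_seqs:
        return pd.DataFrame(
            columns=["w_id", "z_id", "aligned_len", "S", "N", "Sd", "Nd", "dS", "dN"]
        )
    transcripts = synth.extract_transcripts(genome, genes)
    pairs = hom.rbh_pairs(
        w_seqs, transcripts, seed_len=config.seed_len, min_seed_hits=min_seed_hits
    )
    # restrict to Z-chromosome homologs, as the strata analysis needs
    z_gene_ids = set(
        truth.genes.loc[truth.genes["chrom"] == truth.z_chrom, "gene_id"]
    )
    pairs = [p for p in pairs if p.z_id in z_gene_ids]
    table = hom.divergence_table(
        pairs, dict(w_seqs), dict(transcripts), min_nt=config.min_align_len
    )
    log.info("divergence: %d RBH pairs, %d after length filter", len(pairs), len(table))
    return table


def run_pipeline(
    config: RunConfig | None = None,
    seed: int = 0,
    compensated: bool = True,
    min_seed_hits: int = 6,
) -> PipelineResult:
    """Run the full synthetic analysis and return every stage's output."""
    config = config or RunConfig()
    genome, w_records, genes, truth = synth.simulate_genome(
        n_autosomes=config.n_autosomes,
        chrom_len=config.chrom_len,
        n_genes=config.n_genes,
        seed=stage_seed(seed, "genome"),
        gene_len=config.gene_len,
        window_size=config.window_size,
    )
    tracks = depth_tracks(truth, config, seed)
    cov_withw = coverage_stage(truth, tracks, config, include_w=True)
    cov_now = coverage_stage(truth, tracks, config, include_w=False)
    fst_withw, band_withw = fst_stage(truth, genes, config, True, seed)
    fst_now, band_now = fst_stage(truth, genes, config, False, seed)
    expression = synth.simulate_expression(
        truth,
        replicates=config.replicates,
        compensated=compensated,
        seed=stage_seed(seed, "expression"),
    )
    pairs = divergence_stage(
        truth, genome, w_records, genes, expression, config, min_seed_hits
    )
    ds_by_gene = {
        row.z_id: row.dS for row in pairs.itertuples() if not math.isnan(row.dS)
    }
    # F_ST evidence per gene: the larger of the gene's own value and the
    # rolling median over a tight (3-gene) window. The median lets genes
    # whose W copy is lost borrow signal from their differentiated
    # neighbourhood; the raw value keeps genes with their own signal
    # independent of how many neighbours lost theirs. A 3-gene window
    # still flips cleanly at stratum boundaries, and chance autosomal
    # double elevations are absorbed by the downstream call vote.
    fst_withw_sm = blend_gene_fst(fst_withw, config.fst_evidence_smoothing)
    fst_now_sm = blend_gene_fst(fst_now, config.fst_evidence_smoothing)
    evidence = collect_evidence(
        truth.genes,
        cov_withw["smoothed"],
        cov_now["smoothed"],
        fst_withw_sm,
        fst_now_sm,
        ds_by_gene,
        fst_withw_med=smooth_gene_fst(fst_withw, config.fst_evidence_smoothing),
        fst_now_med=smooth_gene_fst(fst_now, config.fst_evidence_smoothing),
    )
    ds_vals = [v for v in ds_by_gene.values() if not math.isnan(v)]
    ds_split = (
        config.ds_split
        if config.ds_split is not None
        else (float(np.median(ds_vals)) if ds_vals else 0.15)
    )
    thresholds = strat.StrataThresholds(
        full_drop=config.full_drop,
        partial_drop=config.partial_drop,
        fst_elevated=band_now[1],
        ds_split=ds_split,
    )
    calls = strat.coverage_fallback(
        strat.classify_table(evidence, thresholds), thresholds
    )
    z_calls = (
        calls[calls["chrom"] == truth.z_chrom]
        .sort_values("start")
        .reset_index(drop=True)
    )
    z_calls_sm, intervals = strat.segment_strata(
        z_calls, config.segment_vote_window, thresholds=thresholds
    )
    # fold the smoothed Z calls back in; apply the same majority-vote
    # smoothing along each autosome so isolated chance calls are absorbed
    calls = calls.merge(
        z_calls_sm[["unit_id", "call_smoothed"]], on="unit_id", how="left"
    )
    for chrom in truth.autosomes:
        sub = calls[calls["chrom"] == chrom].sort_values("start")
        calls.loc[sub.index, "call_smoothed"] = strat.demote_short_runs(
            strat.smooth_calls(list(sub["call"]), config.segment_vote_window)
        )
    calls["call_smoothed"] = calls["call_smoothed"].fillna(calls["call"])
    result = PipelineResult(
        truth=truth,
        genes=genes,
        coverage_withw=cov_withw,
        coverage_now=cov_now,
        fst_withw=fst_withw,
        fst_now=fst_now,
        band_withw=band_withw,
        band_now=band_now,
        pairs=pairs,
        evidence=evidence,
        calls=calls,
        intervals=intervals,
        thresholds=thresholds,
        extras={
            "genome": genome,
            "w_records": w_records,
            "expression": expression,
            "tracks": tracks,
        },
    )
    return result


# ---------------------------------------------------------------------------
# accuracy metrics against planted truth


def stratum_accuracy(calls: pd.DataFrame, truth: synth.SimulatedTruth) -> dict:
    """Per-stratum recall of smoothed calls and autosomal false S-calls."""
    merged = calls.merge(
        truth.genes[["gene_id", "stratum"]],
        left_on="unit_id",
        right_on="gene_id",
    )
    out = {}
    for s in ("S0", "S1", "S2"):
        sub = merged[merged["stratum"] == s]
        out[s] = float((sub["call_smoothed"] == s).mean()) if len(sub) else math.nan
    auto = merged[merged["stratum"] == "autosome"]
    out["autosomal_false_s"] = int(
        auto["call_smoothed"].isin(["S0", "S1", "S2"]).sum()
    )
    return out


def region_boundary_errors(
    regions: list,
    truth: synth.SimulatedTruth,
    window_size: int,
    strata_names: tuple[str, ...] = ("S0", "S1"),
) -> tuple[float, float]:
    """(start, end) boundary error, in windows, of the detected region
    closest to the planted span covering the given strata."""
    spans = [s.z_interval for s in truth.strata if s.name in strata_names]
    lo = min(s.start for s in spans)
    hi = max(s.end for s in spans)
    if not regions:
        return math.inf, math.inf
    best = min(
        regions,
        key=lambda r: abs(r.coords.start - lo) + abs(r.coords.end - hi),
    )
    return (
        abs(best.coords.start - lo) / window_size,
        abs(best.coords.end - hi) / window_size,
    )
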