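"""Window coverage, log2 female:male ratio, smoothing, and region detection.

The differentiated region of a ZW pair is found from sequencing depth: a
female carries one Z dose where a male carries two, so wherever the W copy
is lost or too diverged for female reads to map, the log2(female/male)
coverage ratio sits near -1 while autosomes sit near 0. Regions are called
as maximal runs of windows whose (smoothed) ratio stays below a threshold
anchored at the autosomal median.

Missing values are represented as NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import GenomeCoords, log


@dataclass
class WindowSeries:
    """Fixed-width window values along one chromosome (NaN = missing)."""

    chrom: str
    window_size: int
    values: np.ndarray
    role: str = "depth"  # depth | log2 | smoothed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_windows(self) -> int:
        return int(self.values.size)

    def window_coords(self, i: int, chrom_len: int | None = None) -> GenomeCoords:
        start = i * self.window_size
        end = (i + 1) * self.window_size
        if chrom_len is not None:
            end = min(end, chrom_len)
        return GenomeCoords(self.chrom, start, end)


@dataclass
class DifferentiatedRegion:
    coords: GenomeCoords
    window_span: tuple[int, int]  # (first, last) window index, inclusive
    mean_log2: float

    def to_1based(self) -> tuple[int, int]:
        return self.coords.to_1based()


# ---------------------------------------------------------------------------


def read_depth_tsv(path: str | Path) -> pd.DataFrame:
    """Read a depth table: chrom, pos0, depth (tab-separated, no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"])
    return df


def depth_to_windows(
    depth: pd.DataFrame, window_size: int, chrom_len: int | None = None
) -> dict[str, WindowSeries]:
    """Mean per-base depth in fixed windows, per chromosome.

    Positions absent from the table count as depth 0; the trailing partial
    window uses its true base count as denominator (requires ``chrom_len``,
    otherwise the last position seen defines the extent).
    """
    out: dict[str, WindowSeries] = {}
    for chrom, sub in depth.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"depth positions not sorted on {chrom}")
        extent = chrom_len if chrom_len is not None else int(pos[-1]) + 1
        n_win = int(np.ceil(extent / window_size))
        sums = np.bincount(pos // window_size, weights=sub["depth"].to_numpy(), minlength=n_win)
        sizes = np.full(n_win, window_size, dtype=float)
        sizes[-1] = extent - (n_win - 1) * window_size
        out[chrom] = WindowSeries(str(chrom), window_size, sums / sizes, role="depth")
    return out


def read_window_tsv_frame(df: pd.DataFrame, window_size: int) -> dict[str, WindowSeries]:
    """Windowed depth table (chrom, start, depth) -> WindowSeries per chrom."""
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        if not np.array_equal(starts, np.arange(len(starts)) * window_size):
            raise ValueError(f"window starts not contiguous from 0 on {chrom}")
        out[chrom] = WindowSeries(str(chrom), window_size, sub["depth"].to_numpy(), "depth")
    return out


def read_window_tsv(path: str | Path, window_size: int) -> dict[str, WindowSeries]:
    """Read an already-windowed depth table: chrom, window_start0, depth."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "depth"])
    return read_window_tsv_frame(df, window_size)


def log2_ratio(
    female: WindowSeries, male: WindowSeries, depth_floor: float = 1.0
) -> WindowSeries:
    """Per-window log2(female/male); missing where either depth < floor."""
    if (female.chrom, female.window_size, female.n_windows) != (
        male.chrom, male.window_size, male.n_windows,
    ):
        raise ValueError(
            f"window series mismatch on {female.chrom}/{male.chrom}"
        )
    f, m = female.values, male.values
    vals = np.full(f.shape, np.nan)
    ok = (f >= depth_floor) & (m >= depth_floor)
    vals[ok] = np.log2(f[ok] / m[ok])
    return WindowSeries(female.chrom, female.window_size, vals, role="log2")


def rolling_median(series: WindowSeries, span: int = 30) -> WindowSeries:
    """Centered rolling median over ``span`` windows.

    Positions whose window would extend past either end are missing; missing
    inputs are excluded from each median and the result is missing when
    fewer than span/2 inputs remain. ``span`` = 1 is the identity.
    """
    if span < 1:
        raise ValueError("span must be >= 1")
    v = series.values
    n = v.size
    out = np.full(n, np.nan)
    if span > n:
        log.warning(
            "rolling_median: span %d exceeds series length %d on %s; all missing",
            span, n, series.chrom,
        )
        return WindowSeries(series.chrom, series.window_size, out, role="smoothed")
    half = span // 2
    for i in range(n):
        lo = i - half
        hi = lo + span
        if lo < 0 or hi > n:
            continue
        window = v[lo:hi]
        window = window[~np.isnan(window)]
        if window.size >= span / 2:
            out[i] = float(np.median(window))
    return WindowSeries(series.chrom, series.window_size, out, role="smoothed")


def autosomal_median(series_by_chrom: dict[str, WindowSeries], autosomes: Sequence[str]) -> float:
    """Median of all non-missing log2-ratio windows on the given autosomes."""
    if not autosomes:
        raise ValueError("no autosomes designated")
    vals = np.concatenate(
        [series_by_chrom[c].values for c in autosomes if c in series_by_chrom]
    ) if any(c in series_by_chrom for c in autosomes) else np.array([])
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no non-missing autosomal windows")
    return float(np.median(vals))


def detect_regions(
    smoothed: WindowSeries,
    threshold: float,
    chrom_len: int | None = None,
    max_gap: int = 0,
) -> list[DifferentiatedRegion]:
    """Maximal runs of consecutive windows strictly below ``threshold``.

    Missing values terminate a run. Optional ``max_gap`` merges runs
    separated by at most that many windows (off by default; the default
    pipeline reports the raw segments).
    """
    v = smoothed.values
    below = (~np.isnan(v)) & (v < threshold)
    regions: list[DifferentiatedRegion] = []
    i = 0
    n = v.size
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            regions.append((i, j))
            i = j + 1
        else:
            i += 1
    if max_gap > 0 and regions:
        merged = [regions[0]]
        for s, e in regions[1:]:
            ps, pe = merged[-1]
            if s - pe - 1 <= max_gap:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        regions = merged
    out = []
    ws = smoothed.window_size
    for s, e in regions:
        end_bp = (e + 1) * ws
        if chrom_len is not None:
            end_bp = min(end_bp, chrom_len)
        coords = GenomeCoords(smoothed.chrom, s * ws, end_bp)
        member = v[s : e + 1]
        out.append(DifferentiatedRegion(coords, (s, e), float(np.nanmean(member))))
    return out


# ---------------------------------------------------------------------------
# stage driver


def coverage_analysis(
    female: dict[str, WindowSeries],
    male: dict[str, WindowSeries],
    autosomes: Sequence[str],
    z_chrom: str,
    span: int = 30,
    drop_delta: float = 0.5,
    depth_floor: float = 1.0,
    normalize: bool = True,
    detect_on_smoothed: bool = True,
    absolute_threshold: float | None = None,
    max_gap: int = 0,
) -> dict:
    """Full coverage stage: ratio, smoothing, threshold, region detection.

    ``normalize`` rescales each sex's depths by its autosomal median depth
    before forming the ratio, so a library-size imbalance does not shift the
    log2 baseline away from 0.
    """
    if normalize:
        def med_depth(series: dict[str, WindowSeries]) -> float:
            vals = np.concatenate([series[c].values for c in autosomes if c in series])
            vals = vals[~np.isnan(vals)]
            return float(np.median(vals))

        fmed, mmed = med_depth(female), med_depth(male)
        scale_f = 1.0 / fmed if fmed > 0 else 1.0
        scale_m = 1.0 / mmed if mmed > 0 else 1.0
        female = {
            c: WindowSeries(s.chrom, s.window_size, s.values * scale_f, s.role)
            for c, s in female.items()
        }
        male = {
            c: WindowSeries(s.chrom, s.window_size, s.values * scale_m, s.role)
            for c, s in male.items()
        }
        depth_floor = depth_floor * min(scale_f, scale_m)

    ratios = {
        c: log2_ratio(female[c], male[c], depth_floor=depth_floor) for c in female
    }
    smoothed = {c: rolling_median(r, span) for c, r in ratios.items()}
    auto_med = autosomal_median(ratios, autosomes)
    threshold = (
        absolute_threshold if absolute_threshold is not None else auto_med - drop_delta
    )
    detect_series = smoothed if detect_on_smoothed else ratios
    regions = detect_regions(detect_series[z_chrom], threshold, max_gap=max_gap)
    log.info(
        "coverage: autosomal median %.4f, threshold %.4f, %d region(s) on %s",
        auto_med, threshold, len(regions), z_chrom,
    )
    return {
        "ratio": ratios,
        "smoothed": smoothed,
        "autosomal_median": auto_med,
        "threshold": threshold,
        "regions": regions,
    }


def window_table(
    female: dict[str, WindowSeries],
    male: dict[str, WindowSeries],
    ratio: dict[str, WindowSeries],
    smoothed: dict[str, WindowSeries],
) -> pd.DataFrame:
    rows = []
    for c in female:
        n = female[c].n_windows
        ws = female[c].window_size
        for i in range(n):
            rows.append(
                {
                    "chrom": c,
                    "start0": i * ws,
                    "raw_f": female[c].values[i],
                    "raw_m": male[c].values[i],
                    "log2": ratio[c].values[i],
                    "smoothed": smoothed[c].values[i],
                }
            )
    return pd.DataFrame(rows)
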