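"""Shared coordinate conventions, domain records, and readers/writers.

Everything internal is 0-based half-open; the 1-based inclusive convention
used in genomics reports appears only at the report boundary (``to_1based``
/ ``from_1based``).
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml
from Bio import SeqIO

log = logging.getLogger("zwstrata")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(levelname)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


# ---------------------------------------------------------------------------
# coordinates


@dataclass(frozen=True, order=True)
class GenomeCoords:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def to_1based(self) -> tuple[int, int]:
        """Return (start, end) in 1-based inclusive convention."""
        return self.start + 1, self.end

    @classmethod
    def from_1based(cls, chrom: str, start1: int, end1: int) -> "GenomeCoords":
        """Build from 1-based inclusive coordinates (lossless round trip)."""
        return cls(chrom, start1 - 1, end1)

    def overlaps(self, other: "GenomeCoords") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneModel:
    """A gene with exon structure; exons sorted, non-overlapping, within coords."""

    gene_id: str
    coords: GenomeCoords
    strand: str = "+"
    exons: list[GenomeCoords] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            self.exons = [self.coords]
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = -1
        for e in self.exons:
            if e.chrom != self.coords.chrom:
                raise ValueError(f"exon chrom mismatch in {self.gene_id}")
            if e.start < prev_end:
                raise ValueError(f"overlapping exons in {self.gene_id}")
            if e.start < self.coords.start or e.end > self.coords.end:
                raise ValueError(f"exon outside gene span in {self.gene_id}")
            prev_end = e.end


@dataclass(frozen=True)
class SyncSite:
    """One site of a two-pool sync file; N/del counts are parsed but dropped."""

    chrom: str
    pos: int  # 0-based
    ref: str
    pools: tuple[tuple[int, int, int, int], ...]  # A, T, C, G per pool

    @property
    def coverages(self) -> tuple[int, ...]:
        return tuple(sum(p) for p in self.pools)


# ---------------------------------------------------------------------------
# run configuration

_STRATUM_DEFAULTS = {
    # name: (w_retention, target_dS, w_snp_density per bp)
    "S0": (0.1, 0.40, 0.020),
    "S1": (0.9, 0.15, 0.010),
    "S2": (0.9, 0.05, 0.004),
}


@dataclass
class RunConfig:
    """Every tunable of the pipeline, flat with stage-namespaced names.

    Serializes to/from YAML deterministically; every run should log the
    resolved config so threshold-heavy results stay reproducible.
    """

    # k-mer stage
    kmer_k: int = 21
    kmer_min_count: int = 2
    mkf_threshold: float = 0.2
    # coverage stage
    window_size: int = 10_000
    smoothing_windows: int = 30
    drop_delta: float = 0.5
    depth_floor: float = 1.0
    normalize_by_autosomal_depth: bool = True
    detect_on_smoothed: bool = True
    absolute_threshold: float | None = None  # overrides median - drop_delta
    merge_max_gap: int = 0  # 0 = no merging of nearby regions
    # fst stage
    fst_min_count: int = 2
    fst_min_coverage: int = 10
    fst_max_coverage: int = 500
    fst_gene_smoothing: int = 10  # display track (rolling median over genes)
    fst_evidence_smoothing: int = 3  # classifier evidence; tight odd span
    # so a stratum's edge genes keep a same-stratum majority in the window
    percentile_band: tuple[float, float] = (5.0, 95.0)
    # homology stage
    seed_len: int = 11
    min_seed_hits: int = 1
    specificity_cutoff: float = 0.9
    min_align_len: int = 300
    # strata thresholds
    full_drop: float = -0.75
    partial_drop: float = -0.25
    ds_split: float | None = None  # None = median dS over all ZW pairs
    segment_vote_window: int = 5
    # dosage stage
    tpm_cutoffs: tuple[float, ...] = (0.0, 0.5, 1.0)
    # synthetic data
    n_autosomes: int = 3
    chrom_len: int = 3_000_000
    n_genes: int = 300
    gene_len: int = 1_500
    mean_depth: float = 30.0
    n_reads: int = 5_000
    read_len: int = 1_000
    per_base_error: float = 0.01
    sites_per_gene: int = 10
    pool_depth: int = 50
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kmer_k % 2 == 0 or not (11 <= self.kmer_k <= 31):
            raise ValueError("kmer_k must be odd and within [11, 31]")
        if not (0.0 <= self.mkf_threshold <= 1.0):
            raise ValueError("mkf_threshold must be in [0, 1]")
        if self.window_size <= 0 or self.smoothing_windows < 1:
            raise ValueError("window_size/smoothing_windows out of range")
        if not (0.0 <= self.specificity_cutoff <= 1.0):
            raise ValueError("specificity_cutoff must be in [0, 1]")
        if not (self.full_drop < self.partial_drop < 0):
            raise ValueError("need full_drop < partial_drop < 0")
        lo, hi = self.percentile_band
        if not (0 <= lo < hi <= 100):
            raise ValueError("percentile_band out of range")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["percentile_band"] = list(d["percentile_band"])
        d["tpm_cutoffs"] = list(d["tpm_cutoffs"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "percentile_band" in d:
            d["percentile_band"] = tuple(d["percentile_band"])
        if "tpm_cutoffs" in d:
            d["tpm_cutoffs"] = tuple(d["tpm_cutoffs"])
        return cls(**d)

    def log_resolved(self, stage: str) -> None:
        log.info("%s: resolved config %s", stage, dataclasses.asdict(self))


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercased sequence) pairs.

    Raises on duplicate ids and on empty files; input order is preserved.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a FASTQ file.

    Malformed records raise with the (0-based) record index.
    """
    idx = 0
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record at index {idx} in {path}")
            yield header[1:].split()[0], seq.upper(), qual
            idx += 1


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# sync (PoPoolation2 dialect: chrom, pos1, ref, then A:T:C:G:N:del per pool)


def read_sync(path: str | Path, n_pools: int = 2) -> list[SyncSite]:
    """Parse a sync file; positions are converted from 1-based to 0-based."""
    sites: list[SyncSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_pools:
                raise ValueError(
                    f"{path}:{lineno}: expected {3 + n_pools} fields, got {len(fields)}"
                )
            chrom, pos_s, ref = fields[:3]
            pools = []
            for fld in fields[3:]:
                parts = fld.split(":")
                if len(parts) != 6:
                    raise ValueError(
                        f"{path}:{lineno}: malformed count field {fld!r} "
                        "(expected A:T:C:G:N:del)"
                    )
                try:
                    counts = [int(x) for x in parts]
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer count in {fld!r}"
                    ) from exc
                if any(c < 0 for c in counts):
                    raise ValueError(f"{path}:{lineno}: negative count in {fld!r}")
                pools.append(tuple(counts[:4]))  # A,T,C,G; N/del dropped
            sites.append(SyncSite(chrom, int(pos_s) - 1, ref, tuple(pools)))
    return sites


def write_sync(sites: Iterable[SyncSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fields = [s.chrom, str(s.pos + 1), s.ref]
            for p in s.pools:
                fields.append(":".join(str(c) for c in (*p, 0, 0)))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED / GTF


def write_bed(regions: Sequence[GenomeCoords], path: str | Path) -> None:
    """Write BED3 (0-based half-open), sorted by chrom then start."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_bed(path: str | Path) -> list[GenomeCoords]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append(GenomeCoords(chrom, int(start), int(end)))
    return regions


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.rstrip(";").split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "="):
            return part.split(None, 1)[1].strip().strip('"')
    return None


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF file keyed on the gene_id attribute.

    Gene span comes from ``gene`` records when present, otherwise from the
    union of that gene's exons.
    """
    spans: dict[str, tuple[str, int, int, str]] = {}
    exons: dict[str, list[GenomeCoords]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GTF line in {path}: {line!r}")
            chrom, _, feat, start1, end1, _, strand, _, attrs = f[:9]
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                raise ValueError(f"GTF record without gene_id in {path}")
            start, end = int(start1) - 1, int(end1)
            if gid not in spans and gid not in exons:
                order.append(gid)
            if feat == "gene":
                spans[gid] = (chrom, start, end, strand)
            elif feat == "exon":
                exons.setdefault(gid, []).append(GenomeCoords(chrom, start, end))
    genes = []
    for gid in order:
        ex = exons.get(gid, [])
        if gid in spans:
            chrom, start, end, strand = spans[gid]
        else:
            chrom = ex[0].chrom
            start, end = min(e.start for e in ex), max(e.end for e in ex)
            strand = "+"
        genes.append(GeneModel(gid, GenomeCoords(chrom, start, end), strand, ex))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "zwstrata") -> None:
    with open(path, "w") as fh:
        for g in genes:
            s1, e1 = g.coords.to_1based()
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.coords.chrom}\t{source}\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                xs1, xe1 = ex.to_1based()
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{xs1}\t{xe1}\t.\t{g.strand}\t.\t{attrs}\n"
                )
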