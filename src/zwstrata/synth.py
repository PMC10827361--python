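"""Synthetic ZW genomes with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a female-heterogametic (ZW) genome in which the Z carries three
contiguous evolutionary strata —

* S0, ancestral: W copies mostly lost (low retention), surviving copies
  highly diverged (high dS); female reads from the region no longer map
  to the Z whether or not W scaffolds are in the reference.
* S1, intermediate: W retained and moderately diverged; W reads are
  captured by W scaffolds when those are in the reference, but cross-map
  onto the Z (carrying female-specific variants) when they are not.
* S2, young: W nearly identical to Z; W reads map onto the Z regardless,
  so coverage shows no drop but female pools carry W-specific alleles.

Everything is parameterized through :class:`StratumSpec`; sexed depth
tracks, long reads, pooled allele counts (sync) and expression tables are
drawn from this planted truth with independent seeded RNG streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .homology import ng_dnds
from .io_core import _STRATUM_DEFAULTS, GeneModel, GenomeCoords, SyncSite, log

_NONSTOP_CODONS = None  # filled lazily


def _nonstop_codons() -> np.ndarray:
    global _NONSTOP_CODONS
    if _NONSTOP_CODONS is None:
        import itertools

        from Bio.Data import CodonTable

        stops = set(CodonTable.unambiguous_dna_by_id[1].stop_codons)
        _NONSTOP_CODONS = np.array(
            ["".join(c) for c in itertools.product("ACGT", repeat=3)
             if "".join(c) not in stops]
        )
    return _NONSTOP_CODONS


@dataclass
class StratumSpec:
    """Planted parameters of one evolutionary stratum on the Z."""

    name: str  # S0 | S1 | S2
    z_interval: GenomeCoords
    w_retention: float  # fraction of genes with a surviving W homolog
    target_dS: float  # expected synonymous Z-W divergence
    w_snp_density: float  # W-specific variants per bp

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_retention <= 1.0):
            raise ValueError(f"{self.name}: w_retention outside [0, 1]")
        if self.target_dS < 0 or self.w_snp_density < 0:
            raise ValueError(f"{self.name}: negative rate")


# fraction of W-derived female reads that cross-map onto the Z, by stratum,
# for each mapping reference (with vs without the W scaffolds); W scaffolds
# capture part of the W reads even where the W is nearly identical to Z,
# so every stratum's female-pool W signal weakens when they are included
CROSS_MAP_WITH_W = {"S0": 0.0, "S1": 0.0, "S2": 0.7}
CROSS_MAP_NO_W = {"S0": 0.0, "S1": 0.5, "S2": 0.9}


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated genome (the acceptance oracle)."""

    strata: list[StratumSpec]
    genes: pd.DataFrame  # gene_id, chrom, start, end, stratum, w_present
    z_chrom: str
    autosomes: list[str]
    chrom_len: int
    seed: int
    compensated: bool | None = None

    def stratum_of(self, name: str) -> StratumSpec | None:
        for s in self.strata:
            if s.name == name:
                return s
        return None

    def cross_map(self, stratum: str, include_w: bool) -> float:
        """Cross-mapping fraction r for a Z position's stratum label."""
        if stratum in ("autosome", "z_undiff"):
            return 1.0
        return (CROSS_MAP_WITH_W if include_w else CROSS_MAP_NO_W)[stratum]

    def stratum_label(self, chrom: str, pos: int) -> str:
        if chrom != self.z_chrom:
            return "autosome"
        for s in self.strata:
            if s.z_interval.contains_point(pos):
                return s.name
        return "z_undiff"


def default_strata(chrom_len: int = 3_000_000) -> list[StratumSpec]:
    """Three contiguous strata in order S2-S0-S1 in the middle of the Z."""
    edges = [int(chrom_len * f) for f in (0.20, 0.40, 0.70, 0.85)]
    order = ["S2", "S0", "S1"]
    out = []
    for name, lo, hi in zip(order, edges[:-1], edges[1:]):
        ret, ds, dens = _STRATUM_DEFAULTS[name]
        out.append(StratumSpec(name, GenomeCoords("Z", lo, hi), ret, ds, dens))
    return out


def _validate_strata(strata: Sequence[StratumSpec], chrom_len: int) -> None:
    ivs = sorted(strata, key=lambda s: s.z_interval.start)
    for a, b in zip(ivs, ivs[1:]):
        if a.z_interval.end > b.z_interval.start:
            raise ValueError(f"strata {a.name} and {b.name} overlap")
    for s in strata:
        if s.z_interval.end > chrom_len:
            raise ValueError(f"stratum {s.name} extends past the Z")
    by_name = {s.name: s for s in strata}
    if set(by_name) == {"S0", "S1", "S2"}:
        if by_name["S0"].w_retention > min(s.w_retention for s in strata):
            raise ValueError("S0 must have the lowest w_retention")
        if by_name["S0"].target_dS < max(s.target_dS for s in strata):
            raise ValueError("S0 must have the highest target_dS")
        if by_name["S2"].target_dS > min(s.target_dS for s in strata):
            raise ValueError("S2 must have the lowest target_dS")


# ---------------------------------------------------------------------------
# sequence helpers


def _random_chrom(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random chromosome as a uint8 byte array over ACGT."""
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.integers(0, 4, size=length)]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random open reading frame (no internal stop codons)."""
    codons = _nonstop_codons()
    return "".join(codons[rng.integers(0, codons.size, size=n_codons)])


def mutate_sequence(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each position independently with probability ``rate``."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        lut = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}
        for i in hit:
            choices = lut.get(int(arr[i]), b"ACG")
            arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def calibrate_w_cds(
    rng: np.random.Generator, z_cds: str, target_ds: float, rel_tol: float = 0.10,
    max_tries: int = 40,
) -> str:
    """Mutate a Z coding sequence until its NG86 dS to the original reaches
    ``target_ds`` within ``rel_tol`` (rejection loop with rate re-scaling)."""
    if target_ds <= 0:
        return z_cds
    # inverse Jukes-Cantor as the starting per-site rate
    mu = 0.75 * (1.0 - np.exp(-4.0 * target_ds / 3.0))
    best = None
    for _ in range(max_tries):
        cand = mutate_sequence(rng, z_cds, mu)
        ds = ng_dnds(z_cds, cand).dS
        if np.isnan(ds) or ds <= 0:
            mu *= 0.5
            continue
        err = abs(ds - target_ds) / target_ds
        if best is None or err < best[0]:
            best = (err, cand)
        if err <= rel_tol:
            return cand
        mu *= target_ds / ds
        mu = float(np.clip(mu, 1e-6, 0.7))
    log.warning(
        "calibrate_w_cds: settled at relative dS error %.3f for target %.3f",
        best[0], target_ds,
    )
    return best[1]


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    n_autosomes: int = 3,
    chrom_len: int = 3_000_000,
    strata: Sequence[StratumSpec] | None = None,
    n_genes: int = 300,
    seed: int = 0,
    gene_len: int = 1_500,
    window_size: int = 10_000,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[GeneModel], SimulatedTruth]:
    """Simulate a diploid ZW genome with planted strata.

    Returns (Z+autosome fasta records, W fasta records, gene models, truth).
    W sequences derive from Z genes by per-site substitution calibrated to
    each stratum's target dS; a gene has a W copy with probability
    ``w_retention``. Deterministic for a fixed seed.
    """
    if chrom_len < 100 * window_size:
        raise ValueError("chrom_len must be at least 100 windows")
    if strata is None:
        strata = default_strata(chrom_len)
    _validate_strata(strata, chrom_len)
    if gene_len % 3:
        raise ValueError("gene_len must be a multiple of 3")

    rng = np.random.default_rng(seed)
    chrom_names = [f"A{i + 1}" for i in range(n_autosomes)] + ["Z"]
    per_chrom = n_genes // len(chrom_names)
    extra = n_genes - per_chrom * len(chrom_names)

    genome: list[tuple[str, str]] = []
    w_records: list[tuple[str, str]] = []
    genes: list[GeneModel] = []
    rows = []
    gi = 0
    for ci, chrom in enumerate(chrom_names):
        arr = _random_chrom(rng, chrom_len)
        n_here = per_chrom + (1 if ci < extra else 0)
        spacing = chrom_len // n_here
        for j in range(n_here):
            start = j * spacing + (spacing - gene_len) // 2
            coords = GenomeCoords(chrom, start, start + gene_len)
            gid = f"g{gi:04d}"
            gi += 1
            cds = _random_cds(rng, gene_len // 3)
            arr[start : start + gene_len] = np.frombuffer(cds.encode(), dtype=np.uint8)
            genes.append(GeneModel(gid, coords, "+", [coords]))
            stratum = "autosome"
            if chrom == "Z":
                stratum = "z_undiff"
                for s in strata:
                    if s.z_interval.contains_point(coords.midpoint):
                        stratum = s.name
                        break
            w_present = False
            if stratum in ("S0", "S1", "S2"):
                spec = next(s for s in strata if s.name == stratum)
                if rng.random() < spec.w_retention:
                    w_present = True
                    w_cds = calibrate_w_cds(rng, cds, spec.target_dS)
                    w_records.append((f"W_{gid}", w_cds))
            rows.append(
                {
                    "gene_id": gid,
                    "chrom": chrom,
                    "start": coords.start,
                    "end": coords.end,
                    "stratum": stratum,
                    "w_present": w_present,
                }
            )
        genome.append((chrom, arr.tobytes().decode()))

    truth = SimulatedTruth(
        strata=list(strata),
        genes=pd.DataFrame(rows),
        z_chrom="Z",
        autosomes=chrom_names[:-1],
        chrom_len=chrom_len,
        seed=seed,
    )
    return genome, w_records, genes, truth


def extract_transcripts(
    genome: list[tuple[str, str]], genes: list[GeneModel]
) -> list[tuple[str, str]]:
    """Pull each gene's spliced (here single-exon) sequence from the genome."""
    seqs = dict(genome)
    out = []
    for g in genes:
        chrom_seq = seqs[g.coords.chrom]
        out.append((g.gene_id, "".join(chrom_seq[e.start : e.end] for e in g.exons)))
    return out


# ---------------------------------------------------------------------------
# depth


def expected_female_z_factor(stratum: str, include_w: bool) -> float:
    """Expected female/male depth ratio for a Z position given its stratum."""
    r = 1.0 if stratum == "z_undiff" else (
        CROSS_MAP_WITH_W if include_w else CROSS_MAP_NO_W
    )[stratum]
    return 0.5 + 0.5 * r


def simulate_depth(
    truth: SimulatedTruth,
    sex: str,
    mean_depth: float = 30.0,
    include_w: bool = True,
    seed: int = 0,
    window_size: int = 10_000,
) -> pd.DataFrame:
    """Per-window depth track for one sex: (chrom, window_start0, depth).

    Autosomes have expected depth ``mean_depth`` in both sexes; the male Z
    does too (males are ZZ). The female Z window expectation is
    ``mean_depth * (0.5 + 0.5 r)`` where r is the stratum's cross-mapping
    fraction under the chosen mapping reference (overlap-weighted for
    windows straddling a stratum boundary). Window depth is Poisson:
    the total base count over the window divided by the window size.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex label {sex!r}")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    chroms = truth.autosomes + [truth.z_chrom]
    n_win = int(np.ceil(truth.chrom_len / window_size))
    rows = []
    for chrom in chroms:
        expected = np.full(n_win, mean_depth)
        if chrom == truth.z_chrom and sex == "female":
            factors = np.full(n_win, 1.0)
            for i in range(n_win):
                lo, hi = i * window_size, min((i + 1) * window_size, truth.chrom_len)
                acc = 0.0
                pos = lo
                # overlap-weighted mixture of stratum factors
                bounds = sorted(
                    {lo, hi}
                    | {s.z_interval.start for s in truth.strata}
                    | {s.z_interval.end for s in truth.strata}
                )
                for a, b in zip(bounds, bounds[1:]):
                    if b <= lo or a >= hi:
                        continue
                    seg = min(b, hi) - max(a, lo)
                    label = truth.stratum_label(chrom, max(a, lo))
                    acc += seg * expected_female_z_factor(label, include_w)
                    pos += seg
                factors[i] = acc / (hi - lo)
            expected = expected * factors
        sizes = np.full(n_win, window_size, dtype=float)
        sizes[-1] = truth.chrom_len - (n_win - 1) * window_size
        depth = rng.poisson(expected * sizes) / sizes
        for i in range(n_win):
            rows.append({"chrom": chrom, "start": i * window_size, "depth": depth[i]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# long reads


def simulate_long_reads(
    sequences: list[tuple[str, str]],
    n_reads: int,
    read_len: int = 1_000,
    per_base_error: float = 0.01,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Uniformly drawn error-prone long reads with per-read origin truth.

    Reads are drawn uniformly over all valid start positions of all input
    sequences; sequencing errors are i.i.d. substitutions.
    """
    rng = np.random.default_rng(seed)
    lens = [len(s) for _, s in sequences]
    if n_reads > 0 and read_len > max(lens, default=0):
        raise ValueError("read_len exceeds every source sequence length")
    weights = np.array([max(0, L - read_len + 1) for L in lens], dtype=float)
    weights /= weights.sum()
    reads: list[tuple[str, str, str]] = []
    rows = []
    qual = "I" * read_len
    picks = rng.choice(len(sequences), size=n_reads, p=weights)
    for i, si in enumerate(picks):
        name, seq = sequences[si]
        start = int(rng.integers(0, len(seq) - read_len + 1))
        read = seq[start : start + read_len]
        if per_base_error > 0:
            read = mutate_sequence(rng, read, per_base_error)
        rid = f"read{i:06d}"
        reads.append((rid, read, qual))
        rows.append({"read_id": rid, "origin": name, "start": start})
    return reads, pd.DataFrame(rows, columns=["read_id", "origin", "start"])


# ---------------------------------------------------------------------------
# pooled allele counts (sync)

_ALT_OF = {"A": "C", "T": "G", "C": "A", "G": "T"}
_BASE_COL = {"A": 0, "T": 1, "C": 2, "G": 3}


def _counts(ref: str, alt: str, n_ref: int, n_alt: int) -> tuple[int, int, int, int]:
    pool = [0, 0, 0, 0]
    pool[_BASE_COL[ref]] += n_ref
    pool[_BASE_COL[alt]] += n_alt
    return tuple(pool)


def simulate_sync(
    truth: SimulatedTruth,
    sites_per_gene: int = 10,
    pool_depth: int = 50,
    include_w: bool = True,
    seed: int = 0,
    gene_len: int | None = None,
) -> list[SyncSite]:
    """Pooled (female, male) allele counts per gene with planted W signal.

    Every gene gets ``sites_per_gene`` background polymorphic sites where
    both pools sample the same allele frequency (F_ST expectation ~ 0).
    Genes in strata with a surviving W homolog additionally carry
    W-specific sites (Poisson with mean ``w_snp_density * gene length``);
    there the female pool contains the W allele at frequency
    0.5 r / (0.5 + 0.5 r) — the W-derived share of the female reads that
    map — while the male pool is fixed for the reference.
    """
    if pool_depth < 10:
        raise ValueError("pool_depth must be >= 10")
    rng = np.random.default_rng(seed)
    sites: list[SyncSite] = []
    for row in truth.genes.itertuples():
        length = (row.end - row.start) if gene_len is None else gene_len
        positions = rng.choice(length, size=min(sites_per_gene, length), replace=False)
        positions = np.sort(positions) + row.start
        for pos in positions:
            p = rng.uniform(0.05, 0.95)
            ref, alt = "A", "C"
            f_alt = rng.binomial(pool_depth, p)
            m_alt = rng.binomial(pool_depth, p)
            sites.append(
                SyncSite(
                    row.chrom,
                    int(pos),
                    ref,
                    (
                        _counts(ref, alt, pool_depth - f_alt, f_alt),
                        _counts(ref, alt, pool_depth - m_alt, m_alt),
                    ),
                )
            )
        if row.stratum in ("S0", "S1", "S2") and row.w_present:
            spec = truth.stratum_of(row.stratum)
            r = truth.cross_map(row.stratum, include_w)
            if r <= 0:
                continue
            phi = 0.5 * r / (0.5 + 0.5 * r)
            n_w = rng.poisson(spec.w_snp_density * length)
            if n_w == 0:
                continue
            wpos = np.sort(rng.choice(length, size=min(n_w, length), replace=False)) + row.start
            for pos in wpos:
                ref, alt = "G", "T"
                f_alt = rng.binomial(pool_depth, phi)
                sites.append(
                    SyncSite(
                        row.chrom,
                        int(pos),
                        ref,
                        (
                            _counts(ref, alt, pool_depth - f_alt, f_alt),
                            _counts(ref, alt, pool_depth, 0),
                        ),
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    truth: SimulatedTruth,
    tissues: Sequence[str] = ("head", "gonad"),
    replicates: int = 2,
    compensated: bool = True,
    seed: int = 0,
    base_mu: float = 3.0,
    base_sigma: float = 0.8,
    rep_sigma: float = 0.15,
    w_male_scale: float = 0.1,
    uncompensated_genes: str = "S0",
) -> dict[str, pd.DataFrame]:
    """TPM-like expression tables per tissue (columns tissue_sex_rep).

    ``compensated=True`` draws Z-differentiated genes from the autosomal
    expression distribution in both sexes (the dosage-compensated null);
    ``compensated=False`` halves female expression of the uncompensated
    stratum's genes (a log2 shift of -1). W transcripts (for genes with a
    surviving W copy) are female-limited: female expression mirrors the
    gene's base level, male expression is residual noise, so the >= 0.9
    female-specificity filter is exercisable.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates")
    rng = np.random.default_rng(seed)
    gene_ids = list(truth.genes["gene_id"])
    strata_of = dict(zip(truth.genes["gene_id"], truth.genes["stratum"]))
    w_ids = [f"W_{g}" for g, w in zip(truth.genes["gene_id"], truth.genes["w_present"]) if w]

    base = {g: float(rng.lognormal(base_mu, base_sigma)) for g in gene_ids}
    w_base = {w: float(rng.lognormal(base_mu, base_sigma)) for w in w_ids}

    out: dict[str, pd.DataFrame] = {}
    for tissue in tissues:
        cols = {}
        for sex in ("M", "F"):
            for rep in range(1, replicates + 1):
                vals = []
                for g in gene_ids:
                    mu = base[g]
                    if (
                        not compensated
                        and sex == "F"
                        and strata_of[g] == uncompensated_genes
                    ):
                        mu = mu * 0.5
                    vals.append(mu * float(rng.lognormal(0.0, rep_sigma)))
                for w in w_ids:
                    if sex == "F":
                        vals.append(w_base[w] * float(rng.lognormal(0.0, rep_sigma)))
                    else:
                        vals.append(float(rng.exponential(w_male_scale)))
                cols[f"{tissue}_{sex}_{rep}"] = vals
        out[tissue] = pd.DataFrame(cols, index=gene_ids + w_ids)
        out[tissue].index.name = "gene_id"
    truth.compensated = compensated
    return out
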