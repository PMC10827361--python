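# Methods

This note documents the models and estimators implemented in `zwstrata`,
the synthetic-data generator that exercises them, the numeric defaults,
and the design decisions taken where the design was genuinely open. No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## The biological setting

In a ZW system females are the heterogametic sex (ZW) and males are ZZ.
Once recombination between Z and W stops, the W degenerates in steps,
leaving *evolutionary strata*: contiguous Z regions whose W counterparts
stopped recombining at different times and therefore show characteristic
levels of Z–W divergence. Three observable signals date a region:

- **Coverage.** A female carries one Z dose where a male carries two.
  Where the W copy is lost, or too diverged for female reads to map to
  the Z, female Z coverage is halved (log2(F/M) ≈ −1). Mapping once with
  and once without W scaffolds in the reference separates regions whose W
  reads are merely *captured* by the W scaffolds from regions whose W is
  gone: an intermediate stratum shows a full drop only when the W
  scaffolds soak up its reads.
- **Pooled F_ST.** Variants fixed on the W are carried only by females.
  Wherever W reads still cross-map onto the Z, the female pool carries
  those alleles at intermediate frequency and per-gene F_ST between the
  sexed pools rises above the autosomal background.
- **dS.** Surviving W transcripts can be paired with their Z homologs and
  dated by synonymous divergence.

The joint signatures define the stratum classes used throughout:

| class  | cov (with W) | cov (no W) | F_ST with W | F_ST no W | dS |
|--------|--------------|------------|-------------|-----------|-----|
| S0     | full drop    | full drop  | quiet       | quiet     | high or no pair |
| S1     | full drop    | partial    | quiet       | elevated  | intermediate |
| S2     | none/slight  | none/slight| elevated    | elevated  | very low |
| undiff | none         | none       | quiet       | quiet     | — |

## Synthetic data generator

`zwstrata.synth` plants exactly this structure. Defaults (all
`RunConfig` keys): 3 autosomes + 1 Z of 3 Mb each, 10-kb windows (≥ 100
windows per stratum for stable medians), 300 evenly spaced single-exon
genes of 1,500 bp (500 codons), mean depth 30×, pool depth 50, two
replicates per tissue × sex. Strata sit contiguously on the Z in order
S2–S0–S1 at fractions 0.20–0.40–0.70–0.85 of its length, with

| stratum | W retention | target dS | W-SNP density /bp |
|---------|-------------|-----------|-------------------|
| S0      | 0.1         | 0.40      | 0.020 |
| S1      | 0.9         | 0.15      | 0.010 |
| S2      | 0.9         | 0.05      | 0.004 |

Choices and rationale:

- **W sequences** derive from Z coding sequences by uniform per-site
  substitution, re-scaled in a rejection loop until the NG86 dS of the
  pair is within ±10% of the stratum target (initialized at the inverse
  Jukes–Cantor rate). This makes dS recovery testable without a
  codon-model simulator; dN ≈ dS under uniform substitution, which is not
  how selection shapes real coding divergence but is irrelevant to every
  check performed here.
- **Cross-mapping fractions** r (the share of W-derived female reads that
  end up on the Z): without W scaffolds r = 0 / 0.5 / 0.9 for S0/S1/S2;
  with W scaffolds r = 0 / 0 / 0.7 — the W scaffolds capture S1's reads
  entirely, while the nearly identical S2 W still cross-maps, only
  somewhat less, so the F_ST elevation weakens on *both* flanks when W
  scaffolds are included yet remains elevated in S2. These fractions are
  free parameters of the simulation, not literature values.
- **Depth** is simulated directly per window (Poisson on the window's
  total base count) rather than via read mapping; expected female Z depth
  is mean_depth × (0.5 + 0.5 r), overlap-weighted across stratum
  boundaries inside a window. The two mapping-reference tracks use
  independent RNG streams.
- **Pooled counts (sync)**: every gene gets 10 background sites whose
  allele frequency (Uniform 0.05–0.95) is shared by both pools — the
  F_ST-null — and W-retaining stratum genes add Poisson(density × length)
  W-specific sites where the female pool carries the W allele at
  frequency 0.5 r/(0.5 + 0.5 r) and the male pool is fixed. The two
  tracks are again independent draws.
- **Expression**: per-gene base levels are log-normal (μ=3, σ=0.8 on the
  log scale, i.e. median ≈ 20 TPM), with log-normal replicate noise
  (σ=0.15). `compensated=True` draws Z genes from the same distribution
  as autosomes; `compensated=False` halves female expression of S0 genes
  (a planted log2 shift of −1). W transcripts are female-limited: female
  expression mirrors a base level, male expression is residual
  (Exponential, scale 0.1), so the ≥ 0.9 female-specificity filter is
  exercised with a realistic failure margin. Values are TPM-like but
  columns are not re-normalized to sum to 10⁶: quantile normalization
  downstream makes column rescaling a no-op, and re-normalizing would
  couple the planted shift into every other gene.

What the generator deliberately omits — and hence what passing tests do
not establish about real data: indels and structural variation, GC or
mappability bias, linked selection, expression-level covariation with
chromatin context, read-mapping artifacts beyond the single cross-mapping
fraction per stratum, and any within-stratum heterogeneity in divergence.

## Estimators

**K-mer classification.** Canonical k-mers (lexicographic minimum of a
k-mer and its reverse complement, 2-bit encoded; k odd so no k-mer is its
own reverse complement). A read's mkf is the fraction of its N-free
k-mers found in the female-minus-male set; label W iff mkf ≥ 0.2
(inclusive). When building sets from reads, a k-mer needs ≥ min_count
occurrences (default 2, suppressing singleton sequencing errors); sets
built from assembled sequence use min_count 1.

**Coverage.** Window value = mean per-base depth (trailing partial
windows use their true size). Optional per-sex rescaling by the autosomal
median depth (default on) makes the log2 baseline 0 regardless of library
sizes. log2(F/M) is missing where either depth is below the floor (no
pseudocount). Rolling medians are centered; positions whose window would
cross either end are missing, missing inputs are excluded, and a result
is missing when fewer than span/2 inputs remain. The detection threshold
is autosomal median − `drop_delta` (default 0.5); an absolute threshold
is available by config. Detection runs on the smoothed series by default
and reports maximal runs of windows strictly below the threshold, in both
0-based half-open and 1-based inclusive coordinates. Nearby regions are
not merged by default (`merge_max_gap` 0).

**Pooled F_ST.** Classical pooled estimator: per biallelic site,
π_k = 2 p_k (1 − p_k) · C_k/(C_k − 1), π_within = mean of the two pools,
π_total = 2 p̄ (1 − p̄) · C_min/(C_min − 1) with p̄ the mean frequency, and
F_ST = (π_total − π_within)/π_total. Sites pass when both pools are
within coverage bounds (10–500 by default), and exactly two alleles
remain after masking alleles with combined count < 2 — these site filters
are this package's defaults, stated here because upstream tools do not
print theirs. Per gene the statistic is a ratio of sums over passing
exonic sites (sites in overlapping genes count for each); a gene with no
passing polymorphic site is missing. Frequencies from pooled RNA are
expression-weighted; the estimator treats DNA and RNA counts alike. The
autosomal band is the empirical 5th–95th percentile (linear
interpolation) of autosomal gene values.

**Homology and dS.** W transcripts are kept when female/(male+female)
summed head+gonad expression ≥ 0.9. Candidate pairs share exact 11-mers
(both strands; pairs sharing fewer than `min_seed_hits` seeds are not
aligned — default 1, pipeline 6, since true homologs share tens of seeds
while codon-structured transcripts share a few by chance), scored by
affine local alignment (match +2, mismatch −3, gap open −5, extend −2,
Biopython gap semantics), and reciprocal best hits are kept (ties broken
by lower partner id; both directions derive from one pass of pair scores,
which is exact because the local score is symmetric). Pairs are
codon-aligned via global protein alignment (BLOSUM62, gap open −15,
extend −2 — stiff gaps, because cheap gap pairs at high divergence shift
the codon correspondence between them and inflate dS); codon columns with
a gap, an N, or a stop in either sequence are removed, and alignments
shorter than 300 nt after column filtering are excluded (the stricter
post-filter reading). NG86 counting: synonymous sites per codon =
Σ_positions (#synonymous one-step changes)/3 with a fixed denominator of
3 (so S + N = 3 × codons and changes to stops count as nonsynonymous site
mass), averaged between the two sequences; multi-position codon
differences are averaged over all minimal mutational pathways excluding
those through stop codons (if every ordering is blocked, the exclusion is
waived for that pair); dS = −(3/4) ln(1 − (4/3) pS), undefined (missing)
when pS ≥ 3/4. Codons containing ambiguity symbols are dropped before
counting.

**Strata calls.** All cut-offs live in `StrataThresholds`: full drop
log2 ≤ −0.75, partial (−0.75, −0.25], slight (−0.25, −0.1], F_ST elevated
above the autosomal 95th percentile, dS high ≥ `ds_split` (default: the
median dS over all Z–W pairs). These numbers are this package's
operationalization of verbal class definitions and are echoed in every
report header. dS is a soft criterion — a missing value never blocks a
call, since S0 genes typically have no surviving W homolog. The "slight"
class exists because a young stratum whose W reads partially cross-map
shows a small but real female coverage deficit that truly
undifferentiated sequence never shows; `undiff` demands no deficit at
all, while S2 tolerates a slight one.

Per-gene evidence construction (the noise-control layer):

- coverage evidence is the smoothed log2 track at the gene midpoint
  (a rolling *median* of a step profile switches at the boundary, so
  boundary contamination is ≤ 1 gene);
- F_ST evidence is max(own gene value, 3-gene rolling median) for
  *elevation* checks — the median lets a gene whose W copy is lost borrow
  its neighbourhood's signal, the raw value keeps genes independent of
  how many neighbours lost theirs — and the 3-gene median alone for
  *absence-of-elevation* checks, so one gene's sampling noise cannot veto
  a call its whole region supports;
- calls are then smoothed by an iterated majority vote in a 5-gene
  window in which `ambiguous` abstains and conversion needs a strict
  majority of ≥ 2 voters; isolated stratum runs shorter than 3 genes are
  demoted (a stratum is by definition a multi-gene region; short runs
  bordering another stratum run are kept);
- genes still ambiguous whose coverage signature is produced by exactly
  one class (full/full → S0, full/partial → S1) are assigned by coverage
  alone, and a boundary-tied ambiguous gene joins the flanking class its
  coverage signature is compatible with.

Each element addresses a specific failure mode of naive per-gene rules at
stratum boundaries and at genes whose W copy was lost; the end-to-end
recovery rates are measured by the acceptance checks, not asserted here.

**Dosage.** Quantile normalization per tissue (sorted values replaced by
cross-sample rank means; ties get their block mean, so tied inputs stay
tied), computed over annotated genes only — sex-limited W transcripts
violate the equal-distribution assumption and must not enter the
normalization reference. Genes are kept at a TPM cutoff (0, 0.5, 1;
"above" read as ≥) when their replicate mean passes in *both* sexes of
the tissue. Rank-sum tests compare log2 mean TPM of Z-differentiated
versus autosomal genes per tissue and sex: exact two-sided p by full
enumeration of group assignments (midrank ties) when min(n) < 8,
otherwise the tie-corrected normal approximation with continuity
correction. log2(F/M) panels use no pseudocount; genes with a zero mean
in a needed sex are excluded with counts reported.

## Numerical and interface conventions

Internal coordinates are 0-based half-open everywhere; 1-based inclusive
appears only at report boundaries. Sync N/del counts are parsed and
dropped. Missing values are NaN throughout. All generators are
deterministic given a seed; the pipeline derives an independent stream
per stage from the run seed. Percentiles use numpy's linear
interpolation; even-length medians use the mean-of-middle convention.

## Problem sizes

The default simulation (3 Mb chromosomes, 300 genes, 500-codon genes,
5,000 long reads, 50× pools) gives ≥ 100 windows per stratum and ≈ 11–15
genes per stratum — enough for stable medians and meaningful recovery
rates while a full pipeline run takes a few seconds. The acceptance
checks use 20 replicate pipeline runs and 100 expression replicates.

## Known limitations

- S2 genes whose W copy is lost carry no F_ST signal of their own; when
  two such genes are adjacent at a stratum edge, no honest evidence
  rescues them and the per-stratum recovery dips (the acceptance rates
  quantify how often).
- The ds_split default (median over all pairs) sits close to the S2 level
  when young-stratum pairs dominate the pair set; isolated S2 genes
  crossing it are absorbed by the call vote.
- F_ST from pooled RNA weights alleles by expression; the estimator
  inherits that property silently.
- The replicated SAM-tag uniqueness filter used upstream of real depth
  tables (unique-alignment filtering) is out of scope; the pipeline
  consumes depth tables as given.
- Seed-and-extend homolog search and automated alignment-block filtering
  are performed by the internal seeded aligner and the simple
  codon-column filter described above, not by external tools; scoring
  constants are package choices.
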