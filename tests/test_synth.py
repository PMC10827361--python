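import numpy as np
import pandas as pd
import pytest

from zwstrata import synth
from zwstrata.homology import ng_dnds
from zwstrata.io_core import GenomeCoords
from zwstrata.kmers import build_kmer_set, female_specific


def small_strata(chrom_len=100_000, retention=(0.1, 0.9, 0.9), ds=(0.4, 0.15, 0.05)):
    e = [int(chrom_len * f) for f in (0.2, 0.4, 0.7, 0.85)]
    names = ["S2", "S0", "S1"]
    rets = {"S0": retention[0], "S1": retention[1], "S2": retention[2]}
    dss = {"S0": ds[0], "S1": ds[1], "S2": ds[2]}
    dens = {"S0": 0.02, "S1": 0.01, "S2": 0.004}
    return [
        synth.StratumSpec(n, GenomeCoords("Z", lo, hi), rets[n], dss[n], dens[n])
        for n, lo, hi in zip(names, e[:-1], e[1:])
    ]


def small_genome(seed=0, **kw):
    return synth.simulate_genome(
        n_autosomes=1,
        chrom_len=100_000,
        strata=kw.pop("strata", small_strata()),
        n_genes=kw.pop("n_genes", 40),
        seed=seed,
        gene_len=kw.pop("gene_len", 300),
        window_size=1_000,
        **kw,
    )


class TestSimulateGenome:
    def test_deterministic_for_fixed_seed(self):
        a = small_genome(seed=7)
        b = small_genome(seed=7)
        assert a[0] == b[0] and a[1] == b[1]
        pd.testing.assert_frame_equal(a[3].genes, b[3].genes)

    def test_zero_retention_means_no_w_copies(self):
        strata = small_strata(retention=(0.0, 0.0, 0.0))
        _, w_records, _, truth = small_genome(strata=strata)
        assert w_records == []
        assert not truth.genes["w_present"].any()

    def test_zero_target_ds_gives_identical_w(self):
        strata = small_strata(ds=(0.4, 0.15, 0.0), retention=(0.0, 0.0, 1.0))
        genome, w_records, genes, truth = small_genome(strata=strata)
        seqs = dict(synth.extract_transcripts(genome, genes))
        s2 = truth.genes[(truth.genes["stratum"] == "S2") & truth.genes["w_present"]]
        assert len(w_records) == len(s2) > 0
        for wid, wseq in w_records:
            assert wseq == seqs[wid[2:]]

    def test_overlapping_strata_rejected(self):
        bad = small_strata()
        bad[1] = synth.StratumSpec(
            "S0", GenomeCoords("Z", 10_000, 50_000), 0.1, 0.4, 0.02
        )
        with pytest.raises(ValueError, match="overlap"):
            small_genome(strata=bad)

    def test_w_divergence_calibrated_to_target(self):
        strata = small_strata(retention=(1.0, 1.0, 1.0))
        genome, w_records, genes, truth = small_genome(strata=strata, gene_len=900)
        seqs = dict(synth.extract_transcripts(genome, genes))
        targets = {s.name: s.target_dS for s in strata}
        strat_of = dict(zip(truth.genes["gene_id"], truth.genes["stratum"]))
        for wid, wseq in w_records:
            gid = wid[2:]
            ds = ng_dnds(seqs[gid], wseq).dS
            assert ds == pytest.approx(targets[strat_of[gid]], rel=0.25)


class TestSimulateDepth:
    def test_autosomal_mean_recovered(self):
        _, _, _, truth = small_genome()
        df = synth.simulate_depth(truth, "male", 30.0, seed=1, window_size=1_000)
        auto = df[df["chrom"] == "A1"]["depth"]
        se = np.sqrt(30.0 / 1_000) / np.sqrt(len(auto))
        assert abs(auto.mean() - 30.0) < 3 * se * np.sqrt(len(auto))

    def test_s0_female_dose_is_half(self):
        _, _, _, truth = small_genome()
        df = synth.simulate_depth(truth, "female", 30.0, include_w=True, seed=2,
                                  window_size=1_000)
        s0 = next(s for s in truth.strata if s.name == "S0").z_interval
        z = df[df["chrom"] == "Z"]
        inside = z[(z["start"] >= s0.start) & (z["start"] < s0.end - 1_000)]
        assert inside["depth"].mean() == pytest.approx(15.0, rel=0.05)

    def test_male_z_keeps_full_dose(self):
        _, _, _, truth = small_genome()
        df = synth.simulate_depth(truth, "male", 30.0, seed=3, window_size=1_000)
        z = df[df["chrom"] == "Z"]["depth"]
        assert z.mean() == pytest.approx(30.0, rel=0.05)

    def test_unknown_sex_rejected(self):
        _, _, _, truth = small_genome()
        with pytest.raises(ValueError, match="sex"):
            synth.simulate_depth(truth, "hermaphrodite", 30.0)


class TestSimulateLongReads:
    def test_error_free_w_reads_have_only_female_specific_kmers(self):
        genome, w_records, _, _ = small_genome(
            strata=small_strata(retention=(1.0, 1.0, 1.0), ds=(0.4, 0.3, 0.3))
        )
        male_set = build_kmer_set([s for _, s in genome], k=21)
        female_set = build_kmer_set(
            [s for _, s in genome] + [s for _, s in w_records], k=21
        )
        fs = female_specific(female_set, male_set)
        reads, truth = synth.simulate_long_reads(
            w_records, n_reads=20, read_len=150, per_base_error=0.0, seed=4
        )
        from zwstrata.kmers import classify_read

        for _, seq, _ in reads:
            cls = classify_read(seq, fs, 0.2)
            # W sequences at >= 30% divergence: nearly all k-mers W-specific
            assert cls.fraction > 0.9

    def test_empty_and_oversized_requests(self):
        genome, _, _, _ = small_genome()
        reads, truth = synth.simulate_long_reads(genome, 0, read_len=100, seed=0)
        assert reads == [] and len(truth) == 0
        with pytest.raises(ValueError, match="read_len"):
            synth.simulate_long_reads([("x", "ACGT" * 10)], 5, read_len=100, seed=0)

    def test_deterministic(self):
        genome, _, _, _ = small_genome()
        a, _ = synth.simulate_long_reads(genome, 50, 200, 0.01, seed=9)
        b, _ = synth.simulate_long_reads(genome, 50, 200, 0.01, seed=9)
        assert a == b


class TestSimulateSync:
    def test_deterministic(self):
        _, _, _, truth = small_genome()
        a = synth.simulate_sync(truth, seed=5)
        b = synth.simulate_sync(truth, seed=5)
        assert a == b

    def test_hemizygous_female_site_shape(self):
        # a fully divergent W site: female pool half W-allele, male fixed
        _, _, _, truth = small_genome(
            strata=small_strata(retention=(0.0, 0.0, 1.0))
        )
        # without W scaffolds S2 cross-maps at r=0.9 -> phi = 0.45/0.95
        sites = synth.simulate_sync(
            truth, sites_per_gene=0, pool_depth=400, include_w=False, seed=6
        )
        assert sites, "expected planted W-specific sites"
        phis = []
        for s in sites:
            female, male = s.pools
            assert sum(male) == 400 and male[3] == 400  # fixed reference G
            phis.append(female[1] / 400)  # T = W allele
        assert np.mean(phis) == pytest.approx(0.45 / 0.95, abs=0.03)

    def test_null_densities_make_z_indistinguishable(self):
        from scipy.stats import ranksums

        from zwstrata.fst import genewise_fst

        genome, _, genes, truth = synth.simulate_genome(
            n_autosomes=1, chrom_len=200_000, strata=small_strata(200_000),
            n_genes=400, seed=3, gene_len=300, window_size=2_000,
        )
        for s in truth.strata:
            s.w_snp_density = 0.0
        sites = synth.simulate_sync(truth, sites_per_gene=8, pool_depth=50, seed=11)
        table = genewise_fst(genes, sites)
        z = table[table["chrom"] == "Z"]["fst"].dropna()
        a = table[table["chrom"] == "A1"]["fst"].dropna()
        assert ranksums(z, a).pvalue > 0.05


class TestSimulateExpression:
    def test_uncompensated_plants_minus_one_shift(self):
        _, _, _, truth = small_genome(n_genes=300)
        expr = synth.simulate_expression(truth, compensated=False, seed=12)
        mat = expr["head"]
        s0 = truth.genes[truth.genes["stratum"] == "S0"]["gene_id"]
        f = mat.loc[s0, ["head_F_1", "head_F_2"]].mean(axis=1)
        m = mat.loc[s0, ["head_M_1", "head_M_2"]].mean(axis=1)
        assert np.median(np.log2(f / m)) == pytest.approx(-1.0, abs=0.2)

    def test_w_transcripts_are_female_specific(self):
        _, _, _, truth = small_genome(
            n_genes=300, strata=small_strata(retention=(0.9, 0.9, 0.9))
        )
        expr = synth.simulate_expression(truth, seed=13)
        w_ids = [g for g in expr["head"].index if g.startswith("W_")]
        assert len(w_ids) >= 20
        ok = 0
        for w in w_ids:
            f = sum(expr[t].loc[w, [f"{t}_F_1", f"{t}_F_2"]].mean() for t in expr)
            m = sum(expr[t].loc[w, [f"{t}_M_1", f"{t}_M_2"]].mean() for t in expr)
            ok += f / (f + m) >= 0.9
        assert ok / len(w_ids) >= 0.95

    def test_replicate_floor(self):
        _, _, _, truth = small_genome()
        with pytest.raises(ValueError):
            synth.simulate_expression(truth, replicates=1)
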