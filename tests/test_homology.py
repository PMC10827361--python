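import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ng_oracle
from zwstrata.homology import (
    HomologPair,
    SpecificityRecord,
    best_hits,
    codon_align,
    length_filter,
    ng_dnds,
    rbh_pairs,
    reciprocal_best,
    specificity_filter,
)

_NONSTOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_cds(rng, n_codons):
    return "".join(rng.choice(_NONSTOP, n_codons))


def mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


class TestNgDnds:
    def test_worked_example(self):
        e = ng_dnds("TTTAAAGGGCCC", "TTCAAAGGGCCC")
        assert e.S == pytest.approx(8 / 3, abs=1e-12)
        assert e.N == pytest.approx(28 / 3, abs=1e-12)
        assert (e.Sd, e.Nd) == (1.0, 0.0)
        assert e.pS == pytest.approx(0.375)
        assert e.dS == pytest.approx(-0.75 * math.log(0.5), abs=1e-12)
        assert e.dN == 0.0

    def test_identical_sequences(self):
        e = ng_dnds("ATGACC", "ATGACC")
        assert (e.Sd, e.Nd, e.dS, e.dN) == (0.0, 0.0, 0.0, 0.0)

    def test_saturation_reported_missing(self):
        # every third position differs synonymously everywhere it can:
        # force pS >= 3/4 with highly divergent 4-fold codons
        a = "GGT" * 40
        b = "GGA" * 40  # all synonymous differences: pS = 40 / (40 * 1 ... )
        e = ng_dnds(a, b)
        # Sd = 40, S = 40 * (4-fold site + others) -> pS near 1
        assert e.pS >= 0.75
        assert math.isnan(e.dS)

    def test_input_contract(self):
        with pytest.raises(ValueError):
            ng_dnds("ACGT", "ACGT")
        with pytest.raises(ValueError):
            ng_dnds("", "")

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = random_cds(rng, 30)
        b = mutate(rng, a, 0.1)
        ea, eb = ng_dnds(a, b), ng_dnds(b, a)
        for f in ("S", "N", "Sd", "Nd"):
            assert getattr(ea, f) == pytest.approx(getattr(eb, f), abs=1e-12)

    def test_matches_pathway_enumeration_oracle(self, rng):
        # deeper sweep (1,000 random 100-codon pairs) runs in the
        # acceptance suite; this is a quick regression at 100 pairs
        for _ in range(100):
            a = random_cds(rng, 50)
            b = mutate(rng, a, rng.uniform(0.01, 0.3))
            got = ng_dnds(a, b)
            S, N, Sd, Nd, dS, dN = ng_oracle(a, b)
            assert got.S == pytest.approx(S, abs=1e-9)
            assert got.Sd == pytest.approx(Sd, abs=1e-9)
            assert got.Nd == pytest.approx(Nd, abs=1e-9)
            if math.isnan(dS):
                assert math.isnan(got.dS)
            else:
                assert got.dS == pytest.approx(dS, abs=1e-9)


class TestCodonAlign:
    def test_identical_sequences_full_length(self, rng):
        cds = random_cds(rng, 100)
        a, b = codon_align(cds, cds)
        assert a == b == cds

    def test_insertion_column_removed(self, rng):
        cds = random_cds(rng, 60)
        with_ins = cds[:90] + "GCT" + cds[90:]
        a, b = codon_align(with_ins, cds)
        assert len(a) == len(b) == len(cds)
        assert b == cds

    def test_n_containing_column_removed(self, rng):
        cds = random_cds(rng, 40)
        with_n = cds[:30] + "NNN" + cds[33:]
        a, b = codon_align(with_n, cds)
        assert len(a) == len(cds) - 3
        assert "N" not in a

    def test_empty_translation_rejected(self):
        with pytest.raises(ValueError):
            codon_align("AC", "ATGGCT")


class TestBestHits:
    def test_self_match_scores_two_per_base(self, rng):
        t = random_cds(rng, 40)
        hits = best_hits([("q", t)], [("t1", t), ("t2", random_cds(rng, 40))])
        assert hits["q"][0].target_id == "t1"
        assert hits["q"][0].score == 2 * len(t)

    def test_no_shared_seed_no_hits(self):
        hits = best_hits([("q", "A" * 30)], [("t", "C" * 30)])
        assert hits["q"] == []

    def test_reverse_complement_hit_flagged(self, rng):
        t = random_cds(rng, 40)
        rc = t.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        hits = best_hits([("q", rc)], [("t", t)])
        assert hits["q"][0].strand == "-"
        assert hits["q"][0].score == 2 * len(t)

    def test_empty_query_set(self):
        assert best_hits([], [("t", "ACGTACGTACGTACG")]) == {}


class TestReciprocalBest:
    def test_unique_matches_pair_up(self, rng):
        targets = [(f"t{i}", random_cds(rng, 40)) for i in range(3)]
        queries = [(f"q{i}", seq) for i, (_, seq) in enumerate(targets)]
        fwd = best_hits(queries, targets)
        rev = best_hits(targets, queries)
        pairs = reciprocal_best(fwd, rev)
        assert {(p.w_id, p.z_id) for p in pairs} == {("q0", "t0"), ("q1", "t1"), ("q2", "t2")}

    def test_non_reciprocal_excluded(self):
        from zwstrata.homology import Hit

        fwd = {"w": [Hit("w", "z", 100, "+")]}
        rev = {"z": [Hit("z", "w2", 100, "+")]}
        assert reciprocal_best(fwd, rev) == []

    def test_empty_sides(self):
        assert reciprocal_best({}, {}) == []

    def test_rbh_pairs_agrees_with_two_pass(self, rng):
        targets = [(f"t{i}", random_cds(rng, 50)) for i in range(6)]
        queries = [(f"q{i}", mutate(rng, seq, 0.05)) for i, (_, seq) in enumerate(targets[:4])]
        fwd = best_hits(queries, targets)
        rev = best_hits(targets, queries)
        expect = {(p.w_id, p.z_id) for p in reciprocal_best(fwd, rev)}
        got = {(p.w_id, p.z_id) for p in rbh_pairs(queries, targets)}
        assert got == expect


class TestSpecificityFilter:
    def test_boundary_inclusive(self):
        r = SpecificityRecord("t", 5, 4, 1, 0)  # 9/10 exactly
        assert specificity_filter([r], 0.9) == ["t"]

    def test_male_only_dropped(self):
        assert specificity_filter([SpecificityRecord("t", 0, 0, 3, 2)], 0.9) == []

    def test_zero_denominator_dropped(self):
        assert specificity_filter([SpecificityRecord("t", 0, 0, 0, 0)], 0.9) == []

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError):
            specificity_filter([SpecificityRecord("t", -1, 0, 0, 0)])


class TestLengthFilter:
    @pytest.mark.parametrize("length,kept", [(299, False), (300, True), (0, False)])
    def test_boundary(self, length, kept):
        p = HomologPair("w", "z", 10.0, aligned_len_nt=length)
        assert (length_filter([p]) == [p]) is kept
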