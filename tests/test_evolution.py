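import math
import random
from itertools import product

import pytest

from nbskit.evolution import (
    CODON_TABLE,
    STOP_CODONS,
    AlignmentError,
    family_evolution,
    jc_distance,
    jukes_cantor,
    ng86_pair,
    ng86_sites,
)
from oracles import ng86_oracle, syn_sites_oracle

SENSE_CODONS = sorted(CODON_TABLE)


def random_cds(rng, n_codons):
    out = []
    while len(out) < n_codons:
        c = rng.choice(SENSE_CODONS)
        out.append(c)
    return "".join(out)


def mutate_no_stop(rng, cds, n_subs):
    s = list(cds)
    done = 0
    while done < n_subs:
        pos = rng.randrange(len(s))
        new = rng.choice([b for b in "ACGT" if b != s[pos]])
        c0 = pos - pos % 3
        codon = "".join(s[c0 : c0 + 3])
        mutant = codon[: pos - c0] + new + codon[pos - c0 + 1 :]
        if mutant in STOP_CODONS:
            continue
        s[pos] = new
        done += 1
    return "".join(s)


class TestJukesCantor:
    def test_identical(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == (0.0, 0.0)

    def test_closed_form_at_p_005(self):
        # 1 difference in 20 sites -> p = 0.05
        a = "A" * 20
        b = "C" + "A" * 19
        p, d = jc_distance(a, b)
        assert p == pytest.approx(0.05)
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * 0.05 / 3), abs=1e-12)
        assert d == pytest.approx(0.0517447, abs=1e-6)

    def test_saturation_is_na(self):
        a = "AAAA"
        b = "CCCA"  # p = 0.75
        p, d = jc_distance(a, b)
        assert p == 0.75 and d is None

    def test_gap_and_ambiguity_columns_excluded(self):
        p, d = jc_distance("AC-GN", "ACTGA")
        assert p == 0.0  # only A, C and G columns compared

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(AlignmentError):
            jc_distance("---", "AAA")

    def test_monotone_in_p(self):
        grid = [i / 100 for i in range(0, 75)]
        vals = [jukes_cantor(p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestSites:
    @pytest.mark.parametrize(
        "codon,expected",
        [("GCT", 1.0), ("TTT", 1 / 3), ("TGG", 0.0)],
    )
    def test_reference_codons(self, codon, expected):
        s, n = ng86_sites(codon)
        assert s == pytest.approx(expected, abs=1e-12)
        assert s + n == pytest.approx(3.0)

    def test_all_sense_codons_match_enumeration_oracle(self):
        for codon in SENSE_CODONS:
            s, n = ng86_sites(codon)
            assert s == pytest.approx(syn_sites_oracle(codon), abs=1e-12), codon
            assert 0.0 <= s <= 3.0
            assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")


class TestPairwise:
    def test_identical_pair(self):
        cds = "ATGGCTGCTAAA"
        pe = ng86_pair(cds, cds)
        assert pe.dN == 0.0 and pe.dS == 0.0
        assert pe.ka_ks is None  # dS = 0 -> undefined ratio

    def test_synonymous_only_changes_give_zero_ratio(self):
        rng = random.Random(0)
        a = random_cds(rng, 100)
        b = list(a)
        changed = 0
        for i in range(0, len(a), 3):
            codon = a[i : i + 3]
            syns = [
                c for c in SENSE_CODONS
                if CODON_TABLE[c] == CODON_TABLE[codon]
                and sum(x != y for x, y in zip(c, codon)) == 1
            ]
            if syns and changed < 8:  # < 10% of sites
                b[i : i + 3] = syns[0]
                changed += 1
        pe = ng86_pair(a, "".join(b))
        assert pe.dN == 0.0
        assert pe.dS > 0.0
        assert pe.ka_ks == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_pathway_oracle(self, seed):
        rng = random.Random(seed)
        a = random_cds(rng, 300)
        b = mutate_no_stop(rng, a, 80)
        pe = ng86_pair(a, b)
        S, N, Sd, Nd, dS, dN, ratio = ng86_oracle(a, b)
        assert pe.S == pytest.approx(S, abs=1e-12)
        assert pe.N == pytest.approx(N, abs=1e-12)
        assert pe.Sd == pytest.approx(Sd, abs=1e-12)
        assert pe.Nd == pytest.approx(Nd, abs=1e-12)
        assert pe.dS == pytest.approx(dS, abs=1e-12)
        assert pe.dN == pytest.approx(dN, abs=1e-12)
        assert pe.ka_ks == pytest.approx(ratio, abs=1e-12)

    def test_symmetry(self):
        rng = random.Random(9)
        a = random_cds(rng, 120)
        b = mutate_no_stop(rng, a, 40)
        pab, pba = ng86_pair(a, b), ng86_pair(b, a)
        assert pab.S == pytest.approx(pba.S)
        assert pab.Sd == pytest.approx(pba.Sd)
        assert pab.ka_ks == pytest.approx(pba.ka_ks)

    def test_codons_with_gaps_or_stops_skipped(self):
        a = "ATG" + "TAA" + "GC-" + "GCT"
        b = "ATG" + "GCT" + "GCT" + "GCA"
        pe = ng86_pair(a, b)
        assert pe.n_codons == 2  # stop pair and gapped pair skipped

    def test_length_mismatch_is_error(self):
        with pytest.raises(AlignmentError):
            ng86_pair("ATGGCT", "ATG")


class TestFamilyEvolution:
    def test_identical_members_have_zero_divergence(self):
        cds = "ATGGCTAAAGCT" * 10
        fe = family_evolution("f", ["a", "b", "c"], {k: cds for k in "abc"})
        assert fe.avg_divergence == 0.0
        assert fe.avg_ka_ks is None  # all ratios undefined at dS = 0
        assert fe.n_pairs == 3
        assert fe.n_na_ka_ks == 3

    def test_pair_count_is_n_choose_2(self):
        rng = random.Random(4)
        base = random_cds(rng, 60)
        aln = {f"m{i}": mutate_no_stop(rng, base, 10) for i in range(5)}
        fe = family_evolution("f", list(aln), aln)
        assert fe.n_pairs == 10

    def test_small_family_refused(self):
        with pytest.raises(ValueError, match="members"):
            family_evolution("f", ["a", "b"], {"a": "ATG", "b": "ATG"})

    def test_missing_member_is_error(self):
        with pytest.raises(KeyError):
            family_evolution("f", ["a", "b", "c"], {"a": "ATG", "b": "ATG"})
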