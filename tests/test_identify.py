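import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbskit.genome_io import DomainHit, GeneModel
from nbskit.identify import (
    COILS_GAUSSIANS,
    COILS_MTK_PROPENSITIES,
    COILS_RATIO_G_CC,
    CoilsProfile,
    NBSGene,
    assign_class_subtype,
    coils_probability,
    coils_score,
    deduplicate_by_locus,
    exon_stats,
    select_candidates,
)
from oracles import coils_prob_oracle


def hit(gene, domain, e, lo=1, hi=100):
    return DomainHit(gene, domain, e, lo, hi)


class TestSelectCandidates:
    def test_evalue_cutoff_is_inclusive(self):
        hits = [
            hit("keep", "NB-ARC", 1e-5),
            hit("edge", "NB-ARC", 1e-4),
            hit("drop", "NB-ARC", 1e-3),
            hit("tir_only", "TIR", 1e-30),
        ]
        assert select_candidates(hits) == {"keep", "edge"}

    def test_empty_result_allowed(self):
        assert select_candidates([hit("g", "NB-ARC", 1.0)]) == set()


def gene(gid, start, end, cds_len, scaffold="s1"):
    return GeneModel(gid, "sp", scaffold, start, end, "+", cds="A" * cds_len)


class TestDeduplicate:
    def test_high_overlap_keeps_longest_cds(self):
        a = gene("a", 0, 1000, 600)
        b = gene("b", 100, 1000, 900)  # 90% of the shorter interval overlaps
        assert deduplicate_by_locus([a, b]) == [b]

    def test_low_overlap_keeps_both(self):
        a = gene("a", 0, 1000, 600)
        b = gene("b", 900, 2000, 600)  # 10% overlap of shorter
        assert deduplicate_by_locus([a, b]) == [a, b]

    def test_identical_triplicates_collapse_to_one(self):
        gs = [gene(f"g{i}", 0, 500, 300) for i in range(3)]
        assert deduplicate_by_locus(gs) == [gs[0]]  # lexicographic tie-break

    def test_different_scaffolds_never_merge(self):
        a = gene("a", 0, 1000, 600, "s1")
        b = gene("b", 0, 1000, 600, "s2")
        assert deduplicate_by_locus([a, b]) == [a, b]

    @given(st.lists(
        st.tuples(st.integers(0, 5000), st.integers(50, 800), st.integers(60, 900)),
        min_size=1, max_size=12,
    ))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_and_idempotent(self, spec):
        genes = [
            gene(f"g{i:02d}", s, s + ln, cl) for i, (s, ln, cl) in enumerate(spec)
        ]
        survivors = deduplicate_by_locus(genes)
        # idempotence
        assert deduplicate_by_locus(survivors) == survivors
        # no two survivors overlap by >50% of the shorter interval
        for i, a in enumerate(survivors):
            for b in survivors[i + 1 :]:
                ov = min(a.end, b.end) - max(a.start, b.start)
                assert ov <= 0.5 * min(a.length, b.length)
        # brute-force transitive closure gives the same cluster count
        parent = list(range(len(genes)))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i, a in enumerate(genes):
            for j, b in enumerate(genes):
                if i < j:
                    ov = min(a.end, b.end) - max(a.start, b.start)
                    if ov > 0.5 * min(a.length, b.length):
                        parent[find(j)] = find(i)
        assert len({find(i) for i in range(len(genes))}) == len(survivors)


class TestCoils:
    def test_poly_glycine_is_not_coiled_coil(self):
        prof = coils_score("G" * 100)
        assert prof.max_prob_first200 < 0.9
        assert not prof.has_cc()

    def test_leucine_zipper_is_coiled_coil(self):
        prof = coils_score("LEALEGK" * 5)
        assert prof.has_cc()
        assert prof.max_prob_first200 > 0.99

    def test_short_protein_gets_zero_profile(self):
        prof = coils_score("MKLLEA" * 3 + "QQ")  # length 20 < window 28
        assert prof.max_prob_first200 == 0.0
        assert np.all(prof.probabilities == 0.0)

    def test_cc_must_lie_in_first_200_residues(self):
        tail_cc = "G" * 250 + "LEALEGK" * 8
        prof = coils_score(tail_cc)
        assert not prof.has_cc()
        assert prof.probabilities[260:].max() > 0.9  # signal exists, just late

    def test_probability_monotone_in_raw_score(self):
        scores = np.linspace(0.0, 3.0, 60)
        probs = [coils_probability(s) for s in scores]
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_naive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        prot = "".join(aas[i] for i in rng.integers(0, 20, size=60))
        prot = prot[:15] + "LEALEGK" * 4 + prot[15:]
        expected = coils_prob_oracle(
            prot, COILS_MTK_PROPENSITIES, COILS_GAUSSIANS, COILS_RATIO_G_CC
        )
        got = coils_score(prot).probabilities
        assert np.allclose(got, expected, atol=1e-9)


def _profile(p):
    return CoilsProfile(np.array([p]), p)


class TestClassSubtype:
    CAND = GeneModel("c1", "sp", "s1", 0, 900, "+", cds="ATG" * 300,
                     exons=[(0, 900)])

    def _classify(self, domains, cc_prob, ctx=None):
        hits = [hit("c1", d, 1e-20) for d in domains]
        return assign_class_subtype(self.CAND, hits, _profile(cc_prob), ctx)

    def test_tir_with_lrr_is_tnl(self):
        g = self._classify(["NB-ARC", "TIR", "LRR"], 0.0)
        assert (g.klass, g.subtype) == ("TIR", "TNL")

    def test_cc_without_lrr_is_cn(self):
        g = self._classify(["NB-ARC"], 0.95)
        assert (g.klass, g.subtype) == ("nonTIR", "CN")

    def test_x_gene_takes_class_from_tree_context(self):
        g = self._classify(["NB-ARC", "LRR"], 0.0, ctx={"c1": "TIR"})
        assert (g.klass, g.subtype) == ("TIR", "XNL")
        assert "unresolved_class" not in g.flags

    def test_x_gene_without_context_flagged_nontir(self):
        g = self._classify(["NB-ARC", "LRR"], 0.0)
        assert g.klass == "nonTIR"
        assert "unresolved_class" in g.flags

    def test_no_nbarc_hit_is_an_error(self):
        with pytest.raises(ValueError, match="NB-ARC"):
            self._classify(["TIR"], 0.0)

    def test_subtype_flag_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            NBSGene(
                gene=self.CAND, nbarc_span=(1, 100), has_tir=True, has_lrr=True,
                has_cc=False, klass="TIR", subtype="TN", exon_count=1,
            )


class TestExonStats:
    def _nbs(self, klass, exons):
        has_tir = klass == "TIR"
        return NBSGene(
            gene=self.__class__.CAND, nbarc_span=(1, 100), has_tir=has_tir,
            has_lrr=False, has_cc=False, klass=klass,
            subtype="TN" if has_tir else "XN", exon_count=exons,
        )

    CAND = GeneModel("e1", "sp", "s1", 0, 900, "+")

    def test_mean_by_class(self):
        genes = [self._nbs("TIR", 5), self._nbs("TIR", 7), self._nbs("nonTIR", 2)]
        stats = exon_stats(genes)
        assert stats["TIR"] == pytest.approx(6.0)
        assert stats["nonTIR"] == pytest.approx(2.0)

    def test_empty_class_is_na(self):
        stats = exon_stats([self._nbs("TIR", 4)])
        assert stats["TIR"] == 4.0
        assert stats["nonTIR"] is None

    def test_simulated_tir_genes_have_more_exons(self, study_run):
        stats = exon_stats(study_run.result.nbs_genes)
        assert stats["TIR"] > stats["nonTIR"]
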