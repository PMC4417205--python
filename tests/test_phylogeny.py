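import numpy as np
import pytest

from nbskit.genome_io import GeneModel
from nbskit.identify import NBSGene
from nbskit.phylogeny import (
    DistanceMatrix,
    PhylogenyError,
    bootstrap,
    cds_subsequence,
    extract_nbs_domain,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    species_specific_clades,
    tree_class_assignment,
    ungapped_identity,
)
from oracles import ls_best_bipartitions, tree_bipartition_set


class TestDomainExtraction:
    def test_protein_span_maps_to_cds_bases(self):
        cds = "ATGGCATCA" * 14  # 42 codons, varied content
        assert cds_subsequence(cds, 1, 10) == cds[0:30]
        assert cds_subsequence(cds, 11, 20) == cds[30:60]

    def test_extracted_length_divisible_by_three(self):
        cds = "ATG" * 50
        for lo, hi in [(1, 5), (3, 17), (20, 50)]:
            assert len(cds_subsequence(cds, lo, hi)) % 3 == 0

    def test_span_beyond_cds_is_error(self):
        with pytest.raises(PhylogenyError):
            cds_subsequence("ATG" * 10, 5, 11)

    def test_extract_from_gene(self):
        gm = GeneModel("g", "A", "s", 0, 300, "+", cds="ATG" * 100)
        g = NBSGene(gene=gm, nbarc_span=(11, 20), has_tir=False, has_lrr=False,
                    has_cc=False, klass="nonTIR", subtype="XN", exon_count=1)
        assert extract_nbs_domain(g) == gm.cds[30:60]


class TestK2P:
    def test_identical(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_pure_transitions(self):
        # 10 A->G transitions over 100 sites: P=0.1, Q=0
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        assert k2p_distance(a, b) == pytest.approx(0.1115718, abs=1e-7)

    def test_pure_transversions(self):
        # 10 A->C transversions over 100 sites: P=0, Q=0.1
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        assert k2p_distance(a, b) == pytest.approx(0.1084661, abs=1e-7)

    def test_equals_jc_when_ts_tv_ratio_is_half(self):
        # P = 2Q/2 i.e. transitions = half of changes split as 1 ts : 2 tv
        from nbskit.evolution import jc_distance

        a = "A" * 300
        b = "G" * 10 + "C" * 10 + "T" * 10 + "A" * 270
        d_k2p = k2p_distance(a, b)
        _, d_jc = jc_distance(a, b)
        assert d_k2p == pytest.approx(d_jc, rel=1e-9)

    def test_saturation_is_na(self):
        assert k2p_distance("ACAC", "CACA") is None  # Q = 1

    def test_gap_columns_excluded_and_empty_is_error(self):
        assert k2p_distance("AC-G", "ACTG") == 0.0
        with pytest.raises(PhylogenyError):
            k2p_distance("----", "ACGT")

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(5)
        aln = {
            f"t{i}": "".join("ACGT"[b] for b in rng.integers(0, 4, 200))
            for i in range(6)
        }
        dm = k2p_matrix(aln)
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    expect = k2p_distance(aln[a], aln[b])
                    if expect is None:
                        assert np.isnan(dm.matrix[i, j])
                    else:
                        assert dm.matrix[i, j] == pytest.approx(expect, abs=1e-12)


def additive_matrix(labels, dists):
    n = len(labels)
    m = np.zeros((n, n))
    for (a, b), d in dists.items():
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = d
    return DistanceMatrix(list(labels), m)


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = additive_matrix("ABC", {("A", "B"): 3, ("A", "C"): 4, ("B", "C"): 5})
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_additive_four_taxon_tree_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4))
        dm = additive_matrix(
            "ABCD",
            {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
             ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7},
        )
        tree = nj_tree(dm)
        biparts = tree_bipartition_set(tree, dm.labels)
        assert biparts == {frozenset({"A", "B"})}
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        # internal branch
        internal = [n for n in tree.root.traverse(include_self=False)
                    if not n.is_tip()]
        assert [n.length for n in internal] == pytest.approx([1.0])

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (6, 2)])
    def test_matches_least_squares_brute_force_on_random_additive_trees(
        self, n_taxa, seed
    ):
        rng = np.random.default_rng(seed)
        labels = [chr(65 + i) for i in range(n_taxa)]
        topo_edges = None
        from oracles import all_unrooted_topologies, ls_fit

        topos = all_unrooted_topologies(labels)
        topo_edges = topos[rng.integers(len(topos))]
        lengths = {frozenset(e): float(rng.uniform(0.5, 3.0)) for e in topo_edges}
        import networkx as nx

        G = nx.Graph(topo_edges)
        m = np.zeros((n_taxa, n_taxa))
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                path = nx.shortest_path(G, labels[i], labels[j])
                m[i, j] = m[j, i] = sum(
                    lengths[frozenset((u, v))] for u, v in zip(path, path[1:])
                )
        dm = DistanceMatrix(labels, m)
        nj_biparts = tree_bipartition_set(nj_tree(dm), labels)
        ls_biparts, sse = ls_best_bipartitions(labels, m)
        assert sse == pytest.approx(0.0, abs=1e-18)
        assert nj_biparts == ls_biparts
        # additivity: NJ path lengths reproduce the matrix exactly
        tree = nj_tree(dm)
        tips = {t.name: t for t in tree.root.tips()}
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                d = tips[labels[i]].distance(tips[labels[j]])
                assert d == pytest.approx(m[i, j], abs=1e-9)

    def test_label_order_invariance(self):
        dm = additive_matrix(
            "ABCD",
            {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
             ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7},
        )
        perm = [3, 1, 0, 2]
        labels2 = [dm.labels[i] for i in perm]
        m2 = dm.matrix[np.ix_(perm, perm)]
        t1 = tree_bipartition_set(nj_tree(dm), dm.labels)
        t2 = tree_bipartition_set(nj_tree(DistanceMatrix(labels2, m2)), labels2)
        assert t1 == t2

    def test_na_entries_are_an_error(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.nan
        with pytest.raises(PhylogenyError, match="NA"):
            nj_tree(DistanceMatrix(["a", "b", "c"], m))


def two_group_alignment(rng, n_per_group=4, L=300, intra=2, inter=90):
    base1 = rng.integers(0, 4, L)
    base2 = base1.copy()
    idx = rng.choice(L, size=inter, replace=False)
    base2[idx] = (base2[idx] + rng.integers(1, 4, inter)) % 4
    aln = {}
    for g, base, sp in ((0, base1, "A"), (1, base2, "B")):
        for i in range(n_per_group):
            row = base.copy()
            idx = rng.choice(L, size=intra, replace=False)
            row[idx] = (row[idx] + rng.integers(1, 4, intra)) % 4
            aln[f"{sp}|{g}{i}"] = "".join("ACGT"[b] for b in row)
    return aln


class TestBootstrap:
    def test_separated_groups_get_high_central_support(self):
        aln = two_group_alignment(np.random.default_rng(0))
        tree = bootstrap(aln, n_reps=100, seed=1)
        full = frozenset(aln)
        group_a = frozenset(k for k in aln if k.startswith("A"))
        supports = {
            bp: n.support for bp, n in tree.bipartitions().items()
        }
        central = [s for bp, s in supports.items() if bp in (group_a, full - group_a)]
        assert central and min(central) >= 99.0

    def test_zero_reps_leaves_no_supports(self):
        aln = two_group_alignment(np.random.default_rng(2))
        tree = bootstrap(aln, n_reps=0, seed=0)
        assert all(
            getattr(n, "support", None) is None
            for n in tree.bipartitions().values()
        )

    def test_same_seed_gives_identical_supports(self):
        aln = two_group_alignment(np.random.default_rng(3))
        t1 = bootstrap(aln, n_reps=50, seed=9)
        t2 = bootstrap(aln, n_reps=50, seed=9)
        s1 = {bp: n.support for bp, n in t1.bipartitions().items()}
        s2 = {bp: n.support for bp, n in t2.bipartitions().items()}
        assert s1 == s2


class TestTreeContext:
    def test_majority_vote_in_smallest_informative_clade(self):
        aln = two_group_alignment(np.random.default_rng(4))
        tree = bootstrap(aln, n_reps=0, seed=0)
        labels = sorted(aln)
        classified = {l: ("TIR" if l.startswith("A") else "nonTIR")
                      for l in labels}
        unknown = labels[0]
        del classified[unknown]
        ctx = tree_class_assignment(tree, classified)
        assert ctx == {unknown: "TIR"}


class TestCladeMining:
    def _setup(self, rng_seed=0):
        aln = two_group_alignment(
            np.random.default_rng(rng_seed), n_per_group=5, intra=3
        )
        tree = bootstrap(aln, n_reps=100, seed=5)
        return tree, aln

    def test_planted_radiation_found(self):
        tree, aln = self._setup()
        clades = species_specific_clades(tree, aln)
        by_species = {c.species: c for c in clades}
        assert set(by_species) == {"A", "B"}
        assert all(c.size == 5 for c in clades)
        assert all(c.support > 50 for c in clades)
        assert all(c.min_pairwise_similarity > 0.9 for c in clades)

    def test_low_support_disqualifies(self):
        tree, aln = self._setup()
        for node in tree.bipartitions().values():
            node.support = 40.0
        assert species_specific_clades(tree, aln) == []

    def test_low_similarity_disqualifies(self):
        tree, aln = self._setup()
        assert species_specific_clades(tree, aln, min_similarity=0.999) == []

    def test_min_size_is_strictly_more_than_two(self):
        tree, aln = self._setup()
        clades = species_specific_clades(tree, aln, min_size=6)
        assert clades == []

    def test_truth_recovery_on_simulated_repertoires(self, study_run):
        truth = study_run.sim.truth
        found = [set(c.members) for c in study_run.result.clades]

        def recovered(members):
            T = set(members)
            return any(T <= R or len(T & R) / len(T | R) >= 0.8 for R in found)

        sens = sum(
            recovered(c["members"]) for c in truth.expansion_clades
        ) / len(truth.expansion_clades)
        assert sens >= 0.9


def test_ungapped_identity():
    assert ungapped_identity("ACGT", "ACGA") == 0.75
    assert ungapped_identity("AC-T", "ACTT") == 1.0  # gap column dropped
    with pytest.raises(PhylogenyError):
        ungapped_identity("----", "ACGT")
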