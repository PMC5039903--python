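import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_loglik, make_alignment
from dielscan.io import Alignment, SequenceRecord
from dielscan.phylo import (
    HKYParams,
    PhyloError,
    Tree,
    discrete_gamma_rates,
    empirical_base_freqs,
    fit_ml_tree,
    hky_gamma_loglik,
    hky_rate_matrix,
    k80_distance_matrix,
    monophyly_test,
    neighbor_joining,
)


class TestK80Distances:
    def test_identical_rows_zero(self):
        aln = make_alignment({"a": "ACGT" * 5, "b": "ACGT" * 5})
        _, D, flagged = k80_distance_matrix(aln)
        assert D[0, 1] == 0.0 and not flagged.any()

    def test_closed_form_hand_case(self):
        # 20 sites, 2 transitions (A<->G), 1 transversion (C<->A): P=0.1, Q=0.05
        a = "A" * 20
        b = "G" * 2 + "C" * 1 + "A" * 17
        aln = make_alignment({"a": a, "b": b})
        _, D, _ = k80_distance_matrix(aln)
        expect = -0.5 * math.log(1 - 2 * 0.1 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
        assert D[0, 1] == pytest.approx(expect, abs=1e-9)
        assert D[0, 1] == pytest.approx(0.17018, abs=5e-6)

    def test_saturated_pair_flagged_and_capped(self):
        # all sites transitions: P=1 -> log argument <= 0
        aln = make_alignment({"a": "A" * 12, "b": "G" * 12})
        _, D, flagged = k80_distance_matrix(aln)
        assert flagged[0, 1]
        assert D[0, 1] == pytest.approx(5.0)


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        ids = ["A", "B", "C"]
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(D, ids)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_exact_on_additive_four_taxon_matrix(self):
        # distances of tree ((A:1,B:2):1,(C:3,D:4))
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(D, ids)
        assert tree.splits() == {frozenset({"C", "D"})}
        lengths = {n.name: n.length for n in tree.postorder() if n.is_tip}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        internal = [n.length for n in tree.internal_edges()]
        assert internal == pytest.approx([1.0])

    def test_matches_skbio_on_random_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        # build a random additive matrix from a random binary tree with 6 tips
        base = Tree.from_newick(
            "((A:{}, B:{}):{}, (C:{}, D:{}):{}, (E:{}, F:{}):{});".format(
                *rng.uniform(0.05, 0.5, 9)
            )
        )
        ids = sorted(base.tip_names())
        # path distances (root at x, depth of y, plus x's own terminal branch)
        def dist(t, x, y):
            rx = t.rooted_at(x)
            depth = {}

            def rec(n, d):
                if n.is_tip:
                    depth[n.name] = d
                for c in n.children:
                    rec(c, d + (c.length or 0.0))

            rec(rx.root, 0.0)
            return depth[y] + (rx.find_tip(x).length or 0.0)
        D = np.zeros((6, 6))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i < j:
                    D[i, j] = D[j, i] = dist(base, x, y)
        mine = neighbor_joining(D, ids)
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        ref_tree = Tree.from_newick(str(ref))
        assert mine.splits() == ref_tree.splits() == base.splits()

    def test_tie_case_resolves_deterministically(self):
        ids = ["a", "b", "c", "d"]
        D = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(D, ids)
        t2 = neighbor_joining(D, ids)
        assert t1.newick() == t2.newick()
        assert all(n.length == pytest.approx(0.0, abs=1e-12) for n in t1.internal_edges())

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(PhyloError, match="symmetric"):
            neighbor_joining(D, ["a", "b", "c"])


class TestLikelihood:
    EQUAL = HKYParams(kappa=1.0, base_freqs=(0.25,) * 4, alpha=1.0, n_categories=1)

    def test_zero_distance_two_tips(self):
        aln = make_alignment({"x": "A", "y": "A"})
        tree = Tree.from_newick("(x:1e-9,y:1e-9);")
        assert hky_gamma_loglik(tree, aln, self.EQUAL) == pytest.approx(math.log(0.25), abs=1e-6)

    @pytest.mark.parametrize("d", [0.05, 0.3, 1.0])
    def test_jc_closed_form_same_and_different(self, d):
        # kappa=1, equal frequencies, no rate variation -> JC69
        same = make_alignment({"x": "A", "y": "A"})
        diff = make_alignment({"x": "A", "y": "C"})
        tree = Tree.from_newick(f"(x:{d / 2},y:{d / 2});")
        p_same = 0.25 + 0.75 * math.exp(-4 * d / 3)
        p_diff = (1 - p_same) / 3
        assert hky_gamma_loglik(tree, same, self.EQUAL) == pytest.approx(math.log(0.25 * p_same))
        assert hky_gamma_loglik(tree, diff, self.EQUAL) == pytest.approx(math.log(0.25 * p_diff))

    def test_large_alpha_approaches_no_rate_variation(self):
        aln = make_alignment({"x": "ACGTT", "y": "ACATT"})
        tree = Tree.from_newick("(x:0.1,y:0.15);")
        with_cats = HKYParams(kappa=1.0, base_freqs=(0.25,) * 4, alpha=1e7, n_categories=4)
        assert hky_gamma_loglik(tree, aln, with_cats) == pytest.approx(
            hky_gamma_loglik(tree, aln, self.EQUAL), abs=1e-6
        )

    def test_pruning_equals_brute_force_four_tips(self):
        rng = np.random.default_rng(1)
        rows = {n: "".join(rng.choice(list("ACGT"), 3)) for n in "abcd"}
        aln = make_alignment(rows)
        tree = Tree.from_newick("((a:0.1,b:0.2):0.15,c:0.3,d:0.05);")
        params = HKYParams(kappa=2.3, base_freqs=(0.3, 0.2, 0.3, 0.2), alpha=0.7, n_categories=4)
        assert hky_gamma_loglik(tree, aln, params) == pytest.approx(
            brute_force_loglik(tree, aln, params), rel=1e-10
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_pruning_equals_brute_force_random_sweep(self, seed):
        """Property sweep: random <=5-taxon, <=4-site alignments and trees."""
        rng = np.random.default_rng(seed)
        ntax = int(rng.integers(2, 6))
        nsites = int(rng.integers(1, 5))
        names = [f"t{i}" for i in range(ntax)]
        rows = {n: "".join(rng.choice(list("ACGT"), nsites)) for n in names}
        aln = Alignment(tuple(SequenceRecord(n, s) for n, s in rows.items()))
        # random caterpillar topology with random lengths
        nwk = names[0] + f":{rng.uniform(0.01, 0.5):.4f}"
        for n in names[1:]:
            nwk = f"({nwk},{n}:{rng.uniform(0.01, 0.5):.4f}):{rng.uniform(0.01, 0.3):.4f}"
        tree = Tree.from_newick(nwk[: nwk.rfind(":")] + ";")
        f = rng.dirichlet([5, 5, 5, 5])
        params = HKYParams(
            kappa=float(rng.uniform(0.5, 5)),
            base_freqs=tuple(f),
            alpha=float(rng.uniform(0.3, 3)),
            n_categories=int(rng.integers(1, 5)),
        )
        assert hky_gamma_loglik(tree, aln, params) == pytest.approx(
            brute_force_loglik(tree, aln, params), rel=1e-9
        )

    def test_invariant_under_rerooting_and_row_order(self):
        rng = np.random.default_rng(2)
        rows = {n: "".join(rng.choice(list("ACGT"), 30)) for n in "abcde"}
        aln = make_alignment(rows)
        tree = Tree.from_newick("((a:0.1,b:0.2):0.1,(c:0.15,d:0.25):0.05,e:0.3);")
        params = HKYParams(kappa=3.0, base_freqs=(0.2, 0.3, 0.3, 0.2), alpha=1.5)
        ll = hky_gamma_loglik(tree, aln, params)
        permuted = make_alignment({k: rows[k] for k in "edcba"})
        assert hky_gamma_loglik(tree, permuted, params) == pytest.approx(ll)
        rerooted = tree.rooted_at("c")
        assert hky_gamma_loglik(rerooted, aln, params) == pytest.approx(ll, abs=1e-7)

    def test_discrete_gamma_rates_mean_one_and_monotone(self):
        for alpha in (0.2, 1.0, 1.9765, 10.0):
            r = discrete_gamma_rates(alpha, 4)
            assert r.mean() == pytest.approx(1.0)
            assert (np.diff(r) > 0).all()

    def test_rate_matrix_normalised(self):
        pi = (0.1, 0.4, 0.3, 0.2)
        Q = hky_rate_matrix(5.0, pi)
        assert Q.sum(axis=1) == pytest.approx(np.zeros(4), abs=1e-12)
        assert -(np.array(pi) * np.diag(Q)).sum() == pytest.approx(1.0)


class TestFit:
    def test_identical_sequences_collapse(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 200))
        aln = make_alignment({n: seq for n in "abcd"})
        res = fit_ml_tree(aln, fixed_alpha=1.0, max_cycles=3)
        assert all(n.length <= 1e-6 for n in res.tree.branch_nodes())
        # loglik = sum over sites of log pi(site state)
        pi = dict(zip("ACGT", empirical_base_freqs(aln)))
        expect = sum(math.log(pi[c]) for c in seq)
        assert res.loglik == pytest.approx(expect, rel=1e-4)

    def test_refit_is_a_fixed_point(self):
        from dielscan.simulate import simulate_alignment, six_taxon_config
        from dielscan.trimming import complete_deletion

        aln, _, _ = simulate_alignment(six_taxon_config(seed=9, length=800))
        caln, _ = complete_deletion(aln)
        res = fit_ml_tree(caln, fixed_alpha=1.9765)
        res2 = fit_ml_tree(caln, init=res.tree, fixed_alpha=1.9765, kappa0=res.params.kappa)
        assert res2.loglik == pytest.approx(res.loglik, abs=0.05)
        assert res2.tree.splits() == res.tree.splits()

    def test_too_few_taxa_rejected(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        with pytest.raises(PhyloError, match=">= 4"):
            fit_ml_tree(aln)


class TestNewickRoundTrip:
    def test_topology_lengths_supports_preserved(self):
        nwk = "((a:0.100000,b:0.200000)95:0.050000,(c:0.300000,d:0.400000)87:0.060000,e:0.700000);"
        tree = Tree.from_newick(nwk)
        assert tree.newick() == nwk
        again = Tree.from_newick(tree.newick())
        assert again.splits() == tree.splits()
        assert sorted(n.support for n in again.internal_edges()) == [87.0, 95.0]


class TestMonophyly:
    def test_clean_split_both_monophyletic(self):
        from conftest import make_metadata

        tree = Tree.from_newick("(((A:1,B:1):1,(C:1,D:1):1):1,O:3);")
        meta = make_metadata(
            {
                "A": ("Haplorhini", "Diurnal"),
                "B": ("Haplorhini", "Diurnal"),
                "C": ("Strepsirrhini", "Nocturnal"),
                "D": ("Strepsirrhini", "Nocturnal"),
                "O": ("outgroup", "Nocturnal"),
            }
        )
        res = monophyly_test(tree, meta, "behavior", "O")
        assert res["Diurnal"].is_monophyletic and res["Nocturnal"].is_monophyletic
        assert res["Diurnal"].n_intruders == 0

    def test_species_tree_diurnal_not_monophyletic(self, table1_metadata, table1_tree):
        """On the species-tree fixture the diurnal taxa do not form a clade:
        the nocturnal owl monkey and tarsier nest inside Haplorhini."""
        res = monophyly_test(table1_tree, table1_metadata, "behavior", "Mouse")
        assert not res["Diurnal"].is_monophyletic
        assert res["Diurnal"].smallest_containing_clade_size == 14
        assert res["Diurnal"].n_intruders == 5
        assert not res["Nocturnal"].is_monophyletic

    def test_group_trait_monophyly_on_species_tree(self, table1_metadata, table1_tree):
        res = monophyly_test(table1_tree, table1_metadata, "group", "Mouse")
        assert res["Haplorhini"].is_monophyletic
        assert res["Strepsirrhini"].is_monophyletic

    def test_single_level_trivially_monophyletic(self):
        from conftest import make_metadata

        tree = Tree.from_newick("((A:1,B:1):1,O:2);")
        meta = make_metadata(
            {"A": ("Haplorhini", "Diurnal"), "B": ("Haplorhini", "Diurnal"), "O": ("outgroup", "Nocturnal")}
        )
        res = monophyly_test(tree, meta, "behavior", "O")
        assert res == {"Diurnal": res["Diurnal"]}
        assert res["Diurnal"].is_monophyletic
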