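"""Trees, the Felsenstein kernel, likelihoods, fitting, and resampling."""

import math

import numpy as np
import pytest

import phylonull as pn
from phylonull.phylo import (
    Tree,
    TreeFormatError,
    _site_log_likelihoods,
    transition_probability,
)

import oracles


@pytest.fixture
def four_leaf_tree():
    # root -> (int1 -> A, B), (int2 -> C, D)
    parent = np.array([-1, 0, 0, 1, 1, 2, 2])
    blen = np.array([0.0, 0.3, 0.5, 0.2, 0.7, 0.4, 0.1])
    return Tree(parent, blen, [None, None, None, "A", "B", "C", "D"])


class TestNewick:
    def test_three_leaf_parse(self):
        tree = Tree.from_newick("((A:0.1,B:0.1):0.2,C:0.3);")
        assert tree.n_leaves == 3
        assert sorted(tree.leaf_labels) == ["A", "B", "C"]
        depths = dict(zip(tree.leaf_labels, tree.leaf_depths()))
        assert depths["A"] == pytest.approx(0.3)
        assert depths["C"] == pytest.approx(0.3)

    def test_round_trip(self, tmp_path, four_leaf_tree):
        p = tmp_path / "t.nwk"
        four_leaf_tree.write(p)
        back = pn.read_newick(p)
        assert sorted(back.leaf_labels) == ["A", "B", "C", "D"]
        d0 = four_leaf_tree.leaf_distance_matrix()
        order0 = four_leaf_tree.leaf_labels
        d1 = back.leaf_distance_matrix()
        order1 = back.leaf_labels
        idx = [order1.index(x) for x in order0]
        np.testing.assert_allclose(d1[np.ix_(idx, idx)], d0, atol=1e-9)

    def test_single_leaf_is_error(self):
        with pytest.raises((ValueError, TreeFormatError)):
            Tree.from_newick("(A:1.0);")

    def test_malformed_is_format_error(self):
        with pytest.raises(TreeFormatError):
            Tree.from_newick("((A:1,B:2;")

    def test_missing_lengths_default_zero_with_warning(self):
        with pytest.warns(UserWarning):
            tree = Tree.from_newick("((A:0.1,B),C:0.3);")
        assert tree.n_leaves == 3


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_topology(self):
        # additive metric from a known tree: (A,B) vs (C,D) split
        gen = Tree.from_newick("((A:0.2,B:0.3):0.5,(C:0.4,D:0.6):0.5);")
        labels = gen.leaf_labels
        dm = pn.DistanceMatrix(gen.leaf_distance_matrix() / 4.0, labels)
        out = pn.nj_tree(dm)
        d = out.leaf_distance_matrix()
        lab = out.leaf_labels
        i = {x: k for k, x in enumerate(lab)}
        # A-B and C-D must be closer than any cross pair
        cross = min(d[i["A"], i["C"]], d[i["A"], i["D"]], d[i["B"], i["C"]], d[i["B"], i["D"]])
        assert d[i["A"], i["B"]] < cross
        assert d[i["C"], i["D"]] < cross

    def test_path_lengths_track_additive_input(self):
        gen = Tree.from_newick("(((A:0.1,B:0.2):0.2,C:0.5):0.3,(D:0.4,E:0.1):0.2);")
        labels = gen.leaf_labels
        truth = gen.leaf_distance_matrix()
        out = pn.nj_tree(pn.DistanceMatrix(truth / truth.max(), labels))
        d = out.leaf_distance_matrix()
        idx = [out.leaf_labels.index(x) for x in labels]
        iu = np.triu_indices(5, 1)
        r = np.corrcoef(d[np.ix_(idx, idx)][iu], truth[iu])[0, 1]
        assert r > 0.9

    def test_ultrametric_three_taxa_pairing(self):
        d = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]])
        out = pn.nj_tree(pn.DistanceMatrix(d, ["A", "B", "C"]))
        dd = out.leaf_distance_matrix()
        i = {x: k for k, x in enumerate(out.leaf_labels)}
        assert dd[i["A"], i["B"]] < dd[i["A"], i["C"]]

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            pn.nj_tree(pn.DistanceMatrix(np.zeros((2, 2)), ["A", "B"]))


class TestSaturationCorrection:
    def test_small_distances_nearly_unchanged_and_order_preserved(self):
        prof = pn.Profile(np.full((4, 5), 0.2))  # plateau b = 0.8
        d = np.array([[0.0, 0.01, 0.4], [0.01, 0.0, 0.7], [0.4, 0.7, 0.0]])
        out = pn.correct_saturation(pn.DistanceMatrix(d, list("abc")), prof)
        assert out.d[0, 1] == pytest.approx(0.01, rel=0.05)
        # correction is monotone and expands deep distances
        assert out.d[0, 2] > d[0, 2]
        assert out.d[1, 2] > out.d[0, 2]
        assert (np.diag(out.d) == 0).all()

    def test_plateau_distances_capped_finite(self):
        prof = pn.Profile(np.full((4, 5), 0.2))
        d = np.array([[0.0, 0.8], [0.8, 0.0]])  # exactly at the plateau
        out = pn.correct_saturation(pn.DistanceMatrix(d, list("ab")), prof)
        assert np.isfinite(out.d).all()

    def test_pipeline_returns_consistent_tree_and_model(self, small_phylo_family):
        tree, model = pn.fit_resampling_model(small_phylo_family.alignment)
        assert tree.n_leaves == small_phylo_family.alignment.M
        assert model.L == small_phylo_family.alignment.L
        assert model.mu > 0


class TestTransitionKernel:
    def test_t_zero_is_identity(self):
        om = np.array([0.2, 0.3, 0.5])
        assert transition_probability(1, 1, 0.0, 1.0, om) == 1.0
        assert transition_probability(1, 2, 0.0, 1.0, om) == 0.0

    def test_t_infinity_is_stationary(self):
        om = np.array([0.2, 0.3, 0.5])
        for a in range(3):
            assert transition_probability(a, 2, 1e9, 1.0, om) == pytest.approx(0.5, abs=1e-12)

    def test_rows_normalize(self):
        om = np.array([0.1, 0.2, 0.3, 0.4])
        for t in (0.0, 0.3, 2.0, 50.0):
            for a in range(4):
                s = sum(transition_probability(a, b, t, 0.7, om) for b in range(4))
                assert s == pytest.approx(1.0, abs=1e-12)

    def test_stationarity(self):
        om = np.array([0.25, 0.35, 0.4])
        for t in (0.1, 1.0, 10.0):
            for b in range(3):
                tot = sum(om[a] * transition_probability(a, b, t, 1.3, om) for a in range(3))
                assert tot == pytest.approx(om[b], abs=1e-12)

    def test_chapman_kolmogorov(self):
        om = np.array([0.5, 0.2, 0.3])
        mu, t1, t2 = 0.9, 0.4, 1.1
        for a in range(3):
            for c in range(3):
                composed = sum(
                    transition_probability(a, b, t1, mu, om)
                    * transition_probability(b, c, t2, mu, om)
                    for b in range(3)
                )
                direct = transition_probability(a, c, t1 + t2, mu, om)
                assert composed == pytest.approx(direct, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(0, 0, -0.1, 1.0, np.array([1.0]))


class TestSiteLikelihood:
    def test_star_tree_long_branches_factorizes(self):
        parent = np.array([-1, 0, 0, 0])
        blen = np.array([0.0, 50.0, 50.0, 50.0])
        tree = Tree(parent, blen, [None, "a", "b", "c"])
        om = np.array([[0.2, 0.3, 0.5]])
        model = pn.FelsensteinModel(1.0, om)
        aln = pn.Alignment(np.array([[0], [1], [2]], dtype=np.int8), ["a", "b", "c"], "-AC")
        ll = pn.site_log_likelihood(aln, tree, model, 0)
        expected = math.log(0.2) + math.log(0.3) + math.log(0.5)
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_zero_branches_disagreeing_leaves_impossible(self):
        parent = np.array([-1, 0, 0])
        tree = Tree(parent, np.zeros(3), [None, "a", "b"])
        model = pn.FelsensteinModel(1.0, np.array([[0.5, 0.5]]))
        aln = pn.Alignment(np.array([[0], [1]], dtype=np.int8), ["a", "b"], "-A")
        assert pn.site_log_likelihood(aln, tree, model, 0) == -np.inf

    @pytest.mark.parametrize("q", [2, 3])
    def test_matches_exhaustive_enumeration(self, four_leaf_tree, q, rng):
        om = rng.dirichlet([1.0] * q)
        mu = 0.8
        for _ in range(10):
            states = rng.integers(0, q, size=4)
            leaf_states = dict(zip(four_leaf_tree.leaves, states.tolist()))
            brute = oracles.felsenstein_site_likelihood_bruteforce(
                four_leaf_tree, leaf_states, mu, om
            )
            col = states.reshape(4, 1).astype(np.int8)
            ll = _site_log_likelihoods(col, four_leaf_tree, mu, om.reshape(1, q))
            assert float(ll[0]) == pytest.approx(math.log(brute), abs=1e-10)

    def test_five_leaf_enumeration(self, rng):
        parent = np.array([-1, 0, 0, 1, 1, 2, 2, 3, 3])
        blen = np.array([0.0, 0.2, 0.4, 0.3, 0.5, 0.1, 0.6, 0.2, 0.3])
        tree = Tree(parent, blen, [None] * 4 + ["a", "b", "c", "d", "e"][:5])
        # nodes 4..8 are leaves
        q = 3
        om = rng.dirichlet([0.8] * q)
        states = rng.integers(0, q, size=tree.n_leaves)
        leaf_states = dict(zip(tree.leaves, states.tolist()))
        brute = oracles.felsenstein_site_likelihood_bruteforce(tree, leaf_states, 1.1, om)
        col = states.reshape(-1, 1).astype(np.int8)
        ll = _site_log_likelihoods(col, tree, 1.1, om.reshape(1, q))
        assert float(ll[0]) == pytest.approx(math.log(brute), abs=1e-10)


class TestFitting:
    def test_parameter_recovery(self):
        # data simulated at mu*=1.0 recovers mu within 25 percent
        errs = []
        for seed in range(3):
            sample = pn.generate_phylo_msa(pn.BenchmarkSpec(M=200, L=30, mu=1.0, seed=seed))
            model = pn.fit_felsenstein(sample.alignment, sample.tree)
            errs.append(abs(model.mu - 1.0))
        assert np.median(errs) < 0.25

    def test_consistency_with_depth(self):
        # median relative error of mu-hat does not grow from M=50 to M=400
        med = {}
        for M in (50, 400):
            errs = []
            for rep in range(10):
                sample = pn.generate_phylo_msa(
                    pn.BenchmarkSpec(M=M, L=30, mu=1.0, seed=1000 * M + rep)
                )
                model = pn.fit_felsenstein(sample.alignment, sample.tree)
                errs.append(abs(model.mu - 1.0))
            med[M] = float(np.median(errs))
        assert med[400] <= med[50]

    def test_em_round_does_not_decrease_likelihood(self, small_phylo_family):
        aln, tree = small_phylo_family.alignment, small_phylo_family.tree
        base = pn.fit_felsenstein(aln, tree, refine_omega=False)
        refined = pn.fit_felsenstein(aln, tree, refine_omega=True, em_rounds=1)
        assert refined.log_likelihood >= base.log_likelihood - 1e-6

    def test_degenerate_alignment_warns_at_boundary(self):
        parent = np.array([-1, 0, 0, 0])
        tree = Tree(parent, np.zeros(4), [None, "s1", "s2", "s3"])
        aln = pn.Alignment.from_sequences(["AAA"] * 3, labels=["s1", "s2", "s3"])
        with pytest.warns(UserWarning):
            model = pn.fit_felsenstein(aln, tree, refine_omega=False)
        assert model.mu > 0


class TestResampling:
    def test_zero_branch_lengths_copy_root(self):
        parent = np.array([-1, 0, 0, 0])
        tree = Tree(parent, np.zeros(4), [None, "s1", "s2", "s3"])
        model = pn.FelsensteinModel(1.0, np.full((8, 4), 0.25))
        aln = pn.resample_on_tree(model, tree, seed=0)
        assert (aln.data == aln.data[0]).all()

    def test_star_tree_long_branches_iid_from_omega(self, rng):
        M, L, q = 400, 6, 4
        parent = np.concatenate([[-1], np.zeros(M, dtype=int)])
        blen = np.concatenate([[0.0], np.full(M, 100.0)])
        tree = Tree(parent, blen, [None] + [f"s{i}" for i in range(M)])
        omega = rng.dirichlet([1.0] * q, size=L)
        model = pn.FelsensteinModel(1.0, omega)
        aln = pn.resample_on_tree(model, tree, seed=5)
        freq = pn.compute_profile(aln).freq
        bound = 3 * np.sqrt(omega * (1 - omega) / M) + 1e-9
        assert (np.abs(freq - omega) < np.maximum(bound, 0.05)).all()

    def test_seeds_give_independent_msas(self, small_phylo_family):
        model = pn.fit_felsenstein(small_phylo_family.alignment, small_phylo_family.tree)
        a1 = pn.resample_on_tree(model, small_phylo_family.tree, seed=1)
        a2 = pn.resample_on_tree(model, small_phylo_family.tree, seed=2)
        assert not np.array_equal(a1.data, a2.data)

    def test_no_excess_covariation_vs_star_control(self):
        # tree-resampled columns carry no intrinsic couplings: the mean
        # absolute covariance matches an i.i.d. (star-tree) control once the
        # phylogenetic depth is removed; compare at matched M on shallow trees
        spec = pn.BenchmarkSpec(M=120, L=12, q=6, mu=3.0, seed=3, tree_model="star")
        star = pn.generate_phylo_msa(spec)

        def mean_abs_offdiag_cov(aln):
            C = pn.covariance_matrix(
                pn.compute_profile(aln), pn.compute_pair_frequencies(aln)
            ).tensor
            L = aln.L
            vals = [np.abs(C[i, :, j, :]).mean() for i in range(L) for j in range(i + 1, L)]
            return float(np.mean(vals))

        obs = mean_abs_offdiag_cov(star.alignment)
        controls = []
        for seed in range(30):
            ctl = pn.generate_phylo_msa(
                pn.BenchmarkSpec(M=120, L=12, q=6, mu=3.0, seed=100 + seed,
                                 tree_model="star")
            )
            controls.append(mean_abs_offdiag_cov(ctl.alignment))
        lo, hi = np.quantile(controls, [0.025, 0.975])
        assert lo <= obs <= hi
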