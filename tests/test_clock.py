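"""Likelihood engine and molecular clock test."""

import math

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from geminate_clock import (
    DistanceMatrix,
    LocusConfig,
    SimulationConfig,
    TN93Params,
    clock_lrt,
    nj_tree,
    simulate_geminate,
    tree_loglik,
)
from geminate_clock.errors import TreeError
from geminate_clock.trees import parse_newick

from conftest import make_alignment


def tn93_joint_oracle(pi, k1, k2, t):
    """Independent TN93 pair joint probabilities via matrix exponential."""
    pi = np.asarray(pi)
    rel = np.ones((4, 4))
    rel[0, 2] = rel[2, 0] = k1
    rel[1, 3] = rel[3, 1] = k2
    q = rel * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -np.dot(pi, np.diag(q))
    p = expm(q / mu * t)
    return pi[:, None] * p


class TestNJ:
    def test_additive_matrix_recovered_exactly(self):
        # distances generated from a known tree are additive; NJ must
        # reproduce every leaf-to-leaf path length
        true = {"AB": 0.3, "AC": 0.45, "AD": 0.55, "BC": 0.55, "BD": 0.65, "CD": 0.3}
        ids = ("A", "B", "C", "D")
        d = np.zeros((4, 4))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    d[i, j] = d[j, i] = true[a + b]
        tree = nj_tree(DistanceMatrix(ids, d, "p"))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(true[a + b])

    def test_leaf_set_conserved(self):
        rng = np.random.default_rng(0)
        n = 6
        d = rng.random((n, n)) * 0.2
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        ids = tuple(f"t{i}" for i in range(n))
        tree = nj_tree(DistanceMatrix(ids, d, "p"))
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == sorted(ids)

    def test_too_few_taxa(self):
        d = np.array([[0.0, 0.1], [0.1, 0.0]])
        with pytest.raises(TreeError):
            nj_tree(DistanceMatrix(("a", "b"), d, "p"))


class TestTreeLoglik:
    def test_two_taxon_matches_closed_form(self):
        """Pair likelihood equals the TN93 joint probability (expm oracle)."""
        pi = (0.28, 0.18, 0.18, 0.36)
        k1, k2 = 6.0, 3.0
        aln = make_alignment(["ACGTAG", "ATGTAA"], ids=["A", "B"])
        t1, t2 = 0.05, 0.07
        tree = parse_newick(f"(A:{t1},B:{t2});")
        got = tree_loglik(aln, tree, TN93Params(pi, k1, k2), gamma_categories=1)
        joint = tn93_joint_oracle(pi, k1, k2, t1 + t2)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = sum(
            math.log(joint[idx[x], idx[y]]) for x, y in zip("ACGTAG", "ATGTAA")
        )
        assert got == pytest.approx(expected, abs=1e-8)

    def test_identical_sequences_zero_branches(self):
        """With no substitutions the likelihood is the stationary product."""
        pi = (0.25, 0.25, 0.25, 0.25)
        seq = "ACGTACGT"
        aln = make_alignment([seq] * 3, ids=["A", "B", "C"])
        tree = parse_newick("(A:0,B:0,C:0);")
        got = tree_loglik(aln, tree, TN93Params(pi, 2.0, 2.0))
        assert got == pytest.approx(len(seq) * math.log(0.25), abs=1e-10)

    def test_gamma_limit_matches_homogeneous(self):
        """Very large shape with k=4 converges to the homogeneous model."""
        aln = make_alignment(["ACGTACGTAC", "ACGAACGTAC", "TCGAACTTAC"],
                             ids=["A", "B", "C"])
        tree = parse_newick("(A:0.1,B:0.05,C:0.2);")
        params_h = TN93Params((0.25,) * 4, 4.0, 4.0, gamma_shape=None)
        params_g = TN93Params((0.25,) * 4, 4.0, 4.0, gamma_shape=5e4)
        h = tree_loglik(aln, tree, params_h)
        g = tree_loglik(aln, tree, params_g, gamma_categories=4)
        assert g == pytest.approx(h, abs=1e-4)

    def test_gaps_marginalized(self):
        """A fully gapped column contributes zero log-likelihood."""
        pi = (0.25,) * 4
        aln1 = make_alignment(["ACGT", "ACGA"], ids=["A", "B"])
        aln2 = make_alignment(["ACGT-", "ACGA-"], ids=["A", "B"])
        tree = parse_newick("(A:0.05,B:0.05);")
        p = TN93Params(pi, 2.0, 2.0)
        assert tree_loglik(aln2, tree, p) == pytest.approx(
            tree_loglik(aln1, tree, p), abs=1e-10
        )

    def test_leaf_order_invariance(self, geminate_dataset):
        alignments, _, _ = geminate_dataset
        aln = alignments["COI"]
        from geminate_clock import Alignment

        shuffled = Alignment(aln.locus, list(aln.records[::-1]))
        tree = nj_tree(DistanceMatrix_from_aln(aln))
        p = TN93Params((0.25,) * 4, 4.0, 4.0, gamma_shape=0.5)
        assert tree_loglik(shuffled, tree, p) == pytest.approx(
            tree_loglik(aln, tree, p), abs=1e-8
        )

    def test_mismatched_leaves_rejected(self):
        aln = make_alignment(["ACGT", "ACGA"], ids=["A", "B"])
        tree = parse_newick("(A:0.1,X:0.1);")
        with pytest.raises(TreeError):
            tree_loglik(aln, tree, TN93Params((0.25,) * 4, 2.0, 2.0))


def DistanceMatrix_from_aln(aln):
    from geminate_clock import tn93_distances

    return tn93_distances(aln)


class TestClockLRT:
    def test_identical_sequences_do_not_reject(self):
        aln = make_alignment(["ACGTACGTACGTACGTACGT"] * 4, ids=list("ABCD"))
        res = clock_lrt(aln, seed=0)
        assert res.lr_stat == pytest.approx(0.0, abs=1e-3)
        assert res.p_value > 0.99
        assert res.df == 2

    def test_free_dominates_clock(self, geminate_dataset):
        alignments, _, _ = geminate_dataset
        res = clock_lrt(alignments["COI"], seed=0)
        assert res.lnL_free >= res.lnL_clock - 1e-6
        assert 0.0 <= res.p_value <= 1.0
        assert res.df == len(alignments["COI"]) - 2

    def test_violated_clock_detected(self):
        cfg = SimulationConfig(
            loci=(LocusConfig("COI", 658, 0.049),),
            n_per_clade=4,
            n_regions_per_clade=3,
            intra_clade_theta=0.005,
            seed=5,
        )
        from geminate_clock import simulate_clock_violation

        alignments, _, _ = simulate_clock_violation(cfg, "wa04", 5.0)
        res = clock_lrt(alignments["COI"], seed=0)
        assert res.p_value < 0.05

    def test_outgroup_rooting(self, geminate_dataset):
        alignments, _, _ = geminate_dataset
        aln = alignments["COI"]
        res = clock_lrt(aln, outgroup=aln.ids[0], seed=0)
        # outgroup-rooted clock tree still yields a valid nested comparison
        assert res.lnL_free >= res.lnL_clock - 1e-6
        root_children = parse_newick(res.clock_tree).seed_node.child_nodes()
        labels = {
            l.taxon.label
            for c in root_children
            for l in (c.leaf_iter() if not c.is_leaf() else [c])
        }
        assert aln.ids[0] in labels
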