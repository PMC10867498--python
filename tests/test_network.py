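"""Haplotype collapsing and minimum-spanning network construction."""

import itertools

import numpy as np
import pytest

from geminate_clock import build_msn, collapse_haplotypes, mutational_steps
from geminate_clock.network import Haplotype, roman

from conftest import make_alignment


class TestCollapse:
    def test_hand_grouping(self):
        aln = make_alignment(["ACGT", "ACGT", "ACGA"])
        haps = collapse_haplotypes(aln)
        assert [h.haplotype_id for h in haps] == ["I", "II"]
        assert [h.frequency for h in haps] == [2, 1]
        assert haps[0].members == ("s1", "s2")

    def test_all_identical(self):
        haps = collapse_haplotypes(make_alignment(["ACGT"] * 5))
        assert len(haps) == 1
        assert haps[0].frequency == 5

    def test_frequencies_conserve_sample_count(self, geminate_dataset):
        alignments, _, _ = geminate_dataset
        aln = alignments["COI"]
        haps = collapse_haplotypes(aln)
        assert sum(h.frequency for h in haps) == len(aln)
        members = [m for h in haps for m in h.members]
        assert sorted(members) == sorted(aln.ids)

    def test_first_occurrence_ordering(self):
        aln = make_alignment(["TTTT", "ACGT", "TTTT"])
        haps = collapse_haplotypes(aln)
        assert haps[0].representative == "TTTT"
        assert haps[0].haplotype_id == "I"


class TestMutationalSteps:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", 0),
            ("ACGT", "TCGA", 2),
            ("ANGT", "ACGT", 0),  # ambiguous site excluded
            ("A-GT", "ACGT", 0),
        ],
    )
    def test_counts(self, a, b, expected):
        assert mutational_steps(a, b) == expected

    def test_unequal_length(self):
        with pytest.raises(Exception):
            mutational_steps("ACG", "ACGT")


def brute_force_mst_weight(n, weight):
    """Minimum spanning-tree weight by Prüfer-sequence enumeration."""
    if n == 1:
        return 0
    best = None
    for seq in itertools.product(range(n), repeat=n - 2):
        # decode Prüfer sequence into its tree's edges
        degree = [1] * n
        for x in seq:
            degree[x] += 1
        seq_list = list(seq)
        edges = []
        avail = sorted(i for i in range(n) if degree[i] == 1)
        work_degree = degree[:]
        for x in seq_list:
            leaf = min(i for i in range(n) if work_degree[i] == 1)
            edges.append((leaf, x))
            work_degree[leaf] = 0
            work_degree[x] -= 1
        last = [i for i in range(n) if work_degree[i] == 1]
        edges.append((last[0], last[1]))
        w = sum(weight[a][b] for a, b in edges)
        if best is None or w < best:
            best = w
    return best


class TestMSN:
    def test_three_haplotype_example(self):
        haps = [
            Haplotype("H1", "AAAA", ("a",)),
            Haplotype("H2", "AAAT", ("b",)),
            Haplotype("H3", "CCAT", ("c",)),
        ]
        # steps: H1-H2=1, H2-H3=2, H1-H3=3
        net = build_msn(haps)
        assert net.edges == (("H1", "H2", 1), ("H2", "H3", 2))
        assert net.total_steps == 3

    def test_singleton_network(self):
        net = build_msn([Haplotype("I", "ACGT", ("a",))])
        assert net.edges == ()

    def test_deterministic(self, geminate_dataset):
        alignments, _, _ = geminate_dataset
        haps = collapse_haplotypes(alignments["COI"])
        n1 = build_msn(haps)
        n2 = build_msn(haps)
        assert n1.edges == n2.edges

    @pytest.mark.parametrize("seed", range(10))
    def test_weight_matches_exhaustive_enumeration(self, seed):
        """MST weight equals the brute-force minimum over all spanning trees."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        length = 30
        bases = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(bases, length)) for _ in range(n)]
        haps = [Haplotype(f"H{i}", s, (f"x{i}",)) for i, s in enumerate(seqs)]
        weight = [[mutational_steps(a, b) for b in seqs] for a in seqs]
        net = build_msn(haps)
        assert net.total_steps == brute_force_mst_weight(n, weight)

    def test_spanning_tree_shape(self, geminate_dataset):
        alignments, _, _ = geminate_dataset
        haps = collapse_haplotypes(alignments["COI"])
        net = build_msn(haps)
        assert len(net.edges) == len(net.nodes) - 1
        # connectivity: union-find over edge list
        parent = {h.haplotype_id: h.haplotype_id for h in net.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b, _ in net.edges:
            parent[find(a)] = find(b)
        roots = {find(h.haplotype_id) for h in net.nodes}
        assert len(roots) == 1


class TestAlternativeLinks:
    def test_tied_edge_reported_without_changing_tree(self):
        # square of haplotypes with two equally minimal closing edges
        haps = [
            Haplotype("H1", "AAAA", ("a",)),
            Haplotype("H2", "AAAT", ("b",)),
            Haplotype("H3", "AATT", ("c",)),
            Haplotype("H4", "AATA", ("d",)),
        ]
        base = build_msn(haps)
        with_alt = build_msn(haps, include_alternatives=True)
        assert with_alt.edges == base.edges
        # the unused side of the square ties the bottleneck weight
        assert ("H1", "H4", 1) in with_alt.alternative_edges or (
            "H3", "H4", 1
        ) in with_alt.alternative_edges

    def test_no_alternatives_on_distinct_weights(self):
        haps = [
            Haplotype("H1", "AAAA", ("a",)),
            Haplotype("H2", "AAAT", ("b",)),
            Haplotype("H3", "CCAT", ("c",)),
        ]
        net = build_msn(haps, include_alternatives=True)
        assert net.alternative_edges == ()


def test_roman_labels():
    assert [roman(i) for i in (1, 2, 4, 9, 14)] == ["I", "II", "IV", "IX", "XIV"]
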