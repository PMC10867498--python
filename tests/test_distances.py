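"""Distance estimators: definitions, TN93 oracle, composite likelihood."""

import itertools
import math

import numpy as np
import pytest

from geminate_clock import (
    DistanceMatrix,
    GroupPartition,
    LocusConfig,
    SimulationConfig,
    mcl_distances,
    p_distance,
    pairwise_valid_sites,
    simulate_geminate,
    summarize_divergence,
    tn93_distance,
    tn93_distances,
)
from geminate_clock.errors import DistanceError, SaturationError

from conftest import make_alignment


class TestValidSites:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("AC-T", "ACGT", {1, 2, 4}),
            ("NNNN", "ACGT", set()),
            ("ACGT", "ACGT", {1, 2, 3, 4}),
            ("ARGT", "ACGT", {1, 3, 4}),  # ambiguity codes excluded
        ],
    )
    def test_definition(self, a, b, expected):
        assert pairwise_valid_sites(a, b) == expected

    def test_unequal_length(self):
        with pytest.raises(DistanceError):
            pairwise_valid_sites("ACG", "ACGT")


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "ACGA", 0.25),
            ("AC-T", "ACGA", 1 / 3),  # pairwise deletion leaves 3 sites
        ],
    )
    def test_values(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_no_valid_sites(self):
        with pytest.raises(DistanceError):
            p_distance("NNNN", "ACGT")


def tn93_reference(p1, p2, q, pi):
    """Independent evaluation of the closed-form TN93 distance."""
    pa, pc, pg, pt = pi
    pr, py = pa + pg, pc + pt
    return (
        -(2 * pa * pg / pr) * math.log(1 - pr * p1 / (2 * pa * pg) - q / (2 * pr))
        - (2 * pt * pc / py) * math.log(1 - py * p2 / (2 * pt * pc) - q / (2 * py))
        - 2
        * (pr * py - pa * pg * py / pr - pt * pc * pr / py)
        * math.log(1 - q / (2 * pr * py))
    )


def _constructed_pair(n_p1, n_p2, n_q, block=20):
    """Pair with symmetric substitutions so pooled frequencies stay equal."""
    a = list("A" * block + "C" * block + "G" * block + "T" * block)
    b = list(a)
    # mutual swaps preserve pooled counts: half A->G, half G->A, etc.
    for i in range(n_p1 // 2):
        b[i] = "G"  # A->G
        b[2 * block + i] = "A"  # G->A
    for i in range(n_p2 // 2):
        b[block + i] = "T"  # C->T
        b[3 * block + i] = "C"  # T->C
    off = block // 2
    for i in range(n_q // 2):
        b[off + i] = "C"  # A->C
        b[block + off + i] = "A"  # C->A
    return "".join(a), "".join(b)


class TestTN93:
    def test_identical_is_zero(self):
        assert tn93_distance("ACGT" * 25, "ACGT" * 25) == 0.0

    @pytest.mark.parametrize("n_p1, n_p2, n_q", [(8, 4, 4), (4, 2, 2), (12, 6, 2)])
    def test_matches_closed_form_oracle(self, n_p1, n_p2, n_q):
        a, b = _constructed_pair(n_p1, n_p2, n_q)
        n = len(a)
        expected = tn93_reference(n_p1 / n, n_p2 / n, n_q / n, (0.25,) * 4)
        assert tn93_distance(a, b) == pytest.approx(expected, abs=1e-10)

    def test_frozen_value_equal_frequencies(self):
        # P1=0.10, P2=0.05, Q=0.05 at equal frequencies:
        # d = -0.25 ln(0.55 * 0.75 * 0.9)
        a, b = _constructed_pair(8, 4, 4)
        expected = -0.25 * math.log(0.55 * 0.75 * 0.9)
        assert tn93_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_saturation_raises(self):
        a = "A" * 50 + "C" * 50
        b = "C" * 50 + "A" * 50  # all transversions: log argument <= 0
        with pytest.raises(SaturationError):
            tn93_distance(a, b)

    def test_correction_dominates_p_distance(self):
        """TN93's multiple-hit correction is non-negative on random pairs."""
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        checked = 0
        for _ in range(300):
            length = rng.integers(50, 400)
            a = "".join(rng.choice(bases, length))
            # mutate a fraction of sites
            b = list(a)
            n_mut = rng.integers(0, length // 3)
            for pos in rng.choice(length, size=n_mut, replace=False):
                b[pos] = rng.choice(bases)
            b = "".join(b)
            try:
                d_tn = tn93_distance(a, b)
            except SaturationError:
                continue
            assert d_tn >= p_distance(a, b) - 1e-12
            checked += 1
        assert checked > 250


class TestMCL:
    def test_identical_alignment_all_zero(self):
        aln = make_alignment(["ACGTACGTAC"] * 4)
        dm = mcl_distances(aln)
        assert np.all(dm.d == 0)

    def test_close_to_per_pair_tn93(self, geminate_dataset):
        """Shared-parameter distances track per-pair TN93 closely."""
        alignments, _, _ = geminate_dataset
        aln = alignments["COI"]
        dm_mcl = mcl_distances(aln)
        dm_tn = tn93_distances(aln)
        iu = np.triu_indices(len(aln), k=1)
        rel = np.abs(dm_mcl.d[iu] - dm_tn.d[iu]) / np.maximum(dm_tn.d[iu], 1e-9)
        assert rel.mean() < 0.05

    def test_recovers_generating_ratios(self):
        """Shared kappas estimated near the simulation truth."""
        from geminate_clock import TN93Params

        cfg = SimulationConfig(
            loci=(
                LocusConfig(
                    "L", 4000, 0.049, TN93Params((0.28, 0.18, 0.18, 0.36), 6.0, 6.0)
                ),
            ),
            n_per_clade=6,
            intra_clade_theta=0.01,
            seed=11,
        )
        alignments, _, _ = simulate_geminate(cfg)
        _, params = mcl_distances(alignments["L"], return_params=True)
        assert params.kappa1 == pytest.approx(6.0, rel=0.5)
        assert params.kappa2 == pytest.approx(6.0, rel=0.5)


class TestConsistency:
    def test_bias_shrinks_with_length(self):
        """Mean signed TN93 error is small at both L=500 and L=5000."""
        truth = 0.049 * 2.8  # divergence accumulated since the split
        errors = {}
        for length in (500, 5000):
            errs = []
            for seed in range(25):
                cfg = SimulationConfig(
                    loci=(LocusConfig("L", length, 0.049),),
                    n_per_clade=1,
                    intra_clade_theta=0.0,
                    seed=seed,
                )
                alignments, _, _ = simulate_geminate(cfg)
                a, b = (r.residues for r in alignments["L"].records)
                errs.append(tn93_distance(a, b) - truth)
            errors[length] = float(np.mean(errs))
        assert abs(errors[5000]) < 0.005
        assert abs(errors[500]) < 0.015


class TestDistanceMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(DistanceError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 0.1], [0.2, 0.0]]), "p")
        with pytest.raises(DistanceError):
            DistanceMatrix(("a", "b"), np.array([[0.1, 0.1], [0.1, 0.0]]), "p")
        with pytest.raises(DistanceError):
            DistanceMatrix(("a", "b"), np.array([[0.0, -0.1], [-0.1, 0.0]]), "p")

    def test_csv_round_trip(self, tmp_path):
        d = np.array([[0.0, 0.1, 0.2], [0.1, 0.0, 0.3], [0.2, 0.3, 0.0]])
        dm = DistanceMatrix(("a", "b", "c"), d, "tn93")
        p = tmp_path / "dm.csv"
        dm.to_csv(p)
        back = DistanceMatrix.from_csv(p, model="tn93")
        assert back.ids == dm.ids
        np.testing.assert_allclose(back.d, dm.d)


class TestSummarize:
    def test_single_pair_between(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 0.1], [0.1, 0.0]]), "p")
        part = GroupPartition({"a": ("g1", "g1"), "b": ("g2", "g2")})
        s = summarize_divergence(dm, part)
        assert s.within["g1"] is None and s.within["g2"] is None
        assert s.between[("g1", "g2")] == (0.1, 0.1, 0.1)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 11))
            ids = tuple(f"s{i}" for i in range(n))
            d = np.round(rng.random((n, n)), 3)
            d = 0.5 * (d + d.T)
            np.fill_diagonal(d, 0.0)
            groups = [f"g{rng.integers(0, 3)}" for _ in range(n)]
            part = GroupPartition({i: (g, g) for i, g in zip(ids, groups)})
            s = summarize_divergence(DistanceMatrix(ids, d, "p"), part)
            # brute-force oracle: enumerate every unordered pair directly
            within = {}
            between = {}
            for i, j in itertools.combinations(range(n), 2):
                gi, gj = groups[i], groups[j]
                if gi == gj:
                    within.setdefault(gi, []).append(d[i, j])
                else:
                    between.setdefault(tuple(sorted((gi, gj))), []).append(d[i, j])
            for g in set(groups):
                vals = within.get(g, [])
                if not vals:
                    assert s.within[g] is None
                else:
                    mean, lo, hi = s.within[g]
                    assert mean == pytest.approx(np.mean(vals))
                    assert (lo, hi) == (min(vals), max(vals))
            for key, vals in between.items():
                skey = key if key in s.between else (key[1], key[0])
                mean, lo, hi = s.between[skey]
                assert mean == pytest.approx(np.mean(vals))
                assert (lo, hi) == (min(vals), max(vals))

    def test_unlabeled_sample_rejected(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 0.1], [0.1, 0.0]]), "p")
        part = GroupPartition({"a": ("g1", "g1")})
        with pytest.raises(Exception, match="b"):
            summarize_divergence(dm, part)
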