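import dataclasses

import numpy as np
import pytest

from editnet.core import Cohort, PatternCounts, SiteSet, from_read_matrix
from editnet.simulate import GroupDesign, preset, sample_cohort
from editnet.stats import (
    PairTable,
    all_pairs,
    cluster_sites,
    dice_distance,
    g_statistic,
    jaccard_distance,
    pair_table,
    permutation_group_test,
    phi,
    phi_inference,
)


class TestPairTable:
    def test_all_edited(self, sites5):
        pc = PatternCounts("x", np.eye(32, dtype=int)[31] * 7)
        for i, j in sites5.pairs():
            t = pair_table(pc, i, j)
            assert (t.n11, t.n10, t.n01, t.n00) == (7, 0, 0, 0)

    def test_disjoint_patterns(self, sites5):
        counts = np.zeros(32, int)
        counts[0b10000] = 4  # only A edited
        counts[0b01000] = 6  # only B edited
        t = pair_table(PatternCounts("x", counts), 0, 1)
        assert (t.n11, t.n10, t.n01, t.n00) == (0, 4, 6, 0)

    def test_total_conserved(self, rng):
        pc = PatternCounts("r", rng.integers(0, 40, 32))
        for i, j in [(0, 4), (2, 3)]:
            assert pair_table(pc, i, j).N == pc.N

    def test_same_site_rejected(self, toy_counts2):
        with pytest.raises(ValueError):
            pair_table(toy_counts2, 1, 1)


class TestPhi:
    def test_hand_computed(self):
        assert phi(PairTable((0, 1), 40, 10, 10, 40)) == pytest.approx(0.6)

    def test_perfect_agreement(self):
        assert phi(PairTable((0, 1), 9, 0, 0, 9)) == pytest.approx(1.0)

    def test_independent_table(self):
        assert phi(PairTable((0, 1), 10, 10, 10, 10)) == pytest.approx(0.0)

    def test_zero_margin_undefined(self):
        assert np.isnan(phi(PairTable((0, 1), 5, 0, 5, 0)))

    def test_equals_pearson_on_expanded_reads(self, rng, sites5):
        rows = ["".join(map(str, rng.integers(0, 2, 5))) for _ in range(200)]
        pc = from_read_matrix(rows, "x", sites5)
        mat = np.array([[int(ch) for ch in r] for r in rows])
        for i, j in [(0, 1), (2, 4)]:
            expect = np.corrcoef(mat[:, i], mat[:, j])[0, 1]
            assert phi(pair_table(pc, i, j)) == pytest.approx(expect)


class TestPhiInference:
    def test_z_formula(self, sites5):
        # three individuals engineered to give phi = 0.5, 0.6, 0.7
        def table_counts(n11, n10, n01, n00):
            c = np.zeros(32, int)
            c[0b11000] = n11
            c[0b10000] = n10
            c[0b01000] = n01
            c[0b00000] = n00
            return c

        inds = [
            PatternCounts("a", table_counts(75, 25, 25, 75)),   # phi=0.5
            PatternCounts("b", table_counts(80, 20, 20, 80)),   # phi=0.6
            PatternCounts("c", table_counts(85, 15, 15, 85)),   # phi=0.7
        ]
        cohort = Cohort(sites=sites5, individuals=inds)
        res = phi_inference(cohort, (0, 1))
        assert res.mean == pytest.approx(0.6)
        assert res.sd == pytest.approx(0.1)
        assert res.z == pytest.approx(0.6 / (0.1 / np.sqrt(3)), rel=1e-6)

    def test_degenerate_all_zero(self, sites5):
        counts = np.zeros(32, int)
        counts[[0b11000, 0b10000, 0b01000, 0b00000]] = 10
        inds = [PatternCounts(f"i{k}", counts) for k in range(3)]
        cohort = Cohort(sites=sites5, individuals=inds)
        res = phi_inference(cohort, (0, 1))
        assert res.degenerate and res.p == 1.0

    def test_fdr_monotone(self, small_cohort):
        results = all_pairs(small_cohort)
        assert len(results) == 10
        for r in results:
            assert r.q is not None and r.q >= r.p - 1e-12


class TestDistances:
    def test_identical_columns(self):
        pc = PatternCounts("x", np.array([5, 0, 0, 5]))  # S=2, patterns 00/11
        assert jaccard_distance(pc, 0, 1) == 0.0
        assert dice_distance(pc, 0, 1) == 0.0

    def test_disjoint_columns(self):
        pc = PatternCounts("x", np.array([0, 5, 5, 0]))
        assert jaccard_distance(pc, 0, 1) == 1.0
        assert dice_distance(pc, 0, 1) == 1.0

    def test_hand_computed(self):
        # n11=30, n10=10, n01=10
        pc = PatternCounts("x", np.array([0, 10, 10, 30]))
        assert jaccard_distance(pc, 0, 1) == pytest.approx(0.4)
        assert dice_distance(pc, 0, 1) == pytest.approx(0.25)

    def test_dice_never_exceeds_jaccard(self, rng):
        pc = PatternCounts("r", rng.integers(1, 50, 32))
        for i, j in [(0, 1), (1, 3), (2, 4)]:
            assert dice_distance(pc, i, j) <= jaccard_distance(pc, i, j) + 1e-12


class TestClustering:
    def test_identical_individuals_full_support(self, sites5, rng):
        counts = rng.integers(1, 60, 32)
        inds = [PatternCounts(f"i{k}", counts) for k in range(5)]
        cohort = Cohort(sites=sites5, individuals=inds)
        dend = cluster_sites(cohort)
        assert len(dend.node_sets) == 4
        assert all(s == 1.0 for s in dend.supports)

    def test_strong_pair_merges_first(self):
        cohort = sample_cohort(preset("human-like", seed=5,
                                      reads_per_individual=3000))
        dend = cluster_sites(cohort)
        assert dend.node_sets[0] == frozenset({0, 1})  # sites A and B
        assert dend.supports[0] > 0.95

    def test_heights_nondecreasing(self, small_cohort):
        dend = cluster_sites(small_cohort)
        h = dend.linkage_matrix[:, 2]
        assert np.all(np.diff(h) >= -1e-12)

    def test_jaccard_dice_same_topology_on_preset(self):
        cohort = sample_cohort(preset("human-like", seed=5,
                                      reads_per_individual=3000))
        dj = cluster_sites(cohort, metric="jaccard")
        dd = cluster_sites(cohort, metric="dice")
        assert dj.node_sets == dd.node_sets

    def test_newick_roundtrips_supports(self, small_cohort):
        nwk = cluster_sites(small_cohort).to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 4


class TestGStatistic:
    def test_identical_proportions_zero(self):
        a = np.array([30, 20, 10])
        assert g_statistic(a, 2 * a) == 0.0

    def test_hand_computed(self):
        assert g_statistic(np.array([10, 0]), np.array([0, 10])) == \
            pytest.approx(40 * np.log(2))

    def test_category_permutation_invariant(self, rng):
        a = rng.integers(0, 50, 32)
        b = rng.integers(0, 50, 32)
        perm = rng.permutation(32)
        assert g_statistic(a, b) == pytest.approx(
            g_statistic(a[perm], b[perm])
        )

    def test_equals_mutual_information_form(self, rng):
        """G = 2N * MI(group; category) of the pooled table."""
        a = rng.integers(1, 50, 8).astype(float)
        b = rng.integers(1, 50, 8).astype(float)
        table = np.stack([a, b])
        N = table.sum()
        pij = table / N
        mi = (pij * np.log(
            pij / (pij.sum(1, keepdims=True) @ pij.sum(0, keepdims=True).reshape(1, -1))
        )).sum()
        assert g_statistic(a, b) == pytest.approx(2 * N * mi)


@pytest.fixture(scope="module")
def two_group_cohort():
    spec = preset("null", reads_per_individual=1000)
    spec = dataclasses.replace(
        spec, groups=(GroupDesign("ctrl", 10), GroupDesign("case", 10)),
        seed=17,
    )
    return sample_cohort(spec)


class TestPermutationTest:
    def test_identical_groups_p_one(self, sites5, rng):
        counts = rng.integers(1, 40, 32)
        inds = [PatternCounts(f"i{k}", counts) for k in range(6)]
        group = {f"i{k}": ("a" if k < 3 else "b") for k in range(6)}
        cohort = Cohort(sites=sites5, individuals=inds, group=group)
        res = permutation_group_test(cohort, reps=500, seed=1)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == 1.0

    def test_seed_reproducibility(self, two_group_cohort):
        r1 = permutation_group_test(two_group_cohort, reps=1000, seed=4)
        r2 = permutation_group_test(two_group_cohort, reps=1000, seed=4)
        assert r1.p_value == r2.p_value
        assert r1.n_greater_equal == r2.n_greater_equal

    def test_relabel_invariance(self, two_group_cohort):
        """Swapping the two group labels leaves the p-value unchanged."""
        swapped = Cohort(
            sites=two_group_cohort.sites,
            individuals=two_group_cohort.individuals,
            group={
                i: ("case" if g == "ctrl" else "ctrl")
                for i, g in two_group_cohort.group.items()
            },
        )
        r1 = permutation_group_test(two_group_cohort, reps=800, seed=9)
        r2 = permutation_group_test(swapped, reps=800, seed=9)
        assert r1.statistic == pytest.approx(r2.statistic)
        # same null distribution by symmetry of the subset draw
        assert abs(r1.p_value - r2.p_value) < 0.05

    def test_distinct_truths_detected(self):
        spec = preset("null", reads_per_individual=5000)
        alt_cpts = dict(spec.cpts)
        alt_cpts[0] = np.array([0.45])  # shift site A editing level
        spec = dataclasses.replace(
            spec,
            groups=(GroupDesign("ctrl", 10),
                    GroupDesign("case", 10, cpts=alt_cpts)),
            seed=23,
        )
        cohort = sample_cohort(spec)
        res = permutation_group_test(cohort, reps=2000, seed=3)
        assert res.p_value <= 0.01

    def test_argument_validation(self, two_group_cohort, small_cohort):
        with pytest.raises(ValueError):
            permutation_group_test(two_group_cohort, reps=0)
        one_group = Cohort(
            sites=small_cohort.sites,
            individuals=small_cohort.individuals,
        )
        with pytest.raises(ValueError, match="two groups"):
            permutation_group_test(one_group, reps=10)
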