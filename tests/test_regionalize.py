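"""beta-sim turnover, UPGMA, indicator species, optimal cluster count."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from sdmstack import beta_sim, dissimilarity_matrix, indval, optimal_k, upgma
from sdmstack.regionalize import cut_tree, dendrogram_to_newick
from tests.conftest import random_pam


class TestBetaSim:
    def test_identical_assemblages_zero(self):
        s = {"a", "b", "c", "d", "e"}
        assert beta_sim(s, set(s)) == 0.0

    def test_disjoint_assemblages_one(self):
        assert beta_sim({"a", "b", "c"}, {"d", "e", "f", "g"}) == 1.0

    def test_component_formula(self):
        # a=2 shared, b=1, c=3 unique -> min(1,3)/(1+2) = 1/3
        i = {"s1", "s2", "u1"}
        j = {"s1", "s2", "v1", "v2", "v3"}
        assert beta_sim(i, j) == pytest.approx(1 / 3)

    def test_richness_surplus_of_richer_cell_irrelevant(self):
        i = {"s1", "s2", "u1"}
        j = {"s1", "s2", "v1", "v2", "v3"}
        j_big = j | {f"extra{k}" for k in range(20)}
        assert beta_sim(i, j) == beta_sim(i, j_big)

    def test_both_empty_errors(self):
        with pytest.raises(ValueError):
            beta_sim(set(), set())


class TestDissimilarityMatrix:
    def test_matches_set_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        pam = random_pam(rng, n_cells=40, n_species=25)
        dm = dissimilarity_matrix(pam)
        sets = pam.cell_sets()
        for _ in range(1000):
            i, j = rng.integers(dm.n, size=2)
            if i == j:
                continue
            expect = beta_sim(sets[dm.cell_ids[i]], sets[dm.cell_ids[j]])
            assert dm.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_symmetric_zero_diagonal_unit_interval(self):
        rng = np.random.default_rng(1)
        dm = dissimilarity_matrix(random_pam(rng))
        np.testing.assert_array_equal(dm.values, dm.values.T)
        np.testing.assert_array_equal(np.diag(dm.values), 0.0)
        assert dm.values.min() >= 0 and dm.values.max() <= 1

    def test_identical_rows_have_zero_dissimilarity(self):
        rng = np.random.default_rng(2)
        pam = random_pam(rng, n_cells=10)
        pam.pa.iloc[3] = pam.pa.iloc[7]
        dm = dissimilarity_matrix(pam)
        i = np.flatnonzero(dm.cell_ids == 3)[0]
        j = np.flatnonzero(dm.cell_ids == 7)[0]
        assert dm.values[i, j] == 0.0

    def test_empty_cells_excluded(self):
        rng = np.random.default_rng(3)
        pam = random_pam(rng, n_cells=12)
        pam.pa.iloc[5] = 0
        dm = dissimilarity_matrix(pam)
        assert 5 in dm.excluded_cells and 5 not in dm.cell_ids

    def test_genus_aggregation_toy(self):
        # 3 cells; congeneric species collapse so shared genera can exceed
        # shared species, lowering turnover at genus level
        pa = pd.DataFrame(
            [[1, 0, 0], [0, 1, 1], [1, 1, 0]],
            columns=["Acer_a", "Acer_b", "Pinus_a"])
        from sdmstack.stacking import PresenceAbsenceMatrix
        pam = PresenceAbsenceMatrix(pa=pa, thresholds=pd.DataFrame())
        gmap = {"Acer_a": "Acer", "Acer_b": "Acer", "Pinus_a": "Pinus"}
        d_sp = dissimilarity_matrix(pam, level="species")
        d_ge = dissimilarity_matrix(pam, level="genus", genus_map=gmap)
        # cells 0 and 1 share no species but share the genus Acer
        assert d_sp.values[0, 1] == 1.0
        assert d_ge.values[0, 1] < 1.0

    def test_genus_level_requires_map(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            dissimilarity_matrix(random_pam(rng), level="genus")


def _naive_upgma_cophenetic(D: np.ndarray) -> np.ndarray:
    """Independent O(n^3) average-linkage agglomeration oracle."""
    n = D.shape[0]
    members = {i: [i] for i in range(n)}
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    active = list(range(n))
    while len(active) > 1:
        best = min(
            ((dist[(a, b)], a, b) for ai, a in enumerate(active)
             for b in active[ai + 1:]),
            key=lambda t: (t[0], t[1], t[2]))
        d, a, b = best
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = d
        na, nb = len(members[a]), len(members[b])
        for c in active:
            if c in (a, b):
                continue
            key_ac = (min(a, c), max(a, c))
            key_bc = (min(b, c), max(b, c))
            dist[key_ac] = (na * dist[key_ac] + nb * dist[key_bc]) / (na + nb)
        members[a] += members[b]
        active.remove(b)
    return coph


class TestUPGMA:
    def test_three_item_hand_agglomeration(self):
        D = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]])
        Z = upgma(D)
        assert Z[0, 2] == pytest.approx(0.1)  # first merge A,B at 0.1
        assert Z[1, 2] == pytest.approx(0.5)  # then C at 0.5
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_ultrametric_input_reproduced_exactly(self):
        # build an ultrametric from a random tree by max-linkage property
        rng = np.random.default_rng(5)
        D0 = squareform(rng.random(28))
        Z0 = upgma(D0)
        U = squareform(cophenet(Z0))
        Z = upgma(U)
        np.testing.assert_allclose(squareform(cophenet(Z)), U, atol=1e-12)

    def test_matches_naive_oracle_up_to_n20(self):
        rng = np.random.default_rng(6)
        for n in (8, 14, 20):
            D = squareform(rng.random(n * (n - 1) // 2))
            Z = upgma(D)
            np.testing.assert_allclose(squareform(cophenet(Z)),
                                       _naive_upgma_cophenetic(D), atol=1e-10)

    def test_newick_export_parses_with_all_tips(self):
        import io
        from Bio import Phylo
        rng = np.random.default_rng(7)
        D = squareform(rng.random(15))
        Z = upgma(D)
        nwk = dendrogram_to_newick(Z, labels=[f"cell{i}" for i in range(6)])
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == \
            [f"cell{i}" for i in range(6)]

    def test_single_item_errors(self):
        with pytest.raises(ValueError):
            upgma(np.zeros((1, 1)))


class TestIndval:
    def test_perfect_indicator_scores_100(self):
        labels = np.array([0] * 5 + [1] * 5)
        M = np.zeros((10, 1), dtype=np.int8)
        M[:5, 0] = 1  # everywhere in cluster 0, nowhere else
        res = indval(M, labels, n_perm=99, seed=0)
        assert res["indval"].iloc[0] == pytest.approx(100.0)
        assert res["p"].iloc[0] < 0.05

    @pytest.mark.parametrize("k", [2, 4])
    def test_ubiquitous_species_scores_100_over_k(self, k):
        labels = np.repeat(np.arange(k), 6)
        M = np.ones((6 * k, 1), dtype=np.int8)
        res = indval(M, labels, n_perm=19, seed=0)
        assert res["indval"].iloc[0] == pytest.approx(100.0 / k)

    def test_cluster_relabeling_leaves_scores_unchanged(self):
        rng = np.random.default_rng(8)
        M = (rng.random((20, 10)) < 0.4).astype(np.int8)
        labels = rng.integers(0, 3, 20)
        r1 = indval(M, labels, n_perm=49, seed=1)
        r2 = indval(M, (labels + 1) % 3, n_perm=49, seed=1)
        np.testing.assert_allclose(r1["indval"], r2["indval"])

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            indval(np.ones((5, 2), dtype=np.int8), np.zeros(5), n_perm=9)


class TestOptimalK:
    def test_recovers_four_regions_with_high_ari(self, region_world,
                                                 region_pam):
        reg = optimal_k(region_pam, k_range=range(2, 9), subsample_size=200,
                        n_repeats=2, n_perm=49, seed=5)
        assert reg.chosen_k == 4
        truth = region_world.true_regions[reg.cell_ids]
        assert adjusted_rand_score(truth, reg.labels) > 0.8

    def test_curve_complete_and_deterministic(self, region_pam):
        r1 = optimal_k(region_pam, k_range=range(2, 7), subsample_size=150,
                       n_repeats=2, n_perm=29, seed=9)
        r2 = optimal_k(region_pam, k_range=range(2, 7), subsample_size=150,
                       n_repeats=2, n_perm=29, seed=9)
        assert list(r1.summed_p.index) == list(range(2, 7))
        assert not r1.summed_p.isna().any().any()
        pd.testing.assert_frame_equal(r1.summed_p, r2.summed_p)

    def test_labels_partition_all_retained_cells(self, region_pam):
        reg = optimal_k(region_pam, k_range=range(2, 6), subsample_size=150,
                        n_repeats=1, n_perm=19, seed=2)
        assert len(reg.labels) == len(reg.cell_ids)
        assert set(reg.labels) == set(range(reg.chosen_k))

    def test_k_max_must_be_below_subsample(self, region_pam):
        with pytest.raises(ValueError):
            optimal_k(region_pam, k_range=range(2, 100), subsample_size=50,
                      n_repeats=1, n_perm=9)


def test_cut_tree_exact_k_under_ties():
    # saturated dissimilarities (many exact 1.0 ties) must still cut into k
    D = np.ones((6, 6)) - np.eye(6)
    Z = upgma(D)
    for k in (2, 3, 4):
        labels = cut_tree(Z, k)
        assert len(set(labels)) == k


def test_optimal_k_alternative_criterion_also_recovers(region_pam,
                                                       region_world):
    reg = optimal_k(region_pam, k_range=range(2, 7), subsample_size=150,
                    n_repeats=1, n_perm=49, seed=4,
                    criterion="n_significant")
    assert reg.chosen_k == 4
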