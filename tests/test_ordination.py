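"""NMDS, environmental vector fitting, Getis-Ord Gi*."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from sdmstack import dissimilarity_matrix, envfit, gi_star, nmds, ret_table
from sdmstack.core import EnvMatrix, GridDomain
from sdmstack.ordination import OrdinationResult, coarsen, kruskal_stress
from tests.conftest import random_pam


def _ord(scores):
    scores = scores - scores.mean(axis=0)
    return OrdinationResult(scores=scores, stress=0.1, n_starts=1,
                            best_start=0, start_stress=np.array([0.1]))


class TestNMDS:
    def test_planar_configuration_reaches_zero_stress(self):
        rng = np.random.default_rng(0)
        pts = rng.random((50, 2))
        D = squareform(pdist(pts))
        res = nmds(D, n_starts=5, seed=1)
        assert res.stress <= 1e-3

    def test_equilateral_triangle_zero_stress(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = nmds(D, n_starts=3, seed=0)
        assert res.stress <= 1e-6

    def test_same_seed_identical_scores(self):
        rng = np.random.default_rng(2)
        pam = random_pam(rng, n_cells=25)
        dm = dissimilarity_matrix(pam)
        r1 = nmds(dm, n_starts=3, seed=7)
        r2 = nmds(dm, n_starts=3, seed=7)
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_scores_centered_and_best_stress_minimal(self):
        rng = np.random.default_rng(3)
        pam = random_pam(rng, n_cells=30)
        res = nmds(dissimilarity_matrix(pam), n_starts=4, seed=0)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-9)
        assert res.stress == res.start_stress.min()

    def test_stress_invariant_under_rigid_motion_and_scaling(self):
        rng = np.random.default_rng(4)
        pts = rng.random((20, 2))
        D = squareform(pdist(pts)) + 0.05 * squareform(
            rng.random(190))
        np.fill_diagonal(D, 0)
        D = (D + D.T) / 2
        scores = rng.standard_normal((20, 2))
        s0 = kruskal_stress(D, scores)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        assert kruskal_stress(D, 3.2 * scores @ R) == pytest.approx(s0,
                                                                    abs=1e-10)
        assert kruskal_stress(D, scores @ np.diag([1, -1])) == pytest.approx(
            s0, abs=1e-10)


class TestEnvfit:
    def test_predictor_equal_to_axis_one(self):
        rng = np.random.default_rng(5)
        scores = rng.standard_normal((80, 2))
        env = EnvMatrix(pd.DataFrame({"x": scores[:, 0]}))
        res = envfit(_ord(scores), env, n_perm=99, seed=0)
        row = res.table.loc["x"]
        assert row["r2"] == pytest.approx(1.0, abs=1e-10)
        assert abs(row["cos1"]) == pytest.approx(1.0, abs=1e-6)
        assert row["p"] == pytest.approx(1 / 100)

    def test_diagonal_predictor_direction(self):
        rng = np.random.default_rng(6)
        scores = rng.standard_normal((100, 2))
        # orthonormalize axes so the coefficient vector is exactly (1,1)
        q, _ = np.linalg.qr(scores - scores.mean(axis=0))
        y = q[:, 0] + q[:, 1]
        env = EnvMatrix(pd.DataFrame({"d": y}))
        res = envfit(_ord(q), env, n_perm=49, seed=0)
        row = res.table.loc["d"]
        assert abs(row["cos1"]) == pytest.approx(1 / np.sqrt(2), abs=1e-8)
        assert abs(row["cos2"]) == pytest.approx(1 / np.sqrt(2), abs=1e-8)

    def test_r2_matches_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        scores = rng.standard_normal((60, 2))
        y = rng.standard_normal(60)
        env = EnvMatrix(pd.DataFrame({"y": y}))
        res = envfit(_ord(scores), env, n_perm=9, seed=0)
        Xd = np.column_stack([np.ones(60), scores - scores.mean(axis=0)])
        beta, *_ = np.linalg.lstsq(Xd, (y - y.mean()) / y.std(), rcond=None)
        fitted = Xd @ beta
        r2 = ((fitted - fitted.mean()) ** 2).sum() / (
            ((y - y.mean()) / y.std()) ** 2).sum()
        assert res.table.loc["y", "r2"] == pytest.approx(r2, abs=1e-10)

    def test_independent_predictor_type_one_rate(self):
        rng = np.random.default_rng(8)
        scores = rng.standard_normal((80, 2))
        ordn = _ord(scores)
        hits = 0
        reps = 200
        for i in range(reps):
            env = EnvMatrix(pd.DataFrame({"x": rng.standard_normal(80)}))
            res = envfit(ordn, env, n_perm=99, alpha=0.05, seed=i)
            hits += bool(res.table["p"].iloc[0] < 0.05)
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 4 * se

    def test_constant_predictor_flagged(self):
        rng = np.random.default_rng(9)
        scores = rng.standard_normal((30, 2))
        env = EnvMatrix(pd.DataFrame({"c": np.full(30, 3.0)}))
        res = envfit(_ord(scores), env, n_perm=9, seed=0)
        assert res.table.loc["c", "r2"] == 0.0
        assert res.table.loc["c", "p"] == 1.0


class TestGiStar:
    def _oracle(self, x, region):
        x = np.asarray(x, dtype=float)
        n = x.size
        n_r = len(region)
        xbar = x.mean()
        s = np.sqrt(np.mean(x ** 2) - xbar ** 2)
        num = sum(x[i] for i in region) - n_r * xbar
        return num / (s * np.sqrt((n * n_r - n_r ** 2) / (n - 1)))

    def test_region_at_global_mean_is_zero(self):
        # symmetric values; the region holds the middle pair, whose values
        # equal the global mean exactly
        v = np.array([-2.0, -1.0, 0.0, 0.0, 1.0, 2.0])
        assert gi_star(v, [2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_shifted_region_exceeds_threshold(self):
        """A 50-cell region moved +3 global SD on 1,200 cells has z > 2."""
        rng = np.random.default_rng(10)
        x = rng.standard_normal(1200)
        region = rng.choice(1200, 50, replace=False)
        x[region] += 3 * x.std()
        assert gi_star(x, region) > 2

    def test_complement_region_has_opposite_sign(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(100)
        region = list(range(30))
        comp = list(range(30, 100))
        assert np.sign(gi_star(x, region)) == -np.sign(gi_star(x, comp))

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.standard_normal(80)
            k = rng.integers(5, 40)
            region = rng.choice(80, k, replace=False).tolist()
            assert gi_star(x, region) == pytest.approx(
                self._oracle(x, region), abs=1e-10)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            gi_star(np.ones(10), [1, 2])
        with pytest.raises(ValueError):
            gi_star(np.arange(10.0), range(10))


class TestRetTable:
    def test_coarsen_factor_one_is_identity(self, region_world, region_pam):
        from sdmstack import optimal_k
        reg = optimal_k(region_pam, k_range=range(2, 6), subsample_size=150,
                        n_repeats=1, n_perm=19, seed=2)
        t1 = ret_table(reg, region_world.grid, region_world.env,
                       coarsen_factor=1)
        # direct per-cell computation
        full_labels = np.full(region_world.grid.n_cells, -1)
        full_labels[reg.cell_ids] = reg.labels
        r0 = np.flatnonzero(full_labels == 0)
        direct = gi_star(region_world.env["precip"], r0)
        assert t1.loc["precip", "region0"] == pytest.approx(direct, abs=1e-10)

    def test_not_all_regions_positive_for_one_predictor(self, region_world,
                                                        region_pam):
        from sdmstack import optimal_k
        reg = optimal_k(region_pam, k_range=range(2, 6), subsample_size=150,
                        n_repeats=1, n_perm=19, seed=2)
        tab = ret_table(reg, region_world.grid, region_world.env,
                        coarsen_factor=2)
        zcols = [c for c in tab.columns if not c.endswith("_sig")]
        for pred in tab.index:
            z = tab.loc[pred, zcols].to_numpy(dtype=float)
            z = z[np.isfinite(z)]
            assert not np.all(z > 0)  # global-mean constraint

    def test_gradient_region_is_significant_hotspot(self, region_world,
                                                    region_pam):
        # the region sitting highest on the longitudinal precipitation
        # gradient must show a positive significant Gi* for it
        from sdmstack import optimal_k
        reg = optimal_k(region_pam, k_range=range(2, 6), subsample_size=150,
                        n_repeats=1, n_perm=19, seed=2)
        full_labels = np.full(region_world.grid.n_cells, -1)
        full_labels[reg.cell_ids] = reg.labels
        means = [region_world.env["precip"][full_labels == r].mean()
                 for r in range(reg.chosen_k)]
        top = int(np.argmax(means))
        tab = ret_table(reg, region_world.grid, region_world.env,
                        coarsen_factor=2)
        assert tab.loc["precip", f"region{top}"] > 2
        assert bool(tab.loc["precip", f"region{top}_sig"])


def test_coarsen_majority_vote_and_mean():
    g = GridDomain.regular(4, 4)
    env = EnvMatrix(pd.DataFrame({"x": np.arange(16.0)}, index=g.cell_ids))
    labels = np.array([0] * 8 + [1] * 8)
    env_c, lab_c = coarsen(g, env, labels, factor=2)
    assert env_c.n_cells == 4
    # south-west block = cells 0,1,4,5 -> mean 2.5
    assert env_c["x"][0] == pytest.approx((0 + 1 + 4 + 5) / 4)
    assert lab_c[0] == 0 and lab_c[-1] == 1
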