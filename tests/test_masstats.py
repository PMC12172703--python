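"""Robust statistics, level-1 regression, clustering, and the level-2 test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import taptone as tt
from taptone import masstats
from taptone.masstats import (DegenerateSampleError, _grid_graph, find_clusters,
                              second_level, trimmed_mean, winsorized_variance,
                              yuen_t_one_sample)


def yuen_oracle(x, trim=0.2):
    """Independent brute-force evaluation of the Yuen one-sample formula."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    g = int(np.floor(trim * n))
    tm = x[g:n - g].mean()
    w = x.copy()
    w[:g] = x[g]
    w[n - g:] = x[n - g - 1]
    sw = np.sqrt(np.sum((w - w.mean()) ** 2) / (n - 1))
    t = tm / (sw / ((1 - 2 * trim) * np.sqrt(n)))
    return t, n - 2 * g - 1


def flood_fill_oracle(mask, adjacency):
    """Exhaustive BFS labeling of (channel, point) clusters."""
    C, P = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    clusters = []
    for c0 in range(C):
        for p0 in range(P):
            if not mask[c0, p0] or seen[c0, p0]:
                continue
            comp, stack = [], [(c0, p0)]
            seen[c0, p0] = True
            while stack:
                c, p = stack.pop()
                comp.append((c, p))
                for pn in (p - 1, p + 1):
                    if 0 <= pn < P and mask[c, pn] and not seen[c, pn]:
                        seen[c, pn] = True
                        stack.append((c, pn))
                for cn in range(C):
                    if adjacency[c, cn] and mask[cn, p] and not seen[cn, p]:
                        seen[cn, p] = True
                        stack.append((cn, p))
            clusters.append(frozenset(comp))
    return set(clusters)


class TestTrimmedMean:
    def test_one_to_ten(self):
        assert trimmed_mean(np.arange(1, 11), 0.2) == 5.5

    def test_trim_zero_is_mean(self):
        x = np.random.default_rng(0).standard_normal(37)
        assert abs(trimmed_mean(x, 0.0) - x.mean()) < 1e-12

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-1e6, 1e6), st.integers(1, 40))
    def test_constant_sample(self, v, n):
        assert trimmed_mean(np.full(n, v), 0.2) == pytest.approx(v)

    def test_empty_rejected(self):
        with pytest.raises(DegenerateSampleError):
            trimmed_mean(np.empty(0))


class TestYuenT:
    def test_symmetric_sample_t_zero(self):
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        t, df, p = yuen_t_one_sample(x)
        assert t == 0.0
        assert p == 1.0

    def test_matches_hand_oracle_one_to_ten(self):
        x = np.arange(1.0, 11.0)
        t, df, p = yuen_t_one_sample(x, 0.2)
        # winsorized data is [3,3,3,4,5,6,7,8,8,8]
        w = np.array([3, 3, 3, 4, 5, 6, 7, 8, 8, 8], dtype=float)
        sw = w.std(ddof=1)
        t_expect = 5.5 / (sw / (0.6 * np.sqrt(10)))
        assert t == pytest.approx(t_expect, abs=1e-12)
        assert df == 5

    def test_shift_monotone(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(15)
        ts = [yuen_t_one_sample(x + c)[0] for c in (-1.0, 0.0, 1.0, 2.0)]
        assert all(b > a for a, b in zip(ts, ts[1:]))

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            yuen_t_one_sample(np.full(10, 2.0))


class TestLevel1:
    def test_noiseless_exact_interpolation(self):
        n = 20
        rng = np.random.default_rng(0)
        usage = rng.uniform(0, 5, n)
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float), usage])
        Y = (1.0 + 3.0 * X[:, 1] + 2.0 * X[:, 2])[:, None, None] * np.ones((1, 2, 3))
        res = masstats.level1_regress(Y, X)
        assert res.included
        assert np.allclose(res.betas[..., 0], 1.0, atol=1e-9)
        assert np.allclose(res.betas[..., 1], 3.0, atol=1e-9)
        assert np.allclose(res.betas[..., 2], 2.0, atol=1e-9)

    def test_too_few_bins_excluded(self):
        X = np.column_stack([np.ones(9), np.arange(9.0),
                             np.random.default_rng(0).uniform(0, 5, 9)])
        res = masstats.level1_regress(np.zeros((9, 2, 3)), X)
        assert not res.included
        assert res.reason == "too-few-bins"

    def test_rank_deficient_excluded(self):
        n = 12
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float),
                             np.arange(n, dtype=float)])  # usage == time
        res = masstats.level1_regress(np.zeros((n, 2, 3)), X)
        assert not res.included
        assert res.reason == "rank-deficient"

    def test_matches_normal_equations(self):
        # oracle: explicit (X'X)^-1 X'Y
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = rng.integers(10, 25)
            X = np.column_stack([np.ones(n), np.arange(n, dtype=float),
                                 rng.uniform(0, 5, n)])
            Y = rng.standard_normal((n, 3, 4))
            res = masstats.level1_regress(Y, X)
            expect = np.linalg.solve(X.T @ X, X.T @ Y.reshape(n, -1))
            got = np.moveaxis(res.betas, -1, 0).reshape(3, -1)
            assert np.allclose(got, expect, atol=1e-8)

    def test_irls_matches_ols_on_clean_data(self):
        rng = np.random.default_rng(3)
        n = 30
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float),
                             rng.uniform(0, 5, n)])
        Y = (X @ np.array([1.0, 0.5, -2.0]))[:, None, None] * np.ones((1, 2, 2))
        a = masstats.level1_regress(Y, X, method="ols")
        b = masstats.level1_regress(Y, X, method="irls")
        assert np.allclose(a.betas, b.betas, atol=1e-6)


class TestSubjectFilter:
    def _res(self, usage_sd, included=True):
        return masstats.Level1Result(np.zeros((2, 3, 3)), np.zeros((2, 3)),
                                     included, None, 20, usage_sd)

    def test_low_usage_sd_removed(self):
        keep = masstats.filter_level2_subjects(
            [self._res(0.0), self._res(1.5), self._res(2.0)])
        assert keep == [1, 2]

    def test_boundary_is_strict(self):
        keep = masstats.filter_level2_subjects(
            [self._res(1.0), self._res(1.01), self._res(3.0)])
        assert keep == [1, 2]

    def test_all_constant_usage_error(self):
        with pytest.raises(DegenerateSampleError):
            masstats.filter_level2_subjects([self._res(0.0), self._res(0.5)])


class TestFindClusters:
    def test_empty_mask(self, montage16):
        out = find_clusters(np.ones((16, 5)), np.zeros((16, 5), dtype=bool),
                            montage16.adjacency)
        assert out == []

    def test_full_mask_single_cluster(self, montage16):
        F = np.random.default_rng(0).uniform(1, 2, (16, 5))
        out = find_clusters(F, np.ones((16, 5), dtype=bool), montage16.adjacency)
        assert len(out) == 1
        assert out[0].mass == pytest.approx(F.sum())

    def test_chain_montage_two_patches(self):
        # 4-channel chain: adjacency 0-1-2-3
        adj = np.zeros((4, 4), dtype=bool)
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = True
        F = np.arange(20.0).reshape(4, 5) + 1
        mask = np.zeros((4, 5), dtype=bool)
        mask[0:2, 0:2] = True      # patch A
        mask[3, 3:5] = True        # patch B
        out = find_clusters(F, mask, adj)
        got = {frozenset(c.members): c.mass for c in out}
        oracle = flood_fill_oracle(mask, adj)
        assert set(got) == oracle
        for comp in oracle:
            assert got[comp] == pytest.approx(sum(F[c, p] for c, p in comp))

    def test_random_masks_match_flood_fill(self):
        rng = np.random.default_rng(7)
        adj = tt.make_montage(6).adjacency
        for _ in range(50):
            mask = rng.random((6, 8)) < 0.35
            F = rng.uniform(0.5, 3.0, (6, 8))
            got = {frozenset(c.members) for c in find_clusters(F, mask, adj)}
            assert got == flood_fill_oracle(mask, adj)


class TestSecondLevel:
    def test_f_equals_t_squared(self, montage16):
        rng = np.random.default_rng(0)
        betas = rng.standard_normal((12, 16, 10))
        res = second_level(betas, montage16.adjacency, B=60, seed=0)
        assert np.allclose(res.f_map, res.t_map**2, atol=0, rtol=0)

    def test_centering_makes_null_well_formed(self, montage16):
        rng = np.random.default_rng(1)
        betas = rng.standard_normal((12, 16, 10)) + 3.0
        gm = trimmed_mean(betas.reshape(12, -1), 0.2, axis=0)
        centered = betas.reshape(12, -1) - gm
        assert np.abs(trimmed_mean(centered, 0.2, axis=0)).max() < 1e-10

    def test_planted_patch_detected(self, montage16):
        """A patch whose group trimmed mean is 5x the between-subject SD
        must come out significant in every run."""
        rng = np.random.default_rng(2)
        for trial in range(3):
            betas = rng.standard_normal((20, 16, 40))
            betas[:, 2:5, 10:20] += 5.0
            res = second_level(betas, montage16.adjacency, B=200, seed=trial)
            sig = res.significant_clusters
            assert sig
            members = set().union(*(c.members for c in sig))
            planted = {(c, p) for c in range(2, 5) for p in range(10, 20)}
            assert planted <= members

    def test_seeded_determinism(self, montage16):
        rng = np.random.default_rng(3)
        betas = rng.standard_normal((10, 16, 8))
        a = second_level(betas, montage16.adjacency, B=80, seed=11)
        b = second_level(betas, montage16.adjacency, B=80, seed=11)
        assert np.array_equal(a.t_map, b.t_map)
        assert np.array_equal(a.max_mass_null, b.max_mass_null)
        assert [c.p for c in a.clusters] == [c.p for c in b.clusters]

    def test_effect_monotonicity(self, montage16):
        """On a fixed noise realization, a larger planted effect never
        shrinks the detected cluster mass."""
        rng = np.random.default_rng(4)
        noise = rng.standard_normal((15, 16, 20))
        masses = []
        for eff in (2.0, 4.0, 8.0):
            betas = noise.copy()
            betas[:, 0:3, 5:12] += eff
            res = second_level(betas, montage16.adjacency, B=60, seed=5)
            masses.append(max((c.mass for c in res.clusters), default=0.0))
        assert masses[0] <= masses[1] <= masses[2]

    def test_p_value_floor(self, montage16):
        rng = np.random.default_rng(5)
        betas = rng.standard_normal((12, 16, 10))
        betas[:, 0:4, :] += 10.0
        res = second_level(betas, montage16.adjacency, B=100, seed=6)
        assert all(c.p >= 1.0 / 101 for c in res.clusters)

    def test_too_few_subjects_rejected(self, montage16):
        with pytest.raises(DegenerateSampleError):
            second_level(np.zeros((4, 16, 5)), montage16.adjacency, B=60)

    def test_small_b_warns(self, montage16):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="B < 50"):
            second_level(rng.standard_normal((8, 16, 4)),
                         montage16.adjacency, B=20, seed=0)


class TestSignFlipNull:
    def test_signflip_fwer_near_nominal(self):
        """The sign-flip variant of the cluster-mass null is close to its
        nominal familywise error rate on i.i.d. global-null maps."""
        fw = masstats.fwer_calibration(n_datasets=100, B=200, seed=101,
                                       null="signflip")
        assert 0.01 <= fw <= 0.12
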