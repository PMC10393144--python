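"""Statistical engine: t statistics, permutation tests, effect sizes, TFCE."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps

from esport_erp import stats
from esport_erp.montage import channel_adjacency

from conftest import brute_force_tfce


class TestWelchT:
    def test_matches_scipy_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 30))
            b = rng.normal(1.0, 2.0, size=rng.integers(3, 30))
            t, df = stats.welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert df == pytest.approx(ref.df, rel=1e-12)

    def test_identical_samples_give_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        t, _ = stats.welch_t(a, a)
        assert t == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(0.5, 1.5, size=9)
        t1, _ = stats.welch_t(a, b)
        t2, _ = stats.welch_t(3.7 * a, 3.7 * b)
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_zero_variance_equal_means(self):
        t, _ = stats.welch_t([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0

    def test_welch_t_map_matches_scalar(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(6, 11))
        B = rng.normal(0.3, 1.0, size=(8, 11))
        tmap = stats.welch_t_map(A, B)
        for j in range(11):
            t, _ = stats.welch_t(A[:, j], B[:, j])
            assert tmap[j] == pytest.approx(t, rel=1e-12)


class TestPermutationTest:
    def test_exact_enumeration_matches_brute_force(self):
        a = np.array([1.1, 2.9, 0.3])
        b = np.array([4.0, 5.2, 3.7])
        t_obs, _, p = stats.permutation_test(a, b, n_perm=100_000)
        pooled = np.concatenate([a, b])
        t_all = []
        for idx in itertools.combinations(range(6), 3):
            ia = np.array(idx)
            ib = np.setdiff1d(np.arange(6), ia)
            t_all.append(stats.welch_t(pooled[ia], pooled[ib])[0])
        p_brute = np.mean(np.abs(t_all) >= abs(t_obs) - 1e-12)
        assert len(t_all) == 20
        assert p == pytest.approx(p_brute, abs=1e-12)

    def test_identical_samples_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        _, _, p = stats.permutation_test(a, a.copy(), n_perm=2000, seed=0)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=12), rng.normal(0.8, 1, size=12)
        r1 = stats.permutation_test(a, b, n_perm=3000, seed=42)
        r2 = stats.permutation_test(a, b, n_perm=3000, seed=42)
        assert r1 == r2

    def test_strong_effect_small_p(self):
        a = np.zeros(10) + np.arange(10) * 0.01
        b = a + 5.0
        _, _, p = stats.permutation_test(a, b, n_perm=2000, seed=0)
        assert p < 0.01


class TestHedgesG:
    def test_exact_vs_approximate_correction(self):
        # J(df) ~ 1 - 3/(4 df - 1) for moderate df
        for df in range(10, 60):
            exact = stats._hedges_correction(df)
            approx = 1.0 - 3.0 / (4.0 * df - 1.0)
            assert exact == pytest.approx(approx, abs=1e-3)

    def test_equal_means_zero(self):
        assert stats.hedges_g([1, 2, 3], [3, 2, 1]) == 0.0

    def test_summary_and_raw_agree(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10), rng.normal(1, 2, size=10)
        g_raw = stats.hedges_g(a, b)
        g_sum = stats.hedges_g_from_summary(a.mean(), a.std(ddof=1), 10,
                                            b.mean(), b.std(ddof=1), 10)
        assert g_raw == pytest.approx(g_sum, rel=1e-12)


class TestMannWhitney:
    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 5), (5, 5)])
    def test_exact_p_matches_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        a = rng.normal(size=na)
        b = rng.normal(0.5, 1, size=nb)
        u_obs, p = stats.mann_whitney_u(a, b)
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        center = na * nb / 2.0
        devs = []
        for idx in itertools.combinations(range(na + nb), na):
            r_a = ranks[list(idx)].sum()
            u = r_a - na * (na + 1) / 2.0
            devs.append(abs(u - center))
        u_dev = abs(u_obs - center)
        p_brute = np.mean(np.array(devs) >= u_dev - 1e-12)
        assert p == pytest.approx(p_brute, abs=1e-12)

    def test_mirrored_samples_p_one(self):
        _, p = stats.mann_whitney_u([1.0, 4.0], [2.0, 3.0])
        assert p == pytest.approx(1.0)


class TestTFCE:
    def test_zero_map(self):
        assert np.all(stats.tfce(np.zeros((4, 4))) == 0)

    def test_plateau_closed_form(self):
        # single 1-D plateau: e(h) = e0 for all h <= h0
        e0, h0, dh = 4, 1.0, 0.1
        m = np.zeros(10)
        m[2:2 + e0] = h0
        params = stats.TFCEParams(E=0.5, H=2.0, dh=dh)
        enh = stats.tfce(m, params)
        heights = np.arange(dh, h0 + dh / 2, dh)
        expected = (e0 ** 0.5) * np.sum(heights ** 2) * dh
        assert enh[3] == pytest.approx(expected, rel=1e-9)

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(5)
        params = stats.TFCEParams(E=0.5, H=2.0, dh=0.1)
        for _ in range(25):
            m = rng.integers(-3, 5, size=(5, 5)).astype(float)
            enh = stats.tfce(m, params)
            ref = brute_force_tfce(m, 0.5, 2.0, 0.1)
            assert np.allclose(enh, ref, atol=1e-9)

    def test_graph_adjacency_equals_lattice(self):
        rng = np.random.default_rng(6)
        m = rng.integers(0, 4, size=(4, 6)).astype(float)
        params = stats.TFCEParams(dh=0.1)
        lat = stats.tfce(m, params)
        adj = stats.lattice_adjacency(m.shape)
        gra = stats.tfce(m, params, adjacency=adj)
        assert np.allclose(lat, gra)

    def test_raising_a_point_never_decreases_its_enhancement(self):
        rng = np.random.default_rng(7)
        m = rng.integers(0, 4, size=(5, 5)).astype(float)
        params = stats.TFCEParams(dh=0.1)
        base = stats.tfce(m, params)
        m2 = m.copy()
        m2[2, 2] += 1.0
        raised = stats.tfce(m2, params)
        assert raised[2, 2] >= base[2, 2] - 1e-12

    def test_group_comparison_null_and_antisymmetry(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(8, 30))
        B = rng.normal(size=(8, 30))
        res = stats.tfce_group_comparison(A, B, n_perm=300, seed=0)
        assert not res.mask.any()  # identical distributions: nothing flagged
        res_sw = stats.tfce_group_comparison(B, A, n_perm=300, seed=0)
        assert np.allclose(res.statistic, -res_sw.statistic)


class TestSpearman:
    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=12)
        Y = rng.normal(size=(12, 5))
        rho = stats.spearman_rho(x, Y)
        for j in range(5):
            ref = sps.spearmanr(x, Y[:, j]).statistic
            assert rho[j] == pytest.approx(ref, rel=1e-12)

    def test_monotone_transform_gives_unit_rho(self):
        x = np.array([0.3, 1.2, -0.5, 2.0, 0.9, -1.4])
        y = np.exp(x)
        assert stats.spearman_rho(x, y[:, None])[0] == pytest.approx(1.0)

    def test_enumeration_p_at_n6(self):
        # brute-force permutation null over all 720 orderings of x
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho_obs = stats.spearman_rho(x, y[:, None])[0]
        count = 0
        total = 0
        for perm in itertools.permutations(range(6)):
            r = stats.spearman_rho(x[list(perm)], y[:, None])[0]
            count += abs(r) >= abs(rho_obs) - 1e-12
            total += 1
        p_exact = count / total
        # mid-rank formula on distinct data: rho = 1 - 6*sum d^2/(n(n^2-1))
        d = sps.rankdata(x) - sps.rankdata(y)
        rho_formula = 1 - 6 * (d ** 2).sum() / (6 * 35)
        assert rho_obs == pytest.approx(rho_formula, rel=1e-12)
        assert 0 < p_exact <= 1

    def test_tfce_map_flags_planted_channel_cluster(self):
        rng = np.random.default_rng(10)
        adj = channel_adjacency()
        n_sub, n_ch = 10, 32
        x = rng.normal(size=n_sub)
        Y = rng.normal(size=(n_sub, n_ch)) * 0.2
        planted = [21, 22, 23, 26, 27]  # P3, Pz, P4, PO3, POz region
        for c in planted:
            Y[:, c] += x
        res = stats.spearman_tfce_map(x, Y, adj, n_perm=300, seed=0)
        assert res.mask[planted].any()

    def test_constant_predictor_raises(self):
        adj = channel_adjacency()
        with pytest.raises(ValueError):
            stats.spearman_tfce_map(np.ones(8), np.random.default_rng(0).normal(size=(8, 32)), adj)
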