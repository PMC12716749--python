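import itertools

import networkx as nx
import numpy as np
import pytest

from sibcm.data_io import ParcellatedTimeSeries, ParcellationMap
from sibcm.fixtures import fractional_gaussian_noise
from sibcm.metrics import (
    NyquistError,
    dfc_similarity,
    dynamic_fc,
    fc_similarity,
    fcd_ks,
    graph_metrics,
    hurst_exponent,
    icc,
    kuramoto_order,
    network_block_fc,
    phase_dynamics,
    power_spectrum,
    proportional_threshold,
    spectral_cosine_distance,
    static_fc,
    weighted_global_efficiency,
)


def _ts(values, tr=1.0):
    return ParcellatedTimeSeries(values, tr, [f"R{i}" for i in range(values.shape[1])])


class TestStaticFc:
    def test_matches_bruteforce_loop(self):
        values = np.random.default_rng(0).standard_normal((40, 5))
        fc = static_fc(_ts(values))
        for i, j in itertools.combinations(range(5), 2):
            expect = np.corrcoef(values[:, i], values[:, j])[0, 1]
            assert abs(fc[i, j] - expect) < 1e-12

    def test_identical_and_flipped_regions(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        fc = static_fc(_ts(np.column_stack([x, x + 0.0, -x])))
        assert fc[0, 1] == pytest.approx(1.0)
        assert fc[0, 2] == pytest.approx(-1.0)


class TestFcSimilarity:
    def test_identical_gives_ones(self):
        fc = static_fc(_ts(np.random.default_rng(2).standard_normal((50, 6))))
        assert fc_similarity(fc, fc) == pytest.approx((1.0, 1.0))

    def test_common_permutation_invariance(self):
        fc = static_fc(_ts(np.random.default_rng(3).standard_normal((50, 6))))
        perm = np.random.default_rng(4).permutation(6)
        permuted = fc[np.ix_(perm, perm)]
        # the same relabelling applied to both arguments
        edge_r, node_r = fc_similarity(fc[np.ix_(perm, perm)], permuted)
        assert edge_r == pytest.approx(1.0) and node_r == pytest.approx(1.0)

    def test_node_r_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        fc_a = static_fc(_ts(rng.standard_normal((50, 5))))
        fc_b = static_fc(_ts(rng.standard_normal((50, 5))))
        _, node_r = fc_similarity(fc_a, fc_b)
        mean_a = [(fc_a[i].sum() - 1) / 4 for i in range(5)]
        mean_b = [(fc_b[i].sum() - 1) / 4 for i in range(5)]
        assert node_r == pytest.approx(np.corrcoef(mean_a, mean_b)[0, 1], abs=1e-12)


class TestDynamicFc:
    def test_matches_bruteforce_on_toy(self):
        values = np.random.default_rng(6).standard_normal((30, 5))
        stack, sigma_dfc, fcd = dynamic_fc(_ts(values), window_length=10, step=5)
        mats = []
        for start in range(0, 21, 5):
            mats.append(np.corrcoef(values[start : start + 10], rowvar=False))
        mats = np.array(mats)
        iu = np.triu_indices(5, k=1)
        for i, j in zip(*iu):
            assert abs(sigma_dfc[i, j] - mats[:, i, j].std()) < 1e-10
        for p, q in itertools.combinations(range(len(mats)), 2):
            expect = np.corrcoef(mats[p][iu], mats[q][iu])[0, 1]
            assert abs(fcd[p, q] - expect) < 1e-10

    def test_proportional_region_has_zero_sigma_dfc(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(60)
        values = np.column_stack([x, 2 * x, rng.standard_normal(60)])
        _, sigma_dfc, fcd = dynamic_fc(_ts(values), window_length=20, step=10)
        assert sigma_dfc[0, 1] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.diag(fcd), 1.0)

    def test_full_window_reproduces_static_fc(self):
        values = np.random.default_rng(8).standard_normal((40, 4))
        ts = _ts(values)
        stack, sigma_dfc, _ = dynamic_fc(ts, window_length=40, step=10)
        assert stack.matrices.shape[0] == 1
        np.testing.assert_array_equal(stack.matrices[0], static_fc(ts))
        assert np.abs(sigma_dfc).max() == 0.0


class TestFcdKs:
    def test_identical_is_zero_and_disjoint_is_one(self):
        values = np.random.default_rng(9).standard_normal((60, 5))
        _, _, fcd = dynamic_fc(_ts(values), 20, 10)
        assert fcd_ks(fcd, fcd) == 0.0
        lo = np.full((4, 4), -0.9)
        hi = np.full((4, 4), 0.9)
        assert fcd_ks(lo, hi) == 1.0

    def test_matches_bruteforce_ecdf_scan(self):
        rng = np.random.default_rng(10)
        fcd_a = rng.uniform(-1, 1, size=(5, 5))
        fcd_b = rng.uniform(-1, 1, size=(6, 6))
        a = fcd_a[np.triu_indices(5, 1)]
        b = fcd_b[np.triu_indices(6, 1)]
        grid = np.concatenate([a, b])
        stat = max(abs((a <= g).mean() - (b <= g).mean()) for g in grid)
        assert fcd_ks(fcd_a, fcd_b) == pytest.approx(stat, abs=1e-10)


class TestSpectra:
    def test_self_distance_zero_and_scale_invariance(self):
        values = np.random.default_rng(11).standard_normal((128, 3))
        _, pxx = power_spectrum(_ts(values, tr=0.72))
        assert spectral_cosine_distance(pxx, pxx) == pytest.approx(0.0, abs=1e-12)
        assert spectral_cosine_distance(pxx, 2 * pxx) == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_peak_bin(self):
        tr = 1.0
        t = np.arange(256)
        f0 = 0.125
        values = np.column_stack([np.sin(2 * np.pi * f0 * t),
                                  np.sin(2 * np.pi * f0 * t + 1)])
        freqs, pxx = power_spectrum(_ts(values, tr))
        peak = freqs[np.argmax(pxx[0])]
        assert abs(peak - f0) <= freqs[1] - freqs[0]


class TestHurst:
    def test_white_noise_near_half(self):
        values = np.random.default_rng(12).standard_normal((2000, 3))
        h = hurst_exponent(_ts(values))
        assert np.all(np.abs(h - 0.5) < 0.1)

    def test_persistent_fgn_near_nominal(self):
        values = np.column_stack(
            [fractional_gaussian_noise(2000, 0.8, seed=s) for s in range(3)]
        )
        h = hurst_exponent(_ts(values))
        assert np.all(np.abs(h - 0.8) < 0.1)

    def test_constant_region_rejected(self):
        values = np.random.default_rng(13).standard_normal((200, 2))
        values[:, 1] = 1.0
        with pytest.raises(Exception):
            hurst_exponent(_ts(values))


class TestPhaseDynamics:
    def test_identical_signals_fully_synchronous(self):
        x = np.sin(2 * np.pi * 0.05 * np.arange(200) * 0.72)
        x = x + np.random.default_rng(14).standard_normal(200) * 1e-6
        values = np.column_stack([x, x, x])
        values = values + np.random.default_rng(15).standard_normal((200, 3)) * 1e-9
        r = kuramoto_order(_ts(values, tr=0.72))
        assert r.mean() == pytest.approx(1.0, abs=1e-3)
        assert r.std() == pytest.approx(0.0, abs=1e-3)

    def test_order_parameter_bounded(self):
        values = np.random.default_rng(16).standard_normal((300, 8))
        r = kuramoto_order(_ts(values, tr=0.72))
        assert r.min() >= 0.0 and r.max() <= 1.0

    def test_isor_self_reference_near_half(self):
        values = np.random.default_rng(17).standard_normal((330, 6))
        summary = phase_dynamics(_ts(values, tr=0.72), window_length=30, step=10)
        n_w = len(summary.window_integration)
        expect = np.mean(summary.window_integration
                         > np.median(summary.window_integration))
        assert summary.isor == pytest.approx(expect)
        if n_w % 2 == 1:
            assert summary.isor == pytest.approx((n_w // 2) / n_w)

    def test_infeasible_band_rejected(self):
        values = np.random.default_rng(18).standard_normal((100, 3))
        with pytest.raises(NyquistError):
            phase_dynamics(_ts(values, tr=10.0), band=(0.01, 0.1))


class TestGraphMetrics:
    def test_complete_graph_closed_forms(self):
        m = 6
        fc = np.full((m, m), 0.5)
        np.fill_diagonal(fc, 1.0)
        gm = graph_metrics(fc, density=1.0)
        assert gm.clustering == pytest.approx(1.0)
        assert gm.path_length == pytest.approx(1.0)
        assert gm.global_efficiency == pytest.approx(1.0)
        assert gm.local_efficiency == pytest.approx(1.0)

    def test_two_triangles_modularity_bruteforce(self):
        # two disconnected triangles; partition = the two triangles
        adj = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.combinations(block, 2):
                adj[i, j] = adj[j, i] = 1.0
        parcmap = ParcellationMap({f"R{i}": ("VIS" if i < 3 else "DMN")
                                   for i in range(6)})
        gm = graph_metrics(adj, density=1.0, parcmap=parcmap,
                           region_ids=[f"R{i}" for i in range(6)])
        # brute force over the modularity sum: Q = sum_c (e_c/m - (d_c/2m)^2)
        m_edges = 6.0
        q_expect = sum(3 / m_edges - (6 / (2 * m_edges)) ** 2 for _ in range(2))
        assert gm.modularity == pytest.approx(q_expect, abs=1e-10)
        assert not gm.connected

    def test_participation_zero_for_intra_module_nodes(self):
        adj = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.combinations(block, 2):
                adj[i, j] = adj[j, i] = 1.0
        parcmap = ParcellationMap({f"R{i}": ("VIS" if i < 3 else "DMN")
                                   for i in range(6)})
        gm = graph_metrics(adj, density=1.0, parcmap=parcmap,
                           region_ids=[f"R{i}" for i in range(6)])
        assert gm.participation == pytest.approx(0.0)

    def test_proportional_threshold_density(self):
        fc = np.random.default_rng(19).uniform(-1, 1, size=(10, 10))
        fc = 0.5 * (fc + fc.T)
        adj = proportional_threshold(fc, density=0.2)
        assert adj.sum() // 2 == round(0.2 * 45)

    def test_weighted_efficiency_matches_networkx(self):
        w = np.random.default_rng(20).uniform(0.1, 1.0, size=(5, 5))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        ours = weighted_global_efficiency(w)
        g = nx.Graph()
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(i, j, distance=1.0 / w[i, j])
        acc = []
        for i in range(5):
            for j in range(5):
                if i != j:
                    acc.append(1.0 / nx.dijkstra_path_length(g, i, j, weight="distance"))
        assert ours == pytest.approx(np.mean(acc), abs=1e-12)


class TestNetworkBlockFc:
    def _parcmap(self, labels):
        return ParcellationMap({f"R{i}": lab for i, lab in enumerate(labels)})

    def test_block_constant_fc_recovered_exactly(self):
        labels = ["VIS"] * 3 + ["DMN"] * 3
        fc = np.full((6, 6), 0.2)
        fc[:3, :3] = 0.8
        fc[3:, 3:] = 0.8
        np.fill_diagonal(fc, 1.0)
        block = network_block_fc(fc, self._parcmap(labels), [f"R{i}" for i in range(6)])
        assert block[0, 0] == pytest.approx(0.8)   # VIS within
        assert block[6, 6] == pytest.approx(0.8)   # DMN within
        assert block[0, 6] == pytest.approx(0.2)   # between

    def test_matches_bruteforce_masked_means(self):
        rng = np.random.default_rng(21)
        fc = rng.uniform(-1, 1, size=(6, 6))
        fc = 0.5 * (fc + fc.T)
        labels = ["VIS", "VIS", "SMN", "SMN", "DMN", "DMN"]
        block = network_block_fc(fc, self._parcmap(labels), [f"R{i}" for i in range(6)])
        vis = [0, 1]
        smn = [2, 3]
        assert block[0, 0] == pytest.approx(np.mean([fc[0, 1], fc[1, 0]]))
        assert block[0, 1] == pytest.approx(
            np.mean([fc[i, j] for i in vis for j in smn]))

    def test_single_region_network_missing_within(self):
        labels = ["VIS", "DMN", "DMN", "DMN"]
        fc = np.eye(4)
        block = network_block_fc(fc, self._parcmap(labels), [f"R{i}" for i in range(4)])
        assert np.isnan(block[0, 0])


class TestIcc:
    def test_perfect_consistency_is_one(self):
        table = np.repeat(np.arange(5.0)[:, None], 3, axis=1)
        assert icc(table) == pytest.approx(1.0)

    def test_matches_anova_bruteforce(self):
        rng = np.random.default_rng(22)
        table = rng.normal(size=(6, 2)) + 2 * rng.normal(size=(6, 1))
        n, k = table.shape
        grand = table.mean()
        msr = k * ((table.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((table.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (((table - grand) ** 2).sum()
               - msr * (n - 1) - msc * (k - 1)) / ((n - 1) * (k - 1))
        expect = (msr - mse) / (msr + (k - 1) * mse)
        assert icc(table) == pytest.approx(expect, abs=1e-10)

    def test_matches_pingouin_icc3(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(23)
        table = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 3),
            "session": np.tile(np.arange(3), 8),
            "value": table.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="session",
                                 ratings="value")
        icc3 = float(ref.loc[ref["Type"].isin(["ICC3", "ICC(C,1)"]), "ICC"].iloc[0])
        assert icc(table) == pytest.approx(icc3, abs=1e-10)

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((1, 3)))
        with pytest.raises(ValueError):
            icc(np.ones((4, 1)))


def test_null_edge_similarity_is_small():
    rng = np.random.default_rng(24)
    fc_a = static_fc(_ts(rng.standard_normal((500, 30))))
    fc_b = static_fc(_ts(rng.standard_normal((500, 30))))
    edge_r, _ = fc_similarity(fc_a, fc_b)
    assert abs(edge_r) < 0.1


def test_dfc_similarity_self_is_one():
    values = np.random.default_rng(25).standard_normal((80, 5))
    _, sigma_dfc, _ = dynamic_fc(_ts(values), 20, 10)
    assert dfc_similarity(sigma_dfc, sigma_dfc) == pytest.approx(1.0)
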