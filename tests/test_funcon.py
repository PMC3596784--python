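"""Directed functional-connectivity inference and cross-correlation tests."""

import numpy as np
import pytest
from scipy import stats

from finitenet import funcon as fc
from finitenet import synthetic_calcium as syn


def series_from(onsets, duration):
    return fc.OnsetSeries(onsets=tuple(np.asarray(o, float) for o in onsets), duration=duration)


class TestPairwiseLags:
    def test_fixed_delay(self):
        oj = np.arange(10.0, 100.0, 10.0)
        ok = oj + 0.1
        lags = fc.pairwise_lags(oj, ok)
        assert np.allclose(lags, 100.0)

    def test_out_of_window_empty(self):
        oj = np.array([10.0, 20.0])
        ok = np.array([11.0, 21.0])  # 1 s away > 500 ms
        assert fc.pairwise_lags(oj, ok).size == 0

    def test_nearest_is_selected(self):
        oj = np.array([10.0])
        ok = np.array([9.7, 10.1])  # -300 vs +100: nearest wins
        assert fc.pairwise_lags(oj, ok).tolist() == [pytest.approx(100.0)]

    def test_one_lag_per_source_onset(self):
        oj = np.array([10.0])
        ok = np.array([10.05, 10.1, 10.2])
        assert fc.pairwise_lags(oj, ok).size == 1

    def test_independent_poisson_lags_look_uniform(self):
        # the null lag distribution matches uniform on [-500, 500] ms
        nonsig = tested = 0
        for seed in range(40):
            a, b = syn.make_poisson_onsets(2, 0.1, 600.0, seed=seed)
            lags = fc.pairwise_lags(a, b)
            if lags.size < 5:
                continue
            tested += 1
            p = stats.kstest(lags, stats.uniform(loc=-500, scale=1000).cdf).pvalue
            nonsig += p > 0.05
        assert tested >= 20
        assert nonsig >= 0.9 * tested


class TestTestDirection:
    def test_consistent_positive_lags_give_forward_edge(self):
        rng = np.random.default_rng(0)
        lags = 100.0 + rng.normal(0, 1e-6, 20)
        decision, t_p, ks_p = fc.test_direction(lags)
        assert decision == "forward"
        assert t_p < 0.05 and ks_p < 0.05

    def test_zero_mean_gaussian_rejected_at_alpha(self):
        # synchronous pairs (Gaussian lags centred on zero) must not connect
        decisions = []
        for seed in range(100):
            lags = np.random.default_rng(seed).normal(0, 50, 200)
            decisions.append(fc.test_direction(lags)[0])
        edge_rate = np.mean([d != "none" for d in decisions])
        assert edge_rate <= 0.05 + 0.03

    def test_uniform_lags_rejected(self):
        # uncorrelated pairs (uniform lags) must almost never connect
        decisions = []
        for seed in range(100):
            lags = np.random.default_rng(seed).uniform(-500, 500, 200)
            decisions.append(fc.test_direction(lags)[0])
        assert np.mean([d != "none" for d in decisions]) <= 0.05 + 0.02

    def test_insufficient_data_guard(self):
        decision, t_p, ks_p = fc.test_direction(np.array([100.0, 90.0, 110.0]))
        assert decision == "none"
        assert np.isnan(t_p)

    def test_negative_lags_give_backward_edge(self):
        rng = np.random.default_rng(1)
        assert fc.test_direction(-120.0 + rng.normal(0, 5, 30))[0] == "backward"


class TestBuildFunctionalGraph:
    def test_chain_recovery(self):
        recovered, reversed_edges = [], []
        for seed in range(10):
            onsets, truth = syn.make_chain_population(5, 120.0, 10.0, 50, seed=seed)
            series = series_from(onsets, truth.duration_s)
            g = fc.build_functional_graph(series)
            found = g.edge_set()
            recovered.append(
                sum((e in found) for e in truth.edges) / len(truth.edges)
            )
            reversed_edges.append(sum(((b, a) in found) for a, b in truth.edges))
        assert np.mean(recovered) >= 0.9
        assert sum(reversed_edges) == 0

    def test_time_reversal_flips_all_edges(self):
        onsets, truth = syn.make_chain_population(4, 150.0, 15.0, 30, seed=3)
        T = truth.duration_s
        series = series_from(onsets, T)
        rev = series_from([np.sort(T - o) for o in onsets], T)
        g = fc.build_functional_graph(series)
        g_rev = fc.build_functional_graph(rev)
        assert g_rev.edge_set() == {(b, a) for a, b in g.edge_set()}

    def test_poisson_null_edge_rate(self):
        total_pairs = edges = 0
        for seed in range(20):
            onsets = syn.make_poisson_onsets(10, 0.2, 600.0, seed=seed)
            g = fc.build_functional_graph(series_from(onsets, 600.0))
            edges += len(g.edges)
            total_pairs += 45
        assert edges / total_pairs <= 0.05 + 0.02

    def test_at_most_one_direction_per_pair(self):
        onsets, truth = syn.make_chain_population(5, 120.0, 10.0, 50, seed=1)
        g = fc.build_functional_graph(series_from(onsets, truth.duration_s))
        pairs = [(min(e.source, e.target), max(e.source, e.target)) for e in g.edges]
        assert len(pairs) == len(set(pairs))

    def test_insufficient_repetitions_guard(self):
        onsets, truth = syn.make_chain_population(2, 120.0, 0.0, 1, seed=0)
        g = fc.build_functional_graph(series_from(onsets, truth.duration_s))
        assert len(g.edges) == 0


class TestRankNodes:
    def graph_from_edges(self, n, edges):
        return fc.DirectedFunctionalGraph(
            n_neurons=n,
            edges=tuple(
                fc.FunctionalEdge(a, b, 100.0, 10, 0.01, 0.01) for a, b in edges
            ),
        )

    def test_star_hub_is_top_output(self):
        g = self.graph_from_edges(6, [(0, k) for k in range(1, 6)])
        assert fc.rank_nodes(g, "output")[0] == 0
        assert 0 not in fc.rank_nodes(g, "input")

    def test_empty_graph(self):
        g = self.graph_from_edges(4, [])
        assert fc.rank_nodes(g, "input") == []

    def test_chain_endpoints(self):
        g = self.graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        assert 0 not in fc.rank_nodes(g, "input")
        assert 3 not in fc.rank_nodes(g, "output")
        assert fc.rank_nodes(g, "input", top_n=3) == [1, 2, 3]

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            fc.rank_nodes(self.graph_from_edges(2, []), "sideways")


def naive_cc(a, b, max_lag):
    """Independent double-loop evaluation of the normalised correlogram."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = len(a)
    am, bm = a.mean(), b.mean()
    sa, sb = a.std(), b.std()
    lags = range(-max_lag, max_lag + 1)
    out = []
    for tau in lags:
        acc = 0.0
        cnt = 0
        for t in range(n):
            if 0 <= t + tau < n:
                acc += (a[t] - am) * (b[t + tau] - bm)
                cnt += 1
        out.append(acc / (cnt * sa * sb))
    return np.array(list(lags)), np.array(out)


class TestCrossCorrelation:
    def test_autocorrelation_peak(self):
        rng = np.random.default_rng(0)
        a = (rng.random(300) < 0.1).astype(float)
        lags, curve, cc_max, tau_max = fc.cross_correlation(a, a, 20)
        assert cc_max == pytest.approx(1.0)
        assert tau_max == 0

    def test_delay_sign_convention(self):
        rng = np.random.default_rng(1)
        a = (rng.random(300) < 0.1).astype(float)
        b = np.roll(a, 10)  # b happens 10 samples after a: a leads
        _, _, _, tau_max = fc.cross_correlation(a, b, 30)
        assert tau_max == 10

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a = (rng.random(200) < 0.15).astype(float)
            b = (rng.random(200) < 0.15).astype(float)
            if a.std() == 0 or b.std() == 0:
                continue
            lags, curve, _, _ = fc.cross_correlation(a, b, 25)
            nl, nc = naive_cc(a, b, 25)
            assert np.array_equal(lags, nl)
            assert np.max(np.abs(curve - nc)) < 1e-12

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(3)
        a = (rng.random(250) < 0.2).astype(float)
        b = (rng.random(250) < 0.2).astype(float)
        _, cab, _, _ = fc.cross_correlation(a, b, 30)
        _, cba, _, _ = fc.cross_correlation(b, a, 30)
        assert np.array_equal(cab, cba[::-1])
        assert np.max(np.abs(cab)) <= 1.0 + 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fc.cross_correlation(np.zeros(100), np.ones(100), 10)


class TestSummarizeCorrelations:
    def test_identical_neurons(self):
        rng = np.random.default_rng(4)
        onsets = np.sort(rng.uniform(0, 100, 30))
        series = series_from([onsets, onsets.copy()], 100.0)
        summary = fc.summarize_correlations(series)
        assert summary.cc_max[0] == pytest.approx(1.0)
        assert summary.cc_max[1] == pytest.approx(1.0)
        assert summary.tau_max[0] == pytest.approx(0.0)
        assert not summary.excluded.any()

    def test_chain_lag_signs(self):
        onsets, truth = syn.make_chain_population(
            3, 300.0, 0.0, 40, seed=5, inter_sweep_s=20.0
        )
        summary = fc.summarize_correlations(series_from(onsets, truth.duration_s))
        # leader activates before its partners: positive mean lag
        assert summary.tau_max[0] > 0
        assert summary.tau_max[-1] < 0

    def test_silent_neuron_excluded(self):
        rng = np.random.default_rng(6)
        onsets = [np.sort(rng.uniform(0, 100, 20)), np.array([])]
        summary = fc.summarize_correlations(series_from(onsets, 100.0))
        assert summary.excluded[1]
        assert np.isnan(summary.cc_max[1])

    def test_early_subgroup_separates_on_lag_axis(self):
        # two synchronised assemblies, one recruited 300 ms before the other
        rng = np.random.default_rng(7)
        sweeps = (np.arange(40) + 0.5) * 15.0
        early = [
            np.sort(sweeps + rng.normal(0, 0.01, 40)) for _ in range(4)
        ]
        late = [
            np.sort(sweeps + 0.3 + rng.normal(0, 0.01, 40)) for _ in range(4)
        ]
        series = series_from(early + late, 600.0)
        summary = fc.summarize_correlations(series)
        tau_early = summary.tau_max[:4]
        tau_late = summary.tau_max[4:]
        p = stats.mannwhitneyu(tau_early, tau_late, alternative="greater").pvalue
        assert p < 0.05


class TestFDRMode:
    def test_bh_gate_is_more_conservative_on_null(self):
        edges_raw = edges_fdr = 0
        for seed in range(10):
            onsets = syn.make_poisson_onsets(10, 0.2, 600.0, seed=seed)
            series = series_from(onsets, 600.0)
            edges_raw += len(fc.build_functional_graph(series).edges)
            edges_fdr += len(fc.build_functional_graph(series, fdr=True).edges)
        assert edges_fdr <= edges_raw

    def test_bh_keeps_strong_chain_edges(self):
        onsets, truth = syn.make_chain_population(5, 120.0, 10.0, 50, seed=2)
        series = series_from(onsets, truth.duration_s)
        found = fc.build_functional_graph(series, fdr=True).edge_set()
        assert all(e in found for e in truth.edges)
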