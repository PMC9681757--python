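"""Network construction: Fisher-z Spearman weighting, proportional
thresholding (edge counts, tie policy, density nesting) and LCC-based
density-range selection."""

import numpy as np
import pytest
from scipy import stats as sps

from betaconn.construction import (
    BetaSeriesSet,
    WeightedNetwork,
    beta_correlation,
    edge_count_at_density,
    lcc_size,
    proportional_threshold,
    select_density_range,
)

from conftest import complete, network


def beta_set(values, **kw):
    return BetaSeriesSet(values=np.asarray(values, dtype=float),
                         participant="p", condition="c", **kw)


class TestBetaCorrelation:
    def test_matches_scipy_spearman_with_fisher_z(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 6))
        w = beta_correlation(beta_set(x)).w
        for i in range(6):
            for j in range(i + 1, 6):
                rho = sps.spearmanr(x[:, i], x[:, j]).statistic
                assert w[i, j] == pytest.approx(np.arctanh(rho))

    def test_known_spearman_value(self):
        # ranks (1..5) vs (1,3,5,2,4): sum d^2 = 10 -> rho = 0.5,
        # Fisher z = atanh(0.5) = 0.5493
        x = np.column_stack([np.arange(1, 6), [1, 3, 5, 2, 4]]).astype(float)
        rho = sps.spearmanr(x[:, 0], x[:, 1]).statistic
        assert rho == pytest.approx(0.5)
        w = beta_correlation(beta_set(x)).w
        assert w[0, 1] == pytest.approx(0.5493061443340549)

    def test_monotone_transform_invariance_and_clipping(self):
        trials = np.linspace(0, 1, 20)
        x = np.column_stack([trials, np.exp(3 * trials)])  # monotone map
        w = beta_correlation(beta_set(x)).w
        assert np.isfinite(w[0, 1])
        assert w[0, 1] > 10  # atanh of (1 - 1e-12)
        # any strictly monotone transform leaves the weight unchanged
        x2 = np.column_stack([trials**3 + 5, np.exp(3 * trials)])
        w2 = beta_correlation(beta_set(x2)).w
        assert w2[0, 1] == pytest.approx(w[0, 1])

    def test_independent_columns_center_on_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(80, 40))
        w = beta_correlation(beta_set(x)).w
        iu = np.triu_indices(40, k=1)
        # SE of the mean of ~780 weakly dependent z values, se(z) ~ 1/sqrt(77)
        se = 1 / np.sqrt(77) / np.sqrt(len(iu[0]))
        assert abs(w[iu].mean()) < 3 * se * 3  # generous dependence allowance

    def test_constant_column_error_names_node(self):
        x = np.ones((10, 3))
        x[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="n001|n002"):
            beta_correlation(beta_set(x))

    def test_zero_diagonal_and_symmetry(self):
        rng = np.random.default_rng(2)
        w = beta_correlation(beta_set(rng.normal(size=(20, 5)))).w
        assert np.allclose(np.diag(w), 0.0)
        assert np.allclose(w, w.T)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            beta_set(np.zeros((2, 3)))


class TestProportionalThreshold:
    def test_edge_count_round_half_up(self):
        assert edge_count_at_density(263, 15.0) == 5168  # 0.15 * 34453 = 5167.95
        assert edge_count_at_density(5, 20.0) == 2
        assert edge_count_at_density(5, 25.0) == 3  # 2.5 rounds up

    def test_keeps_largest_weights(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=(5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        bn = proportional_threshold(WeightedNetwork(w=w), 20.0)
        iu = np.triu_indices(5, k=1)
        order = np.argsort(-w[iu])
        expected = set(zip(iu[0][order[:2]], iu[1][order[:2]]))
        got = set(map(tuple, np.argwhere(np.triu(bn.a, k=1))))
        assert got == expected

    def test_full_density_gives_complete_graph(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=(6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        bn = proportional_threshold(WeightedNetwork(w=w), 99.999)
        assert bn.n_edges == 15

    def test_tie_policy_is_lexicographic(self):
        w = np.zeros((6, 6))  # all weights equal
        bn = proportional_threshold(WeightedNetwork(w=w), 10.0)
        m = edge_count_at_density(6, 10.0)
        assert bn.n_edges == m
        got = sorted(map(tuple, np.argwhere(np.triu(bn.a, k=1))))
        assert got == [(0, 1), (0, 2)][:m]

    def test_absolute_ranking_flag(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = -5.0
        w[2, 3] = w[3, 2] = 1.0
        bn_signed = proportional_threshold(WeightedNetwork(w=w), 17.0)
        bn_abs = proportional_threshold(WeightedNetwork(w=w), 17.0,
                                        ranking="absolute")
        assert bn_signed.a[2, 3] == 1 and bn_signed.a[0, 1] == 0
        assert bn_abs.a[0, 1] == 1 and bn_abs.a[2, 3] == 0

    def test_density_nesting(self):
        """Edge sets are nested across increasing densities, hence LCC
        size is non-decreasing."""
        rng = np.random.default_rng(5)
        w = rng.normal(size=(30, 30))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        wn = WeightedNetwork(w=w)
        prev_edges = None
        prev_lcc = 0
        for d in [5, 10, 15, 20, 40]:
            bn = proportional_threshold(wn, d)
            edges = set(map(tuple, np.argwhere(np.triu(bn.a, k=1))))
            if prev_edges is not None:
                assert prev_edges <= edges
            assert lcc_size(bn) >= prev_lcc
            prev_edges, prev_lcc = edges, lcc_size(bn)


class TestLcc:
    def test_complete_graph(self):
        assert lcc_size(complete(5)) == 5

    def test_two_triangles_plus_isolate(self):
        bn = network(7, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert lcc_size(bn) == 3

    def test_empty_graph_has_singleton_components(self):
        assert lcc_size(network(4, [])) == 1


def _network_connecting_at(n: int, m_connect: int) -> WeightedNetwork:
    """A weighted network whose binarization is fully connected exactly
    when at least ``m_connect`` edges are kept: a high-weight spanning
    path over nodes 1..n-1, node 0 attached by the edge ranked exactly
    ``m_connect``."""
    n_pairs = n * (n - 1) // 2
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    # descending distinct weights for all pairs not involving node 0
    weights = iter(np.linspace(100, 50, n_pairs))
    ranked = []
    for i in range(1, n - 1):  # spanning path first: always present early
        ranked.append((i, i + 1))
    for i, j in zip(iu, ju):
        if i == 0 or (i, j) in ranked:
            continue
        ranked.append((i, j))
    ranked.insert(m_connect - 1, (0, 1))  # node 0 attaches at rank m_connect
    for (i, j), val in zip(ranked, np.linspace(100, 50, len(ranked))):
        w[i, j] = w[j, i] = val
    # remaining node-0 pairs get the lowest weights
    low = iter(np.linspace(10, 1, n))
    for j in range(2, n):
        w[0, j] = w[j, 0] = next(low)
    return WeightedNetwork(w=w)


class TestSelectDensityRange:
    def test_ensemble_mirroring_the_lcc_rule(self):
        """90% of networks fully connect at 15%, all at 22% ->
        range (15, 22)."""
        n = 20
        m15 = edge_count_at_density(n, 15.0)
        m22 = edge_count_at_density(n, 22.0)
        nets = [_network_connecting_at(n, m15) for _ in range(9)]
        nets.append(_network_connecting_at(n, m22))
        rng = select_density_range(nets, [13.0, 14.0, 15.0, 22.0])
        assert (rng.d_low, rng.d_high) == (15.0, 22.0)
        assert rng.fractions[15.0] == pytest.approx(0.9)
        assert rng.fractions[22.0] == 1.0

    def test_everything_connects_at_single_density(self):
        n = 15
        m = edge_count_at_density(n, 15.0)
        nets = [_network_connecting_at(n, m) for _ in range(5)]
        rng = select_density_range(nets, [10.0, 15.0, 20.0])
        assert rng.d_low == rng.d_high == 15.0

    def test_single_network(self):
        n = 12
        m = edge_count_at_density(n, 18.0)
        rng = select_density_range([_network_connecting_at(n, m)],
                                   [16.0, 18.0, 20.0])
        assert rng.d_low == rng.d_high == 18.0

    def test_failure_reports_fraction_table(self):
        n = 12
        nets = [_network_connecting_at(n, edge_count_at_density(n, 50.0))]
        with pytest.raises(ValueError, match="fractions"):
            select_density_range(nets, [5.0, 10.0])
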