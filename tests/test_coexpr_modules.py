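"""Adjacency, TOM, clustering, eigengenes and soft-power selection."""

import numpy as np
import pandas as pd
import pytest

from cttkit.errors import ParameterError, ValidationError
from cttkit import coexpr_modules as cm


def brute_force_tom(adj):
    """O(n^3) triple-loop topological overlap oracle."""
    adj = np.asarray(adj, float)
    n = adj.shape[0]
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def random_adjacency(n, rng):
    m = rng.random((n, n))
    adj = (m + m.T) / 2
    np.fill_diagonal(adj, 1.0)
    return adj


class TestAdjacency:
    @pytest.mark.parametrize("r,beta,expected", [
        (0.8, 6, 0.8**6), (1.0, 3, 1.0), (-0.8, 6, 0.8**6)])
    def test_power_of_abs_correlation(self, r, beta, expected):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        y = r * x + np.sqrt(1 - r**2) * rng.standard_normal(2000)
        # exact check on the algebra, approximate on the realized correlation
        adj = cm.adjacency(np.vstack([x, y]), beta)
        realized_r = np.corrcoef(x, y)[0, 1]
        assert adj[0, 1] == pytest.approx(abs(realized_r) ** beta)
        assert adj[0, 1] == pytest.approx(expected, abs=0.05)
        assert adj[0, 0] == 1.0

    def test_constant_gene_zeroed(self):
        expr = np.vstack([np.ones(10), np.arange(10.0)])
        adj = cm.adjacency(expr, 2)
        assert adj[0, 1] == 0.0 and adj[0, 0] == 1.0


class TestTom:
    @pytest.mark.parametrize("a", [0.1, 0.5, 0.9])
    def test_equal_adjacency_closed_form(self, a):
        adj = np.full((3, 3), a)
        np.fill_diagonal(adj, 1.0)
        tom = cm.tom_similarity(adj)
        off = tom[~np.eye(3, dtype=bool)]
        # (a^2 + a) / (2a + 1 - a) = a for every off-diagonal entry
        assert off == pytest.approx(a)

    def test_empty_network(self):
        tom = cm.tom_similarity(np.eye(4))
        assert (tom == np.eye(4)).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        adj = random_adjacency(8, rng)
        assert cm.tom_similarity(adj) == pytest.approx(brute_force_tom(adj), abs=1e-12)

    def test_asymmetric_rejected(self):
        bad = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ValidationError):
            cm.tom_similarity(bad)


class TestClusterModules:
    def _two_block_diss(self, sizes=(40, 40), within=0.1, between=0.9):
        n = sum(sizes)
        d = np.full((n, n), between)
        start = 0
        for s in sizes:
            d[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(d, 0.0)
        return d

    def test_two_blocks_recovered(self):
        d = self._two_block_diss()
        labels = cm.cluster_modules(d, cm.ModuleConfig(min_module_size=30,
                                                       cut_height=0.5))
        assert sorted(labels.value_counts().to_dict().items()) == [(1, 40), (2, 40)]
        assert labels.iloc[:40].nunique() == 1 and labels.iloc[40:].nunique() == 1

    def test_small_block_unassigned(self):
        d = self._two_block_diss(sizes=(40, 10))
        labels = cm.cluster_modules(d, cm.ModuleConfig(min_module_size=30,
                                                       cut_height=0.5))
        assert (labels.iloc[40:] == 0).all()
        assert (labels.iloc[:40] == 1).all()

    def test_degenerate_all_zero_single_module(self):
        d = np.zeros((35, 35))
        labels = cm.cluster_modules(d, cm.ModuleConfig(min_module_size=30))
        assert (labels == 1).all()

    def test_gene_permutation_invariance(self):
        d = self._two_block_diss()
        genes = [f"g{i:03d}" for i in range(80)]
        cfg = cm.ModuleConfig(min_module_size=30, cut_height=0.5)
        base = cm.cluster_modules(d, cfg, genes=genes)
        rng = np.random.default_rng(1)
        perm = rng.permutation(80)
        permuted = cm.cluster_modules(d[np.ix_(perm, perm)], cfg,
                                      genes=[genes[i] for i in perm])
        assert base.sort_index().equals(permuted.sort_index())


class TestEigengene:
    def test_rank_one_module(self):
        base = np.linspace(-1, 1, 12)
        expr = pd.DataFrame([base, 2 * base, -3 * base],
                            index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(12)])
        labels = pd.Series([1, 1, 1], index=["a", "b", "c"])
        eig, ve = cm.module_eigengene(expr, labels, 1)
        assert ve == pytest.approx(1.0)

    def test_two_uncorrelated_genes(self):
        rng = np.random.default_rng(0)
        n = 4000
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        y -= x * (x @ y) / (x @ x)  # exactly orthogonal after projection
        expr = pd.DataFrame([x, y], index=["a", "b"],
                            columns=[f"s{i}" for i in range(n)])
        labels = pd.Series([1, 1], index=["a", "b"])
        _, ve = cm.module_eigengene(expr, labels, 1)
        assert ve == pytest.approx(0.5, abs=0.02)

    def test_sign_convention(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.standard_normal((5, 30)),
                            index=list("abcde"),
                            columns=[f"s{i}" for i in range(30)])
        labels = pd.Series(1, index=list("abcde"))
        eig, _ = cm.module_eigengene(expr, labels, 1)
        z = (expr.to_numpy() - expr.to_numpy().mean(1, keepdims=True))
        z /= z.std(1, keepdims=True)
        assert np.corrcoef(eig.to_numpy(), z.mean(0))[0, 1] >= 0

    def test_missing_module_rejected(self):
        expr = pd.DataFrame(np.ones((2, 5)), index=["a", "b"])
        with pytest.raises(ValidationError):
            cm.module_eigengene(expr, pd.Series([1, 1], index=["a", "b"]), 9)


class TestModuleCorrelation:
    def test_identical_orthogonal_antipodal(self):
        n = 1000
        rng = np.random.default_rng(0)
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        x -= x.mean()
        y -= y.mean()
        y -= x * (x @ y) / (x @ x)  # centered and exactly orthogonal to x
        eig = pd.DataFrame([x, x, y, -x], index=[1, 2, 3, 4])
        corr = cm.module_correlation(eig)
        assert corr.loc[1, 2] == pytest.approx(1.0)
        assert corr.loc[1, 3] == pytest.approx(0.0, abs=1e-12)
        assert corr.loc[1, 4] == pytest.approx(-1.0)


class TestSoftPower:
    def test_hub_structured_data_reaches_target(self):
        # heterogeneous loadings create hubs -> approximately scale-free degrees
        rng = np.random.default_rng(0)
        f = rng.standard_normal(100)
        load = rng.uniform(0.3, 0.95, size=200)
        expr = (load[:, None] * f[None, :]
                + np.sqrt(1 - load**2)[:, None] * rng.standard_normal((200, 100)))
        res = cm.pick_soft_power(expr)
        assert res.reached_target and res.fit >= 0.85 and res.beta <= 20

    def test_pure_noise_flagged(self):
        rng = np.random.default_rng(1)
        res = cm.pick_soft_power(rng.standard_normal((100, 60)))
        assert not res.reached_target

    def test_forced_single_power(self):
        rng = np.random.default_rng(2)
        res = cm.pick_soft_power(rng.standard_normal((50, 30)),
                                 cm.ModuleConfig(powers=[6]))
        assert res.beta == 6

    def test_degenerate_rejected(self):
        with pytest.raises(ParameterError):
            cm.pick_soft_power(np.ones((30, 20)))
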