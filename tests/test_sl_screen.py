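"""Gene inactivation calls and the two mechanism screens."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cttkit.errors import ParameterError
from cttkit.omics_io import OmicsBundle
from cttkit import sl_screen as scr


def exhaustive_ranksum_p(x, y, alternative):
    """Brute-force rank-sum p-value over all C(n+m, n) rank assignments.

    Independent oracle: enumerates which pooled ranks fall to the x group
    (valid for tie-free data) and counts assignments at least as extreme.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    order = pooled.argsort()
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, pooled.size + 1)
    w_obs = ranks[: x.size].sum()
    stats = [sum(c) for c in itertools.combinations(range(1, pooled.size + 1), x.size)]
    n = len(stats)
    p_ge = sum(s >= w_obs for s in stats) / n
    p_le = sum(s <= w_obs for s in stats) / n
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxon:
    def test_complete_separation_greater(self):
        w, p = scr.wilcoxon_rank_sum([4, 5, 6], [1, 2, 3], "greater")
        assert w == 15
        assert p == pytest.approx(1 / 20)

    def test_complete_separation_two_sided(self):
        w, p = scr.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], "two_sided")
        assert w == 6
        assert p == pytest.approx(2 / 20)

    def test_degenerate_constant(self):
        w, p = scr.wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0], "two_sided")
        assert p == 1.0

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    @pytest.mark.parametrize("n,m", [(1, 1), (2, 5), (4, 4), (6, 3), (8, 8)])
    def test_exact_matches_enumeration(self, n, m, alternative):
        rng = np.random.default_rng(n * 100 + m)
        pooled = rng.permutation(np.arange(n + m, dtype=float) + 1)
        x, y = pooled[:n], pooled[n:]
        _, p = scr.wilcoxon_rank_sum(x, y, alternative)
        assert p == pytest.approx(exhaustive_ranksum_p(x, y, alternative), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            scr.wilcoxon_rank_sum([], [1.0], "greater")


class TestPearson:
    def test_perfect_linearity(self):
        r, p = scr.pearson_cor_test([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_zero_correlation_hand_case(self):
        r, _ = scr.pearson_cor_test([1, 2, 3], [1, -2, 1])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_sign_flip(self):
        x = np.array([1.0, 2, 3, 5])
        r, _ = scr.pearson_cor_test(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            scr.pearson_cor_test([1, 1, 1], [1, 2, 3])


def _bundle(expr, mut=None, cnv=None):
    genes = [f"g{i}" for i in range(expr.shape[0])]
    samples = [f"s{j}" for j in range(expr.shape[1])]
    wrap = lambda m: None if m is None else pd.DataFrame(
        m, index=genes, columns=samples)
    return OmicsBundle(genes=genes, samples=samples, expression=wrap(expr),
                       mutation=wrap(mut), cnv=wrap(cnv))


class TestInactivation:
    def test_rule_clauses(self):
        rng = np.random.default_rng(1)
        expr = rng.standard_normal((3, 10))
        expr[1, 0] = expr[1].min() - 1  # clearly below the 10% quantile
        expr[2, 0] = expr[2].max() + 1  # clearly above it
        mut = np.zeros((3, 10), int)
        mut[0, 3] = 1
        cnv = np.zeros((3, 10))
        cnv[1, 0] = -0.6
        cnv[2, 0] = -0.6
        prof = scr.call_inactivation(_bundle(expr, mut, cnv))
        calls = prof.calls.to_numpy()
        assert calls[0, 3] == 1      # mutation alone suffices
        assert calls[1, 0] == 1      # copy loss AND low expression
        assert calls[2, 0] == 0      # copy loss but high expression
        assert prof.rule["cnv_loss_cutoff"] == -0.3

    def test_quantile_validated(self):
        with pytest.raises(ParameterError):
            scr.call_inactivation(_bundle(np.ones((2, 4)), np.zeros((2, 4))),
                                  expression_quantile=1.5)


class TestCompensationScreen:
    def test_planted_shift_detected(self):
        rng = np.random.default_rng(7)
        n = 100
        expr = rng.standard_normal((2, n))
        mut = np.zeros((2, n), int)
        mut[0, :20] = 1
        expr[1, :20] += 3.0  # partner over-expressed where gene 0 inactive
        bundle = _bundle(expr, mut)
        pairs = pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g1"]})
        res = scr.compensation_screen(pairs, bundle,
                                      scr.call_inactivation(bundle))
        row = res.iloc[0]
        assert row.passed and row.p_value < 0.01
        assert row.direction == "g0" and row.n_inactive == 20

    def test_not_testable_small_groups(self):
        expr = np.random.default_rng(0).standard_normal((2, 30))
        mut = np.zeros((2, 30), int)
        mut[0, 0] = 1  # only one inactive sample < min_group
        bundle = _bundle(expr, mut)
        pairs = pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g1"]})
        res = scr.compensation_screen(pairs, bundle, scr.call_inactivation(bundle))
        assert res.iloc[0].not_testable and not res.iloc[0].passed

    def test_pass_rule_strict(self):
        # threshold is strict: p >= alpha must not pass
        rng = np.random.default_rng(3)
        expr = rng.standard_normal((2, 60))
        mut = np.zeros((2, 60), int)
        mut[0, :10] = 1
        bundle = _bundle(expr, mut)
        pairs = pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g1"]})
        res = scr.compensation_screen(pairs, bundle, scr.call_inactivation(bundle))
        row = res.iloc[0]
        assert bool(row.passed) == (row.p_value < 0.01)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(5)
        expr = rng.standard_normal((2, 50))
        mut = rng.integers(0, 2, (2, 50))
        bundle = _bundle(expr, mut)
        pairs = pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g1"]})
        res1 = scr.compensation_screen(pairs, bundle, scr.call_inactivation(bundle))
        perm = rng.permutation(50)
        bundle2 = _bundle(expr[:, perm], mut[:, perm])
        res2 = scr.compensation_screen(pairs, bundle2, scr.call_inactivation(bundle2))
        assert res1.iloc[0].p_value == pytest.approx(res2.iloc[0].p_value)


class TestCoexpressionScreen:
    def test_pass_requires_both_gates(self):
        rng = np.random.default_rng(11)
        n = 200
        a = rng.standard_normal(n)
        strong = 0.8 * a + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        weak = 0.3 * a + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        expr = np.vstack([a, strong, weak])
        bundle = _bundle(expr)
        pairs = pd.DataFrame({"gene_a": ["g0", "g0"], "gene_b": ["g1", "g2"]})
        res = scr.coexpression_screen(pairs, bundle)
        strong_row = res.iloc[0]
        weak_row = res.iloc[1]
        assert strong_row.passed and strong_row.statistic > 0.5
        # weak pair: p is tiny at n=200 but r <= 0.5, so the r gate rejects it
        assert weak_row.p_value < 0.05 and not weak_row.passed

    def test_boundary_r_exactly_half_fails(self):
        # sum-of-squares construction with exact integer cross-products: r = 1/2
        x = np.tile([1.0, 0.0, -1.0], 30)
        y = np.tile([1.0, -1.0, 0.0], 30)
        res = scr.coexpression_screen(
            pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g1"]}),
            _bundle(np.vstack([x, y])))
        row = res.iloc[0]
        assert row.statistic == pytest.approx(0.5, abs=1e-9)
        assert row.p_value < 0.001
        assert not row.passed

    def test_small_n_high_r_fails_on_p(self):
        # n = 4, r = 0.9 -> two-sided t-test p = 0.1 > 0.05
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 1.6, 3.8, 3.6])
        r, p = scr.pearson_cor_test(x, y)
        t = r * math.sqrt((4 - 2) / (1 - r**2))
        from scipy.stats import t as tdist
        assert p == pytest.approx(2 * tdist.sf(abs(t), df=2), rel=1e-9)
        if p >= 0.05:
            res = scr.coexpression_screen(
                pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g1"]}),
                _bundle(np.vstack([x, y])))
            assert not res.iloc[0].passed

    def test_constant_gene_not_testable(self):
        expr = np.vstack([np.ones(10), np.arange(10.0)])
        res = scr.coexpression_screen(
            pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g1"]}), _bundle(expr))
        assert res.iloc[0].not_testable

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        expr = rng.standard_normal((2, 40))
        res1 = scr.coexpression_screen(
            pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g1"]}), _bundle(expr))
        res2 = scr.coexpression_screen(
            pd.DataFrame({"gene_a": ["g1"], "gene_b": ["g0"]}), _bundle(expr))
        assert res1.iloc[0].statistic == pytest.approx(res2.iloc[0].statistic)
        assert res1.iloc[0].p_value == pytest.approx(res2.iloc[0].p_value)
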