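"""Mechanism screens for synthetic-lethal gene pairs.

Two screens over candidate pairs, following the DAISY-style logic:

* **compensation** — in samples where gene A is inactivated (non-silent
  mutation, or copy-number loss combined with low expression) its SL partner
  B becomes essential and is over-expressed.  Tested with a one-sided
  Wilcoxon rank-sum comparison of B's expression between A-inactive and
  A-active samples (default alpha 0.01, strict).
* **co-expression** — SL partners participate in tightly coupled processes
  and are co-expressed.  Tested with a Pearson correlation (default pass
  rule p < 0.05 and r > 0.5, both strict).

Raw thresholds are applied, mirroring the screening procedure this package
implements; an optional Benjamini-Hochberg correction is available but off
by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .omics_io import OmicsBundle

#: Maximum pooled size for the exact rank-sum null enumeration.
EXACT_MAX_POOLED = 16

DEFAULT_CNV_LOSS_CUTOFF = -0.3
DEFAULT_EXPRESSION_QUANTILE = 0.1
DEFAULT_COMP_ALPHA = 0.01
DEFAULT_COEXPR_ALPHA = 0.05
DEFAULT_R_MIN = 0.5
DEFAULT_MIN_GROUP = 5


@dataclass
class InactivationProfile:
    """Binary gene x sample inactivation calls plus the thresholds used."""

    calls: pd.DataFrame
    rule: dict

    def inactive_samples(self, gene: str) -> np.ndarray:
        return self.calls.loc[gene].to_numpy().astype(bool)


def call_inactivation(
    bundle: OmicsBundle,
    cnv_loss_cutoff: float = DEFAULT_CNV_LOSS_CUTOFF,
    expression_quantile: float = DEFAULT_EXPRESSION_QUANTILE,
) -> InactivationProfile:
    """Call gene inactivation per sample.

    Gene g is inactive in sample s iff it carries a non-silent mutation, or
    its copy number is below ``cnv_loss_cutoff`` while its expression falls
    below the per-gene ``expression_quantile``.  Requires expression plus at
    least one of the mutation/cnv layers.
    """
    if not 0 < expression_quantile < 1:
        raise ParameterError("expression_quantile must lie in (0, 1)")
    if bundle.mutation is None and bundle.cnv is None:
        raise ParameterError("inactivation needs a mutation or cnv layer")
    expr = bundle.expression.to_numpy()
    calls = np.zeros(expr.shape, dtype=bool)
    if bundle.mutation is not None:
        calls |= bundle.mutation.to_numpy().astype(bool)
    if bundle.cnv is not None:
        thresh = np.quantile(expr, expression_quantile, axis=1, keepdims=True)
        low_expr = expr < thresh
        loss = bundle.cnv.to_numpy() < cnv_loss_cutoff
        calls |= loss & low_expr
    rule = {
        "mutation": bundle.mutation is not None,
        "cnv_loss_cutoff": cnv_loss_cutoff,
        "expression_quantile": expression_quantile,
    }
    df = pd.DataFrame(calls.astype(int), index=bundle.genes, columns=bundle.samples)
    return InactivationProfile(calls=df, rule=rule)


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (rank-sum statistic W of x, p-value).

    W is the sum of x's midranks in the pooled ranking.  The p-value is
    exact (full enumeration of the rank-assignment null) when the pooled
    size is at most 16 and there are no ties, otherwise the normal
    approximation with tie and continuity corrections is used.  If every
    pooled value is identical the test is degenerate and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ParameterError("both groups must be non-empty")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}.get(alternative)
    if alt is None:
        raise ParameterError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if np.unique(pooled).size == 1:
        return w, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_POOLED and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alt, method=method, use_continuity=True)
    return w, float(res.pvalue)


SCREEN_COLUMNS = [
    "gene_a", "gene_b", "mechanism", "statistic", "p_value", "effect",
    "direction", "n_inactive", "n_active", "passed", "not_testable",
]


def compensation_screen(
    pairs: pd.DataFrame,
    bundle: OmicsBundle,
    inact: InactivationProfile,
    alpha: float = DEFAULT_COMP_ALPHA,
    min_group: int = DEFAULT_MIN_GROUP,
    alternative: str = "greater",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Compensation screen over canonical gene pairs.

    For each pair (A, B) and both orientations, the partner's expression in
    the conditioning gene's inactive samples is compared against its active
    samples (one-sided "greater" by default: over-expression compensates).
    An orientation is evaluated only when both groups hold at least
    ``min_group`` samples; the pair passes when any evaluated orientation is
    significant (strict p < alpha), and the best (smallest-p) orientation is
    recorded.  Pairs with no evaluable orientation are flagged not_testable.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    gene_idx = {g: i for i, g in enumerate(bundle.genes)}
    expr = bundle.expression.to_numpy()
    calls = inact.calls.to_numpy().astype(bool)
    rows = []
    for a, b in pairs[["gene_a", "gene_b"]].itertuples(index=False):
        best = None
        for cond, meas in ((a, b), (b, a)):
            ic, im = gene_idx.get(cond), gene_idx.get(meas)
            if ic is None or im is None:
                continue
            mask = calls[ic]
            n_in, n_act = int(mask.sum()), int((~mask).sum())
            if n_in < min_group or n_act < min_group:
                continue
            grp_in = expr[im, mask]
            grp_act = expr[im, ~mask]
            w, p = wilcoxon_rank_sum(grp_in, grp_act, alternative=alternative)
            effect = float(np.median(grp_in) - np.median(grp_act))
            cand = {"statistic": w, "p_value": p, "effect": effect,
                    "direction": cond, "n_inactive": n_in, "n_active": n_act}
            if best is None or cand["p_value"] < best["p_value"]:
                best = cand
        if best is None:
            rows.append({"gene_a": a, "gene_b": b, "mechanism": "compensation",
                         "statistic": np.nan, "p_value": np.nan, "effect": np.nan,
                         "direction": "", "n_inactive": 0, "n_active": 0,
                         "passed": False, "not_testable": True})
        else:
            rows.append({"gene_a": a, "gene_b": b, "mechanism": "compensation",
                         **best, "passed": bool(best["p_value"] < alpha),
                         "not_testable": False})
    out = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    if bh_correct and len(out):
        testable = ~out["not_testable"]
        if testable.any():
            _, q, _, _ = multipletests(out.loc[testable, "p_value"], method="fdr_bh")
            out.loc[testable, "p_value_bh"] = q
            out.loc[testable, "passed"] = q < alpha
    return out


def pearson_cor_test(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-test p-value.

    p comes from t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of
    freedom.  Requires n >= 3 and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def coexpression_screen(
    pairs: pd.DataFrame,
    bundle: OmicsBundle,
    alpha: float = DEFAULT_COEXPR_ALPHA,
    r_min: float = DEFAULT_R_MIN,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Co-expression screen: pass iff p < alpha and r > r_min (both strict)."""
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    gene_idx = {g: i for i, g in enumerate(bundle.genes)}
    expr = bundle.expression.to_numpy()
    n = expr.shape[1]
    rows = []
    for a, b in pairs[["gene_a", "gene_b"]].itertuples(index=False):
        ia, ib = gene_idx.get(a), gene_idx.get(b)
        testable = (
            ia is not None and ib is not None and n >= 3
            and np.ptp(expr[ia]) > 0 and np.ptp(expr[ib]) > 0
        )
        if not testable:
            rows.append({"gene_a": a, "gene_b": b, "mechanism": "coexpression",
                         "statistic": np.nan, "p_value": np.nan, "effect": np.nan,
                         "direction": "", "n_inactive": 0, "n_active": n,
                         "passed": False, "not_testable": True})
            continue
        r, p = pearson_cor_test(expr[ia], expr[ib])
        rows.append({"gene_a": a, "gene_b": b, "mechanism": "coexpression",
                     "statistic": r, "p_value": p, "effect": r, "direction": "",
                     "n_inactive": 0, "n_active": n,
                     "passed": bool(p < alpha and r > r_min),
                     "not_testable": False})
    out = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    if bh_correct and len(out):
        testable = ~out["not_testable"]
        if testable.any():
            _, q, _, _ = multipletests(out.loc[testable, "p_value"], method="fdr_bh")
            out.loc[testable, "p_value_bh"] = q
            out.loc[testable, "passed"] = (q < alpha) & (out.loc[testable, "statistic"] > r_min)
    return out
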