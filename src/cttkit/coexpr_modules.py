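"""Weighted co-expression network module detection.

Implements the classic weighted-network workflow from scratch: soft
threshold (power) selection against a scale-free topology criterion,
unsigned adjacency a_ij = |cor_ij|^beta, topological overlap similarity
(TOM), average-linkage hierarchical clustering of 1 - TOM with a static
tree cut, module eigengenes (first principal component of the standardized
module expression) and eigengene correlations.

The static height cut is a deliberate simplification of the dynamic hybrid
tree cut: it is fully specified by two numbers (cut height and minimum
module size) and therefore exactly testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ModuleConfig:
    powers: list[int] = field(default_factory=lambda: list(range(1, 21)))
    rsq_target: float = 0.85
    network_type: str = "unsigned"
    min_module_size: int = 30
    cut_height: float = 0.99

    def __post_init__(self):
        if any(p < 1 for p in self.powers):
            raise ParameterError("powers must be positive integers")
        if not 0 < self.rsq_target < 1:
            raise ParameterError("rsq_target must lie in (0, 1)")
        if self.min_module_size < 2:
            raise ParameterError("min_module_size must be >= 2")
        if self.network_type != "unsigned":
            raise ParameterError("only the unsigned network type is implemented")


@dataclass
class ModuleAssignment:
    """Gene -> module labels (0 = unassigned) plus eigengene summaries."""

    labels: pd.Series
    eigengenes: pd.DataFrame
    beta_used: int
    scale_free_fit: float
    variance_explained: dict[int, float] = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})


def adjacency(expr: np.ndarray, beta: int) -> np.ndarray:
    """Unsigned weighted adjacency a_ij = |pearson r|^beta with unit diagonal.

    ``expr`` is genes x samples.  Constant genes get zero connectivity
    (their correlations are undefined and set to 0, logged).
    """
    if beta < 1:
        raise ParameterError("beta must be >= 1")
    expr = np.asarray(expr, dtype=float)
    sd = expr.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(expr)
    corr = np.nan_to_num(corr, nan=0.0)
    if constant.any():
        logger.info("adjacency: %d constant genes, correlations set to 0",
                    int(constant.sum()))
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivity values are cut into ``n_bins`` equal-width bins; per bin
    the mean connectivity (bin midpoint where the bin is empty or zero) and
    the relative frequency are log10-transformed (frequencies with a 1e-9
    pseudo-count, so empty bins stay in the regression) and regressed.  The
    fit index carries the sign requirement for scale-free topology: it is
    positive R^2 only when the slope is negative.  Returns (fit, slope).
    """
    k = np.asarray(connectivity, dtype=float)
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    dk = np.empty(n_bins)
    pk = np.empty(n_bins)
    for b in range(n_bins):
        members = k[which == b]
        pk[b] = members.size / k.size
        mean = members.mean() if members.size else 0.0
        dk[b] = mean if mean > 0 else mids[b]
    keep = dk > 0
    if keep.sum() < 3:
        return 0.0, 0.0
    lx = np.log10(dk[keep])
    ly = np.log10(pk[keep] + 1e-9)
    res = stats.linregress(lx, ly)
    fit = float(res.rvalue**2) * (-np.sign(res.slope) if res.slope != 0 else 0.0)
    return float(fit), float(res.slope)


@dataclass
class SoftPowerResult:
    beta: int
    fit: float
    reached_target: bool
    table: pd.DataFrame


def pick_soft_power(expr: np.ndarray, config: ModuleConfig | None = None) -> SoftPowerResult:
    """Choose the smallest power whose scale-free fit reaches the target.

    If no candidate reaches ``rsq_target`` the best-fitting power is
    returned with ``reached_target=False`` (logged as a warning).
    """
    config = config or ModuleConfig()
    expr = np.asarray(expr, dtype=float)
    if expr.shape[0] < 20 or expr.shape[1] < 10:
        raise ParameterError("need >= 20 genes and >= 10 samples for power selection")
    if np.ptp(expr) == 0:
        raise ParameterError("degenerate expression matrix (all values equal)")
    rows = []
    for beta in config.powers:
        adj = adjacency(expr, beta)
        connectivity = adj.sum(axis=0) - 1.0
        fit, slope = scale_free_fit(connectivity)
        rows.append({"power": beta, "fit": fit, "slope": slope,
                     "mean_k": float(connectivity.mean())})
        if fit >= config.rsq_target:
            return SoftPowerResult(beta=beta, fit=fit, reached_target=True,
                                   table=pd.DataFrame(rows))
    table = pd.DataFrame(rows)
    best = table.loc[table["fit"].idxmax()]
    logger.warning("pick_soft_power: no power reached fit %.2f; best %.3f at %d",
                   config.rsq_target, best["fit"], int(best["power"]))
    return SoftPowerResult(beta=int(best["power"]), fit=float(best["fit"]),
                           reached_target=False, table=table)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted network.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i the connectivity of node i
    (diagonal excluded).  The diagonal is set to 1.
    """
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(adj, adj.T):
        raise ValidationError("adjacency must be symmetric")
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # (A^2)_ij = sum_u a_iu a_uj with u != i,j since diag 0
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def cluster_modules(
    diss: np.ndarray,
    config: ModuleConfig | None = None,
    genes: list[str] | None = None,
) -> pd.Series:
    """Average-linkage clustering of a dissimilarity with a static height cut.

    Clusters below ``min_module_size`` are relabelled 0 (unassigned);
    surviving clusters are renumbered 1..K by decreasing size, ties broken
    by their lexicographically smallest member gene id.
    """
    config = config or ModuleConfig()
    diss = np.asarray(diss, dtype=float)
    if diss.shape[0] != diss.shape[1] or not np.allclose(diss, diss.T):
        raise ValidationError("dissimilarity must be square and symmetric")
    n = diss.shape[0]
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(n)]
    if n < config.min_module_size:
        logger.warning("cluster_modules: %d genes < min_module_size, all unassigned", n)
        return pd.Series(0, index=genes, dtype=int)
    d = diss.copy()
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    z = linkage(condensed, method="average")
    raw = fcluster(z, t=config.cut_height, criterion="distance")
    by_cluster: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        by_cluster.setdefault(int(c), []).append(g)
    surviving = [c for c, members in by_cluster.items()
                 if len(members) >= config.min_module_size]
    surviving.sort(key=lambda c: (-len(by_cluster[c]), min(by_cluster[c])))
    relabel = {c: i + 1 for i, c in enumerate(surviving)}
    labels = pd.Series([relabel.get(int(c), 0) for c in raw], index=genes, dtype=int)
    return labels


def module_eigengene(
    expr: pd.DataFrame, labels: pd.Series, module_id: int
) -> tuple[pd.Series, float]:
    """First principal component of a module's standardized expression.

    Returns the unit-norm sample-indexed eigengene (sign fixed so that its
    correlation with the mean member profile is non-negative) and the
    fraction of variance it explains.
    """
    members = labels.index[labels == module_id].tolist()
    if len(members) < 2:
        raise ValidationError(f"module {module_id} has fewer than 2 members")
    sub = expr.loc[members].to_numpy()
    sd = sub.std(axis=1, ddof=0)
    mean = sub.mean(axis=1, keepdims=True)
    z = np.where(sd[:, None] > 0, (sub - mean) / np.where(sd[:, None] > 0, sd[:, None], 1.0), 0.0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum()) if (s**2).sum() > 0 else 0.0
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns), var_explained


def module_correlation(eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between module eigengenes (modules x samples input)."""
    if eigengenes.shape[0] < 2:
        raise ParameterError("need >= 2 modules for a correlation matrix")
    corr = np.corrcoef(eigengenes.to_numpy())
    return pd.DataFrame(corr, index=eigengenes.index, columns=eigengenes.index)


def detect_modules(
    expr: pd.DataFrame, config: ModuleConfig | None = None
) -> ModuleAssignment:
    """Full workflow: power selection, adjacency, TOM, clustering, eigengenes."""
    config = config or ModuleConfig()
    mat = expr.to_numpy()
    power = pick_soft_power(mat, config)
    adj = adjacency(mat, power.beta)
    tom = tom_similarity(adj)
    labels = cluster_modules(1.0 - tom, config, genes=list(expr.index))
    eig_rows = {}
    var_explained = {}
    for mid in sorted(set(labels) - {0}):
        eig, ve = module_eigengene(expr, labels, mid)
        eig_rows[mid] = eig
        var_explained[mid] = ve
    eigengenes = pd.DataFrame(eig_rows).T if eig_rows else pd.DataFrame(
        columns=expr.columns
    )
    eigengenes.index.name = "module"
    return ModuleAssignment(labels=labels, eigengenes=eigengenes,
                            beta_used=power.beta, scale_free_fit=power.fit,
                            variance_explained=var_explained)
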