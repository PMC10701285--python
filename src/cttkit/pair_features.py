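"""Fixed-length multi-omics feature vectors for gene pairs.

A gene pair is unordered, so the encoding must be order-invariant: per-gene
summary profiles are combined elementwise as min, max and |difference|, and
pair-level interaction features (correlations across layers, co-mutation
frequency, pathway Jaccard overlap) are symmetric by construction.

Per-gene summaries per layer: expression mean and sample sd, mutation
frequency, cnv mean and sd, methylation mean, the mean of each auxiliary
layer, and the count of pathway memberships.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .omics_io import OmicsBundle

logger = logging.getLogger(__name__)


def _safe_corr(mat: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation with constant rows mapped to 0."""
    sd = mat.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info("pair_features: %d constant rows, correlations set to 0",
                    int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.atleast_2d(np.corrcoef(mat))
    corr = np.nan_to_num(corr, nan=0.0)
    corr = (corr + corr.T) / 2.0  # exact symmetry (corrcoef rounds asymmetrically)
    np.fill_diagonal(corr, 1.0)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    return corr


class PairFeaturizer:
    """Precomputes per-gene profiles and pairwise interaction tables.

    Guarantees one stable feature-name list for the whole run; optional
    layers absent from the bundle simply contribute no features.
    """

    def __init__(self, bundle: OmicsBundle, pathways: dict[str, set[str]] | None = None):
        self.bundle = bundle
        self.pathways = dict(pathways or {})
        self.gene_idx = {g: i for i, g in enumerate(bundle.genes)}

        profile_cols: dict[str, np.ndarray] = {}
        expr = bundle.expression.to_numpy()
        profile_cols["expr_mean"] = expr.mean(axis=1)
        profile_cols["expr_sd"] = expr.std(axis=1, ddof=1)
        self._expr_corr = _safe_corr(expr)

        self._mut_corr = None
        if bundle.mutation is not None:
            mut = bundle.mutation.to_numpy().astype(float)
            profile_cols["mut_freq"] = mut.mean(axis=1)
            self._comut = (mut @ mut.T) / mut.shape[1]
        else:
            self._comut = None

        self._cnv_corr = None
        if bundle.cnv is not None:
            cnv = bundle.cnv.to_numpy()
            profile_cols["cnv_mean"] = cnv.mean(axis=1)
            profile_cols["cnv_sd"] = cnv.std(axis=1, ddof=1)
            self._cnv_corr = _safe_corr(cnv)

        self._meth_corr = None
        if bundle.methylation is not None:
            meth = bundle.methylation.to_numpy()
            profile_cols["meth_mean"] = meth.mean(axis=1)
            self._meth_corr = _safe_corr(meth)

        for name, layer in bundle.auxiliary.items():
            profile_cols[f"aux_{name}_mean"] = layer.to_numpy().mean(axis=1)

        if self.pathways:
            membership = np.zeros((len(bundle.genes), len(self.pathways)), dtype=bool)
            for j, members in enumerate(self.pathways.values()):
                idx = [self.gene_idx[g] for g in members if g in self.gene_idx]
                membership[idx, j] = True
            profile_cols["pathway_count"] = membership.sum(axis=1).astype(float)
            self._membership = membership
        else:
            self._membership = None

        self.profiles = pd.DataFrame(profile_cols, index=bundle.genes)

        names = []
        for col in self.profiles.columns:
            names += [f"min_{col}", f"max_{col}", f"absdiff_{col}"]
        names.append("expr_r")
        if self._comut is not None:
            names.append("comut_freq")
        if self._cnv_corr is not None:
            names.append("cnv_r")
        if self._meth_corr is not None:
            names.append("meth_r")
        if self._membership is not None:
            names.append("pathway_jaccard")
        self.feature_names: list[str] = names

    # ------------------------------------------------------------------
    def gene_profile(self, gene: str) -> pd.Series:
        """Per-layer summary vector for one gene."""
        if gene not in self.gene_idx:
            raise ValidationError(f"unknown gene {gene!r}")
        return self.profiles.loc[gene]

    def _interactions(self, ia: np.ndarray, ib: np.ndarray) -> list[np.ndarray]:
        cols = [self._expr_corr[ia, ib]]
        if self._comut is not None:
            cols.append(self._comut[ia, ib])
        if self._cnv_corr is not None:
            cols.append(self._cnv_corr[ia, ib])
        if self._meth_corr is not None:
            cols.append(self._meth_corr[ia, ib])
        if self._membership is not None:
            inter = (self._membership[ia] & self._membership[ib]).sum(axis=1)
            union = (self._membership[ia] | self._membership[ib]).sum(axis=1)
            with np.errstate(invalid="ignore"):
                jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
            cols.append(jac.astype(float))
        return cols

    def matrix(self, pairs: pd.DataFrame) -> pd.DataFrame:
        """Feature matrix (pairs x features) indexed by ``gene_a|gene_b``.

        Pairs containing an unknown gene are dropped with a logged count;
        row order otherwise follows the input pair table.
        """
        if pairs.empty:
            raise ValidationError("empty pair table")
        known = pairs["gene_a"].isin(self.gene_idx) & pairs["gene_b"].isin(self.gene_idx)
        n_drop = int((~known).sum())
        if n_drop:
            logger.info("pair_features: dropped %d pairs with unknown genes", n_drop)
        sub = pairs.loc[known]
        ia = sub["gene_a"].map(self.gene_idx).to_numpy()
        ib = sub["gene_b"].map(self.gene_idx).to_numpy()
        prof = self.profiles.to_numpy()
        pa, pb = prof[ia], prof[ib]
        blocks = []
        for j in range(prof.shape[1]):
            a, b = pa[:, j], pb[:, j]
            blocks += [np.minimum(a, b), np.maximum(a, b), np.abs(a - b)]
        blocks += self._interactions(ia, ib)
        mat = np.column_stack(blocks) if len(sub) else np.empty((0, len(self.feature_names)))
        idx = sub["gene_a"] + "|" + sub["gene_b"]
        out = pd.DataFrame(mat, columns=self.feature_names, index=idx)
        if not np.isfinite(out.to_numpy()).all():
            raise ValidationError("feature matrix contains non-finite values")
        return out

    def pair_vector(self, gene_a: str, gene_b: str) -> pd.Series:
        """Feature vector for a single (unordered) gene pair."""
        pair = pd.DataFrame({"gene_a": [gene_a], "gene_b": [gene_b]})
        mat = self.matrix(pair)
        if mat.empty:
            raise ValidationError(f"unknown gene in pair ({gene_a}, {gene_b})")
        return mat.iloc[0]


# Convenience wrappers -------------------------------------------------

def gene_profile(gene, bundle, pathways=None) -> pd.Series:
    return PairFeaturizer(bundle, pathways).gene_profile(gene)


def pair_vector(pair, bundle, pathways=None) -> pd.Series:
    a, b = pair
    return PairFeaturizer(bundle, pathways).pair_vector(a, b)


def build_feature_matrix(pairs, bundle, pathways=None) -> pd.DataFrame:
    return PairFeaturizer(bundle, pathways).matrix(pairs)
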