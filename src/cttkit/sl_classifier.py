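"""Training-set construction, randomized-tree classifiers, CV AUC and
consensus prediction of synthetic-lethal pairs.

One classifier is trained per mechanism (compensation / co-expression),
each with positives = known SL pairs passing that mechanism's screen and
negatives sampled at a 1:20 positive:negative ratio from the gene-pair
universe.  The final prediction is the intersection (consensus) of the two
mechanisms' predicted pair sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import ParameterError, ValidationError
from .omics_io import canonical_pairs

DEFAULT_NEGATIVE_RATIO = 20
DEFAULT_N_TREES = 500
DEFAULT_CV_FOLDS = 10
DEFAULT_SCORE_THRESHOLD = 0.5


@dataclass
class TrainingSet:
    positives: pd.DataFrame
    negatives: pd.DataFrame
    mechanism: str
    seed: int


@dataclass
class TrainedClassifier:
    """A fitted tree ensemble plus the metadata needed to reuse it."""

    model: RandomForestClassifier
    feature_names: list[str]
    n_trees: int
    seed: int
    mechanism: str = ""
    cv_auc: float | None = None

    def scores(self, features: pd.DataFrame) -> np.ndarray:
        missing = [n for n in self.feature_names if n not in features.columns]
        if missing:
            raise ValidationError(f"missing feature columns: {missing}")
        X = features.loc[:, self.feature_names].to_numpy()
        return self.model.predict_proba(X)[:, 1]

    def metadata(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "cv_auc": self.cv_auc,
            "feature_names": list(self.feature_names),
        }


def sample_negatives(
    positives: pd.DataFrame,
    gene_universe: list[str],
    ratio: int = DEFAULT_NEGATIVE_RATIO,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample ``ratio`` x |positives| distinct canonical pairs avoiding positives.

    Sampling is uniform over the pair universe (all unordered pairs of
    distinct genes from ``gene_universe``), without replacement, and fully
    reproducible from ``seed``.
    """
    universe = sorted(set(gene_universe))
    n_genes = len(universe)
    pos_keys = {tuple(sorted((a, b)))
                for a, b in positives[["gene_a", "gene_b"]].itertuples(index=False)}
    n_needed = ratio * len(pos_keys)
    n_total = n_genes * (n_genes - 1) // 2
    n_pos_in_universe = sum(a in set(universe) and b in set(universe) for a, b in pos_keys)
    available = n_total - n_pos_in_universe
    if available < n_needed:
        max_ratio = available // max(len(pos_keys), 1)
        raise ParameterError(
            f"universe of {n_genes} genes supports at most {available} negatives "
            f"for {len(pos_keys)} positives (maximum feasible ratio {max_ratio})"
        )
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    while len(chosen) < n_needed:
        k = max(n_needed - len(chosen), 1)
        ii = rng.integers(0, n_genes, size=2 * k)
        for i, j in zip(ii[::2], ii[1::2]):
            if i == j:
                continue
            a, b = universe[i], universe[j]
            key = (a, b) if a < b else (b, a)
            if key in pos_keys or key in chosen:
                continue
            chosen.add(key)
            if len(chosen) == n_needed:
                break
    return pd.DataFrame(sorted(chosen), columns=["gene_a", "gene_b"])


def build_training_set(
    known_pairs: pd.DataFrame,
    screen_results: pd.DataFrame,
    gene_universe: list[str],
    mechanism: str,
    ratio: int = DEFAULT_NEGATIVE_RATIO,
    seed: int = 0,
) -> TrainingSet:
    """Positives = known pairs passing the mechanism screen; negatives sampled."""
    passed = screen_results[screen_results["passed"]]
    positives = canonical_pairs(passed[["gene_a", "gene_b"]])
    if positives.empty:
        raise ValidationError(f"no known pairs passed the {mechanism} screen")
    negatives = sample_negatives(positives, gene_universe, ratio=ratio, seed=seed)
    return TrainingSet(positives=positives, negatives=negatives,
                       mechanism=mechanism, seed=seed)


def rank_auc(scores, labels) -> float:
    """AUC via the rank (Mann-Whitney) formulation with midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ParameterError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def train_model(
    features: pd.DataFrame,
    labels,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    mechanism: str = "",
) -> TrainedClassifier:
    """Fit a random-forest ensemble; scores are in [0, 1].

    The reported score is the forest's positive-class probability (the mean
    of per-tree leaf frequencies, which for fully grown trees equals the
    fraction of trees voting positive).
    """
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ParameterError("training labels contain a single class")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(features.to_numpy(), y)
    return TrainedClassifier(model=model, feature_names=list(features.columns),
                             n_trees=n_trees, seed=seed, mechanism=mechanism)


def cv_auc(
    features: pd.DataFrame,
    labels,
    k: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> float:
    """Stratified k-fold CV AUC from pooled out-of-fold scores."""
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ParameterError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k"
        )
    X = features.to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.empty(y.size, dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        model = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        model.fit(X[train_idx], y[train_idx])
        pooled[test_idx] = model.predict_proba(X[test_idx])[:, 1]
    return rank_auc(pooled, y)


def predict_pairs(
    model: TrainedClassifier,
    candidates: pd.DataFrame,
    features: pd.DataFrame,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> pd.DataFrame:
    """Score candidate pairs; a pair is predicted when score > threshold (strict)."""
    scores = model.scores(features)
    out = candidates[["gene_a", "gene_b"]].copy().reset_index(drop=True)
    out["score"] = scores
    out["predicted"] = out["score"] > threshold
    return out


def consensus(pred_comp: pd.DataFrame, pred_coexpr: pd.DataFrame) -> pd.DataFrame:
    """Intersection of the two mechanisms' predicted pair sets.

    Scores are carried along as ``score_comp`` / ``score_coexpr``.  An empty
    intersection is returned as an empty table (with a warning in the log).
    """
    a = pred_comp[pred_comp["predicted"]][["gene_a", "gene_b", "score"]]
    b = pred_coexpr[pred_coexpr["predicted"]][["gene_a", "gene_b", "score"]]
    merged = a.merge(b, on=["gene_a", "gene_b"], suffixes=("_comp", "_coexpr"))
    if merged.empty:
        logging.getLogger(__name__).warning("consensus: empty intersection")
    return merged.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
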