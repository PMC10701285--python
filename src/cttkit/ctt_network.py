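"""Predicted-SL network construction, per-module hub selection and coverage.

Core therapeutic targets (CTTs) are the highest-degree genes ("hubs") of
the predicted synthetic-lethality network within each co-expression module:
per module the top ``fraction`` (default 1%) of members present in the
graph are selected, with a minimum of one per module.  Degree is computed
in the full predicted-SL graph by default, because SL partners routinely
straddle module boundaries; an induced-subgraph mode is available.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import pandas as pd

from .errors import ParameterError

logger = logging.getLogger(__name__)

DEFAULT_HUB_FRACTION = 0.01


def build_sl_graph(pairs: pd.DataFrame) -> nx.Graph:
    """Undirected graph from a canonical pair table (duplicate edges collapse)."""
    g = nx.Graph()
    if pairs.empty:
        logger.warning("build_sl_graph: empty pair table")
        return g
    g.add_edges_from(pairs[["gene_a", "gene_b"]].itertuples(index=False, name=None))
    return g


def select_ctts(
    graph: nx.Graph,
    labels: pd.Series,
    fraction: float = DEFAULT_HUB_FRACTION,
    within_module_degree: bool = False,
) -> pd.DataFrame:
    """Select per-module hub genes by degree.

    For each module m with n_m members present in the graph, the
    ceil(fraction * n_m) highest-degree members are selected (minimum one).
    Ties at the cutoff are broken by higher degree then lexicographically
    smaller gene id.  Unassigned genes (module 0) are never selected.
    Modules with no member in the graph are skipped with a warning.
    """
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must lie in (0, 1]")
    rows = []
    for mid in sorted(set(labels) - {0}):
        members = [g for g in labels.index[labels == mid] if g in graph]
        if not members:
            logger.warning("select_ctts: module %d has no member in the graph", mid)
            continue
        if within_module_degree:
            sub = graph.subgraph(members)
            degree = {g: sub.degree(g) for g in members}
        else:
            degree = {g: graph.degree(g) for g in members}
        n_select = max(1, math.ceil(fraction * len(members)))
        ordered = sorted(members, key=lambda g: (-degree[g], g))
        for rank, gene in enumerate(ordered[:n_select], start=1):
            rows.append({"gene": gene, "module": mid, "degree": degree[gene],
                         "rank_within_module": rank})
    return pd.DataFrame(rows, columns=["gene", "module", "degree", "rank_within_module"])


def coverage(pairs: pd.DataFrame, ctts) -> tuple[int, float]:
    """Number and fraction of pairs with at least one member in ``ctts``."""
    ctts = set(ctts)
    if pairs.empty:
        return 0, 0.0
    hit = pairs["gene_a"].isin(ctts) | pairs["gene_b"].isin(ctts)
    covered = int(hit.sum())
    return covered, covered / len(pairs)
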