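"""Regulatory and drug-network joins for CTTs, plus over-representation tests.

Joins core-therapeutic-target (CTT) gene sets against regulator tables
(miRNA, lncRNA, super-enhancer) and drug-target tables.  Drugs reach CTTs
either directly (drug -> gene) or through a two-hop path via a regulatory
element (drug -> regulator -> gene).

Pathway/GO enrichment is an in-package hypergeometric over-representation
test on user-supplied GMT gene sets with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

logger = logging.getLogger(__name__)


def map_regulators(ctts, reg_table: pd.DataFrame) -> pd.DataFrame:
    """Restrict a regulator edge table to edges targeting CTTs (deduplicated)."""
    ctts = set(ctts)
    out = reg_table[reg_table["target"].isin(ctts)].drop_duplicates().reset_index(drop=True)
    if out.empty:
        logger.warning("map_regulators: no regulator targets a CTT")
    return out


def regulator_target_counts(reg_edges: pd.DataFrame) -> pd.Series:
    """Distinct CTT-target count per regulator."""
    if reg_edges.empty:
        return pd.Series(dtype=int)
    return reg_edges.groupby("regulator")["target"].nunique().sort_values(ascending=False)


def map_drugs(
    ctts, reg_edges: pd.DataFrame, drug_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Drug network over CTTs: direct edges and two-hop edges via regulators.

    Returns the edge table (columns drug, via, gene, kind) and per-drug
    distinct reachable-CTT counts.  ``via`` is empty for direct edges.  The
    two-hop edges are exactly the relational join of the drug table
    (target_class != gene) with the regulator edge table restricted to CTT
    targets.
    """
    ctts = set(ctts)
    rows = []
    direct = drug_table[(drug_table["target_class"] == "gene")
                        & drug_table["target"].isin(ctts)]
    for drug, target in direct[["drug", "target"]].itertuples(index=False):
        rows.append({"drug": drug, "via": "", "gene": target, "kind": "direct"})
    reg_hits = reg_edges[reg_edges["target"].isin(ctts)]
    indirect = drug_table[drug_table["target_class"] != "gene"]
    joined = indirect.merge(reg_hits, left_on="target", right_on="regulator")
    for drug, reg, gene in joined[["drug", "regulator", "target_y"]].itertuples(index=False):
        rows.append({"drug": drug, "via": reg, "gene": gene, "kind": "two_hop"})
    edges = pd.DataFrame(rows, columns=["drug", "via", "gene", "kind"]).drop_duplicates()
    edges = edges.reset_index(drop=True)
    if edges.empty:
        counts = pd.Series(dtype=int)
    else:
        counts = edges.groupby("drug")["gene"].nunique().sort_values(ascending=False)
    return edges, counts


def hypergeom_enrich(
    query, sets: dict[str, set[str]], universe
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    p = P[X >= overlap] with X ~ Hypergeom(N=|universe|, K=|set|, n=|query|);
    gene sets are intersected with the universe first, FDR by
    Benjamini-Hochberg across sets, result sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ParameterError("empty universe")
    query = set(query) & universe
    rows = []
    for name, members in sets.items():
        members = set(members) & universe
        overlap = len(query & members)
        p = float(hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
        rows.append({"set_name": name, "overlap": overlap, "set_size": len(members),
                     "query_size": len(query), "universe_size": len(universe),
                     "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = []
        return out
    _, fdr, _, _ = multipletests(out["p_value"], method="fdr_bh")
    out["fdr"] = fdr
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
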