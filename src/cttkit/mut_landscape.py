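"""Somatic-mutation landscape summaries for a gene set.

Given parsed MAF records and a gene set of interest (e.g. the CTTs, or
their complement among SL genes), this module tabulates variant
classifications, variant types and the six pyrimidine-referenced SNV
substitution classes, per-sample mutation burden (TMB as a raw qualifying
variant count, not per-megabase), the top mutated genes by distinct mutated
samples, and an oncoplot-style gene x sample category matrix.

Silent variants are excluded by default, matching oncoplot conventions.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .errors import ParameterError
from .omics_io import MAFRecord

logger = logging.getLogger(__name__)

#: The 12 ordered single-base substitutions collapsed to 6 classes by
#: complementing purine-origin changes to their pyrimidine equivalent.
SNV_CLASS = {
    ("C", "A"): "C>A", ("G", "T"): "C>A",
    ("C", "G"): "C>G", ("G", "C"): "C>G",
    ("C", "T"): "C>T", ("G", "A"): "C>T",
    ("T", "A"): "T>A", ("A", "T"): "T>A",
    ("T", "C"): "T>C", ("A", "G"): "T>C",
    ("T", "G"): "T>G", ("A", "C"): "T>G",
}

MULTI_HIT = "Multi_Hit"


def classify_snv(ref: str, alt: str) -> str:
    """Map a single-nucleotide substitution to one of the six SNV classes."""
    if len(ref) != 1 or len(alt) != 1:
        raise ParameterError(f"not an SNV: {ref}>{alt}")
    if ref == alt:
        raise ParameterError(f"ref equals alt: {ref}")
    key = (ref.upper(), alt.upper())
    if key not in SNV_CLASS:
        raise ParameterError(f"unrecognized substitution {ref}>{alt}")
    return SNV_CLASS[key]


@dataclass
class MutationSummary:
    classification_counts: dict[str, int]
    type_counts: dict[str, int]
    snv_class_counts: dict[str, int]
    per_sample_burden: pd.Series
    top_genes: list[tuple[str, int]]
    oncomatrix: pd.DataFrame
    n_records: int = 0
    n_classification_kinds: int = 0

    def to_dict(self) -> dict:
        return {
            "classification_counts": dict(self.classification_counts),
            "type_counts": dict(self.type_counts),
            "snv_class_counts": dict(self.snv_class_counts),
            "per_sample_burden": self.per_sample_burden.to_dict(),
            "top_genes": [list(t) for t in self.top_genes],
            "n_records": self.n_records,
            "n_classification_kinds": self.n_classification_kinds,
        }


def _qualifying(records, gene_set, include_silent):
    gene_set = set(gene_set)
    for rec in records:
        if rec.gene not in gene_set:
            continue
        if not include_silent and rec.variant_classification == "Silent":
            continue
        yield rec


def summarize_maf(
    records: list[MAFRecord],
    gene_set,
    top_k: int = 10,
    include_silent: bool = False,
) -> MutationSummary:
    """Summarize qualifying records for the genes in ``gene_set``.

    Top genes are ranked by the number of distinct mutated samples (ties
    broken lexicographically).  The oncomatrix cell for (gene, sample) is
    the variant classification, or ``Multi_Hit`` when more than one
    distinct classification is observed for that cell.
    """
    if not gene_set:
        raise ParameterError("gene_set is empty")
    quals = list(_qualifying(records, gene_set, include_silent))
    if not quals:
        logger.warning("summarize_maf: no qualifying records")
    classification = Counter(r.variant_classification for r in quals)
    types = Counter(r.variant_type for r in quals)
    snv = Counter()
    for r in quals:
        if r.variant_type == "SNP" and len(r.ref) == 1 and len(r.alt) == 1:
            snv[classify_snv(r.ref, r.alt)] += 1
    burden = Counter(r.sample for r in quals)
    burden_s = pd.Series(dict(burden), dtype=int).sort_index()

    cell_classes: dict[tuple[str, str], set[str]] = defaultdict(set)
    gene_samples: dict[str, set[str]] = defaultdict(set)
    for r in quals:
        cell_classes[(r.gene, r.sample)].add(r.variant_classification)
        gene_samples[r.gene].add(r.sample)
    ranked = sorted(gene_samples.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    top = [(g, len(s)) for g, s in ranked[:top_k]]

    genes_seen = sorted(gene_samples)
    samples_seen = sorted({r.sample for r in quals})
    onco = pd.DataFrame("", index=genes_seen, columns=samples_seen, dtype=object)
    for (g, s), classes in cell_classes.items():
        onco.loc[g, s] = MULTI_HIT if len(classes) > 1 else next(iter(classes))

    return MutationSummary(
        classification_counts=dict(classification),
        type_counts=dict(types),
        snv_class_counts=dict(snv),
        per_sample_burden=burden_s,
        top_genes=top,
        oncomatrix=onco,
        n_records=len(quals),
        n_classification_kinds=len(classification),
    )


def tmb(records: list[MAFRecord], gene_set, include_silent: bool = False) -> pd.Series:
    """Per-sample count of qualifying variants within ``gene_set``.

    Raw counts (no per-megabase normalization).  Samples without qualifying
    records are absent from the result; use ``.reindex`` with a sample
    registry to materialize zeros.
    """
    counts = Counter(r.sample for r in _qualifying(records, gene_set, include_silent))
    return pd.Series(dict(counts), dtype=int).sort_index()
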