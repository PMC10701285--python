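"""Reading, validation, alignment and imputation of multi-omics input tables.

All matrices are pandas DataFrames with gene identifiers on the index and
sample identifiers on the columns.  An :class:`OmicsBundle` groups the layers
after alignment to a common gene/sample registry, which is the intersection
of identifiers across the supplied layers.

Supported on-disk formats are plain text only: TSV matrices, MAF mutation
tables, two-column pair lists, GMT gene sets, BED-like super-enhancer tables
and typed edge TSVs (regulator and drug tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Tokens treated as missing in TSV matrices (case-insensitive).
MISSING_TOKENS = ["", "NA", "NaN", "na", "nan", "NAN", "null", "NULL"]

#: Mandatory MAF columns (header-name lookup; order-independent).
MAF_REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Variant_Type",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
)


@dataclass(frozen=True)
class MAFRecord:
    """One somatic variant call from a MAF file."""

    sample: str
    gene: str
    variant_classification: str
    variant_type: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class OmicsBundle:
    """Aligned gene x sample matrices across omics layers.

    ``expression`` is mandatory; ``mutation`` (binary), ``cnv`` (log2
    copy-ratio convention, 0 = neutral) and ``methylation`` (beta values in
    [0, 1]) are optional, as are any named ``auxiliary`` layers (histone,
    DNase, ...).  All present layers share identical gene and sample
    ordering and contain no missing values.
    """

    genes: list[str]
    samples: list[str]
    expression: pd.DataFrame
    mutation: pd.DataFrame | None = None
    cnv: pd.DataFrame | None = None
    methylation: pd.DataFrame | None = None
    auxiliary: dict[str, pd.DataFrame] = field(default_factory=dict)

    def layers(self) -> dict[str, pd.DataFrame]:
        out = {"expression": self.expression}
        for name in ("mutation", "cnv", "methylation"):
            layer = getattr(self, name)
            if layer is not None:
                out[name] = layer
        out.update(self.auxiliary)
        return out

    def validate(self) -> None:
        for name, layer in self.layers().items():
            if list(layer.index) != self.genes or list(layer.columns) != self.samples:
                raise ValidationError(f"layer {name!r} is not aligned to the registry")
            if layer.isna().any().any():
                raise ValidationError(f"layer {name!r} contains missing values")
        if self.mutation is not None:
            vals = self.mutation.to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError("mutation entries must be in {0, 1}")
        if self.methylation is not None:
            vals = self.methylation.to_numpy()
            if vals.min() < 0 or vals.max() > 1:
                raise ValidationError("methylation entries must lie in [0, 1]")


def read_matrix(path, layer: str = "matrix") -> pd.DataFrame:
    """Read a gene x sample TSV matrix (first column gene ids, first row samples).

    Empty cells and "NA"/"NaN" (case-insensitive) are treated as missing.
    Duplicate gene ids or duplicate sample ids are rejected.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=MISSING_TOKENS,
            keep_default_na=False, dtype=str,
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{layer}: empty file {path}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{layer}: no sample columns found in {path} (line 1)")
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise ValidationError(f"{layer}: duplicate gene ids in {path}: {dup_genes}")
    dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise ValidationError(f"{layer}: duplicate sample ids in {path}: {dup_samples}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{layer}: non-numeric cell in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def impute_gene_mean(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing entry by the mean of the observed entries of its gene row.

    Observed entries are left untouched.  A gene row with no observed value
    cannot be imputed and raises :class:`ValidationError` naming the genes.
    """
    all_missing = matrix.index[matrix.isna().all(axis=1)].tolist()
    if all_missing:
        raise ValidationError(f"genes with no observed values: {all_missing}")
    if not matrix.isna().any().any():
        return matrix.copy()
    row_means = matrix.mean(axis=1, skipna=True)
    out = matrix.copy()
    return out.apply(lambda row: row.fillna(row_means[row.name]), axis=1)


def read_maf(path) -> list[MAFRecord]:
    """Parse a MAF file into records; '#'-prefixed lines are skipped.

    Columns are located by header name, so column order is irrelevant;
    missing mandatory columns raise :class:`FormatError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty MAF file {path}") from exc
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"MAF {path} lacks mandatory columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        rec = MAFRecord(
            sample=getattr(row, "Tumor_Sample_Barcode"),
            gene=getattr(row, "Hugo_Symbol"),
            variant_classification=getattr(row, "Variant_Classification"),
            variant_type=getattr(row, "Variant_Type"),
            chrom=str(getattr(row, "Chromosome")),
            pos=int(getattr(row, "Start_Position")),
            ref=getattr(row, "Reference_Allele"),
            alt=getattr(row, "Tumor_Seq_Allele2"),
        )
        records.append(rec)
    return records


def maf_to_mutation_matrix(
    records: list[MAFRecord],
    genes: list[str],
    samples: list[str],
    include_silent: bool = False,
) -> pd.DataFrame:
    """Binary gene x sample mutation indicator from MAF records.

    Entry (g, s) is 1 iff at least one qualifying record exists; Silent
    variants are excluded unless ``include_silent``.  Genes/samples without
    records stay 0 (missing mutation data is interpreted as absence).
    Records for genes or samples outside the registries are dropped with a
    logged count.
    """
    mat = pd.DataFrame(0, index=list(genes), columns=list(samples), dtype=int)
    gene_set, sample_set = set(genes), set(samples)
    dropped = 0
    for rec in records:
        if not include_silent and rec.variant_classification == "Silent":
            continue
        if rec.gene not in gene_set or rec.sample not in sample_set:
            dropped += 1
            continue
        mat.loc[rec.gene, rec.sample] = 1
    if dropped:
        logger.info("maf_to_mutation_matrix: dropped %d records outside registry", dropped)
    return mat


def canonical_pairs(pairs) -> pd.DataFrame:
    """Canonicalize an iterable/DataFrame of gene pairs.

    Each pair is sorted lexicographically, self-pairs are dropped and
    duplicates collapsed; the result is sorted for order-invariance.
    """
    if isinstance(pairs, pd.DataFrame):
        rows = pairs.iloc[:, :2].astype(str).to_numpy().tolist()
    else:
        rows = [[str(a), str(b)] for a, b in pairs]
    seen = set()
    n_dup = n_self = 0
    for a, b in rows:
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in seen:
            n_dup += 1
        seen.add(key)
    if n_dup or n_self:
        logger.info("canonical_pairs: dropped %d duplicates, %d self-pairs", n_dup, n_self)
    out = pd.DataFrame(sorted(seen), columns=["gene_a", "gene_b"])
    return out


def read_pairs(path) -> pd.DataFrame:
    """Read a two-column (or wider) gene-pair TSV and canonicalize it."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty pair file {path}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"pair file {path} needs >= 2 columns")
    out = canonical_pairs(df)
    if out.empty:
        logger.warning("read_pairs: %s yielded no valid pairs", path)
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT {path} line {lineno}: fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise ValidationError(f"GMT {path}: duplicate set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


#: Expected header per edge-table schema.
EDGE_SCHEMAS = {
    "regulator": ("regulator", "regulator_class", "target"),
    "drug": ("drug", "target", "target_class"),
}

REGULATOR_CLASSES = {"miRNA", "lncRNA", "super_enhancer"}
DRUG_TARGET_CLASSES = {"gene", "miRNA", "lncRNA", "super_enhancer"}


def read_edges(path, schema: str) -> pd.DataFrame:
    """Read a typed edge TSV (``regulator`` or ``drug`` schema), deduplicated."""
    if schema not in EDGE_SCHEMAS:
        raise ValidationError(f"unknown edge schema {schema!r}")
    cols = EDGE_SCHEMAS[schema]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty edge file {path}") from exc
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"edge file {path} lacks columns {missing}")
    df = df.loc[:, list(cols)].drop_duplicates().reset_index(drop=True)
    classes = REGULATOR_CLASSES if schema == "regulator" else DRUG_TARGET_CLASSES
    class_col = "regulator_class" if schema == "regulator" else "target_class"
    bad = sorted(set(df[class_col]) - classes)
    if bad:
        raise ValidationError(f"edge file {path}: unknown {class_col} values {bad}")
    return df


def read_bed_superenhancers(path) -> pd.DataFrame:
    """Read a BED-like super-enhancer table (chrom, start, end, se_id, target_gene).

    Coordinates are 0-based half-open (standard BED).  Returned as a
    regulator-schema edge table with class ``super_enhancer``.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if df.shape[1] < 5:
        raise FormatError(f"super-enhancer BED {path} needs 5 columns")
    df = df.iloc[:, :5]
    df.columns = ["chrom", "start", "end", "se_id", "target_gene"]
    if (df["start"].astype(int) < 0).any():
        raise ValidationError(f"super-enhancer BED {path}: negative start")
    edges = pd.DataFrame({
        "regulator": df["se_id"],
        "regulator_class": "super_enhancer",
        "target": df["target_gene"],
    }).drop_duplicates().reset_index(drop=True)
    return edges


def write_table(obj, path) -> None:
    """Write a DataFrame (or a pair table) to TSV; round-trips read_matrix."""
    obj = pd.DataFrame(obj)
    has_named_index = obj.index.name is not None or not isinstance(
        obj.index, pd.RangeIndex
    )
    obj.to_csv(path, sep="\t", index=has_named_index)


def truncate_tcga_barcodes(samples: list[str], length: int = 12) -> list[str]:
    """Optionally normalize TCGA-style sample barcodes to their first 12 chars."""
    return [s[:length] for s in samples]


def build_bundle(
    expression: pd.DataFrame,
    mutation: pd.DataFrame | None = None,
    cnv: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
    auxiliary: dict[str, pd.DataFrame] | None = None,
    impute: bool = True,
) -> OmicsBundle:
    """Align layers to the intersection of gene/sample ids and impute.

    Real-valued layers are gene-mean imputed; the mutation layer has missing
    entries set to 0.  Drop counts per layer are logged.
    """
    auxiliary = dict(auxiliary or {})
    named = {"expression": expression, "mutation": mutation, "cnv": cnv,
             "methylation": methylation, **auxiliary}
    present = {k: v for k, v in named.items() if v is not None}
    genes = None
    samples = None
    for layer in present.values():
        gset = set(layer.index)
        sset = set(layer.columns)
        genes = gset if genes is None else genes & gset
        samples = sset if samples is None else samples & sset
    if not genes or not samples:
        raise ValidationError("no common genes or samples across layers")
    genes = sorted(genes)
    samples = sorted(samples)
    aligned: dict[str, pd.DataFrame] = {}
    for name, layer in present.items():
        n_drop_g = layer.shape[0] - len(genes)
        n_drop_s = layer.shape[1] - len(samples)
        if n_drop_g or n_drop_s:
            logger.info("build_bundle: layer %s dropped %d genes, %d samples",
                        name, n_drop_g, n_drop_s)
        sub = layer.loc[genes, samples]
        if name == "mutation":
            sub = sub.fillna(0).astype(int)
        elif impute and sub.isna().any().any():
            sub = impute_gene_mean(sub)
        aligned[name] = sub
    bundle = OmicsBundle(
        genes=genes,
        samples=samples,
        expression=aligned["expression"],
        mutation=aligned.get("mutation"),
        cnv=aligned.get("cnv"),
        methylation=aligned.get("methylation"),
        auxiliary={k: aligned[k] for k in auxiliary if k in aligned},
    )
    bundle.validate()
    return bundle
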