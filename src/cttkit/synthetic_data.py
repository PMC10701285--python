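"""Synthetic multi-omics bundles with planted synthetic-lethal structure.

The generator emulates the shapes of a tumor multi-omics cohort on a
continuous, post-normalization expression scale:

* expression: unit-variance Gaussian per gene, with block-correlated
  co-expression modules (one shared latent factor per module with loading
  sqrt(within_module_r)),
* planted compensation SL pairs (A, B): gene A is forcibly inactivated
  (non-silent mutation) in a fixed sample subset, in exactly which B's
  expression is shifted upward by ``comp_shift`` within-gene standard
  deviations.  Compensation pairs additionally carry baseline within-pair
  co-expression (``comp_coexpr_r``): SL partners act in coupled pathways,
  so the compensation and co-expression signatures co-occur on the same
  pair, which is what makes an intersection of mechanism-specific
  predictions non-degenerate,
* planted co-expression SL pairs at a target Pearson correlation
  ``coexpr_r`` (in expectation),
* binary mutations at a background per-gene/sample rate with a
  hypermutator sample subpopulation at 10x the rate,
* real-valued copy number (standard normal) with focal loss events of mean
  -1, and Beta(2, 2) methylation values.

The planted compensation-pair and co-expression-pair sets are disjoint by
construction.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .omics_io import MAFRecord, OmicsBundle, MAF_REQUIRED_COLUMNS

HYPERMUTATOR_RATE_MULTIPLIER = 10.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_genes: int = 500
    n_samples: int = 200
    n_modules: int = 2
    module_size: int = 50
    within_module_r: float = 0.7
    n_comp_pairs: int = 100
    comp_shift: float = 2.0
    comp_inactive_fraction: float = 0.15
    comp_coexpr_r: float = 0.7
    n_coexpr_pairs: int = 100
    coexpr_r: float = 0.7
    mutation_rate: float = 0.05
    hypermutator_fraction: float = 0.05
    cnv_loss_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        needed = (self.n_modules * self.module_size
                  + 2 * self.n_comp_pairs + 2 * self.n_coexpr_pairs)
        if needed > self.n_genes:
            raise ParameterError(
                f"config needs {needed} genes (modules + planted pairs) "
                f"but n_genes={self.n_genes}"
            )
        for name in ("mutation_rate", "hypermutator_fraction", "cnv_loss_rate",
                     "comp_inactive_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")
        for name in ("within_module_r", "coexpr_r", "comp_coexpr_r"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must lie in (0, 1)")
        if self.n_genes > 99999:
            raise ParameterError("n_genes above the gene-name padding limit")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, echoing the generator config."""

    planted_comp_pairs: pd.DataFrame
    planted_coexpr_pairs: pd.DataFrame
    module_labels: pd.Series
    comp_inactive_samples: dict[str, list[str]]
    config: dict = field(default_factory=dict)

    def all_planted_pairs(self) -> pd.DataFrame:
        out = pd.concat([self.planted_comp_pairs, self.planted_coexpr_pairs])
        return out.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_bundle(config: SimulationConfig) -> tuple[OmicsBundle, SyntheticTruth]:
    """Generate one synthetic cohort and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_g, n_s = config.n_genes, config.n_samples
    genes = _gene_names(n_g)
    samples = [f"S{j:04d}" for j in range(n_s)]

    # gene layout: [module blocks | comp A | comp B | coexpr A | coexpr B | background]
    cursor = 0
    module_labels = pd.Series(0, index=genes, dtype=int)
    module_members: list[list[int]] = []
    for m in range(config.n_modules):
        idx = list(range(cursor, cursor + config.module_size))
        module_members.append(idx)
        module_labels.iloc[idx] = m + 1
        cursor += config.module_size
    comp_a = list(range(cursor, cursor + config.n_comp_pairs)); cursor += config.n_comp_pairs
    comp_b = list(range(cursor, cursor + config.n_comp_pairs)); cursor += config.n_comp_pairs
    coex_a = list(range(cursor, cursor + config.n_coexpr_pairs)); cursor += config.n_coexpr_pairs
    coex_b = list(range(cursor, cursor + config.n_coexpr_pairs)); cursor += config.n_coexpr_pairs

    expr = rng.standard_normal((n_g, n_s))

    r = config.within_module_r
    for idx in module_members:
        factor = rng.standard_normal(n_s)
        expr[idx, :] = np.sqrt(r) * factor + np.sqrt(1 - r) * expr[idx, :]

    rc = config.coexpr_r
    for ia, ib in zip(coex_a, coex_b):
        expr[ib, :] = rc * expr[ia, :] + np.sqrt(1 - rc**2) * expr[ib, :]

    # mutations: background + hypermutators, then forced inactivation of comp-A genes
    rate = np.full(n_s, config.mutation_rate)
    n_hyper = int(round(config.hypermutator_fraction * n_s))
    hyper = rng.choice(n_s, size=n_hyper, replace=False) if n_hyper else np.array([], int)
    rate[hyper] = min(1.0, HYPERMUTATOR_RATE_MULTIPLIER * config.mutation_rate)
    mutation = (rng.random((n_g, n_s)) < rate[None, :]).astype(int)

    ccr = config.comp_coexpr_r
    n_inactive = max(1, int(round(config.comp_inactive_fraction * n_s)))
    comp_inactive: dict[str, list[str]] = {}
    for ia, ib in zip(comp_a, comp_b):
        expr[ib, :] = ccr * expr[ia, :] + np.sqrt(1 - ccr**2) * expr[ib, :]
        subset = rng.choice(n_s, size=n_inactive, replace=False)
        mutation[ia, subset] = 1
        expr[ib, subset] += config.comp_shift * expr[ib, :].std()
        comp_inactive[genes[ia]] = sorted(samples[j] for j in subset)

    cnv = rng.standard_normal((n_g, n_s))
    loss = rng.random((n_g, n_s)) < config.cnv_loss_rate
    cnv[loss] = rng.normal(-1.0, 0.3, size=int(loss.sum()))

    methylation = rng.beta(2.0, 2.0, size=(n_g, n_s))

    bundle = OmicsBundle(
        genes=genes,
        samples=samples,
        expression=pd.DataFrame(expr, index=genes, columns=samples),
        mutation=pd.DataFrame(mutation, index=genes, columns=samples),
        cnv=pd.DataFrame(cnv, index=genes, columns=samples),
        methylation=pd.DataFrame(methylation, index=genes, columns=samples),
    )
    bundle.validate()

    comp_pairs = pd.DataFrame(
        sorted((genes[ia], genes[ib]) for ia, ib in zip(comp_a, comp_b)),
        columns=["gene_a", "gene_b"],
    )
    coex_pairs = pd.DataFrame(
        sorted((genes[ia], genes[ib]) for ia, ib in zip(coex_a, coex_b)),
        columns=["gene_a", "gene_b"],
    )
    truth = SyntheticTruth(
        planted_comp_pairs=comp_pairs,
        planted_coexpr_pairs=coex_pairs,
        module_labels=module_labels,
        comp_inactive_samples=comp_inactive,
        config=asdict(config),
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# deterministic small fixtures for annotation / mutation-landscape tests

MIRNA_REGULATOR = "hsa-miR-30c-5p"
LNCRNA_REGULATOR = "RAD51-AS1"
SE_REGULATOR = "SE_chr1_0001"
TWO_HOP_DRUG_MIRNA = "Isolinderalactone"
TWO_HOP_DRUG_LNCRNA = "Corylin"
DIRECT_DRUG = "Bortezomib"

#: CTT-target counts wired for the two-hop drugs.
MIRNA_TARGET_COUNT = 4
LNCRNA_TARGET_COUNT = 11


@dataclass
class FixtureTables:
    regulators: pd.DataFrame
    drugs: pd.DataFrame
    gmt: dict[str, set[str]]
    maf_records: list[MAFRecord]
    answer_key: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.regulators.to_csv(outdir / "regulators.tsv", sep="\t", index=False)
        self.drugs.to_csv(outdir / "drugs.tsv", sep="\t", index=False)
        with open(outdir / "pathways.gmt", "w") as fh:
            for name, members in self.gmt.items():
                fh.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")
        maf_rows = [
            {
                "Hugo_Symbol": r.gene,
                "Tumor_Sample_Barcode": r.sample,
                "Variant_Classification": r.variant_classification,
                "Variant_Type": r.variant_type,
                "Chromosome": r.chrom,
                "Start_Position": r.pos,
                "Reference_Allele": r.ref,
                "Tumor_Seq_Allele2": r.alt,
            }
            for r in self.maf_records
        ]
        pd.DataFrame(maf_rows, columns=list(MAF_REQUIRED_COLUMNS)).to_csv(
            outdir / "mutations.maf", sep="\t", index=False
        )
        with open(outdir / "answer_key.json", "w") as fh:
            json.dump(self.answer_key, fh, indent=2, sort_keys=True)


def make_fixture_tables(ctts, seed: int = 0) -> FixtureTables:
    """Small deterministic regulator/drug/GMT/MAF fixtures wired to CTTs.

    The two-hop drug motifs mirror well-known network shapes: one drug
    targets a miRNA regulating exactly 4 CTTs, another targets a lncRNA
    regulating exactly 11 CTTs, and one drug hits a CTT gene directly.
    The 12-record MAF ships its own answer key so downstream summaries are
    hand-checkable.  Byte-identical output for identical inputs.
    """
    ctts = sorted(set(ctts))
    if len(ctts) < LNCRNA_TARGET_COUNT:
        raise ParameterError(
            f"need >= {LNCRNA_TARGET_COUNT} CTTs to wire the fixture motifs"
        )
    del seed  # the fixtures are fully deterministic; kept for interface symmetry

    reg_rows = (
        [{"regulator": MIRNA_REGULATOR, "regulator_class": "miRNA", "target": g}
         for g in ctts[:MIRNA_TARGET_COUNT]]
        + [{"regulator": LNCRNA_REGULATOR, "regulator_class": "lncRNA", "target": g}
           for g in ctts[:LNCRNA_TARGET_COUNT]]
        + [{"regulator": SE_REGULATOR, "regulator_class": "super_enhancer",
            "target": g} for g in ctts[:2]]
    )
    regulators = pd.DataFrame(reg_rows)

    drugs = pd.DataFrame([
        {"drug": TWO_HOP_DRUG_MIRNA, "target": MIRNA_REGULATOR, "target_class": "miRNA"},
        {"drug": TWO_HOP_DRUG_LNCRNA, "target": LNCRNA_REGULATOR, "target_class": "lncRNA"},
        {"drug": DIRECT_DRUG, "target": ctts[0], "target_class": "gene"},
    ])

    gmt = {
        "synthetic_set_a": set(ctts[:5]),
        "synthetic_set_b": set(ctts[2:8]),
        "synthetic_set_c": set(ctts[-4:]),
    }

    g1, g2, g3, g4 = ctts[:4]
    spec = [
        ("S1", g1, "Missense_Mutation", "SNP", "1", 1000, "C", "T"),
        ("S2", g1, "Missense_Mutation", "SNP", "1", 1005, "G", "A"),
        ("S3", g1, "Nonsense_Mutation", "SNP", "1", 1010, "C", "A"),
        ("S1", g2, "Missense_Mutation", "SNP", "2", 2000, "A", "G"),
        ("S2", g2, "Nonsense_Mutation", "SNP", "2", 2005, "G", "T"),
        ("S3", g2, "Nonsense_Mutation", "SNP", "2", 2010, "C", "G"),
        ("S1", g3, "Missense_Mutation", "SNP", "3", 3000, "T", "G"),
        ("S2", g3, "Missense_Mutation", "SNP", "3", 3020, "G", "C"),
        ("S4", g3, "Frame_Shift_Del", "DEL", "3", 3010, "AC", "-"),
        ("S4", g1, "Frame_Shift_Del", "DEL", "1", 1020, "CT", "-"),
        ("S3", g4, "Silent", "SNP", "4", 4000, "C", "T"),
        ("S4", g4, "Silent", "SNP", "4", 4005, "A", "T"),
    ]
    maf_records = [
        MAFRecord(sample=s, gene=g, variant_classification=c, variant_type=t,
                  chrom=ch, pos=p, ref=rf, alt=al)
        for s, g, c, t, ch, p, rf, al in spec
    ]

    answer_key = {
        "n_maf_records": len(spec),
        "classification_counts": {"Missense_Mutation": 5, "Nonsense_Mutation": 3,
                                  "Frame_Shift_Del": 2},
        "type_counts": {"SNP": 8, "DEL": 2},
        "snv_class_counts": {"C>T": 2, "C>A": 2, "C>G": 2, "T>C": 1, "T>G": 1},
        "per_sample_burden": {"S1": 3, "S2": 3, "S3": 2, "S4": 2},
        "top_genes": [[g1, 4], [g2, 3], [g3, 3]],
        "mirna_drug_reach": MIRNA_TARGET_COUNT,
        "lncrna_drug_reach": LNCRNA_TARGET_COUNT,
    }
    return FixtureTables(regulators=regulators, drugs=drugs, gmt=gmt,
                         maf_records=maf_records, answer_key=answer_key)


def write_input_dir(outdir, config: SimulationConfig) -> Path:
    """Materialize a complete input directory for the pipeline CLI.

    Writes the omics matrices, the known-pair table (the planted truth,
    standing in for a curated SL database) and ``truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle, truth = simulate_bundle(config)
    bundle.expression.to_csv(outdir / "expression.tsv", sep="\t")
    bundle.mutation.to_csv(outdir / "mutation.tsv", sep="\t")
    bundle.cnv.to_csv(outdir / "cnv.tsv", sep="\t")
    bundle.methylation.to_csv(outdir / "methylation.tsv", sep="\t")
    truth.all_planted_pairs().to_csv(outdir / "known_pairs.tsv", sep="\t", index=False)
    payload = {
        "config": truth.config,
        "planted_comp_pairs": truth.planted_comp_pairs.to_numpy().tolist(),
        "planted_coexpr_pairs": truth.planted_coexpr_pairs.to_numpy().tolist(),
        "module_labels": truth.module_labels.to_dict(),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return outdir
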