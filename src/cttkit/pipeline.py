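"""End-to-end orchestration of the CTT identification workflow.

Stage order: screen -> pair features -> per-mechanism training -> candidate
prediction -> consensus -> co-expression modules -> hub (CTT) selection ->
regulatory/drug annotation -> mutation landscape.  Every stage's defaults
are the workflow's canonical parameter values (compensation alpha 0.01,
co-expression alpha 0.05 with r > 0.5, 1:20 negative sampling, 500 trees,
tenfold CV, top-1% hubs per module).

A run writes all stage outputs plus ``manifest.json`` (parameters, seeds,
input digests and per-stage record counts) into the output directory.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import coexpr_modules as cm
from . import ctt_network as cn
from . import mut_landscape as ml
from . import omics_io as io
from . import sl_classifier as clf
from . import sl_screen as scr
from .errors import CttkitError, ParameterError, ValidationError
from .pair_features import PairFeaturizer

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and stage parameters for one pipeline run."""

    # input paths (expression + known_pairs mandatory)
    expression: str = ""
    mutation: str = ""
    cnv: str = ""
    methylation: str = ""
    known_pairs: str = ""
    pathways_gmt: str = ""
    regulators: str = ""
    superenhancer_bed: str = ""
    drugs: str = ""
    maf: str = ""
    candidates: str = ""
    outdir: str = "cttkit_run"

    # screen parameters
    cnv_loss_cutoff: float = scr.DEFAULT_CNV_LOSS_CUTOFF
    expression_quantile: float = scr.DEFAULT_EXPRESSION_QUANTILE
    comp_alpha: float = scr.DEFAULT_COMP_ALPHA
    coexpr_alpha: float = scr.DEFAULT_COEXPR_ALPHA
    r_min: float = scr.DEFAULT_R_MIN
    min_group: int = scr.DEFAULT_MIN_GROUP

    # classifier parameters
    negative_ratio: int = clf.DEFAULT_NEGATIVE_RATIO
    n_trees: int = clf.DEFAULT_N_TREES
    cv_folds: int = clf.DEFAULT_CV_FOLDS
    score_threshold: float = clf.DEFAULT_SCORE_THRESHOLD

    # module / hub parameters
    min_module_size: int = 30
    cut_height: float = 0.99
    hub_fraction: float = cn.DEFAULT_HUB_FRACTION

    seed: int = 0

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides or {})
        known = {f.name: f.type for f in fields(cls)}
        unknown = sorted(set(raw) - set(known))
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.expression:
            raise ValidationError("config key 'expression' (path) is required")
        if not self.known_pairs:
            raise ValidationError("config key 'known_pairs' (path) is required")
        for key in ("expression", "mutation", "cnv", "methylation", "known_pairs",
                    "pathways_gmt", "regulators", "superenhancer_bed", "drugs",
                    "maf", "candidates"):
            path = getattr(self, key)
            if path and not Path(path).is_file():
                raise ValidationError(f"config key {key!r}: file not found: {path}")
        for key, lo, hi in (("comp_alpha", 0, 1), ("coexpr_alpha", 0, 1),
                            ("expression_quantile", 0, 1), ("hub_fraction", 0, 1)):
            v = getattr(self, key)
            if not lo < v <= hi:
                raise ValidationError(f"config key {key!r} out of range: {v}")
        if self.negative_ratio < 1 or self.n_trees < 1 or self.cv_folds < 2:
            raise ValidationError("negative_ratio/n_trees/cv_folds out of range")


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(cfg: RunConfig) -> dict:
    """Read and align every configured input."""
    expression = io.read_matrix(cfg.expression, "expression")
    mutation = io.read_matrix(cfg.mutation, "mutation") if cfg.mutation else None
    cnv = io.read_matrix(cfg.cnv, "cnv") if cfg.cnv else None
    methylation = io.read_matrix(cfg.methylation, "methylation") if cfg.methylation else None
    bundle = io.build_bundle(expression, mutation, cnv, methylation)
    data = {
        "bundle": bundle,
        "known_pairs": io.read_pairs(cfg.known_pairs),
        "pathways": io.read_gmt(cfg.pathways_gmt) if cfg.pathways_gmt else {},
        "regulators": io.read_edges(cfg.regulators, "regulator") if cfg.regulators else None,
        "drugs": io.read_edges(cfg.drugs, "drug") if cfg.drugs else None,
        "maf": io.read_maf(cfg.maf) if cfg.maf else None,
        "candidates": io.read_pairs(cfg.candidates) if cfg.candidates else None,
    }
    if cfg.superenhancer_bed:
        se = io.read_bed_superenhancers(cfg.superenhancer_bed)
        regs = data["regulators"]
        data["regulators"] = pd.concat([regs, se]) if regs is not None else se
    return data


def candidate_pairs(known_pairs: pd.DataFrame, bundle: io.OmicsBundle) -> pd.DataFrame:
    """Default candidate universe: all pairs among genes of the known-SL input
    that are present in the bundle."""
    genes = sorted(
        (set(known_pairs["gene_a"]) | set(known_pairs["gene_b"])) & set(bundle.genes)
    )
    return pd.DataFrame(itertools.combinations(genes, 2), columns=["gene_a", "gene_b"])


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": asdict(cfg),
        "inputs": {k: _digest(getattr(cfg, k))
                   for k in ("expression", "mutation", "cnv", "methylation",
                             "known_pairs", "pathways_gmt", "regulators",
                             "superenhancer_bed", "drugs", "maf", "candidates")
                   if getattr(cfg, k)},
        "stages": {},
    }
    stage = "load"
    try:
        data = load_inputs(cfg)
        bundle = data["bundle"]
        known = data["known_pairs"]
        known = known[known["gene_a"].isin(bundle.genes)
                      & known["gene_b"].isin(bundle.genes)].reset_index(drop=True)
        manifest["stages"]["load"] = {
            "n_genes": len(bundle.genes), "n_samples": len(bundle.samples),
            "n_known_pairs": len(known),
        }

        stage = "screen"
        inact = scr.call_inactivation(bundle, cfg.cnv_loss_cutoff, cfg.expression_quantile)
        comp = scr.compensation_screen(known, bundle, inact, alpha=cfg.comp_alpha,
                                       min_group=cfg.min_group)
        coex = scr.coexpression_screen(known, bundle, alpha=cfg.coexpr_alpha,
                                       r_min=cfg.r_min)
        io.write_table(comp, outdir / "screens_compensation.tsv")
        io.write_table(coex, outdir / "screens_coexpression.tsv")
        manifest["stages"]["screen"] = {
            "compensation_passed": int(comp["passed"].sum()),
            "coexpression_passed": int(coex["passed"].sum()),
        }

        stage = "features"
        featurizer = PairFeaturizer(bundle, data["pathways"])
        manifest["stages"]["features"] = {"n_features": len(featurizer.feature_names)}

        stage = "train"
        models = {}
        for mechanism, screen_df in (("compensation", comp), ("coexpression", coex)):
            ts = clf.build_training_set(known, screen_df, bundle.genes,
                                        mechanism, ratio=cfg.negative_ratio,
                                        seed=cfg.seed)
            train_pairs = pd.concat([ts.positives, ts.negatives], ignore_index=True)
            X = featurizer.matrix(train_pairs)
            y = [1] * len(ts.positives) + [0] * len(ts.negatives)
            model = clf.train_model(X, y, n_trees=cfg.n_trees, seed=cfg.seed,
                                    mechanism=mechanism)
            model.cv_auc = clf.cv_auc(X, y, k=cfg.cv_folds, seed=cfg.seed,
                                      n_trees=cfg.n_trees)
            models[mechanism] = model
            with open(outdir / f"model_{mechanism}.json", "w") as fh:
                json.dump(model.metadata(), fh, indent=2)
            manifest["stages"].setdefault("train", {})[mechanism] = {
                "n_positives": len(ts.positives), "n_negatives": len(ts.negatives),
                "cv_auc": model.cv_auc,
            }

        stage = "predict"
        cands = data["candidates"]
        if cands is None:
            cands = candidate_pairs(known, bundle)
        Xc = featurizer.matrix(cands)
        preds = {}
        for mechanism, model in models.items():
            pred = clf.predict_pairs(model, cands, Xc, threshold=cfg.score_threshold)
            preds[mechanism] = pred
            io.write_table(pred, outdir / f"predictions_{mechanism}.tsv")
        cons = clf.consensus(preds["compensation"], preds["coexpression"])
        io.write_table(cons, outdir / "consensus_pairs.tsv")
        manifest["stages"]["predict"] = {
            "n_candidates": len(cands),
            "compensation_predicted": int(preds["compensation"]["predicted"].sum()),
            "coexpression_predicted": int(preds["coexpression"]["predicted"].sum()),
            "n_consensus": len(cons),
        }

        stage = "modules"
        cons_genes = sorted(set(cons["gene_a"]) | set(cons["gene_b"]))
        mod_cfg = cm.ModuleConfig(min_module_size=cfg.min_module_size,
                                  cut_height=cfg.cut_height)
        if len(cons_genes) >= 20:
            assignment = cm.detect_modules(bundle.expression.loc[cons_genes], mod_cfg)
        else:
            logger.warning("modules: only %d consensus genes, none assigned",
                           len(cons_genes))
            assignment = cm.ModuleAssignment(
                labels=pd.Series(0, index=cons_genes, dtype=int),
                eigengenes=pd.DataFrame(columns=bundle.samples),
                beta_used=0, scale_free_fit=float("nan"))
        labels_df = assignment.labels.rename("module").rename_axis("gene")
        labels_df.to_frame().to_csv(outdir / "module_labels.tsv", sep="\t")
        assignment.eigengenes.to_csv(outdir / "module_eigengenes.tsv", sep="\t")
        if len(assignment.module_ids) >= 2:
            cm.module_correlation(assignment.eigengenes).to_csv(
                outdir / "module_correlation.tsv", sep="\t")
        manifest["stages"]["modules"] = {
            "n_modules": len(assignment.module_ids),
            "beta_used": assignment.beta_used,
            "scale_free_fit": assignment.scale_free_fit,
        }

        stage = "hubs"
        graph = cn.build_sl_graph(cons)
        ctts = cn.select_ctts(graph, assignment.labels, fraction=cfg.hub_fraction)
        io.write_table(ctts, outdir / "ctts.tsv")
        io.write_table(cons[["gene_a", "gene_b"]], outdir / "sl_edges.tsv")
        covered, cov_frac = cn.coverage(cons, set(ctts["gene"]))
        with open(outdir / "coverage.json", "w") as fh:
            json.dump({"covered_pairs": covered, "fraction": cov_frac,
                       "n_ctts": len(ctts)}, fh, indent=2)
        manifest["stages"]["hubs"] = {
            "n_ctts": len(ctts), "covered_pairs": covered,
            "coverage_fraction": cov_frac,
        }

        ctt_genes = set(ctts["gene"])
        if data["regulators"] is not None:
            stage = "annotate"
            reg_edges = ann.map_regulators(ctt_genes, data["regulators"])
            io.write_table(reg_edges, outdir / "regulator_edges.tsv")
            manifest["stages"]["annotate"] = {"n_regulator_edges": len(reg_edges)}
            if data["drugs"] is not None:
                stage = "drugs"
                drug_edges, reach = ann.map_drugs(ctt_genes, reg_edges, data["drugs"])
                io.write_table(drug_edges, outdir / "drug_edges.tsv")
                manifest["stages"]["drugs"] = {
                    "n_drug_edges": len(drug_edges),
                    "per_drug_reach": reach.to_dict(),
                }
        if data["pathways"] and ctt_genes:
            stage = "enrichment"
            enrich = ann.hypergeom_enrich(ctt_genes, data["pathways"], bundle.genes)
            io.write_table(enrich, outdir / "enrichment.tsv")
            manifest["stages"]["enrichment"] = {"n_sets": len(enrich)}
        if data["maf"] is not None and ctt_genes:
            stage = "mutsum"
            sl_genes = set(cons["gene_a"]) | set(cons["gene_b"])
            for tag, gene_set in (("ctts", ctt_genes),
                                  ("non_ctts", sl_genes - ctt_genes)):
                if not gene_set:
                    continue
                summary = ml.summarize_maf(data["maf"], gene_set)
                with open(outdir / f"mutsum_{tag}.json", "w") as fh:
                    json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
                manifest["stages"].setdefault("mutsum", {})[tag] = {
                    "n_records": summary.n_records,
                    "n_classification_kinds": summary.n_classification_kinds,
                }
    except CttkitError as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
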