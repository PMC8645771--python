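"""Pipeline orchestrator: association -> correction -> enrichment -> subnetworks.

Each stage is a function that can run standalone (the CLI calls them) or as
part of :func:`run_pipeline`, which executes all four in order and writes a
manifest recording versions, seeds, the tuned correction exponent, all
thresholds and input checksums. Identical config + inputs give identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from gwaspathnet import __version__, io
from gwaspathnet.config import RunConfig
from gwaspathnet.gene_scores import (
    allelic_test_matrix, genomic_inflation, map_snps_to_genes, tune_lambda,
    gene_score_table,
)
from gwaspathnet.enrichment import filter_pathways, run_enrichment
from gwaspathnet.subnetwork import select_seeds, decompose, annotate_subnetwork

log = logging.getLogger("gwaspathnet")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _read_study(cfg: RunConfig):
    if cfg.genotype_dialect == "ped_map":
        base = Path(cfg.genotypes)
        return io.read_ped_map(base.with_suffix(".ped"), base.with_suffix(".map"))
    if cfg.genotype_dialect == "tsv":
        return io.read_genotype_tsv(cfg.genotypes)
    raise ValueError(f"unknown genotype dialect: {cfg.genotype_dialect}")


def stage_assoc(cfg: RunConfig, study=None):
    """Per-SNP allelic tests plus the genomic-inflation diagnostic."""
    if study is None:
        study = _read_study(cfg)
    snp_results = allelic_test_matrix(study)
    inflation = genomic_inflation(snp_results["chi2"])
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_snp_results(snp_results, out / "snp_results.tsv")
    log.info("assoc: %d SNPs, genomic inflation %.3f", len(snp_results),
             inflation)
    return study, snp_results, inflation


def stage_correct(cfg: RunConfig, study=None, snp_results=None):
    """SNP-to-gene mapping, exponent tuning, corrected gene score table."""
    if study is None:
        study, snp_results, _ = stage_assoc(cfg)
    elif snp_results is None:
        snp_results = allelic_test_matrix(study)
    gene_models = io.read_bed(cfg.gene_models)
    assignment = map_snps_to_genes(study.snps, gene_models, cfg.flank_bp)
    if cfg.lambda_mode == "auto":
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, cfg.lambda_grid_step),
                        10)
        fit = tune_lambda(study, assignment, grid,
                          n_perm=cfg.lambda_permutations, seed=cfg.seed)
        lam = fit.lambda_star
        lam_info = fit.as_dict()
    else:
        lam = float(cfg.lambda_mode)
        lam_info = {"lambda_star": lam, "mode": "fixed"}
    scores = gene_score_table(study, assignment, lam, snp_results)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_gene_scores(scores, out / "gene_scores.tsv")
    (out / "lambda.json").write_text(json.dumps(lam_info, indent=1))
    log.info("correct: lambda = %.2f over %d genes (%d without SNPs)", lam,
             len(scores), len(assignment.genes_without_snps))
    return study, assignment, lam, scores, gene_models


def stage_enrich(cfg: RunConfig, scores=None, *, study=None, assignment=None,
                 lam=None):
    """Pathway enrichment for the configured methods and weighting modes."""
    if scores is None:
        study, assignment, lam, scores, _ = stage_correct(cfg)
    collection = io.read_gmt(cfg.pathways)
    collection = filter_pathways(collection, scores["gene_id"],
                                 cfg.pathway_min_size, cfg.pathway_max_size)
    prior = io.read_prior_tsv(cfg.prior_scores) if cfg.prior_scores else None
    if prior is None and cfg.weighting != "equal":
        raise FileNotFoundError(
            "weighted enrichment requires the prior-score table "
            "(prior_scores input is missing)")
    modes = (["weighted", "equal"] if cfg.weighting == "both"
             else [cfg.weighting])
    frames = []
    for mode in modes:
        frames.append(run_enrichment(
            scores, collection, prior,
            methods=("gsea", "ss", "hyper"), weighting=mode,
            B=cfg.n_permutations, scheme=cfg.permutation_scheme,
            seed=cfg.seed, sig_threshold=cfg.gene_sig_threshold,
            q_star=cfg.fdr_q, study=study, assignment=assignment, lam=lam))
    results = pd.concat(frames, ignore_index=True)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.10g")
    log.info("enrich: %d pathways x %d method rows", len(collection),
             len(results))
    return results, collection


def stage_subnet(cfg: RunConfig, scores=None, gene_models=None):
    """Seed selection, flow-based decomposition, subnetwork annotation."""
    if scores is None:
        _, _, _, scores, gene_models = stage_correct(cfg)
    prior = io.read_prior_tsv(cfg.prior_scores)
    network = io.read_edge_tsv(cfg.network)
    lengths = None
    if gene_models is not None:
        lengths = gene_models.set_index("gene_id")["length"]
    seed_set = select_seeds(scores, prior, cfg.seed_p_cutoff,
                            cfg.cs_cutoff_mode, lengths)
    subnets = decompose(network, seed_set, cfg.subnetwork_node_limit)
    collection = io.read_gmt(cfg.pathways)
    universe = scores["gene_id"]
    for sn in subnets:
        annotate_subnetwork(sn, collection, universe)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "subnetworks.json").write_text(json.dumps(
        [sn.to_dict() for sn in subnets], indent=1))
    summary = pd.DataFrame([{
        "rank": i + 1, "n_node": sn.n_node, "r_node": sn.r_node,
        "zscore": sn.zscore, "p_hyper": sn.p_hyper,
        "singleton": sn.singleton,
        "top_annotation": (sn.annotations["set_id"].iloc[0]
                           if sn.annotations is not None
                           and not sn.annotations.empty else ""),
    } for i, sn in enumerate(subnets)])
    summary.to_csv(out / "subnetworks_summary.tsv", sep="\t", index=False,
                   float_format="%.6g")
    log.info("subnet: %d seeds -> %d subnetworks", len(seed_set.seed_genes),
             len(subnets))
    return seed_set, subnets


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all four stages in order; abort with the stage name on error."""
    t0 = time.time()
    timings = {}
    try:
        study, snp_results, inflation = stage_assoc(cfg)
        timings["assoc_s"] = round(time.time() - t0, 3)
    except Exception as e:
        raise PipelineError("assoc", e) from e
    try:
        t = time.time()
        study, assignment, lam, scores, gene_models = stage_correct(
            cfg, study, snp_results)
        timings["correct_s"] = round(time.time() - t, 3)
    except Exception as e:
        raise PipelineError("correct", e) from e
    try:
        t = time.time()
        results, collection = stage_enrich(
            cfg, scores, study=study, assignment=assignment, lam=lam)
        timings["enrich_s"] = round(time.time() - t, 3)
    except Exception as e:
        raise PipelineError("enrich", e) from e
    try:
        t = time.time()
        seed_set, subnets = stage_subnet(cfg, scores, gene_models)
        timings["subnet_s"] = round(time.time() - t, 3)
    except Exception as e:
        raise PipelineError("subnet", e) from e

    inputs = {}
    for name in ("gene_models", "pathways", "prior_scores", "network"):
        p = getattr(cfg, name)
        if p:
            inputs[name] = _checksum(p)
    if cfg.genotype_dialect == "ped_map":
        base = Path(cfg.genotypes)
        inputs["genotypes_ped"] = _checksum(base.with_suffix(".ped"))
        inputs["genotypes_map"] = _checksum(base.with_suffix(".map"))
    else:
        inputs["genotypes"] = _checksum(cfg.genotypes)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "lambda": lam,
        "genomic_inflation": inflation,
        "n_permutations": cfg.n_permutations,
        "permutation_scheme": cfg.permutation_scheme,
        "flank_bp": cfg.flank_bp,
        "pathway_size_bounds": [cfg.pathway_min_size, cfg.pathway_max_size],
        "gene_sig_threshold": cfg.gene_sig_threshold,
        "fdr_q": cfg.fdr_q,
        "weighting": cfg.weighting,
        "input_checksums": inputs,
        "timings": timings,
    }
    out = Path(cfg.out_dir)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "study": study, "snp_results": snp_results, "inflation": inflation,
        "lambda": lam, "gene_scores": scores, "enrichment": results,
        "seed_set": seed_set, "subnetworks": subnets, "manifest": manifest,
    }
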