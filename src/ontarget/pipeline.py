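"""End-to-end orchestration: simulate -> normalize -> DE -> target calls ->
GSEA -> MARA -> motif-pathway association -> connectivity signatures.

A single :class:`RunConfig` carries every threshold (all defaulting to the
framework's standard values: CPM >= 5, DE q <= 0.05, GSEA p <= 0.05 or
FDR <= 0.20 with set sizes 5..500 and 1000 permutations, MARA site
threshold 150, association FDR < 0.05, signature size 50 with 100 random
null signatures and a +-80 score threshold) plus one global seed.  The seed
fans out to per-stage seeds through ``numpy.random.SeedSequence.spawn`` so
stages are individually reproducible, and a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import diffexpr, gsea, ingest, mara, signatures, simulate, targetclass

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and flags of one pipeline run."""

    # ingest
    cpm_threshold: float = 5.0
    # differential expression
    de_alpha: float = 0.05
    batch_covariate: bool = False
    # target classification
    kd_both: bool = False
    # GSEA
    gsea_p: float = 0.05
    gsea_fdr: float = 0.20
    min_set_size: int = 5
    max_set_size: int = 500
    n_perm: int = 1000
    weight_p: float = 1.0
    nes_mode: str = "mean"
    # MARA
    min_sites: int = 150
    mara_alpha: float = 0.05
    ridge_lambda: str | float = "auto"
    # association
    assoc_alpha: float = 0.05
    restrict_assoc: bool = True
    # signatures
    signature_k: int = 50
    n_random_signatures: int = 100
    score_threshold: float = 80.0
    signature_fdr: float = 0.05
    # global
    seed: int = 0
    simulate: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        order = ["simulate", "gsea", "signatures"]
        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return int(children[order.index(stage)].generate_state(1)[0] % (2**31))


def validate_config(path) -> RunConfig:
    """Load a YAML config; unknown keys and type errors are all reported at once."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    errors = []
    for key, val in raw.items():
        if key not in fields:
            errors.append(f"unknown key {key!r}")
            continue
    cfg_kwargs = {k: v for k, v in raw.items() if k in fields}
    cfg = RunConfig(**cfg_kwargs)
    for name, lower in [("n_perm", 1), ("min_set_size", 1), ("signature_k", 1), ("n_random_signatures", 2)]:
        v = getattr(cfg, name)
        if not isinstance(v, int) or v < lower:
            errors.append(f"{name} must be an integer >= {lower}, got {v!r}")
    for name in ("cpm_threshold", "de_alpha", "gsea_p", "gsea_fdr", "assoc_alpha", "score_threshold"):
        v = getattr(cfg, name)
        if not isinstance(v, (int, float)) or v < 0:
            errors.append(f"{name} must be a nonnegative number, got {v!r}")
    if cfg.nes_mode not in ("mean", "max"):
        errors.append(f"nes_mode must be 'mean' or 'max', got {cfg.nes_mode!r}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return cfg


def _gene_level_signs(de: pd.DataFrame, gene_map: ingest.PromoterGeneMap) -> pd.DataFrame:
    """Collapse the promoter DE table to genes: per contrast, each gene takes
    the row of its most significant promoter (ties by |lfc| then ID)."""
    tbl = de.copy()
    tbl["gene"] = [gene_map.gene_of(p) for p in tbl.index]
    tbl = tbl.dropna(subset=["gene"])
    tbl = tbl.assign(_abs=tbl.lfc.abs(), _id=tbl.index.astype(str))
    tbl = tbl.sort_values(["p", "_abs", "_id"], ascending=[True, False, True], kind="mergesort")
    best = tbl.groupby(["gene", "contrast"], sort=True).head(1)
    return best.set_index("gene").drop(columns=["_abs", "_id"])


def run_all(
    config: RunConfig,
    out_dir,
    inputs: tuple | None = None,
) -> dict:
    """Run every stage in order; returns a provenance dict (also written).

    ``inputs`` may supply a pre-built experiment (the 5-tuple produced by
    :func:`ontarget.simulate.simulate_experiment`); otherwise one is
    simulated from ``config.simulate`` with the stage seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov: dict = {"seed": config.seed, "thresholds": dataclasses.asdict(config), "stages": {}}

    # --- simulate / load -------------------------------------------------
    if inputs is None:
        sim_cfg = simulate.SimConfig(**config.simulate)
        sim_cfg.seed = config.stage_seed("simulate")
        inputs = simulate.simulate_experiment(sim_cfg)
    counts, site_matrix, gene_sets, gene_map, truth = inputs[:5]
    prov["stages"]["simulate"] = {"n_promoters": counts.counts.shape[0], "n_samples": counts.counts.shape[1]}

    # --- ingest ----------------------------------------------------------
    factors = ingest.rle_normalize(counts)
    filtered = ingest.cpm_filter(counts, factors, config.cpm_threshold)
    factors_f = factors  # factors computed on the full matrix
    expr = ingest.log_transform(filtered, factors_f)
    cpm_mat = ingest.cpm(filtered, factors_f)
    prov["stages"]["ingest"] = {"n_promoters_kept": filtered.counts.shape[0]}

    # --- differential expression -----------------------------------------
    contrasts = simulate.standard_contrasts(counts.metadata)
    de = diffexpr.fit_contrasts(expr, contrasts, batch_covariate=config.batch_covariate, alpha=config.de_alpha)
    de.to_csv(out / "de_table.tsv", sep="\t")
    prov["stages"]["diffexpr"] = {"n_tests": len(de), "n_q_le_alpha": int((de.q <= config.de_alpha).sum())}

    # --- gene-level target classification ---------------------------------
    gde = _gene_level_signs(de, gene_map)
    cmap = {"drug": simulate.contrast_map()}
    gene_calls = targetclass.classify_table(gde, cmap, cell_line="SIMCELL", kd_both=config.kd_both)
    gene_calls.to_csv(out / "gene_calls.tsv", sep="\t", index=False)
    targetclass.summarize_calls(gene_calls).to_csv(out / "gene_call_summary.tsv", sep="\t", index=False)
    prov["stages"]["targetclass"] = {
        "n_calls": len(gene_calls),
        "labels": gene_calls.label.value_counts().to_dict(),
    }

    # --- GSEA -------------------------------------------------------------
    gene_cpm = ingest.collapse_to_genes(cpm_mat, gene_map)
    gene_expr = np.log2(gene_cpm + 1.0)
    gsea_seed = config.stage_seed("gsea")
    meta = counts.metadata
    ctrl = list(meta.index[meta.treatment == "control"])
    gsea_results: dict[str, pd.DataFrame] = {}
    for key, sel in [
        ("kd1", meta.treatment == "kd1"),
        ("kd2", meta.treatment == "kd2"),
        ("6h", (meta.treatment == "drug") & (meta.timepoint == "6h")),
        ("48h", (meta.treatment == "drug") & (meta.timepoint == "48h")),
    ]:
        ranked = gsea.signal_to_noise(gene_expr, list(meta.index[sel]), ctrl)
        gsea_results[key] = gsea.gsea_run(
            ranked,
            gene_sets,
            n_perm=config.n_perm,
            min_size=config.min_set_size,
            max_size=config.max_set_size,
            weight_p=config.weight_p,
            seed=gsea_seed,
            nes_mode=config.nes_mode,
        )
        res_out = gsea_results[key].copy()
        res_out["leading_edge"] = res_out["leading_edge"].map(",".join)
        res_out.to_csv(out / f"gsea_{key}.tsv", sep="\t", index=False)
    pathway_calls = gsea.classify_pathways(
        gsea_results,
        drug="drug",
        cell_line="SIMCELL",
        p_threshold=config.gsea_p,
        fdr_threshold=config.gsea_fdr,
        kd_both=config.kd_both,
    )
    pathway_calls.to_csv(out / "pathway_calls.tsv", sep="\t", index=False)
    prov["stages"]["gsea"] = {
        "n_sets_tested": len(gsea_results["48h"]),
        "pathway_labels": pathway_calls.label.value_counts().to_dict(),
    }

    # --- MARA -------------------------------------------------------------
    site_f = site_matrix.loc[site_matrix.index.intersection(expr.values.index)]
    site_kept = mara.filter_motifs(site_f, config.min_sites)
    act = mara.fit_activities(expr.values, site_kept, ridge_lambda=config.ridge_lambda)
    drug48 = list(meta.index[(meta.treatment == "drug") & (meta.timepoint == "48h")])
    diff_act = mara.differential_activity(act, drug48, ctrl, alpha=config.mara_alpha)
    act.activities.to_csv(out / "motif_activities.tsv", sep="\t")
    diff_act.to_csv(out / "motif_differential.tsv", sep="\t")
    prov["stages"]["mara"] = {
        "n_motifs": act.activities.shape[0],
        "ridge_lambda": act.ridge_lambda,
        "n_diff_motifs": int((diff_act.sign != 0).sum()),
    }

    # --- motif-pathway association ----------------------------------------
    targets = mara.motif_targets(site_kept, gene_map)
    # universe: expressed genes with >=1 promoter represented in the site matrix
    covered = {gene_map.gene_of(p) for p in site_kept.index}
    universe = set(gene_cpm.index) & covered
    diff_motifs = list(diff_act.index[diff_act.sign != 0]) if config.restrict_assoc else None
    sig_pw = (
        list(gsea_results["48h"].loc[gsea.significant(gsea_results["48h"], config.gsea_p, config.gsea_fdr), "set"])
        if config.restrict_assoc
        else None
    )
    if config.restrict_assoc and (not diff_motifs or not sig_pw):
        logger.warning("association restriction left no pairs; falling back to the full scan")
        diff_motifs = sig_pw = None
    pairs = assoc_mod.motif_pathway_scan(
        targets, gene_sets, universe, diff_motifs=diff_motifs, sig_pathways=sig_pw, alpha=config.assoc_alpha
    )
    pairs.to_csv(out / "motif_pathway_pairs.tsv", sep="\t", index=False)
    prov["stages"]["assoc"] = {
        "n_pairs_tested": len(pairs),
        "n_significant": int(pairs["significant"].sum()) if len(pairs) else 0,
    }

    # --- connectivity signatures -------------------------------------------
    sig_seed = config.stage_seed("signatures")
    query = signatures.make_signature(gde[gde.contrast == "drug_48h_vs_ctrl"], "drug_48h", k=config.signature_k)
    references = {}
    for key, sel in [("kd1_profile", meta.treatment == "kd1"), ("drug_48h_profile", (meta.treatment == "drug") & (meta.timepoint == "48h"))]:
        references[key] = gsea.signal_to_noise(gene_expr, list(meta.index[sel]), ctrl)
    conn = signatures.score_signatures(
        [query],
        references,
        k=config.signature_k,
        n_random=config.n_random_signatures,
        seed=sig_seed,
        score_threshold=config.score_threshold,
        fdr_threshold=config.signature_fdr,
    )
    conn.to_csv(out / "connectivity.tsv", sep="\t", index=False)
    prov["stages"]["signatures"] = {"n_pairs": len(conn), "n_significant": int(conn.significant.sum())}

    # --- evaluation vs. planted truth --------------------------------------
    if truth is not None:
        prov["evaluation"] = simulate.evaluate_calls(gene_calls, truth)

    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, default=str)
    return prov
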