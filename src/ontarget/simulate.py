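"""Synthetic CAGE-like experiments with planted ground truth.

The generator emulates a drug-vs-target-knockdown promoter profiling
design: one control group, two independent siRNA knockdowns of the drug's
primary target, and drug treatment at two timepoints (6 h / 48 h), with
negative-binomial tag counts per promoter.  Planted effects:

* *on-target* genes shift with the same sign in both knockdown groups and
  both drug timepoints (the transcriptional footprint of target inhibition);
* *off-target (drug-only)* genes shift in the drug groups only;
* *off-target (reversed)* genes shift oppositely in drug vs. knockdown;
* a subset of motifs is *active*: their per-sample activity adds
  site_count x activity to the log2 mean expression of promoters carrying
  sites, mirroring the linear motif-activity model used downstream;
* gene sets are built so at least one pathway is enriched for each planted
  class, one pathway collects targets of the first active motif (the
  planted motif-pathway association), and the remainder are random.

Counts are NB(mean = baseline_p * size_factor_s * 2^(sum of planted
effects), dispersion phi) with var = mu + phi*mu^2; promoter baselines are
log-normal.  All randomness flows from ``SimConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gsea import GeneSetCollection
from .ingest import CountMatrix, PromoterGeneMap

GROUPS = ("control", "kd1", "kd2", "drug_6h", "drug_48h")
DEFAULT_DESIGN = (("control", 6), ("kd1", 3), ("kd2", 3), ("drug_6h", 3), ("drug_48h", 3))

GENE_CLASSES = ("on_up", "on_down", "off_only_up", "off_only_down", "off_reversed", "null")


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment (one cell line)."""

    n_promoters: int = 5000
    n_genes: int = 2000
    design: tuple = DEFAULT_DESIGN
    n_on_target: int = 50
    n_off_only: int = 50
    n_off_reversed: int = 30
    lfc_magnitude: float = 2.0
    dispersion: float = 0.05
    lib_size_range: tuple = (800_000, 1_200_000)
    n_motifs: int = 20
    n_active_motifs: int = 3
    motif_activity_scale: float = 0.3
    n_pathways: int = 20
    pathway_size_range: tuple = (10, 60)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_promoters <= 0 or self.n_genes <= 0:
            raise ValueError("n_promoters and n_genes must be positive")
        if self.n_promoters < self.n_genes:
            raise ValueError("need at least one promoter per gene")
        planted = self.n_on_target + self.n_off_only + self.n_off_reversed
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        for name in ("n_on_target", "n_off_only", "n_off_reversed", "n_motifs", "n_active_motifs", "n_pathways"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_active_motifs > self.n_motifs:
            raise ValueError("n_active_motifs exceeds n_motifs")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ValueError("lib_size_range must be positive and ordered")
        names = [g for g, _ in self.design]
        if sorted(names) != sorted(GROUPS):
            raise ValueError(f"design must cover the groups {GROUPS}")
        if any(r <= 0 for _, r in self.design):
            raise ValueError("replicate counts must be positive")


#: planted gene class -> the on/off label the step-wise filter should assign
EXPECTED_LABEL = {
    "on_up": "on_up",
    "on_down": "on_down",
    "off_only_up": "off_up",
    "off_only_down": "off_down",
    "off_reversed": "off_up",  # planted with drug sign +1, knockdown sign -1
}


@dataclass
class GroundTruth:
    """Planted truth: per-gene class, per-motif activity profile, per-pathway direction."""

    gene_class: pd.Series                 # gene -> class (disjoint)
    expected_mean: pd.DataFrame           # promoter x sample NB mean mu_ps
    motif_activity: pd.DataFrame          # motif x group planted activity (log2 units)
    pathway_class: pd.Series              # pathway -> planted class ("null" if random)
    promoter_gene: pd.Series              # promoter -> gene

    def planted_genes(self, *classes: str) -> set[str]:
        return set(self.gene_class[self.gene_class.isin(classes)].index)


def evaluate_calls(calls: pd.DataFrame, truth: GroundTruth) -> dict:
    """Sensitivity and label accuracy of gene-level target calls vs. truth.

    ``sensitivity``: fraction of planted on-target genes called ``on_*``
    with the planted direction.  ``label_accuracy``: among planted
    (non-null) genes recovered as differentially expressed (any non-null,
    non-excluded call), the fraction whose label matches the planted class.
    """
    by_gene = calls.set_index("entity_id")["label"]
    planted = truth.gene_class[truth.gene_class != "null"]
    on_genes = planted[planted.isin(["on_up", "on_down"])]
    n_on_hit = sum(1 for g, c in on_genes.items() if by_gene.get(g) == EXPECTED_LABEL[c])
    recovered = {
        g: c
        for g, c in planted.items()
        if by_gene.get(g) not in (None, "null", "excluded_kd_conflict", "excluded_time_conflict")
        and not (isinstance(by_gene.get(g), float) and pd.isna(by_gene.get(g)))
    }
    n_correct = sum(1 for g, c in recovered.items() if by_gene.get(g) == EXPECTED_LABEL[c])
    return {
        "sensitivity": n_on_hit / max(len(on_genes), 1),
        "label_accuracy": n_correct / max(len(recovered), 1),
        "n_on_target_planted": len(on_genes),
        "n_planted_recovered": len(recovered),
    }


def _group_effect(gene_class: str, group: str, lfc: float, sign: int) -> float:
    s = sign * lfc
    if gene_class.startswith("on_"):
        return s if group != "control" else 0.0
    if gene_class.startswith("off_only"):
        return s if group in ("drug_6h", "drug_48h") else 0.0
    if gene_class == "off_reversed":
        if group in ("drug_6h", "drug_48h"):
            return s
        if group in ("kd1", "kd2"):
            return -s
        return 0.0
    return 0.0


def simulate_experiment(config: SimConfig):
    """Generate one synthetic experiment.

    Returns ``(counts, site_matrix, gene_sets, gene_map, truth)``:
    a :class:`~ontarget.ingest.CountMatrix`, a promoter x motif site-count
    DataFrame, a :class:`~ontarget.gsea.GeneSetCollection`, a
    :class:`~ontarget.ingest.PromoterGeneMap` and a :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    promoters = [f"chr1:{1000 + 500 * i}..{1000 + 500 * i + 20},+" for i in range(config.n_promoters)]
    # every gene gets one promoter; the surplus promoters are spread randomly
    gene_of_promoter = np.empty(config.n_promoters, dtype=object)
    gene_of_promoter[: config.n_genes] = genes
    if config.n_promoters > config.n_genes:
        gene_of_promoter[config.n_genes:] = rng.choice(genes, size=config.n_promoters - config.n_genes)
    promoter_gene = pd.Series(gene_of_promoter, index=promoters)

    # disjoint planted gene classes
    order = rng.permutation(config.n_genes)
    cls = pd.Series("null", index=genes)
    cursor = 0

    def take(n):
        nonlocal cursor
        picked = [genes[i] for i in order[cursor : cursor + n]]
        cursor += n
        return picked

    n_on_up = config.n_on_target // 2 + config.n_on_target % 2
    n_on_down = config.n_on_target // 2
    n_off_up = config.n_off_only // 2 + config.n_off_only % 2
    n_off_down = config.n_off_only // 2
    cls[take(n_on_up)] = "on_up"
    cls[take(n_on_down)] = "on_down"
    cls[take(n_off_up)] = "off_only_up"
    cls[take(n_off_down)] = "off_only_down"
    cls[take(config.n_off_reversed)] = "off_reversed"

    # samples and size factors
    sample_ids, groups, batches = [], [], []
    for gname, reps in config.design:
        for r in range(1, reps + 1):
            sample_ids.append(f"{gname}_rep{r}")
            groups.append(gname)
            batches.append(f"batch{(r - 1) % 2 + 1}")
    groups = np.array(groups)
    lo, hi = config.lib_size_range
    lib_target = rng.uniform(lo, hi, size=len(sample_ids))

    # promoter baselines: log-normal relative abundances, rescaled so the
    # expected library size of each sample matches its drawn depth
    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=config.n_promoters)
    baseline_rel = baseline / baseline.sum()

    # planted per-gene log2 shifts per group
    sign_of_class = {"on_up": 1, "on_down": -1, "off_only_up": 1, "off_only_down": -1, "off_reversed": 1}
    lfc_matrix = np.zeros((config.n_promoters, len(GROUPS)))
    group_index = {g: i for i, g in enumerate(GROUPS)}
    gene_cls_arr = cls[promoter_gene.to_numpy()].to_numpy()
    for gi, g in enumerate(GROUPS):
        for c, s in sign_of_class.items():
            mask = gene_cls_arr == c
            if mask.any():
                lfc_matrix[mask, gi] += _group_effect(c, g, config.lfc_magnitude, s)

    # motif site counts (sparse Poisson) and planted activities per group
    motifs = [f"MOTIF{j:03d}" for j in range(config.n_motifs)]
    present = rng.random((config.n_promoters, config.n_motifs)) < 0.05
    site = np.where(present, rng.poisson(1.0, size=present.shape) + 1, 0).astype(float)
    site_matrix = pd.DataFrame(site, index=promoters, columns=motifs)
    activity = np.zeros((config.n_motifs, len(GROUPS)))
    for j in range(config.n_active_motifs):
        # zero in control, condition-specific elsewhere; drug groups share a
        # direction so downstream contrasts see a coherent activity change
        direction = 1 if j % 2 == 0 else -1
        activity[j, group_index["drug_6h"]] = direction * config.motif_activity_scale
        activity[j, group_index["drug_48h"]] = direction * config.motif_activity_scale
        activity[j, group_index["kd1"]] = direction * config.motif_activity_scale * 0.5
        activity[j, group_index["kd2"]] = direction * config.motif_activity_scale * 0.5
    motif_activity = pd.DataFrame(activity, index=motifs, columns=list(GROUPS))
    lfc_matrix = lfc_matrix + site @ activity

    # NB counts
    gi = np.array([group_index[g] for g in groups])
    mu = baseline_rel[:, None] * lib_target[None, :] * 2.0 ** lfc_matrix[:, gi]
    phi = config.dispersion
    if phi > 0:
        shape = 1.0 / phi
        counts = rng.negative_binomial(shape, shape / (shape + mu))
    else:
        counts = rng.poisson(mu)
    metadata = pd.DataFrame(
        {
            "cell_line": "SIMCELL",
            "treatment": ["drug" if g.startswith("drug") else g for g in groups],
            "timepoint": [g.split("_")[1] if g.startswith("drug") else "NA" for g in groups],
            "replicate": [s.rsplit("rep", 1)[1] for s in sample_ids],
            "batch": batches,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    count_matrix = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(promoters, name="promoter_id"), columns=sample_ids),
        metadata,
    )

    # pathways
    sets: dict[str, list[str]] = {}
    pw_class: dict[str, str] = {}
    lo_pw, hi_pw = config.pathway_size_range
    null_genes = list(cls[cls == "null"].index)

    def planted_pathway(name, members, klass):
        size = int(min(max(len(members), lo_pw), hi_pw))
        chosen = list(members[:size])
        if len(chosen) < lo_pw:
            pad = rng.choice(null_genes, size=lo_pw - len(chosen), replace=False)
            chosen += list(pad)
        sets[name] = chosen
        pw_class[name] = klass

    if config.n_pathways > 0 and config.n_on_target > 0:
        planted_pathway("PW_ON_UP", list(cls[cls == "on_up"].index), "on_up")
        if n_on_down > 0:
            planted_pathway("PW_ON_DOWN", list(cls[cls == "on_down"].index), "on_down")
    if config.n_pathways > 0 and config.n_off_only > 0:
        planted_pathway("PW_OFF_UP", list(cls[cls == "off_only_up"].index), "off_only_up")
        if n_off_down > 0:
            planted_pathway("PW_OFF_DOWN", list(cls[cls == "off_only_down"].index), "off_only_down")
    if config.n_pathways > 0 and config.n_off_reversed > 0:
        planted_pathway("PW_OFF_REVERSED", list(cls[cls == "off_reversed"].index), "off_reversed")
    if config.n_pathways > 0 and config.n_active_motifs > 0:
        # pathway drawn from the targets of the first active motif: the
        # planted motif-pathway association
        tg_genes = sorted(set(promoter_gene[site_matrix[motifs[0]] > 0]))
        pick = rng.permutation(len(tg_genes))[: min(hi_pw, len(tg_genes))]
        sets["PW_MOTIF0_TARGETS"] = [tg_genes[i] for i in pick]
        pw_class["PW_MOTIF0_TARGETS"] = "motif0_targets"
    while len(sets) < config.n_pathways:
        name = f"PW_RANDOM{len(sets):03d}"
        size = int(rng.integers(lo_pw, hi_pw + 1))
        sets[name] = list(rng.choice(genes, size=size, replace=False))
        pw_class[name] = "null"

    gene_sets = GeneSetCollection(sets, {n: pw_class[n] for n in sets})
    truth = GroundTruth(
        gene_class=cls,
        expected_mean=pd.DataFrame(mu, index=promoters, columns=sample_ids),
        motif_activity=motif_activity,
        pathway_class=pd.Series(pw_class),
        promoter_gene=promoter_gene,
    )
    return count_matrix, site_matrix, gene_sets, PromoterGeneMap(promoter_gene), truth


def write_fixture_set(outputs, directory) -> dict:
    """Write a simulated experiment to plain-text files; returns the manifest.

    ``outputs`` is the 5-tuple from :func:`simulate_experiment` (optionally
    with the :class:`SimConfig` appended for provenance).  Emits counts.tsv,
    metadata.tsv, motif_sites.tsv, gene_sets.gmt, promoter_gene_map.tsv,
    truth_genes.tsv, truth_motifs.tsv, truth_pathways.tsv and manifest.json.
    """
    counts, site_matrix, gene_sets, gene_map, truth = outputs[:5]
    config = outputs[5] if len(outputs) > 5 else None
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}

    def emit(name, writer):
        path = directory / name
        writer(path)
        files[name] = path.name

    emit("counts.tsv", lambda p: counts.counts.to_csv(p, sep="\t"))
    emit("metadata.tsv", lambda p: counts.metadata.to_csv(p, sep="\t"))
    emit("motif_sites.tsv", lambda p: site_matrix.to_csv(p, sep="\t"))
    emit("gene_sets.gmt", gene_sets.to_gmt)
    emit("promoter_gene_map.tsv", gene_map.to_tsv)
    emit("truth_genes.tsv", lambda p: truth.gene_class.rename("class").to_frame().to_csv(p, sep="\t", index_label="gene"))
    emit("truth_motifs.tsv", lambda p: truth.motif_activity.to_csv(p, sep="\t", index_label="motif"))
    emit("truth_pathways.tsv", lambda p: truth.pathway_class.rename("class").to_frame().to_csv(p, sep="\t", index_label="pathway"))
    manifest = {"files": files, "seed": config.seed if config else None}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_fixture_set(directory):
    """Re-read a fixture directory written by :func:`write_fixture_set`."""
    from .ingest import read_counts

    directory = Path(directory)
    counts = read_counts(directory / "counts.tsv", directory / "metadata.tsv")
    site_matrix = pd.read_csv(directory / "motif_sites.tsv", sep="\t", index_col=0)
    gene_sets = GeneSetCollection.read_gmt(directory / "gene_sets.gmt")
    gene_map = PromoterGeneMap.read_tsv(directory / "promoter_gene_map.tsv")
    return counts, site_matrix, gene_sets, gene_map


def contrast_map(prefix: str = "") -> dict[str, str]:
    """The four canonical contrast names of a simulated experiment."""
    return {"kd1": "kd1_vs_ctrl", "kd2": "kd2_vs_ctrl", "6h": "drug_6h_vs_ctrl", "48h": "drug_48h_vs_ctrl"}


def standard_contrasts(metadata: pd.DataFrame):
    """Build the four treated-vs-control contrasts from simulator metadata."""
    from .diffexpr import Contrast

    def members(treatment, timepoint=None):
        sel = metadata["treatment"] == treatment
        if timepoint is not None:
            sel &= metadata["timepoint"] == timepoint
        return tuple(metadata.index[sel])

    ctrl = members("control")
    return [
        Contrast("kd1_vs_ctrl", members("kd1"), ctrl),
        Contrast("kd2_vs_ctrl", members("kd2"), ctrl),
        Contrast("drug_6h_vs_ctrl", members("drug", "6h"), ctrl),
        Contrast("drug_48h_vs_ctrl", members("drug", "48h"), ctrl),
    ]
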