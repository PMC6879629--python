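"""Connectivity-map style signature matching with a random-signature null.

A query signature is the top-k up- and top-k down-regulated genes of a
condition, ordered by differential-expression significance.  Against a
reference ranked profile the connectivity score is

    score = 100 * (ES(up) - ES(down)) / 2

using the unweighted (p = 0) KS enrichment score, so a query whose up genes
sit at the top and down genes at the bottom of the reference scores +100
and its flip scores -100 exactly.  Significance is calibrated with random
k+k signatures drawn from the reference universe and a one-sample t-test of
the null scores against the observed score; the reporting rule is
|score| >= 80 with FDR <= 5%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import rank_by_significance
from .gsea import enrichment_score

logger = logging.getLogger(__name__)


@dataclass
class Signature:
    name: str
    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError(f"signature {self.name}: up and down lists overlap")

    def flipped(self) -> "Signature":
        return Signature(self.name + "_flipped", list(self.down_genes), list(self.up_genes))


def make_signature(de_table: pd.DataFrame, name: str = "query", k: int = 50) -> Signature:
    """Top-k up and top-k down genes by significance from a DE table."""
    up = rank_by_significance(de_table, "up")
    down = rank_by_significance(de_table, "down")
    if up.empty and down.empty:
        raise ValueError("DE table contains no signed genes")
    if len(up) < k or len(down) < k:
        warnings.warn(
            f"signature {name}: only {len(up)} up / {len(down)} down genes available for k={k}"
        )
    return Signature(name, list(up.index[:k]), list(down.index[:k]))


def connectivity_score(query: Signature, reference_ranked: pd.Series) -> float:
    """Score in [-100, 100]; positive = mimicking, negative = reversing."""
    universe = set(reference_ranked.index)
    up = [g for g in query.up_genes if g in universe]
    down = [g for g in query.down_genes if g in universe]
    n_drop = (len(query.up_genes) - len(up)) + (len(query.down_genes) - len(down))
    if n_drop:
        logger.info("connectivity_score(%s): %d query genes absent from reference", query.name, n_drop)
    es_up = enrichment_score(reference_ranked, up, weight_p=0.0)[0] if up else None
    es_down = enrichment_score(reference_ranked, down, weight_p=0.0)[0] if down else None
    if es_up is None and es_down is None:
        raise ValueError("no query gene overlaps the reference universe")
    es_up = 0.0 if es_up is None else es_up
    es_down = 0.0 if es_down is None else es_down
    return 100.0 * (es_up - es_down) / 2.0


def null_calibration(
    reference_ranked: pd.Series,
    k: int,
    n_random: int = 100,
    seed: int | None = None,
) -> np.ndarray:
    """Connectivity scores of ``n_random`` random k-up/k-down signatures."""
    if n_random < 2:
        raise ValueError("need n_random >= 2")
    genes = list(reference_ranked.index)
    if len(genes) < 2 * k:
        raise ValueError(f"universe of {len(genes)} genes cannot host a {k}+{k} signature")
    rng = np.random.default_rng(seed)
    out = np.empty(n_random)
    for i in range(n_random):
        pick = rng.choice(len(genes), size=2 * k, replace=False)
        sig = Signature(f"random_{i}", [genes[j] for j in pick[:k]], [genes[j] for j in pick[k:]])
        out[i] = connectivity_score(sig, reference_ranked)
    return out


def score_significance(observed: float, null_scores: np.ndarray, mode: str = "ttest") -> float:
    """p-value of an observed score against the random-signature null.

    ``"ttest"`` performs the one-sample t-test of the null scores with the
    observed score as the hypothesized mean; ``"empirical"`` returns the
    two-sided empirical tail fraction with a +1 pseudocount.
    """
    null_scores = np.asarray(null_scores, dtype=float)
    if mode == "ttest":
        return float(stats.ttest_1samp(null_scores, popmean=observed).pvalue)
    if mode == "empirical":
        n = null_scores.size
        tail = int((np.abs(null_scores - null_scores.mean()) >= abs(observed - null_scores.mean())).sum())
        return (1 + tail) / (1 + n)
    raise ValueError(f"mode must be 'ttest' or 'empirical', got {mode!r}")


def score_signatures(
    queries: list[Signature],
    references: dict[str, pd.Series],
    k: int = 50,
    n_random: int = 100,
    seed: int | None = None,
    score_threshold: float = 80.0,
    fdr_threshold: float = 0.05,
    p_mode: str = "ttest",
) -> pd.DataFrame:
    """Score every query against every reference with null calibration.

    Returns a table (query, reference, score, null_mean, null_sd, p, q,
    significant); a pair is significant when |score| >= threshold (inclusive)
    and q <= fdr_threshold (inclusive).
    """
    from .diffexpr import bh_adjust

    rows = []
    for ref_name, ranked in references.items():
        null = null_calibration(ranked, k=k, n_random=n_random, seed=seed)
        for query in queries:
            sc = connectivity_score(query, ranked)
            p = score_significance(sc, null, mode=p_mode)
            rows.append((query.name, ref_name, sc, null.mean(), null.std(ddof=1), p))
    out = pd.DataFrame(rows, columns=["query", "reference", "score", "null_mean", "null_sd", "p"])
    if out.empty:
        out["q"] = out["significant"] = []
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["score"].abs() >= score_threshold) & (out["q"] <= fdr_threshold)
    return out


def read_reference_library(path) -> dict[str, pd.Series]:
    """Read a reference library TSV (reference_name, gene, rank_metric)."""
    df = pd.read_csv(path, sep="\t")
    refs = {}
    for name, sub in df.groupby(df.columns[0]):
        s = pd.Series(sub.iloc[:, 2].to_numpy(dtype=float), index=sub.iloc[:, 1].astype(str))
        order = np.lexsort((s.index.astype(str), -s.to_numpy()))
        refs[str(name)] = s.iloc[order]
    return refs
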