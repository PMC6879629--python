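"""In-house gene-set enrichment analysis (weighted-KS, gene-set permutation).

Genes are ranked by a signal-to-noise metric between two sample groups.  A
gene set's enrichment score (ES) is the signed maximal deviation of a
weighted Kolmogorov-Smirnov running sum over the ranked list: at each member
("hit") the sum rises by |metric|^p normalized over hits, at each non-member
it falls by 1/(N - N_hits).  The null distribution per set comes from random
gene sets of the same size drawn from the ranked universe; the normalized
ES (NES) divides the ES by the mean |null ES| of the same sign, and the FDR
is the standard ratio of null to observed tail areas on the NES scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class GeneSetCollection:
    """Named gene sets with GMT (name, description, members...) round-trip."""

    def __init__(self, sets: dict[str, list[str]], descriptions: dict[str, str] | None = None):
        self.sets = {name: list(dict.fromkeys(members)) for name, members in sets.items()}
        self.descriptions = descriptions or {name: "" for name in sets}

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restrict_size(self, min_size: int, max_size: int, universe=None) -> "GeneSetCollection":
        """Keep sets whose size (within ``universe`` if given) is in [min, max]."""
        out, desc = {}, {}
        for name, members in self.sets.items():
            eff = [g for g in members if g in universe] if universe is not None else members
            if min_size <= len(eff) <= max_size:
                out[name] = members
                desc[name] = self.descriptions.get(name, "")
        dropped = len(self.sets) - len(out)
        if dropped:
            logger.info("size filter [%d,%d]: dropped %d of %d sets", min_size, max_size, dropped, len(self.sets))
        return GeneSetCollection(out, desc)

    @classmethod
    def read_gmt(cls, path) -> "GeneSetCollection":
        sets, desc = {}, {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
                sets[parts[0]] = parts[2:]
                desc[parts[0]] = parts[1]
        return cls(sets, desc)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, self.descriptions.get(name, "")] + list(members)) + "\n")


@dataclass
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    nominal_p: float
    fdr: float
    leading_edge: list[str] = field(default_factory=list)


def signal_to_noise(expr: pd.DataFrame, group_a: list[str], group_b: list[str]) -> pd.Series:
    """Signal-to-noise ranking metric (mu_a - mu_b) / (sd_a + sd_b).

    Each group's sd is floored at max(0.2 * |group mean|, 0.2), the
    convention of the canonical GSEA implementation.  Returns a Series
    sorted descending, ties broken by gene ID, indexed by gene.
    """
    for g, name in ((group_a, "a"), (group_b, "b")):
        if len(g) < 2:
            raise ValueError(f"group {name} needs >=2 samples, got {len(g)}")
    a = expr[list(group_a)].to_numpy(dtype=float)
    b = expr[list(group_b)].to_numpy(dtype=float)
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum(a.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mu_a), 0.2))
    sd_b = np.maximum(b.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mu_b), 0.2))
    metric = (mu_a - mu_b) / (sd_a + sd_b)
    s = pd.Series(metric, index=expr.index)
    order = np.lexsort((s.index.astype(str), -s.to_numpy()))
    return s.iloc[order]


def enrichment_score(ranked: pd.Series, gene_set, weight_p: float = 1.0):
    """Weighted-KS enrichment score and the full running-sum profile.

    ``ranked`` is a metric Series sorted descending.  Returns ``(es,
    running)`` where ``running`` has one value per list position.  Ties in
    |running sum| resolve to the positive extremum.
    """
    genes = ranked.index
    hit = genes.isin(set(gene_set)).astype(bool)
    n = len(genes)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has empty intersection with the ranked list")
    if n_hit == n:
        warnings.warn("gene set covers the whole ranked list; ES degenerates to 1")
        return 1.0, np.ones(n)
    w = np.abs(ranked.to_numpy()) ** weight_p
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all-zero metrics at hits: fall back to unweighted
        w_hit = hit.astype(float)
        total = w_hit.sum()
    inc = np.where(hit, w_hit / total, -1.0 / (n - n_hit))
    running = np.cumsum(inc)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    return float(es), running


def leading_edge(ranked: pd.Series, gene_set, weight_p: float = 1.0) -> list[str]:
    """Members at or before the running-sum extremum (after it for ES<0)."""
    es, running = enrichment_score(ranked, gene_set, weight_p)
    hit = ranked.index.isin(set(gene_set))
    if es >= 0:
        peak = int(np.argmax(running))
        return [g for g, h in zip(ranked.index[: peak + 1], hit[: peak + 1]) if h]
    trough = int(np.argmin(running))
    return [g for g, h in zip(ranked.index[trough:], hit[trough:]) if h]


def _null_es(w: np.ndarray, k: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized ES of ``n_perm`` random size-k sets over a ranked list.

    ``w`` holds |metric|^p per position.  The running sum between hits only
    decreases, so the positive extremum is attained immediately after a hit
    and the negative extremum immediately before one; both are evaluated in
    closed form from the sorted hit positions.
    """
    n = w.size
    pos = np.empty((n_perm, k), dtype=np.int64)
    for r in range(n_perm):
        pos[r] = rng.choice(n, size=k, replace=False)
    pos.sort(axis=1)
    wh = w[pos]
    tot = wh.sum(axis=1, keepdims=True)
    zero = tot[:, 0] == 0
    if zero.any():  # degenerate all-zero weights: unweighted steps
        wh[zero] = 1.0
        tot[zero] = k
    cum = np.cumsum(wh, axis=1) / tot
    j = np.arange(1, k + 1)
    miss = 1.0 / (n - k)
    after = cum - (pos + 1 - j) * miss
    before = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - (pos - (j - 1)) * miss
    hi = np.maximum(after.max(axis=1), 0.0)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def gsea_run(
    ranked: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    weight_p: float = 1.0,
    seed: int | None = None,
    nes_mode: str = "mean",
) -> pd.DataFrame:
    """Run enrichment for every retained set against one ranked list.

    Null ES per set from ``n_perm`` random same-size gene sets drawn from
    the ranked universe (gene-set permutation).  Nominal p is the one-sided
    tail fraction among the same-signed null ES, with a +1 pseudocount.  ``nes_mode="mean"`` normalizes the
    ES by the mean |null ES| of the same sign (the standard definition);
    ``"max"`` divides by the maximum |ES| across sets instead.  FDR is the
    ratio of null to observed NES tail areas, capped at 1.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducible permutation")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution will be poor")
    rng = np.random.default_rng(seed)
    universe = set(ranked.index)
    retained = sets.restrict_size(min_size, max_size, universe=universe)
    if len(retained) == 0:
        raise ValueError("no gene set left after size restriction")

    w = np.abs(ranked.to_numpy()) ** weight_p
    rows = []
    all_null_nes: list[np.ndarray] = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in retained:
        eff = [g for g in members if g in universe]
        es, _ = enrichment_score(ranked, eff, weight_p)
        k = len(eff)
        if k not in null_cache:
            null_cache[k] = _null_es(w, k, n_perm, rng)
        null = null_cache[k]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        # one-sided tail among the same-signed null ES, +1 pseudocount
        nominal_p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size)
        denom = np.abs(same).mean() if same.size else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        null_nes = np.where(
            null >= 0,
            null / (np.abs(null[null >= 0]).mean() if (null >= 0).any() else 1.0),
            null / (np.abs(null[null < 0]).mean() if (null < 0).any() else 1.0),
        )
        all_null_nes.append(null_nes)
        rows.append((name, k, es, nes, nominal_p, leading_edge(ranked, eff, weight_p)))

    res = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p", "leading_edge"])
    if nes_mode == "max":
        m = res["es"].abs().max()
        res["nes"] = res["es"] / m if m > 0 else 0.0
    elif nes_mode != "mean":
        raise ValueError(f"nes_mode must be 'mean' or 'max', got {nes_mode!r}")

    pooled = np.concatenate(all_null_nes)
    obs = res["nes"].to_numpy()
    fdr = np.empty(len(res))
    for i, nes in enumerate(obs):
        if nes >= 0:
            null_tail = (pooled >= nes).mean()
            obs_tail = (obs >= nes).mean()
        else:
            null_tail = (pooled <= nes).mean()
            obs_tail = (obs <= nes).mean()
        fdr[i] = min(null_tail / obs_tail, 1.0) if obs_tail > 0 else 1.0
    res["fdr"] = fdr
    return res


def significant(res: pd.DataFrame, p_threshold: float = 0.05, fdr_threshold: float = 0.20) -> pd.Series:
    """Significance rule: nominal p <= 0.05 or FDR <= 20% (both inclusive)."""
    return (res["p"] <= p_threshold) | (res["fdr"] <= fdr_threshold)


def classify_pathways(
    results: dict[str, pd.DataFrame],
    drug: str = "drug",
    cell_line: str = "cell",
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.20,
    kd_both: bool = False,
) -> pd.DataFrame:
    """On-/off-target calls at pathway level from per-contrast GSEA results.

    ``results`` maps the four contrast keys ``kd1``, ``kd2``, ``6h``,
    ``48h`` to :func:`gsea_run` outputs.  Each pathway's ternary sign per
    contrast is sgn(NES) gated by the significance rule; the gene-level
    step-wise filter then applies unchanged.
    """
    from .targetclass import SignVector, classify

    for key in ("kd1", "kd2", "6h", "48h"):
        if key not in results:
            raise ValueError(f"missing GSEA results for contrast {key!r}")
    signs = {}
    for key, res in results.items():
        sig = significant(res, p_threshold, fdr_threshold)
        signs[key] = pd.Series(
            np.where(sig, np.sign(res["nes"]).astype(int), 0), index=res["set"]
        )
    pathways = signs["kd1"].index
    rows = []
    for pw in pathways:
        sv = SignVector(
            int(signs["kd1"].get(pw, 0)),
            int(signs["kd2"].get(pw, 0)),
            int(signs["6h"].get(pw, 0)),
            int(signs["48h"].get(pw, 0)),
        )
        label, k, d = classify(sv, kd_both=kd_both)
        rows.append((pw, drug, cell_line, label, k, d))
    return pd.DataFrame(
        rows, columns=["entity_id", "drug", "cell_line", "label", "kd_consensus", "drug_sign"]
    )
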