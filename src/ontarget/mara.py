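"""Motif Activity Response Analysis: ridge regression of expression on
transcription-factor binding-site counts.

The model explains the (double-centered) promoter expression matrix E as
E_ps = c_p + c_s + sum_m N_pm * A_ms + noise, where N_pm is the predicted
number of binding sites of motif m in the proximal window of promoter p
(typically -300..+100 bp around the peak) and A_ms is the activity of motif
m in sample s.  Column-centering N absorbs the promoter intercepts; the
per-sample activity vector is the ridge solution
(N'N + lambda I)^-1 N' e_s, with lambda chosen by generalized
cross-validation unless fixed.  Standard errors come from the ridge
sandwich, the per-motif z-score is the root-mean-square of activity over
standard error across samples, and differential activity between two sample
groups is tested on the activities with inverse-variance weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class MotifActivityTable:
    """Motif x sample activities with standard errors and per-motif z."""

    activities: pd.DataFrame  # motifs x samples, centered per motif
    stderr: pd.DataFrame      # same shape, > 0
    z: pd.Series              # per motif
    ridge_lambda: float

    def __post_init__(self):
        if (self.stderr.to_numpy() <= 0).any():
            raise ValueError("activity standard errors must be positive")


def filter_motifs(site_matrix: pd.DataFrame, min_sites: int = 150) -> pd.DataFrame:
    """Drop motifs with predicted sites on fewer than ``min_sites`` promoters."""
    n_target = (site_matrix > 0).sum(axis=0)
    keep = n_target >= min_sites
    if not keep.any():
        raise ValueError(
            f"all motifs have < {min_sites} target promoters; lower min_sites"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_motifs: dropped %d motifs below %d target promoters", dropped, min_sites)
    return site_matrix.loc[:, keep]


def _double_center(E: np.ndarray) -> np.ndarray:
    return E - E.mean(axis=1, keepdims=True) - E.mean(axis=0, keepdims=True) + E.mean()


def fit_activities(
    expr_values: pd.DataFrame,
    site_matrix: pd.DataFrame,
    ridge_lambda: float | str = "auto",
    n_lambda: int = 25,
) -> MotifActivityTable:
    """Estimate per-sample motif activities by ridge regression.

    ``expr_values`` is promoters x samples (log scale), ``site_matrix``
    promoters x motifs on the same promoter index.  ``ridge_lambda`` is a
    positive float, ``"auto"`` (GCV over a log-spaced grid), or 0 for
    ordinary least squares.  Activities are centered across samples per
    motif.
    """
    if not expr_values.index.equals(site_matrix.index):
        common = expr_values.index.intersection(site_matrix.index)
        if len(common) == 0:
            raise ValueError("expression and site matrices share no promoters")
        expr_values = expr_values.loc[common]
        site_matrix = site_matrix.loc[common]
    if expr_values.shape[0] == 0:
        raise ValueError("expression and site matrices share no promoters")
    if expr_values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if isinstance(ridge_lambda, (int, float)) and ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")

    N = site_matrix.to_numpy(dtype=float)
    Nc = N - N.mean(axis=0, keepdims=True)
    E = _double_center(expr_values.to_numpy(dtype=float))
    P, M = Nc.shape
    S = E.shape[1]

    U, d, Vt = np.linalg.svd(Nc, full_matrices=False)
    UtE = U.T @ E  # (r, S)
    ok = d > 1e-12 * max(d.max(), 1.0)

    def shrink_of(lam: float) -> np.ndarray:
        # d/(d^2+lam); at lam=0 this is the pseudo-inverse 1/d on nonzero d
        return np.where(ok, d / (d**2 + lam), 0.0)

    def solve(lam: float):
        shrink = shrink_of(lam)
        A = Vt.T @ (shrink[:, None] * UtE)  # (M, S)
        fitted = U @ ((d * shrink)[:, None] * UtE)
        return A, fitted, shrink

    if ridge_lambda == "auto":
        d2 = d[ok] ** 2
        grid = np.geomspace(d2.mean() * 1e-4, d2.mean() * 1e4, n_lambda)
        best, best_gcv = grid[0], np.inf
        for lam in grid:
            _, fitted, _ = solve(lam)
            rss = ((E - fitted) ** 2).sum()
            tr_h = np.where(ok, d**2 / (d**2 + lam), 0.0).sum()
            gcv = (rss / (P * S)) / (1.0 - tr_h / P) ** 2
            if gcv < best_gcv:
                best, best_gcv = lam, gcv
        lam = float(best)
    else:
        lam = float(ridge_lambda)

    A, fitted, shrink = solve(lam)
    resid = E - fitted
    eff_df = np.where(ok, d**2 / (d**2 + lam), 0.0).sum() if lam > 0 else ok.sum()
    denom = max(P - eff_df, 1.0)
    sigma2 = (resid**2).sum(axis=0) / denom  # per sample
    # Var(A_ms) = sigma2_s * sum_i V_mi^2 * (d_i/(d_i^2+lam))^2
    sand = (Vt.T**2) @ shrink**2
    var = np.outer(sand, sigma2)
    stderr = np.sqrt(np.maximum(var, 1e-300))
    stderr = np.maximum(stderr, 1e-12)

    A = A - A.mean(axis=1, keepdims=True)  # exact per-motif centering
    acts = pd.DataFrame(A, index=site_matrix.columns, columns=expr_values.columns)
    errs = pd.DataFrame(stderr, index=site_matrix.columns, columns=expr_values.columns)
    z = pd.Series(np.sqrt(((A / stderr) ** 2).mean(axis=1)), index=site_matrix.columns)
    return MotifActivityTable(acts, errs, z, lam)


def differential_activity(
    table: MotifActivityTable,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group test on motif activities with inverse-variance weights.

    Returns per motif: ``delta`` (weighted mean a - b), ``p``, ``q`` (BH
    across motifs) and ``sign`` gated at q <= alpha.
    """
    from .diffexpr import bh_adjust

    for g, name in ((group_a, "a"), (group_b, "b")):
        if len(g) < 2:
            raise ValueError(f"group {name} needs >=2 samples")
    A = table.activities
    W = 1.0 / table.stderr**2
    rows = []
    for motif in A.index:
        a, wa = A.loc[motif, list(group_a)].to_numpy(), W.loc[motif, list(group_a)].to_numpy()
        b, wb = A.loc[motif, list(group_b)].to_numpy(), W.loc[motif, list(group_b)].to_numpy()
        ma, mb = np.average(a, weights=wa), np.average(b, weights=wb)
        va = np.average((a - ma) ** 2, weights=wa) * len(a) / (len(a) - 1)
        vb = np.average((b - mb) ** 2, weights=wb) * len(b) / (len(b) - 1)
        se = np.sqrt(va / len(a) + vb / len(b))
        delta = ma - mb
        if se == 0:
            p = 1.0 if delta == 0 else 0.0
            t = 0.0 if delta == 0 else np.inf * np.sign(delta)
        else:
            t = delta / se
            df = len(a) + len(b) - 2
            p = 2 * stats.t.sf(abs(t), df)
        rows.append((motif, delta, p))
    out = pd.DataFrame(rows, columns=["motif", "delta", "p"]).set_index("motif")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["sign"] = np.where(out["q"] <= alpha, np.sign(out["delta"]).astype(int), 0)
    return out


def motif_targets(site_matrix: pd.DataFrame, gene_map) -> dict[str, set[str]]:
    """Gene-level target sets: a gene is a target of a motif iff any of its
    promoters carries at least one predicted site."""
    targets: dict[str, set[str]] = {m: set() for m in site_matrix.columns}
    genes = np.array([gene_map.gene_of(p) for p in site_matrix.index], dtype=object)
    has = site_matrix.to_numpy() > 0
    for j, motif in enumerate(site_matrix.columns):
        gs = genes[has[:, j]]
        targets[motif] = {g for g in gs if g is not None}
    return targets


def count_sites_in_window(
    sites_bed: pd.DataFrame,
    promoter_peaks: pd.DataFrame,
    upstream: int = 300,
    downstream: int = 100,
) -> pd.DataFrame:
    """Count motif sites within [-upstream, +downstream) of promoter peaks.

    Helper for building a site matrix from a BED-like site table with
    columns (chrom, start, end, motif, score, strand) and a peak table with
    (chrom, peak, promoter_id, strand); the window is oriented by strand and
    half-open, as in the ingest module.
    """
    rows = {}
    for _, pk in promoter_peaks.iterrows():
        if pk.strand == "+":
            lo, hi = pk.peak - upstream, pk.peak + downstream
        else:
            lo, hi = pk.peak - downstream + 1, pk.peak + upstream + 1
        sel = sites_bed[(sites_bed.chrom == pk.chrom) & (sites_bed.start >= lo) & (sites_bed.start < hi)]
        rows[pk.promoter_id] = sel.groupby("motif").size()
    return pd.DataFrame(rows).T.fillna(0).astype(int)
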