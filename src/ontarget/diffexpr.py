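"""Per-promoter differential expression by weighted linear-model contrasts.

Each contrast (treated group vs. matched control) is tested with a
fixed-effects linear model per promoter: weighted least squares of the
log2-CPM value on a group indicator, optionally with batch indicator
covariates.  The group coefficient is the log2 fold change; its t statistic
gives the p-value, and Benjamini-Hochberg adjustment is applied across all
promoters within the contrast.  A ternary sign call (-1/0/+1) encodes
direction gated at the FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class Contrast:
    """A named treated-vs-control comparison within one cell line."""

    name: str
    treated: tuple[str, ...]
    control: tuple[str, ...]

    def __post_init__(self):
        if not self.treated or not self.control:
            raise ValueError(f"contrast {self.name}: both sides must be nonempty")
        if set(self.treated) & set(self.control):
            raise ValueError(f"contrast {self.name}: treated and control overlap")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if p.size == 0:
        return p.copy()
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def fit_de(
    expr,
    contrast: Contrast,
    batch_covariate: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Weighted least-squares ANOVA of one contrast, per promoter.

    Returns a DataFrame indexed by promoter with columns ``contrast``,
    ``lfc`` (group coefficient, log2 units), ``p``, ``q`` (BH within the
    contrast) and ``sign`` (sgn(lfc) if q <= alpha else 0).

    Raises if the batch factor is confounded with the group indicator
    (singular design).
    """
    samples = list(contrast.control) + list(contrast.treated)
    missing = [s for s in samples if s not in expr.values.columns]
    if missing:
        raise ValueError(f"contrast {contrast.name}: samples not in matrix: {missing}")
    import warnings

    if len(contrast.treated) < 2 or len(contrast.control) < 2:
        warnings.warn(f"contrast {contrast.name}: fewer than 2 samples on one side")

    Y = expr.values[samples].to_numpy(dtype=float)
    W = expr.weights[samples].to_numpy(dtype=float)
    n = len(samples)
    group = np.array([0.0] * len(contrast.control) + [1.0] * len(contrast.treated))
    X_cols = [np.ones(n), group]
    if batch_covariate:
        batches = expr.metadata.loc[samples, "batch"].astype(str).to_numpy()
        levels = sorted(set(batches))
        for lev in levels[1:]:  # first level absorbed by the intercept
            X_cols.append((batches == lev).astype(float))
    X = np.column_stack(X_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"contrast {contrast.name}: singular design (batch confounded with group)"
        )

    # batched WLS: beta_p = (X' W_p X)^-1 X' W_p y_p
    XtWX = np.einsum("ni,pn,nj->pij", X, W, X)
    XtWy = np.einsum("ni,pn,pn->pi", X, W, Y)
    beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    fittedv = beta @ X.T
    resid = Y - fittedv
    df = n - X.shape[1]
    if df <= 0:
        raise ValueError(f"contrast {contrast.name}: no residual degrees of freedom")
    s2 = np.einsum("pn,pn->p", W, resid**2) / df
    inv = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(s2 * inv[:, 1, 1], 0.0))
    lfc = beta[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    q = bh_adjust(p)
    sign = np.where(q <= alpha, np.sign(lfc).astype(int), 0)
    return pd.DataFrame(
        {"contrast": contrast.name, "lfc": lfc, "p": p, "q": q, "sign": sign},
        index=expr.values.index,
    )


def fit_contrasts(expr, contrasts: list[Contrast], batch_covariate: bool = False, alpha: float = 0.05) -> pd.DataFrame:
    """Run :func:`fit_de` for several contrasts; concatenated long table."""
    tables = [fit_de(expr, c, batch_covariate=batch_covariate, alpha=alpha) for c in contrasts]
    out = pd.concat(tables)
    out.index.name = "promoter_id"
    return out


def rank_by_significance(de_table: pd.DataFrame, direction: str | None = None) -> pd.DataFrame:
    """Order rows by ascending p, ties broken by |lfc| descending then ID.

    ``direction`` restricts to rows with positive (``"up"``) or negative
    (``"down"``) fold change; ``None`` keeps every row.  The ordering is
    fully deterministic.
    """
    if de_table.empty:
        raise ValueError("empty DE table")
    tbl = de_table.copy()
    if direction == "up":
        tbl = tbl[tbl["lfc"] > 0]
    elif direction == "down":
        tbl = tbl[tbl["lfc"] < 0]
    elif direction is not None:
        raise ValueError(f"direction must be 'up', 'down' or None, got {direction!r}")
    tbl = tbl.assign(_abs_lfc=tbl["lfc"].abs(), _id=tbl.index.astype(str))
    tbl = tbl.sort_values(["p", "_abs_lfc", "_id"], ascending=[True, False, True], kind="mergesort")
    return tbl.drop(columns=["_abs_lfc", "_id"])
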