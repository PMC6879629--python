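"""Reading, normalizing and transforming promoter-level tag-count data.

The entry point of the framework is a promoter x sample matrix of CAGE tag
counts (promoters are FANTOM5-style DPI clusters, but any unique string ID
works) together with a per-sample metadata table describing cell line,
treatment, timepoint, replicate and batch.  This module:

* parses count/metadata TSVs (:func:`read_counts`),
* optionally aggregates single-base CTSS records onto promoter regions
  (:func:`aggregate_ctss`, strand-aware, BED half-open convention),
* computes relative-log-expression (RLE) size factors
  (:func:`rle_normalize`),
* filters promoters by counts-per-million (:func:`cpm_filter`),
* produces precision-weighted log2-CPM values via a voom-style
  mean-variance trend (:func:`log_transform`), and
* collapses promoter-level CPM to gene level (:func:`collapse_to_genes`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("cell_line", "treatment", "timepoint", "replicate", "batch")


@dataclass
class CountMatrix:
    """Promoter x sample integer tag counts plus sample metadata.

    ``counts`` is a DataFrame indexed by promoter ID with one column per
    sample; ``metadata`` is indexed by sample ID and carries at least the
    columns in :data:`METADATA_COLUMNS`.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate promoter IDs: {list(dupes[:5])}")
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        extra = [s for s in self.metadata.index if s not in self.counts.columns]
        if extra:
            raise ValueError(f"metadata samples absent from counts: {extra}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
                raise ValueError(
                    "non-integer count at promoter "
                    f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            bad = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise ValueError(
                "negative count at promoter "
                f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
            )
        # align metadata rows to count columns
        self.metadata = self.metadata.loc[list(self.counts.columns)]

    @property
    def promoter_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_promoters(self, keep: pd.Index | list[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[keep], self.metadata.copy())


@dataclass
class ExpressionMatrix:
    """Weighted log2-CPM expression values on the same axes as the counts.

    ``weights`` are inverse-variance precision weights (all positive) from
    the mean-variance trend; ``size_factors`` are the RLE factors the values
    were normalized with.
    """

    values: pd.DataFrame
    weights: pd.DataFrame
    size_factors: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.weights.to_numpy() <= 0).any():
            raise ValueError("precision weights must be strictly positive")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be strictly positive")


class PromoterGeneMap:
    """Many-to-one map from promoter IDs to gene symbols."""

    def __init__(self, mapping: dict[str, str] | pd.Series):
        if isinstance(mapping, pd.Series):
            mapping = mapping.to_dict()
        self.mapping: dict[str, str] = dict(mapping)

    def __len__(self) -> int:
        return len(self.mapping)

    def gene_of(self, promoter_id: str) -> str | None:
        return self.mapping.get(promoter_id)

    def genes(self) -> set[str]:
        return set(self.mapping.values())

    @classmethod
    def read_tsv(cls, path) -> "PromoterGeneMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: promoter->gene map needs two columns")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"promoter_id": list(self.mapping), "gene": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)


def read_counts(counts_path, metadata_path) -> CountMatrix:
    """Read a promoter x sample count TSV and a sample metadata TSV.

    The first column of the counts table holds promoter IDs (FANTOM5 style
    ``chrN:start..end,strand`` or free-form; preserved verbatim).  Sample IDs
    must agree between the two files.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"{metadata_path}: metadata lacks column {col!r}")
    return CountMatrix(counts, meta)


def _parse_bed6(path):
    """Parse a BED6 file into a DataFrame; malformed lines raise with line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BED fields, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
                score = float(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if parts[5] not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {parts[5]!r}")
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            rows.append((parts[0], start, end, parts[3], score, parts[5]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def aggregate_ctss(ctss_beds, promoter_bed, metadata: pd.DataFrame | None = None) -> CountMatrix:
    """Sum CTSS tag counts onto promoter regions, strand-aware.

    ``ctss_beds`` maps sample ID to a BED6 path of single-base CTSS records
    whose score column carries the tag count (a single path is treated as one
    sample named ``sample``).  A CTSS at position p is assigned to a promoter
    iff its chromosome and strand match and ``start <= p < end`` (BED
    half-open).  Unassigned tag counts are logged.
    """
    if not isinstance(ctss_beds, dict):
        ctss_beds = {"sample": ctss_beds}
    promoters = _parse_bed6(promoter_bed)
    if promoters.name.duplicated().any():
        raise ValueError("duplicate promoter names in promoter BED")
    cols = {}
    for sample, path in ctss_beds.items():
        ctss = _parse_bed6(path)
        counts = pd.Series(0.0, index=promoters.name)
        assigned = pd.Series(False, index=ctss.index)
        for (chrom, strand), prom in promoters.groupby(["chrom", "strand"], sort=False):
            sel = ctss[(ctss.chrom == chrom) & (ctss.strand == strand)]
            if sel.empty:
                continue
            starts = prom.start.to_numpy()
            ends = prom.end.to_numpy()
            order = np.argsort(starts, kind="stable")
            pos = sel.start.to_numpy()
            idx = np.searchsorted(starts[order], pos, side="right") - 1
            ok = idx >= 0
            hit = np.where(ok & (pos < ends[order][np.clip(idx, 0, None)]), idx, -1)
            for row, j in zip(sel.index, hit):
                if j >= 0:
                    counts[prom.name.iloc[order[j]]] += ctss.score[row]
                    assigned[row] = True
        unassigned = ctss.score[~assigned].sum()
        if unassigned:
            logger.info("%s: %g CTSS tag counts not assigned to any promoter", sample, unassigned)
        cols[sample] = counts
    counts_df = pd.DataFrame(cols)
    counts_df.index.name = "promoter_id"
    if metadata is None:
        metadata = pd.DataFrame(
            {c: ["NA"] * counts_df.shape[1] for c in METADATA_COLUMNS},
            index=counts_df.columns,
        )
    return CountMatrix(counts_df.round().astype(np.int64), metadata)


def rle_normalize(counts: CountMatrix | pd.DataFrame, min_positive_fraction: float = 1.0) -> pd.Series:
    """Relative-log-expression (median-of-ratios) size factors.

    The reference profile is the per-promoter geometric mean across samples,
    computed over promoters positive in every sample; each sample's factor is
    the median ratio of its counts to the reference, rescaled so the factors
    have geometric mean 1.  If no promoter is all-positive the reference
    falls back to promoters positive in at least ``min_positive_fraction``
    (default: require all; the fallback used by callers is 0.9).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    x = mat.to_numpy(dtype=float)
    if x.shape[1] == 1:
        return pd.Series([1.0], index=mat.columns)
    pos = x > 0
    use = pos.all(axis=1)
    if not use.any():
        if min_positive_fraction >= 1.0:
            raise ValueError(
                "no promoter with positive counts in every sample; "
                "retry with min_positive_fraction < 1"
            )
        use = pos.mean(axis=1) >= min_positive_fraction
        if not use.any():
            raise ValueError("no promoter passes the positive-fraction fallback")
    with np.errstate(divide="ignore"):
        logx = np.where(x[use] > 0, np.log(np.where(x[use] > 0, x[use], 1.0)), np.nan)
    ref = np.exp(np.nanmean(logx, axis=1))
    ratios = x[use] / ref[:, None]
    factors = np.nanmedian(np.where(x[use] > 0, ratios, np.nan), axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns)


def effective_library_sizes(counts: CountMatrix, size_factors: pd.Series) -> pd.Series:
    """Effective library size per sample: geometric-mean raw library x factor.

    The median-of-ratios size factors already carry each sample's relative
    depth, so the per-sample raw library must not enter twice; anchoring on
    the geometric mean keeps CPM on a per-million scale while normalized
    values stay invariant (up to a common constant) under per-sample count
    scaling.
    """
    libsize = counts.counts.sum(axis=0).astype(float)
    gm = np.exp(np.mean(np.log(np.maximum(libsize, 1.0))))
    return gm * size_factors.loc[counts.counts.columns]


def cpm(counts: CountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    """Counts per million on RLE-effective library sizes."""
    return counts.counts / effective_library_sizes(counts, size_factors) * 1e6


def cpm_filter(counts: CountMatrix, size_factors: pd.Series, threshold_cpm: float = 5.0) -> CountMatrix:
    """Keep promoters with CPM >= threshold in at least one sample.

    Mirrors the standard practice of discarding promoters expressed below the
    threshold in *all* samples of a cell line.
    """
    cpm_mat = cpm(counts, size_factors)
    keep = (cpm_mat >= threshold_cpm).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("cpm_filter: dropped %d promoters below %g CPM in all samples", dropped, threshold_cpm)
    return counts.subset_promoters(counts.counts.index[keep])


def _lowess_trend(mean_log_count: np.ndarray, sqrt_sd: np.ndarray, frac: float):
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fit = lowess(sqrt_sd, mean_log_count, frac=frac, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]

    def predict(x):
        return np.interp(x, xs, ys)

    return predict


def log_transform(
    counts: CountMatrix,
    size_factors: pd.Series,
    group: pd.Series | None = None,
    sd_floor: float = 1e-4,
    trend_span: float = 0.5,
    weight_cap: float = 1e4,
) -> ExpressionMatrix:
    """Voom-style transform: log2-CPM values plus precision weights.

    value = log2((count + 0.5) / (effective library size + 1) * 1e6).  The
    weights come from the empirical mean-variance trend: a lowess fit of
    sqrt(residual sd of log-CPM, after removing group means) against mean
    log-count, evaluated at each observation's fitted log-count; the weight
    is the predicted value to the power -4, capped at ``weight_cap``.  With
    fewer than two replicates in every group, weights fall back to 1.
    """
    sf = size_factors.loc[counts.counts.columns]
    eff = effective_library_sizes(counts, sf)
    vals = np.log2((counts.counts + 0.5) / (eff + 1.0) * 1e6)

    if group is None:
        group = (
            counts.metadata["treatment"].astype(str)
            + "/"
            + counts.metadata["timepoint"].astype(str)
        )
    group = pd.Series(group, index=counts.counts.columns)

    sizes = group.value_counts()
    if (sizes < 2).all():
        logger.warning("log_transform: no group has >=2 replicates; weights set to 1")
        weights = pd.DataFrame(1.0, index=vals.index, columns=vals.columns)
        return ExpressionMatrix(vals, weights, sf, counts.metadata.copy())

    # residual sd after removing group means (the fixed-effects fit downstream)
    v = vals.to_numpy()
    fitted = np.zeros_like(v)
    df_resid = 0
    for g, members in group.groupby(group).groups.items():
        cols = [vals.columns.get_loc(s) for s in members]
        fitted[:, cols] = v[:, cols].mean(axis=1, keepdims=True)
        df_resid += len(cols) - 1
    resid = v - fitted
    sd = np.sqrt((resid**2).sum(axis=1) / max(df_resid, 1))
    sd = np.maximum(sd, sd_floor)

    mean_log_count = np.log2(counts.counts.to_numpy().mean(axis=1) + 0.5)
    predict = _lowess_trend(mean_log_count, np.sqrt(sd), frac=trend_span)

    # per-observation fitted log-count from the fitted log-CPM
    fitted_log_count = fitted + np.log2((eff.to_numpy() + 1.0) / 1e6)[None, :]
    pred = predict(fitted_log_count)
    pred = np.where(np.isfinite(pred), pred, 1.0)
    pred = np.clip(pred, np.sqrt(sd_floor), None)
    w = np.minimum(pred**-4.0, weight_cap)
    weights = pd.DataFrame(w, index=vals.index, columns=vals.columns)
    return ExpressionMatrix(vals, weights, sf, counts.metadata.copy())


def collapse_to_genes(matrix: pd.DataFrame, gene_map: PromoterGeneMap) -> pd.DataFrame:
    """Sum per-promoter CPM values of the same gene into one gene row.

    Promoters absent from the map are dropped (count logged).  Raises if no
    promoter of the matrix is mapped at all.
    """
    genes = pd.Series({p: gene_map.gene_of(p) for p in matrix.index})
    unmapped = genes.isna()
    if unmapped.all():
        raise ValueError("no promoter in the matrix is covered by the gene map")
    if unmapped.any():
        logger.info("collapse_to_genes: %d unmapped promoters dropped", int(unmapped.sum()))
    kept = matrix.loc[~unmapped]
    out = kept.groupby(genes[~unmapped]).sum()
    out.index.name = "gene"
    return out
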