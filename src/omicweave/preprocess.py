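"""Filtering, transformation, normalization and the QC metrics that pick one.

The normalization menu operates on log2-scale matrices and covers the
methods commonly compared for TMT proteomics: quantile, median centring,
median+MAD scaling, cyclic loess, per-sample z-transformation, and internal
reference scaling (IRS) across TMT plexes.  Method choice is guided by
pooled within-group variation metrics (PMAD, PCV, PEV -- lower is better)
and the average silhouette width over known groups (higher is better).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import InputError, OmicsDataset

logger = logging.getLogger("omicweave")

__all__ = [
    "NormalizationReport",
    "filter_flagged",
    "filter_missing",
    "log_transform",
    "normalize",
    "NORMALIZATION_METHODS",
    "impute_lls",
    "qc_metrics",
    "avg_silhouette",
    "evaluate_normalizations",
    "variable_features",
    "pca_scores",
    "md_table",
]

NORMALIZATION_METHODS = ("quantile", "median", "medianMAD", "loess", "ztransform", "irs")


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# filtering / transformation


def filter_flagged(ds: OmicsDataset) -> OmicsDataset:
    """Drop features flagged as contaminant or reverse-decoy."""
    flagged = ds.feature_meta["is_contaminant"] | ds.feature_meta["is_reverse"]
    n_con = int(ds.feature_meta["is_contaminant"].sum())
    n_rev = int(ds.feature_meta["is_reverse"].sum())
    keep = ds.feature_ids[~flagged.to_numpy()]
    if len(keep) == 0:
        raise InputError(f"layer {ds.layer_name}: all features flagged, nothing left")
    logger.info(
        "layer %s: removed %d contaminant and %d reverse features (%d kept)",
        ds.layer_name, n_con, n_rev, len(keep),
    )
    return ds.subset_features(keep)


def filter_missing(ds: OmicsDataset, max_missing_frac: float = 0.30) -> OmicsDataset:
    """Drop features whose missing fraction exceeds ``max_missing_frac``."""
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ConfigurationError("max_missing_frac must be in [0, 1]")
    frac = ds.missing_fraction()
    keep = ds.feature_ids[(frac <= max_missing_frac).to_numpy()]
    logger.info(
        "layer %s: missingness filter (> %.0f%%) removed %d of %d features",
        ds.layer_name, 100 * max_missing_frac, ds.n_features - len(keep), ds.n_features,
    )
    return ds.subset_features(keep)


def log_transform(ds: OmicsDataset, base: float = 2.0, pseudocount: float = 0.0) -> OmicsDataset:
    """Elementwise logarithm; refuses to run twice."""
    if ds.log_transformed:
        raise InputError(f"layer {ds.layer_name}: already log-transformed")
    values = ds.intensities.to_numpy(float) + pseudocount
    bad = np.asarray((values <= 0) & np.isfinite(values)).nonzero()
    if bad[0].size:
        i, j = bad[0][0], bad[1][0]
        raise InputError(
            f"layer {ds.layer_name}: non-positive value at feature "
            f"{ds.feature_ids[i]!r}, sample {ds.sample_ids[j]!r}; use a pseudocount"
        )
    out = np.log(values) / np.log(base)
    return ds.with_matrix(
        pd.DataFrame(out, index=ds.feature_ids, columns=ds.sample_ids),
        log_transformed=True,
    )


# ---------------------------------------------------------------------------
# normalization


def _raw_mad(x: np.ndarray) -> float:
    """Median absolute deviation without a consistency constant."""
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def normalize(
    ds: OmicsDataset,
    method: str,
    irs_reference: dict[str, Sequence[str]] | None = None,
    *,
    loess_span: float = 0.7,
    loess_cycles: int = 3,
) -> OmicsDataset:
    """Normalize a log-scale matrix by one of the menu methods.

    Missing values are ignored per column and stay in place.  ``irs`` needs
    ``plex`` labels in the sample metadata and, optionally, an explicit
    mapping plex -> reference sample ids (defaults to all samples of the
    plex acting as a pooled pseudo-reference).
    """
    if not ds.log_transformed:
        raise InputError("normalize expects log-transformed data")
    if method == "none":
        return ds.copy()
    if method not in NORMALIZATION_METHODS:
        raise ConfigurationError(f"unknown normalization method {method!r}")
    x = ds.intensities.to_numpy(float).copy()
    if np.isnan(x).all(axis=0).any():
        raise InputError("column with all values missing")

    if method == "quantile":
        out = _quantile_normalize(x)
    elif method == "median":
        medians = np.nanmedian(x, axis=0)
        out = x - medians + medians.mean()
    elif method == "medianMAD":
        medians = np.nanmedian(x, axis=0)
        mads = np.array([_raw_mad(col[~np.isnan(col)]) for col in x.T])
        target_med, target_mad = medians.mean(), mads.mean()
        scale = np.where(mads > 0, np.divide(target_mad, mads, out=np.ones_like(mads), where=mads > 0), 1.0)
        out = (x - medians) * scale + target_med
    elif method == "ztransform":
        mean = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0, ddof=1)
        if np.any(sd == 0):
            raise InputError("constant column cannot be z-transformed")
        out = (x - mean) / sd
    elif method == "loess":
        out = _cyclic_loess(x, span=loess_span, cycles=loess_cycles)
    else:  # irs
        out = _irs_normalize(ds, x, irs_reference)
    return ds.with_matrix(pd.DataFrame(out, index=ds.feature_ids, columns=ds.sample_ids))


def _quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Rank-mean quantile normalization tolerating missing values.

    Complete columns reproduce the textbook row-rank-mean definition
    exactly; columns with missing entries are mapped through interpolated
    quantiles of the shared reference distribution.
    """
    n, p = x.shape
    grid = np.linspace(0.0, 1.0, n)
    ref = np.zeros(n)
    for j in range(p):
        col = np.sort(x[~np.isnan(x[:, j]), j])
        m = col.size
        ref += col if m == n else np.interp(grid, np.linspace(0.0, 1.0, m), col)
    ref /= p

    out = np.full_like(x, np.nan)
    for j in range(p):
        obs = ~np.isnan(x[:, j])
        col = x[obs, j]
        m = col.size
        # average ranks so tied inputs stay tied
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(m)
        ranks[order] = np.arange(m, dtype=float)
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        sums = np.zeros(counts.size)
        np.add.at(sums, inverse, ranks)
        avg_ranks = sums[inverse] / counts[inverse]
        pos = avg_ranks / (m - 1) if m > 1 else np.full(m, 0.5)
        out[obs, j] = np.interp(pos, grid, ref)
    return out


def _cyclic_loess(x: np.ndarray, span: float, cycles: int) -> np.ndarray:
    """Pairwise cyclic loess on MA coordinates over all column pairs."""
    out = x.copy()
    p = out.shape[1]
    for _ in range(cycles):
        for i in range(p - 1):
            for j in range(i + 1, p):
                both = ~np.isnan(out[:, i]) & ~np.isnan(out[:, j])
                if both.sum() < 10:
                    continue
                m = out[both, i] - out[both, j]
                a = 0.5 * (out[both, i] + out[both, j])
                fit = lowess(m, a, frac=span, return_sorted=False)
                out[both, i] -= fit / 2.0
                out[both, j] += fit / 2.0
    return out


def _irs_normalize(
    ds: OmicsDataset, x: np.ndarray, irs_reference: dict[str, Sequence[str]] | None
) -> np.ndarray:
    if "plex" not in ds.sample_meta.columns:
        raise ConfigurationError("irs normalization needs 'plex' labels in sample metadata")
    plexes = ds.sample_meta["plex"].astype(str)
    sample_ids = list(ds.sample_ids)
    plex_levels = sorted(plexes.unique())
    if len(plex_levels) < 2:
        raise ConfigurationError("irs normalization needs >=2 plexes")
    # per-plex reference profile: mean log intensity over reference samples
    # (arithmetic mean on log scale == geometric mean on raw scale)
    ref_profiles = np.full((x.shape[0], len(plex_levels)), np.nan)
    for k, plex in enumerate(plex_levels):
        if irs_reference is not None:
            if plex not in irs_reference:
                raise ConfigurationError(f"no reference samples given for plex {plex!r}")
            cols = [sample_ids.index(s) for s in irs_reference[plex]]
            if not cols:
                raise ConfigurationError(f"empty reference for plex {plex!r}")
        else:
            cols = [i for i, pl in enumerate(plexes) if pl == plex]
        ref_profiles[:, k] = np.nanmean(x[:, cols], axis=1)
    grand = np.nanmean(ref_profiles, axis=1)
    out = x.copy()
    for k, plex in enumerate(plex_levels):
        cols = [i for i, pl in enumerate(plexes) if pl == plex]
        shift = grand - ref_profiles[:, k]  # per-feature additive (log) scaling
        out[:, cols] = out[:, cols] + shift[:, None]
    return out


# ---------------------------------------------------------------------------
# imputation


def impute_lls(ds: OmicsDataset, k_neighbors: int = 10) -> OmicsDataset:
    """Local least squares imputation.

    Each feature with missing cells is regressed on its ``k`` most
    correlated (absolute Pearson over complete pairs) neighbor features that
    are fully observed on the needed columns; missing cells are filled with
    the regression prediction.  Features with no eligible neighbor fall back
    to their row mean.  Observed cells are never touched.
    """
    if k_neighbors < 1:
        raise ConfigurationError("k_neighbors must be >= 1")
    x = ds.intensities.to_numpy(float)
    miss = np.isnan(x)
    if not miss.any():
        return ds.copy()
    if np.all(miss, axis=1).any():
        raise InputError("feature with no observed value cannot be imputed")
    out = x.copy()
    n = x.shape[0]
    # candidate neighbors are ranked by |corr| computed over complete pairs
    masked = np.ma.masked_invalid(x)
    corr = np.ma.corrcoef(masked)
    corr = np.asarray(corr.filled(0.0))
    np.fill_diagonal(corr, 0.0)

    for i in np.where(miss.any(axis=1))[0]:
        obs_cols = ~miss[i]
        need_cols = miss[i]
        # neighbors must be observed wherever the target is observed or needed
        eligible = ~np.any(miss[:, obs_cols | need_cols], axis=1)
        eligible[i] = False
        cand = np.where(eligible)[0]
        filled = False
        if cand.size:
            order = cand[np.argsort(-np.abs(corr[i, cand]), kind="mergesort")]
            nbrs = order[:k_neighbors]
            X = np.column_stack([np.ones(obs_cols.sum()), x[nbrs][:, obs_cols].T])
            y = x[i, obs_cols]
            if X.shape[0] >= 2:
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                pred = np.column_stack([np.ones(need_cols.sum()), x[nbrs][:, need_cols].T]) @ beta
                if np.all(np.isfinite(pred)):
                    out[i, need_cols] = pred
                    filled = True
        if not filled:
            out[i, need_cols] = np.nanmean(x[i])
    return ds.with_matrix(pd.DataFrame(out, index=ds.feature_ids, columns=ds.sample_ids))


# ---------------------------------------------------------------------------
# QC metrics


@dataclass
class NormalizationReport:
    """Per-method QC metrics with one recommended method flagged."""

    table: pd.DataFrame  # index: method; columns: PMAD, PCV, PEV, silhouette, recommended

    @property
    def recommended(self) -> str:
        return str(self.table.index[self.table["recommended"]][0])


def qc_metrics(ds: OmicsDataset, group_column: str = "group") -> dict[str, float]:
    """Pooled within-group variation metrics.

    Per group with >=2 replicates, using features complete in that group:
    PMAD = mean over features of the raw MAD across replicates, PCV = mean
    of sd/|mean| (sample sd), PEV = mean of the within-group variance.  The
    pooled value is the plain mean over eligible groups.
    """
    groups = ds.sample_meta[group_column].astype(str)
    x = ds.intensities.to_numpy(float)
    pmads, pcvs, pevs = [], [], []
    for g in sorted(groups.unique()):
        cols = np.where((groups == g).to_numpy())[0]
        if cols.size < 2:
            continue
        sub = x[:, cols]
        complete = ~np.isnan(sub).any(axis=1)
        if not complete.any():
            continue
        sub = sub[complete]
        med = np.median(sub, axis=1, keepdims=True)
        pmads.append(np.mean(np.median(np.abs(sub - med), axis=1)))
        sd = np.std(sub, axis=1, ddof=1)
        mean = np.mean(sub, axis=1)
        pcvs.append(np.mean(sd / np.abs(mean)))
        pevs.append(np.mean(sd**2))
    if not pmads:
        raise InputError("no group with >=2 replicates and complete features")
    return {
        "PMAD": float(np.mean(pmads)),
        "PCV": float(np.mean(pcvs)),
        "PEV": float(np.mean(pevs)),
    }


def avg_silhouette(
    ds: OmicsDataset,
    group_column: str = "group",
    space: str = "top_pcs",
    n_pcs: int = 2,
) -> float:
    """Average silhouette width of samples over known groups.

    Euclidean distance between sample vectors built from complete features
    only (``space="features"``) or from their top principal-component
    scores (``space="top_pcs"``, the default).  Singleton groups score 0.
    """
    groups = ds.sample_meta[group_column].astype(str).to_numpy()
    if len(set(groups)) < 2:
        raise InputError("silhouette needs >=2 groups")
    x = ds.intensities.to_numpy(float)
    complete = ~np.isnan(x).any(axis=1)
    if not complete.any():
        raise InputError("no complete features for silhouette")
    data = x[complete].T  # samples x features
    if space == "top_pcs":
        k = min(n_pcs, data.shape[0] - 1, data.shape[1])
        scores, _, _ = pca_scores_matrix(data, k)
        data = scores
    elif space != "features":
        raise ConfigurationError(f"unknown silhouette space {space!r}")
    return _silhouette(data, groups)


def _silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    n = points.shape[0]
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    widths = np.zeros(n)
    uniq = sorted(set(labels))
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if not same.any():
            widths[i] = 0.0  # singleton cluster convention
            continue
        a = d[i, same].mean()
        b = min(d[i, labels == g].mean() for g in uniq if g != labels[i])
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(widths.mean())


def evaluate_normalizations(
    ds: OmicsDataset,
    methods: Sequence[str] = ("quantile", "median", "medianMAD", "loess", "ztransform"),
    group_column: str = "group",
    irs_reference: dict[str, Sequence[str]] | None = None,
    silhouette_space: str = "top_pcs",
) -> NormalizationReport:
    """Run each method, collect QC metrics, and flag the best rank-sum method.

    Ranks: ascending for PMAD/PCV/PEV (lower is better), descending for the
    silhouette.  Ties in the total rank fall back to method-list order.
    """
    if len(methods) < 2:
        raise ConfigurationError("evaluate_normalizations needs >=2 methods")
    rows = []
    for method in methods:
        normed = normalize(ds, method, irs_reference=irs_reference) if method != "none" else ds.copy()
        metrics = qc_metrics(normed, group_column)
        metrics["silhouette"] = avg_silhouette(normed, group_column, space=silhouette_space)
        rows.append(pd.Series(metrics, name=method))
    table = pd.DataFrame(rows)
    ranks = (
        table[["PMAD", "PCV", "PEV"]].rank(method="average", ascending=True).sum(axis=1)
        + table["silhouette"].rank(method="average", ascending=False)
    )
    order = np.lexsort((np.arange(len(methods)), ranks.to_numpy()))
    table["rank_sum"] = ranks
    table["recommended"] = False
    table.iloc[order[0], table.columns.get_loc("recommended")] = True
    table.index.name = "method"
    return NormalizationReport(table)


# ---------------------------------------------------------------------------
# exploratory helpers


def variable_features(ds: OmicsDataset, top_frac: float = 0.10) -> list[str]:
    """Top fraction of features by complete-case variance across samples."""
    if not 0.0 < top_frac <= 1.0:
        raise ConfigurationError("top_frac must be in (0, 1]")
    x = ds.intensities
    var = x.var(axis=1, ddof=1, skipna=True).fillna(-np.inf)
    k = int(np.ceil(top_frac * ds.n_features))
    order = var.sort_values(ascending=False, kind="mergesort")
    return list(order.index[:k])


def pca_scores_matrix(data: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA on a samples x features matrix; returns (scores, loadings, var fractions)."""
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(data)
    return scores, pca.components_, pca.explained_variance_ratio_


def pca_scores(ds: OmicsDataset, n_components: int = 2) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Sample PCA of the complete-feature submatrix (features mean-centred)."""
    x = ds.intensities.to_numpy(float)
    complete = ~np.isnan(x).any(axis=1)
    data = x[complete].T
    if n_components > min(data.shape):
        raise ConfigurationError(
            f"n_components={n_components} exceeds min(n_samples, n_features)={min(data.shape)}"
        )
    scores, components, var_frac = pca_scores_matrix(data, n_components)
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    score_df = pd.DataFrame(scores, index=ds.sample_ids, columns=pcs)
    loading_df = pd.DataFrame(components.T, index=ds.feature_ids[complete], columns=pcs)
    return score_df, loading_df, var_frac


def md_table(diff) -> pd.DataFrame:
    """Mean-difference table (average expression vs logFC) from a fit result."""
    t = diff.table
    return pd.DataFrame(
        {"AveExpr": t["AveExpr"].to_numpy(), "logFC": t["logFC"].to_numpy()},
        index=t.index,
    )
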