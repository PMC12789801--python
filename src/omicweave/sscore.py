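"""Cross-layer integration with the S-score statistic.

Within each omic layer the model-derived logFC of every feature is
standardised against the layer's own logFC distribution, z_i =
(logFC_i - mu_j) / sigma_j, and weighted by w_j = u_j / sqrt(N_j) where
N_j is the number of features tested in the layer and u_j an optional user
multiplier.  After a full join on gene symbols, each gene's contributing
records combine into

    S = sum(w * z) / sqrt(sum(w^2)),

which is standard normal under the null for any weights, so a two-sided
normal p-value and Benjamini-Hochberg adjustment give gene-level
significance.  Concordant but individually sub-threshold effects across
layers reinforce each other, which is the point of the statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import InputError
from .diffexp import DiffExpResult, adjust_bh

logger = logging.getLogger("omicweave")

__all__ = ["LayerStats", "SScoreTable", "layer_stats", "integrate", "significant_genes"]


@dataclass
class LayerStats:
    """Standardised per-feature logFC records for one layer.

    ``records`` columns: layer, feature_id, gene, logfc, z, w, wz.
    """

    layer_name: str
    records: pd.DataFrame
    mu: float
    sigma: float
    n_features: int
    user_weight: float
    weight: float  # u_j / sqrt(N_j)


@dataclass
class SScoreTable:
    """Gene-level integrated scores.

    ``table``: indexed by gene with columns n_features, comb_wz, comb_w,
    sscore, sscore_pval, sscore_adj_pval, significant.  ``records`` keeps
    the per-feature contributions for export/inspection.
    """

    table: pd.DataFrame
    records: pd.DataFrame
    alpha: float


def layer_stats(
    diff: DiffExpResult | pd.DataFrame,
    layer_name: str,
    user_weight: float = 1.0,
) -> LayerStats:
    """Standardise a layer's logFCs and compute its weight.

    Accepts a fitted :class:`DiffExpResult` or any frame with
    ``gene_symbol`` and ``logFC`` columns.  mu_j and sigma_j are the mean
    and sample sd (ddof 1) over features with finite logFC.
    """
    if user_weight <= 0:
        raise InputError("user_weight must be positive")
    frame = diff.table if isinstance(diff, DiffExpResult) else diff
    logfc = frame["logFC"].to_numpy(float)
    genes = frame["gene_symbol"].astype(str).to_numpy()
    ok = np.isfinite(logfc)
    n = int(ok.sum())
    if n < 2:
        raise InputError(f"layer {layer_name!r}: fewer than 2 features with finite logFC")
    mu = float(logfc[ok].mean())
    sigma = float(logfc[ok].std(ddof=1))
    if sigma == 0:
        raise InputError(f"layer {layer_name!r}: zero logFC spread (degenerate layer)")
    w = user_weight / np.sqrt(n)
    z = (logfc[ok] - mu) / sigma
    records = pd.DataFrame(
        {
            "layer": layer_name,
            "feature_id": np.asarray(frame.index)[ok],
            "gene": genes[ok],
            "logfc": logfc[ok],
            "z": z,
            "w": w,
            "wz": w * z,
        }
    )
    return LayerStats(
        layer_name=layer_name,
        records=records,
        mu=mu,
        sigma=sigma,
        n_features=n,
        user_weight=float(user_weight),
        weight=float(w),
    )


def integrate(
    layers: list[LayerStats],
    alpha: float = 0.05,
    collapse_within_layer: bool = False,
) -> SScoreTable:
    """Full join on gene symbols and S-score combination.

    Every contributing feature record adds its own w*z term to the
    numerator and its own w^2 to the denominator, so a gene measured by m
    phosphosites in one layer contributes m terms.  With
    ``collapse_within_layer`` only the max-|z| feature per gene per layer
    contributes.  Genes present in only some layers use only those layers'
    terms.
    """
    if not layers:
        raise InputError("integrate needs >=1 layer")
    records = pd.concat([layer.records for layer in layers], ignore_index=True)
    if records.empty:
        raise InputError("empty join: no gene records")
    if collapse_within_layer:
        records = records.assign(_absz=records["z"].abs()).sort_values(
            by=["_absz", "feature_id"], ascending=[False, True], kind="mergesort"
        )
        records = records.drop_duplicates(subset=["layer", "gene"], keep="first")
        records = records.drop(columns="_absz").sort_index(ignore_index=True)

    grouped = records.groupby("gene", sort=True)
    comb_wz = grouped["wz"].sum()
    comb_w = np.sqrt(grouped["w"].apply(lambda w: float((w.to_numpy() ** 2).sum())))
    n_feat = grouped.size()
    s = comb_wz / comb_w
    pvals = 2.0 * stats.norm.sf(np.abs(s.to_numpy()))
    adj = adjust_bh(pvals)
    table = pd.DataFrame(
        {
            "n_features": n_feat,
            "comb_wz": comb_wz,
            "comb_w": comb_w,
            "sscore": s,
            "sscore_pval": pvals,
            "sscore_adj_pval": adj,
        }
    )
    table["significant"] = table["sscore_adj_pval"] < alpha
    table.index.name = "gene"
    return SScoreTable(table=table, records=records, alpha=alpha)


def significant_genes(table: SScoreTable, alpha: float | None = None) -> list[str]:
    """Genes with adjusted p below alpha, ordered by |S| descending."""
    alpha = table.alpha if alpha is None else alpha
    t = table.table
    sig = t[t["sscore_adj_pval"] < alpha].copy()
    sig["_abs"] = sig["sscore"].abs()
    sig = sig.sort_values(by=["_abs", "sscore_adj_pval"], ascending=[False, True], kind="mergesort")
    return list(sig.index)
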