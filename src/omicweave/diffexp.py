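"""Per-feature linear modelling with empirical-Bayes variance moderation.

The model follows the limma approach: every feature is fitted by ordinary
least squares on its observed samples (complete-case per feature), the
residual variances s_g^2 with residual degrees of freedom d_g are shrunk
toward a scaled inverse-chi-square prior (d0, s0^2) estimated across
features by moment matching on log s_g^2, and the contrast of interest is
tested with a moderated t-statistic on d0 + d_g degrees of freedom.
Multiple testing is controlled with Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import InputError, OmicsDataset, SampleAnnotation

logger = logging.getLogger("omicweave")

__all__ = [
    "DesignMatrix",
    "Contrast",
    "DiffExpResult",
    "build_design",
    "make_contrast",
    "fit_linear_model",
    "ebayes_moderate",
    "adjust_bh",
    "remove_batch_effect",
    "rank_metric",
]


@dataclass
class DesignMatrix:
    """Samples x coefficients matrix plus the spec that generated it."""

    matrix: pd.DataFrame
    factors: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    reference_levels: dict[str, str] = field(default_factory=dict)

    @property
    def coef_names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_coefficients(self) -> int:
        return self.matrix.shape[1]


@dataclass
class Contrast:
    """Named coefficient combination; ``values`` aligns with the design columns."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.any(self.values != 0):
            raise InputError(f"contrast {self.name!r} is all-zero")


@dataclass
class DiffExpResult:
    """Per-feature model output plus the global moderation hyperparameters.

    ``table`` columns: gene_symbol, logFC, AveExpr, s2 (residual variance),
    df_resid, and after moderation t, P.Value, adj.P.Val, s2_post.
    """

    table: pd.DataFrame
    contrast: Contrast
    design: DesignMatrix
    d0: float | None = None  # prior df; None before moderation, inf allowed
    s0_sq: float | None = None  # prior variance

    @property
    def moderated(self) -> bool:
        return self.d0 is not None

    def to_frame(self) -> pd.DataFrame:
        """limma-compatible export table."""
        t = self.table
        out = pd.DataFrame(
            {
                "feature_id": t.index,
                "gene_symbol": t["gene_symbol"].to_numpy(),
                "logFC": t["logFC"].to_numpy(),
                "AveExpr": t["AveExpr"].to_numpy(),
                "t": t.get("t", pd.Series(np.nan, index=t.index)).to_numpy(),
                "P.Value": t.get("P.Value", pd.Series(np.nan, index=t.index)).to_numpy(),
                "adj.P.Val": t.get("adj.P.Val", pd.Series(np.nan, index=t.index)).to_numpy(),
                "df.residual": t["df_resid"].to_numpy(),
            }
        )
        return out


# ---------------------------------------------------------------------------
# design construction


def build_design(
    annotation: SampleAnnotation | pd.DataFrame,
    factors: list[str],
    covariates: list[str] | None = None,
    reference_levels: dict[str, str] | None = None,
) -> DesignMatrix:
    """Treatment-coded design with intercept.

    Each factor contributes indicator columns ``<factor><level>`` for every
    non-reference level (reference = given, else lexicographically first);
    numeric covariates are passed through mean-centred.  Rank deficiency is
    an error naming the aliased columns.
    """
    table = annotation.table if isinstance(annotation, SampleAnnotation) else annotation
    covariates = covariates or []
    reference_levels = dict(reference_levels or {})
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(table))}
    for factor in factors:
        if factor not in table.columns:
            raise InputError(f"factor {factor!r} not in annotation")
        values = table[factor].astype(str)
        levels = sorted(values.unique())
        if len(levels) < 2:
            raise InputError(f"factor {factor!r} has a single level {levels!r}")
        ref = reference_levels.get(factor, levels[0])
        if ref not in levels:
            raise InputError(f"reference level {ref!r} not a level of {factor!r}")
        reference_levels[factor] = ref
        for level in levels:
            if level == ref:
                continue
            cols[f"{factor}{level}"] = (values == level).to_numpy(float)
    for cov in covariates:
        if cov not in table.columns:
            raise InputError(f"covariate {cov!r} not in annotation")
        v = pd.to_numeric(table[cov], errors="raise").to_numpy(float)
        cols[cov] = v - v.mean()
    matrix = pd.DataFrame(cols, index=table.index)
    _check_full_rank(matrix)
    return DesignMatrix(
        matrix=matrix,
        factors=tuple(factors),
        covariates=tuple(covariates),
        reference_levels=reference_levels,
    )


def _check_full_rank(matrix: pd.DataFrame) -> None:
    x = matrix.to_numpy(float)
    if np.linalg.matrix_rank(x) == x.shape[1]:
        return
    aliased = []
    for j in range(1, x.shape[1]):
        if np.linalg.matrix_rank(x[:, : j + 1]) == np.linalg.matrix_rank(x[:, :j]):
            aliased.append(matrix.columns[j])
    raise InputError(f"design matrix is rank deficient; aliased columns: {aliased}")


def make_contrast(design: DesignMatrix, spec: str | dict[str, float] | np.ndarray) -> Contrast:
    """Build a contrast from a coefficient name, a name->weight dict, or a vector."""
    names = design.coef_names
    if isinstance(spec, str):
        if spec not in names:
            raise InputError(f"unknown coefficient {spec!r}; available: {names}")
        values = np.zeros(len(names))
        values[names.index(spec)] = 1.0
        return Contrast(spec, values)
    if isinstance(spec, dict):
        values = np.zeros(len(names))
        for key, weight in spec.items():
            if key not in names:
                raise InputError(f"unknown coefficient {key!r}; available: {names}")
            values[names.index(key)] = weight
        label = "+".join(f"{w:g}*{k}" for k, w in spec.items())
        return Contrast(label, values)
    values = np.asarray(spec, float)
    if values.shape != (len(names),):
        raise InputError(f"contrast vector length {values.size} != {len(names)} coefficients")
    return Contrast("custom", values)


# ---------------------------------------------------------------------------
# fitting


def fit_linear_model(ds: OmicsDataset, design: DesignMatrix, contrast: Contrast | str) -> DiffExpResult:
    """Complete-case OLS per feature; returns an unmoderated result.

    Features observed in fewer samples than the design rank get missing
    coefficients (logged).  ``logFC`` is the contrast of the fitted
    coefficients, ``s2`` the residual variance SSE/d_g, ``AveExpr`` the
    mean of the modelled values.
    """
    if not ds.log_transformed:
        logger.warning("layer %s: fitting non-log-transformed data", ds.layer_name)
    if isinstance(contrast, str):
        contrast = make_contrast(design, contrast)
    X_full = design.matrix.loc[ds.sample_ids].to_numpy(float)
    y_all = ds.intensities.to_numpy(float)
    n_feat = y_all.shape[0]
    logfc = np.full(n_feat, np.nan)
    ave = np.full(n_feat, np.nan)
    s2 = np.full(n_feat, np.nan)
    df_resid = np.zeros(n_feat)
    vc = np.full(n_feat, np.nan)

    masks = ~np.isnan(y_all)
    # batch features sharing a missingness pattern: one decomposition each
    pattern_ids = {}
    for i in range(n_feat):
        pattern_ids.setdefault(masks[i].tobytes(), []).append(i)
    n_skipped = 0
    for key, idx in pattern_ids.items():
        mask = masks[idx[0]]
        n_obs = int(mask.sum())
        if n_obs == 0:
            n_skipped += len(idx)
            continue
        X = X_full[mask]
        rank = np.linalg.matrix_rank(X) if n_obs else 0
        rows = np.asarray(idx)
        Y = y_all[np.ix_(rows, np.where(mask)[0])]
        ave[rows] = Y.mean(axis=1)
        if rank < X.shape[1]:
            n_skipped += len(idx)
            continue
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = Y @ (X @ xtx_inv)  # (features x coef)
        resid = Y - beta @ X.T
        d = n_obs - rank
        df_resid[rows] = d
        sse = (resid**2).sum(axis=1)
        s2[rows] = sse / d if d > 0 else np.nan
        logfc[rows] = beta @ contrast.values
        vc[rows] = float(contrast.values @ xtx_inv @ contrast.values)
    if n_skipped:
        logger.info(
            "layer %s: %d feature(s) observed in fewer samples than the design rank; "
            "coefficients set missing", ds.layer_name, n_skipped,
        )
    table = pd.DataFrame(
        {
            "gene_symbol": ds.feature_meta["gene_symbol"].to_numpy(),
            "logFC": logfc,
            "AveExpr": ave,
            "s2": s2,
            "df_resid": df_resid,
            "contrast_var": vc,
        },
        index=ds.feature_ids,
    )
    return DiffExpResult(table=table, contrast=contrast, design=design)


# ---------------------------------------------------------------------------
# empirical Bayes moderation


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration, tol 1e-8)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to {s_g^2}.

    Works on log s_g^2: the excess of its variance over the expected
    trigamma term determines d0 (infinite when the excess is non-positive,
    in which case s0^2 is the plain mean of the variances).
    """
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    usable = np.isfinite(s2) & (df > 0)
    pos = usable & (s2 > 0)
    if pos.sum() < 2:
        raise InputError("need >=2 features with positive residual variance")
    z = np.log(s2[pos])
    d = df[pos]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(((e - emean) ** 2).sum() / (n - 1))
    excess = evar - float(np.mean(special.polygamma(1, d / 2.0)))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.mean(s2[usable]))
    return d0, s0_sq


def ebayes_moderate(result: DiffExpResult) -> DiffExpResult:
    """Moderate residual variances and compute moderated t / p / adjusted p."""
    t = result.table
    s2 = t["s2"].to_numpy(float)
    df = t["df_resid"].to_numpy(float)
    if not np.any(np.isfinite(s2) & (s2 > 0)):
        raise InputError("all residual variances are zero or missing; degenerate data")
    d0, s0_sq = fit_variance_prior(s2, df)
    with np.errstate(invalid="ignore"):
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            s2_post[~(df > 0)] = np.nan
            df_total = np.full_like(df, np.inf)
        else:
            s2_eff = np.where(np.isfinite(s2), s2, 0.0)
            s2_post = (d0 * s0_sq + df * s2_eff) / (d0 + df)
            s2_post[~(df > 0) & ~np.isfinite(s2)] = np.nan
            df_total = d0 + df
        vc = t["contrast_var"].to_numpy(float)
        tstat = t["logFC"].to_numpy(float) / np.sqrt(s2_post * vc)
    pvals = np.full_like(tstat, np.nan)
    ok = np.isfinite(tstat) & (df > 0)
    finite_df = ok & np.isfinite(df_total)
    inf_df = ok & ~np.isfinite(df_total)
    pvals[finite_df] = 2.0 * stats.t.sf(np.abs(tstat[finite_df]), df_total[finite_df])
    pvals[inf_df] = 2.0 * stats.norm.sf(np.abs(tstat[inf_df]))
    tstat[~ok] = np.nan

    out = t.copy()
    out["s2_post"] = s2_post
    out["t"] = tstat
    out["P.Value"] = pvals
    out["adj.P.Val"] = adjust_bh(pvals)
    return DiffExpResult(table=out, contrast=result.contrast, design=result.design, d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# multiple testing


def adjust_bh(pvals: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; missing values pass through."""
    p = np.asarray(pvals, float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    pf = p[finite]
    n = pf.size
    if n == 0:
        return out
    order = np.argsort(pf, kind="mergesort")
    ranked = pf[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    result = np.empty(n)
    result[order] = adjusted
    out[finite] = result
    return out


# ---------------------------------------------------------------------------
# batch correction (visualization only) and GSEA ranking


def remove_batch_effect(ds: OmicsDataset, design: DesignMatrix, batch_column: str = "batch") -> OmicsDataset:
    """Subtract estimated batch contributions from the matrix.

    Batch enters as sum-coded dummies fitted jointly with the protected
    biological design, then only the batch part is removed.  Intended for
    visualization; the modelling path keeps batch in the design instead.
    """
    if batch_column not in ds.sample_meta.columns:
        raise InputError(f"no {batch_column!r} column in sample metadata")
    batch = ds.sample_meta[batch_column].astype(str)
    levels = sorted(batch.unique())
    if len(levels) < 2:
        raise InputError(f"batch column {batch_column!r} has a single level")
    n = len(batch)
    B = np.zeros((n, len(levels) - 1))
    for j, level in enumerate(levels[:-1]):
        B[(batch == level).to_numpy(), j] = 1.0
    B[(batch == levels[-1]).to_numpy(), :] = -1.0

    X_bio = design.matrix.loc[ds.sample_ids].to_numpy(float)
    X = np.hstack([X_bio, B])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError(f"batch {batch_column!r} is aliased with a protected design term")
    y_all = ds.intensities.to_numpy(float)
    out = y_all.copy()
    masks = ~np.isnan(y_all)
    pattern_ids: dict[bytes, list[int]] = {}
    for i in range(y_all.shape[0]):
        pattern_ids.setdefault(masks[i].tobytes(), []).append(i)
    nb = X_bio.shape[1]
    for idx in pattern_ids.values():
        mask = masks[idx[0]]
        Xm = X[mask]
        if Xm.shape[0] < X.shape[1] or np.linalg.matrix_rank(Xm) < X.shape[1]:
            continue  # cannot estimate batch for this pattern; left untouched
        rows = np.asarray(idx)
        Y = y_all[np.ix_(rows, np.where(mask)[0])]
        beta = Y @ np.linalg.pinv(Xm).T
        batch_part = beta[:, nb:] @ B[mask].T
        out[np.ix_(rows, np.where(mask)[0])] = Y - batch_part
    return ds.with_matrix(pd.DataFrame(out, index=ds.feature_ids, columns=ds.sample_ids))


def rank_metric(result: DiffExpResult, scheme: str = "signed_logp") -> pd.Series:
    """Gene-level ranking score for preranked GSEA.

    ``signed_logp``: sign(logFC) x -log10(raw p).  When several features map
    to one gene the largest-magnitude score wins (ties broken by |logFC|,
    then feature id).
    """
    if scheme != "signed_logp":
        raise ValueError(f"unknown ranking scheme {scheme!r}")
    if not result.moderated:
        raise InputError("rank_metric needs a moderated result")
    t = result.table
    ok = np.isfinite(t["P.Value"].to_numpy(float)) & np.isfinite(t["logFC"].to_numpy(float))
    sub = t.loc[ok, ["gene_symbol", "logFC", "P.Value"]].copy()
    p = np.clip(sub["P.Value"].to_numpy(float), 1e-300, None)
    sub["score"] = np.sign(sub["logFC"].to_numpy(float)) * (-np.log10(p))
    sub["_abs_score"] = sub["score"].abs()
    sub["_abs_lfc"] = sub["logFC"].abs()
    sub = sub.sort_values(
        by=["_abs_score", "_abs_lfc", "gene_symbol"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    sub["_fid"] = sub.index
    sub = sub.sort_values(
        by=["_abs_score", "_abs_lfc", "_fid"], ascending=[False, False, True], kind="mergesort"
    )
    best = sub.drop_duplicates(subset="gene_symbol", keep="first")
    return pd.Series(best["score"].to_numpy(), index=best["gene_symbol"].to_numpy(), name="score")
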