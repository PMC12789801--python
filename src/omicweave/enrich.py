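"""Over-representation analysis and preranked gene-set enrichment.

ORA tests each gene set with a one-sided hypergeometric upper-tail p-value
for the observed overlap between a query gene list and the set, within a
stated universe (by default the measured genes, not the genome).  Preranked
GSEA computes the classic weighted running-sum enrichment score on a
descending score ranking with a gene-label permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, InputError
from .diffexp import adjust_bh

logger = logging.getLogger("omicweave")

__all__ = ["EnrichmentResult", "ora", "gsea_preranked", "enrich_clusters"]


@dataclass
class EnrichmentResult:
    """Per-set results: statistic, overlap/leading-edge genes, p, adjusted p."""

    table: pd.DataFrame
    mode: str  # "ora" or "gsea"


def ora(
    query: Sequence[str],
    universe: Sequence[str],
    sets: GeneSetCollection,
    min_size: int = 3,
    max_size: int = 500,
) -> EnrichmentResult:
    """Hypergeometric over-representation test per gene set.

    The query is intersected with the universe (dropped genes are logged);
    each set is restricted to the universe and size-filtered before
    testing.  BH adjustment runs across the tested sets.
    """
    uni = sorted(set(universe))
    if len(uni) < 10:
        raise InputError(f"universe has {len(uni)} genes, needs >=10")
    uni_set = set(uni)
    q = sorted(set(query) & uni_set)
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.info("ora: %d query gene(s) outside the universe dropped", dropped)
    if not q:
        raise InputError("empty query after intersecting with universe")
    M, n_query = len(uni), len(q)
    qset = set(q)
    rows = []
    for gs in sets:
        members = sorted(set(gs.members) & uni_set)
        if not (min_size <= len(members) <= max_size):
            continue
        overlap = sorted(qset & set(members))
        k = len(overlap)
        pval = float(stats.hypergeom.sf(k - 1, M, len(members), n_query))
        rows.append(
            {
                "set": gs.name,
                "set_size": len(members),
                "overlap_size": k,
                "overlap_genes": ",".join(overlap),
                "pval": pval,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["adj_pval"] = adjust_bh(table["pval"].to_numpy())
        table = table.sort_values(by=["pval", "set"], kind="mergesort", ignore_index=True)
    return EnrichmentResult(table=table, mode="ora")


def _running_sum(hit: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    """Signed extremum of the GSEA running sum and its position."""
    n = hit.size
    n_hit = int(hit.sum())
    n_miss = n - n_hit
    hit_w = np.abs(weights) * hit
    total = hit_w.sum()
    inc = np.where(hit, hit_w / total if total > 0 else 0.0, -1.0 / n_miss if n_miss else 0.0)
    running = np.cumsum(inc)
    pos = int(np.argmax(np.abs(running)))
    return float(running[pos]), pos


def gsea_preranked(
    scores: Mapping[str, float] | pd.Series,
    sets: GeneSetCollection,
    weight_exponent: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 3,
    max_size: int = 500,
) -> EnrichmentResult:
    """Preranked GSEA with a gene-label permutation null.

    Genes are ranked by score descending (ties by gene id ascending); hits
    increment the running sum by |score|^exponent normalised to one, misses
    decrement uniformly; ES is the signed extremum.  NES divides ES by the
    mean |null ES| of the same sign; p is the add-one permutation fraction
    among same-sign permutations.  BH runs across the tested sets.
    """
    if weight_exponent not in (0, 1):
        raise ValueError("weight_exponent must be 0 or 1")
    s = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores.copy()
    if s.index.has_duplicates:
        raise InputError("duplicate genes in the ranking")
    order = np.lexsort((np.asarray(s.index, str), -s.to_numpy(float)))
    genes = np.asarray(s.index, str)[order]
    vals = s.to_numpy(float)[order]
    weights = np.abs(vals) ** weight_exponent
    n = genes.size
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for gs in sets:
        members = [g for g in gs.members if g in gene_pos]
        if not members:
            logger.info("gsea: set %r has no genes in the ranking; skipped", gs.name)
            continue
        if not (min_size <= len(members) <= max_size):
            continue
        hit = np.zeros(n, bool)
        hit[[gene_pos[g] for g in members]] = True
        es, pos = _running_sum(hit, weights)
        # leading edge: hits at or before a positive extremum / at or after a negative one
        if es >= 0:
            leading = [g for g in genes[: pos + 1] if g in set(members)]
        else:
            leading = [g for g in genes[pos:] if g in set(members)]
        null_es = np.empty(n_perm)
        k = len(members)
        for b in range(n_perm):
            perm_hit = np.zeros(n, bool)
            perm_hit[rng.choice(n, size=k, replace=False)] = True
            null_es[b], _ = _running_sum(perm_hit, weights)
        same_sign = null_es[null_es >= 0] if es >= 0 else null_es[null_es < 0]
        denom = float(np.abs(same_sign).mean()) if same_sign.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        pval = (1.0 + float((np.abs(same_sign) >= abs(es)).sum())) / (1.0 + same_sign.size)
        rows.append(
            {
                "set": gs.name,
                "set_size": len(members),
                "ES": es,
                "NES": nes,
                "leading_edge": ",".join(leading),
                "pval": min(pval, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["adj_pval"] = adjust_bh(table["pval"].to_numpy())
        table = table.sort_values(by=["pval", "set"], kind="mergesort", ignore_index=True)
    return EnrichmentResult(table=table, mode="gsea")


def enrich_clusters(
    clusters: Mapping[str, int] | Mapping[str, str],
    universe: Sequence[str],
    sets: GeneSetCollection,
    min_size: int = 3,
    max_size: int = 500,
) -> tuple[dict, pd.DataFrame]:
    """ORA per cluster; the top term annotates the cluster.

    ``clusters`` maps gene -> cluster label; the universe is typically the
    node set of the base interaction network.  Clusters below ``min_size``
    are skipped.  Returns (cluster -> EnrichmentResult, summary frame with
    one representative term per cluster).
    """
    by_cluster: dict = {}
    for gene, cl in clusters.items():
        by_cluster.setdefault(cl, []).append(gene)
    results: dict = {}
    summary_rows = []
    for cl in sorted(by_cluster, key=str):
        genes = sorted(by_cluster[cl])
        if len(genes) < min_size:
            logger.info("cluster %r below min_size (%d genes); skipped", cl, len(genes))
            continue
        res = ora(genes, universe, sets, min_size=min_size, max_size=max_size)
        results[cl] = res
        if not res.table.empty:
            top = res.table.iloc[0]
            summary_rows.append(
                {
                    "cluster": cl,
                    "n_genes": len(genes),
                    "representative_set": top["set"],
                    "pval": top["pval"],
                    "adj_pval": top["adj_pval"],
                }
            )
    return results, pd.DataFrame(summary_rows)
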