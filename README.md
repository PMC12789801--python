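# omicweave

A scriptable toolkit for integrative analysis of multi-omic intensity data
(TMT proteomics, phosphoproteomics, metabolomics and similar feature-by-sample
matrices). It covers the full path from raw abundance tables to interpretable
subnetworks:

1. **Preprocessing & QC** — contaminant/decoy filtering, missingness
   filtering, log2 transformation, a normalization menu (quantile, median,
   median+MAD, cyclic loess, z-transform, internal reference scaling across
   TMT plexes), local-least-squares imputation, and data-driven method
   selection via pooled variation metrics (PMAD, PCV, PEV) and the average
   silhouette width over known groups.
2. **Differential analysis** — per-feature linear models with covariates and
   batch terms (complete-case per feature, so missing values need no
   imputation), empirical-Bayes variance moderation in the limma style, and
   Benjamini–Hochberg adjustment.
3. **S-score integration** — the core statistic. Within each layer *j*, every
   feature's model-derived log fold change is standardized,
   *z*ᵢ = (logFCᵢ − μⱼ)/σⱼ, and weighted by *w*ⱼ = *u*ⱼ/√*N*ⱼ (layer size
   *N*ⱼ, optional user multiplier *u*ⱼ). After a full join on gene symbols,

   S = Σ wᵢzᵢ / √(Σ wᵢ²)

   over all of a gene's contributing features across layers. S is standard
   normal under the null for any weights, so genes get two-sided normal
   p-values and BH-adjusted significance calls. Concordant but individually
   sub-threshold effects across layers reinforce each other — the point of
   integrating.
4. **Enrichment** — hypergeometric over-representation analysis and preranked
   GSEA (weighted running-sum ES, gene-label permutation null) over
   user-supplied GMT collections.
5. **Network discovery** — a prize-collecting Steiner forest over a
   confidence-filtered interaction network (STRING-style combined scores
   ≥ 0.7 by default). Significant genes carry prizes |S|, edges cost
   1 − confidence, and the solver maximizes Σ p(v) − λ Σ c(e), optionally with
   a hub penalty μ·deg(v). Solution modules are clustered by modularity and
   annotated by ORA; hubs are ranked by a composite degree/betweenness score.
6. **Synthetic data** — a generator for multi-layer TMT-style experiments
   with planted differential genes, cross-layer concordance, batch/plex
   structure and plex-level missing-at-random dropout, so every stage can be
   validated against known ground truth.

## Worked example

```python
from omicweave.synth import SyntheticSpec, generate_multiomic
from omicweave import preprocess as pp, diffexp as de, sscore as ss

spec = SyntheticSpec(seed=42, n_genes=500, n_replicates=6, n_plexes=2)
datasets, annotation, truth = generate_multiomic(spec)

fits = {}
for ds in datasets:
    ds = pp.filter_flagged(ds)
    ds = pp.filter_missing(ds, 0.30)
    ds = pp.log_transform(ds)
    ds = pp.normalize(ds, "median")
    design = de.build_design(ds.sample_meta, ["group", "batch"])
    fits[ds.layer_name] = de.ebayes_moderate(
        de.fit_linear_model(ds, design, "groupgroupB")
    )

table = ss.integrate([ss.layer_stats(f, n) for n, f in fits.items()], alpha=0.05)
sig = ss.significant_genes(table)
planted = set(truth.differential_genes)
print(f"significant genes: {len(sig)} "
      f"(planted recovered: {len(set(sig) & planted)}/{len(planted)})")
print(table.table.loc[sig[:5],
      ["n_features", "sscore", "sscore_pval", "sscore_adj_pval"]])
```

Output:

```
significant genes: 37  (planted recovered: 37/50)
        n_features  sscore  sscore_pval  sscore_adj_pval
gene
G00160           4   -6.26      3.8e-10         1.88e-07
G00231           4    5.57     2.59e-08         6.42e-06
G00291           4   -5.36     8.43e-08         1.39e-05
G00029           4    5.18     2.23e-07         2.76e-05
G00395           3   -5.08     3.71e-07         3.67e-05
```

The 500-gene experiment plants a 1.0 log2 effect in 50 genes; integrating
the proteome with the multi-site phospho layer recovers 37 of them at
BH-adjusted p < 0.05. `n_features` counts the features backing each gene
across both layers (e.g. one protein plus three phosphosites), `sscore` is
the combined weighted z-statistic, and a negative value means concordant
down-regulation.

## Command line

```bash
omicweave simulate --profile tiny --seed 7 --out-dir fixtures/
omicweave run --config run.yaml --out-dir results/
omicweave summarize --out-dir results/
```

`run` chains preprocess → diffexp (per layer) → integrate → enrich → network
from one YAML config and writes stage folders (`Preprocess`, `DE_Results`,
`Integration`, `Enrichment`, `Network_Modules`) plus a machine-readable
`summary.json`, a run log and the resolved config. Individual stages are
also available as subcommands (`preprocess`, `diffexp`, `integrate`,
`enrich`, `network`).

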