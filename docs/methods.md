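# Methods

This note documents the statistical models, numerical conventions and
design decisions behind omicweave, plus what the synthetic-data validation
does and does not demonstrate.

## Data model

One omic layer is a feature-by-sample matrix of non-negative abundances or
log2 intensities with aligned feature metadata (gene symbol,
contaminant/decoy flags) and sample metadata (group, replicate, batch, TMT
plex, arbitrary covariates). Missing values are `NaN` throughout; exact
zeros in imported matrices are treated as missing by default, matching the
convention of TMT reporter exports where an unquantified channel is written
as 0 (configurable off). Sample matching between matrix and annotation is
by exact id string; a non-empty intersection is used with a logged warning,
an empty one is an error.

## Preprocessing and normalization

All normalization operates on log2 intensities; missing values are ignored
per column and preserved in place.

- **quantile** — rank-mean normalization. For complete tie-free columns
  every column receives the identical sorted reference (mean of per-column
  sorted values); columns with missing entries or ties are mapped through
  linear interpolation of the reference quantile function, the same scheme
  used by standard microarray implementations.
- **median** — columns shifted so every median equals the grand mean of
  column medians.
- **medianMAD** — affine per-column map to common median and common MAD.
  MAD is the raw median absolute deviation *without* the 1.4826 consistency
  constant, consistent with the "pooled median absolute deviation" reading
  of PMAD below.
- **loess** — cyclic loess on MA pairs over all column pairs, lowess span
  0.7, 3 cycles (parameter choices fixed here; span in the usual 0.3–0.8
  range matters little for the smooth intensity-dependent biases this
  corrects). Each pair's fitted M-trend is split evenly between the two
  columns.
- **ztransform** — per-column mean 0, sd 1 (sample sd, ddof 1 — as
  everywhere in the package).
- **irs** — internal reference scaling across TMT plexes: per plex a
  reference profile (mean log2 intensity of the reference samples, i.e. the
  geometric mean on raw scale) is shifted to the cross-plex average. With
  no explicit reference channels, all samples of a plex act as a pooled
  pseudo-reference.

**QC metrics.** For each group with ≥ 2 replicates, using features complete
within that group: PMAD = mean over features of the raw MAD across
replicates; PCV = mean of sd/|mean|; PEV = mean of the within-group
variance. The pooled value is the plain mean over eligible groups. These
formulas follow the metric names literally; implementations elsewhere may
differ in pooling details, so absolute values should not be compared across
tools — only the ranking of methods within one dataset, which is what the
selection uses. The **average silhouette width** is computed with Euclidean
distances between samples, by default in the top-2 PC space of the
complete-feature submatrix (group separation after dimension reduction);
singleton clusters score 0 and a(i) = b(i) = 0 scores 0. Method selection
ranks PMAD/PCV/PEV ascending and silhouette descending and recommends the
best rank sum (ties: method-list order).

**LLS imputation.** Each feature with missing cells is regressed (with
intercept) on its k = 10 most |Pearson|-correlated neighbor features that
are observed on all needed columns; missing cells get the prediction,
features without eligible neighbors fall back to the row mean. Observed
cells are never modified. For exactly collinear (rank-1) data one neighbor
reconstructs the missing value exactly, which the tests exploit as an
oracle.

## Differential analysis

Designs are treatment-coded with intercept: each factor contributes
indicator columns `<factor><level>` for non-reference levels (reference =
lexicographically first unless specified); numeric covariates enter
mean-centred. Rank deficiency is detected up front and reported with the
aliased column names.

Each feature is fitted by OLS on its observed samples (complete-case per
feature), so missingness reduces that feature's residual df instead of
forcing imputation. The residual variances s²_g with df d_g are shrunk
toward a scaled inverse-chi-square prior (d₀, s₀²) fitted across features
by moment matching on log s²_g: the excess of var(log s²_g) over the mean
trigamma(d_g/2) determines d₀ through the trigamma inverse (Newton
iteration, tolerance 1e-8, 50-iteration cap); non-positive excess gives
d₀ = ∞ with s₀² = mean(s²_g), so homogeneous variances collapse to their
common value. Posterior variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g);
the moderated t uses the contrast's unscaled variance and d₀ + d_g df
(normal when d₀ = ∞); p-values are two-sided always. Features with d_g = 0
keep their effect estimate but carry missing t/p and are excluded from
prior estimation, as are zero variances.

BH adjustment is the classic step-up with cumulative-minimum enforcement
and cap at 1; missing p-values pass through untouched. The robust
(winsorized) moderation variant and consensus intra-block correlation for
repeated measures are out of scope; batch enters the model as a fixed
covariate only. `remove_batch_effect` (sum-coded batch fitted jointly with
the protected design, batch part subtracted) exists for visualization; the
inference path keeps batch in the model.

## S-score integration

Within layer j: zᵢ = (logFCᵢ − μⱼ)/σⱼ with μⱼ, σⱼ the mean and sample sd of
the layer's finite logFCs, and wⱼ = uⱼ/√Nⱼ with Nⱼ the number of features
tested in that layer (the feature count, not the sample count — weighting
by dataset size is the reading under which layers of different breadth get
different weights). After a full join on gene symbols (case-sensitive,
no fuzzy matching), a gene's S-score is Σ wz / √(Σ w²) over *all* of its
contributing feature records: a gene measured by m phosphosites contributes
m terms to both sums, which preserves unit null variance (an optional
collapse mode keeps only the max-|z| feature per gene per layer).
User multipliers enter numerator and denominator alike, so rescaling all
uⱼ by a common constant leaves every S unchanged and null calibration holds
for any weights. Significance: p = 2Φ(−|S|), BH across all emitted genes,
default α = 0.05. Genes absent from a layer simply use the layers that
measured them.

Two properties worth knowing. First, σⱼ includes the planted/real effect
variance, so very strong signals mildly deflate everyone's z — the
statistic is designed for the regime where effects are sparse and modest.
Second, within-gene multiplicity both helps (concordant sites reinforce)
and dilutes (one strong site averaged with weak siblings); the collapse
mode trades one for the other.

## Enrichment

ORA uses the one-sided hypergeometric upper tail for the overlap between a
query and each set, both restricted to a stated universe (default: the
measured genes, not the genome), set sizes 3–500, BH across tested sets.
Preranked GSEA ranks genes by score descending (ties by gene id), hits
increment the running sum by |score|^exponent normalized to 1 (exponent 1
default, 0 supported), misses decrement uniformly; ES is the signed
extremum. The null permutes gene labels (the only choice compatible with a
gene-level score input); NES divides ES by the mean |null ES| of the same
sign and p is the add-one fraction among same-sign permutations (1000 by
default), making p exactly reproducible for a fixed seed and never zero.

## Prize-collecting Steiner forest

Edges of the confidence-filtered interaction network (combined score ≥ 0.7
by default; STRING 0–1000 scales auto-detected and divided by 1000) cost
c(e) = 1 − confidence, clamped to [1e-6, 1] so no edge is free — the
minimal monotone-decreasing cost in the confidence, configurable.
Significant genes present in the network are terminals with raw prize |S|
(prizes must be non-negative; the sign travels as a node attribute into the
GraphML export). The hub penalty subtracts μ·deg(v) (degree in the filtered
base network) from the raw prize, floored at 0. Defaults λ = 1, μ = 0, both
exposed.

The solution model: a forest with **at most one tree per connected
component of the base network** — within a component all selected nodes
must be joined, a singleton prized node being the degenerate tree. This is
the model under which the package's toy fixtures (two prized neighbors
joined at objective 9; an unprofitable neighbor left out at 5; a Steiner
bridge collected at 4) are the optima; without the one-tree rule any
solver would trivially keep every prized node as its own singleton and the
edge-cost trade-off would never bind.

The solver is exact on components of ≤ 12 nodes (enumeration of connected
induced subsets, minimum spanning tree per subset) and otherwise runs a
deterministic Prim-style heuristic: starting from each of the five
highest-prize terminals, repeatedly attach the terminal with the best
(prizes collected − λ·shortest-path cost) gain, then prune leaves whose
prize does not pay for their edge, and keep the best restart, never worse
than the best singleton. `brute_force_pcsf` exposes the exact enumeration
(≤ 15 nodes) as an independent oracle; on random ≤ 10-node instances the
greedy path alone matches the optimum in well over 80% of cases and never
drops below half of it in the validation suite.

Modules are extracted by greedy modularity maximization on the solution
subgraph (confidence-weighted) and annotated by ORA against the base
network's node set. Hub ranking averages min-max-normalized degree and
betweenness within the solution (ties by prize, then name) — a documented
stand-in for more elaborate influence metrics, whose parameters are not
standardized.

## Synthetic data: what it emulates, and what it does not

Log2 intensities are gene baseline N(20, 2) + per-feature layer offset +
group effect (differential genes only) + per-feature×batch offset
(sd 0.5) + per-sample loading shift (sd 0.3) + N(0, 0.4) replicate noise,
with batch ≡ TMT plex and samples spread group-balanced across plexes.
Missingness is plex-level missing-at-random: with probability 0.1 a feature
is unquantified in an entire plex (the dominant dropout mode of multiplexed
DDA data); an optional intensity-dependent component exists and is off by
default. Defaults: 10% differential genes at 1.0 log2 units, cross-layer
sign concordance 0.9, phospho layer 1–3 sites per gene, 2% contaminant rows.
Everything is reproducible from the spec seed.

The generator does *not* model peptide-level roll-up, isotopic
interference, ratio compression, or correlated noise between phosphosites
of one protein. Passing tests therefore demonstrate the statistics behave
as designed under their own assumptions (Gaussian log-scale noise,
independent features), not that any particular real dataset meets those
assumptions.

**Power study conditions.** The integration power experiment plants
per-layer effects of 0.4 × noise sd in 10% of genes, fully concordant
across a proteome (1 feature/gene) and a phospho layer (1–3 sites/gene),
in a 3000-gene, 32-replicates-per-group (4-plex) cohort. The size was set
by a pilot power calculation: the per-layer moderated t has noncentrality
0.4·√(n/2) ≈ 2.3, sitting just at the BH detection threshold for 3000
features, while a gene backed by m concordant features has S-noncentrality
larger by ≈ √m — enough for the integrated test to make consistently more
discoveries. A single-feature-per-layer variant was rejected at design
time: because σⱼ absorbs the planted-effect variance (σⱼ² ≈ se² + f·Δ²),
the attainable z saturates and the √2 two-layer gain barely moves the BH
count; the multi-site design is also the realistic one for phosphodata.

**PCSF recovery conditions.** Planted-module recovery wires 12 prized
(|S| ~ U(3, 8)) module genes at edge probability 0.6 and confidence
0.75–0.99 inside a 120-node background (edge probability 0.03, confidences
straddling the 0.7 cutoff), λ = 1.

## Numerical conventions and degenerate inputs

- Sample sd (ddof 1) everywhere; raw MAD without consistency constant.
- Ties break deterministically: method-list order (normalization
  selection), |logFC| then feature id (GSEA rank metric), score/gene-id
  (GSEA sort), prize then node name (hubs), lexicographic node names
  (solver and exports). Reruns are bit-identical for fixed seeds.
- p = 0 is clipped to 1e-300 before −log10 in the GSEA rank metric.
- Degenerate errors are raised early and named: all features flagged, no
  group with ≥ 2 replicates, a layer with zero logFC spread, all residual
  variances zero, no significant gene mapping into the network.

## Known limitations

- VSN normalization and the robust eBayes variant are not implemented.
- Batch is a fixed effect only; block-correlated designs (paired samples
  within plex) are approximated, not modelled.
- The FragPipe dialects preserve multi-site rows as given (no per-site
  collapse); ID harmonization is an offline two-column table, not a live
  database lookup.
- The PCSF heuristic carries no worst-case approximation proof; its
  quality claims are empirical, backed by the exhaustive oracle on small
  instances.
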