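"""Synthetic multi-omic data with known ground truth.

The generator emulates TMT-style multi-layer experiments: per-gene log2
baselines with layer offsets, group effects planted in a fraction of genes
(with controllable cross-layer sign concordance), per-feature batch/plex
offsets plus per-sample loading shifts, Gaussian replicate noise, and
plex-level missing-at-random dropout (a feature unquantified in a plex is
missing for every sample of that plex).  Contaminant rows are appended with
flagged ids.  Everything is reproducible from the spec seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    GeneSet,
    GeneSetCollection,
    InputError,
    InteractionNetwork,
    OmicsDataset,
    SampleAnnotation,
    build_network,
    make_feature_meta,
)

logger = logging.getLogger("omicweave")

__all__ = [
    "LayerSpec",
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_multiomic",
    "generate_network",
    "end_to_end_fixture",
]


@dataclass(frozen=True)
class LayerSpec:
    """Per-layer feature structure: how many features map to one gene."""

    name: str
    min_features_per_gene: int = 1
    max_features_per_gene: int = 1
    effect_scale: float = 1.0  # multiplies the planted effect in this layer


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic multi-omic experiment."""

    seed: int
    n_genes: int = 1000
    layers: tuple[LayerSpec, ...] = (
        LayerSpec("proteome", 1, 1),
        LayerSpec("phospho", 1, 3),
    )
    n_groups: int = 2
    n_replicates: int = 4
    n_plexes: int = 2
    baseline_mean: float = 20.0  # log2 intensity
    baseline_sd: float = 2.0
    noise_sd: float = 0.4  # log2 replicate noise
    batch_sd: float = 0.5  # per-feature x batch offsets
    sample_shift_sd: float = 0.3  # per-sample loading shift
    effect_frac: float = 0.10
    effect_size: float = 1.0  # log2 units
    concordance: float = 0.9  # P(same sign across layers)
    mar_rate: float = 0.10  # per (feature, plex) dropout probability
    intensity_dependent_missing: float = 0.0  # optional extra low-intensity dropout
    contaminant_frac: float = 0.02

    def __post_init__(self) -> None:
        for name in ("effect_frac", "concordance", "mar_rate", "contaminant_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if self.n_replicates < 1 or self.n_groups < 1:
            raise InputError("need >=1 group with >=1 replicate")
        if not np.isfinite(self.effect_size):
            raise InputError("effect size must be finite")


@dataclass
class SyntheticTruth:
    """Ground truth: planted genes and effects, batch offsets, dropout."""

    genes: pd.DataFrame  # index gene; is_differential + effect_<layer> columns
    feature_maps: dict[str, pd.DataFrame]  # layer -> (feature_id, gene)
    sample_table: pd.DataFrame  # group, replicate, batch, plex, sample_shift
    missing_fraction: dict[str, float]  # realised per layer
    spec: SyntheticSpec

    @property
    def differential_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_differential"]])


def generate_multiomic(
    spec: SyntheticSpec,
) -> tuple[list[OmicsDataset], SampleAnnotation, SyntheticTruth]:
    """Generate one multi-layer dataset, its annotation, and the truth record."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    groups = [f"group{chr(ord('A') + g)}" for g in range(spec.n_groups)]

    # samples: groups x replicates, spread over plexes round-robin so every
    # plex is group-balanced; batch == plex (dissection session == TMT run)
    sample_rows = []
    for gi, group in enumerate(groups):
        for r in range(spec.n_replicates):
            plex = f"plex{(r % spec.n_plexes) + 1}"
            sample_rows.append(
                {
                    "sample_id": f"{group}_r{r + 1}",
                    "group": group,
                    "replicate": f"r{r + 1}",
                    "batch": plex,
                    "plex": plex,
                }
            )
    sample_table = pd.DataFrame(sample_rows).set_index("sample_id")
    n_samples = len(sample_table)
    sample_table["sample_shift"] = rng.normal(0.0, spec.sample_shift_sd, n_samples)

    # planted effects: first fraction of genes differential, random sign,
    # per-layer sign flipped with prob 1 - concordance relative to layer 0
    n_diff = int(round(spec.effect_frac * spec.n_genes))
    is_diff = np.zeros(spec.n_genes, bool)
    diff_idx = rng.choice(spec.n_genes, size=n_diff, replace=False)
    is_diff[diff_idx] = True
    base_sign = rng.choice([-1.0, 1.0], size=spec.n_genes)
    truth_genes = pd.DataFrame({"is_differential": is_diff}, index=pd.Index(genes, name="gene"))

    baselines = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)
    group_codes = pd.Categorical(sample_table["group"], categories=groups).codes
    plex_levels = sorted(sample_table["plex"].unique())
    plex_codes = pd.Categorical(sample_table["plex"], categories=plex_levels).codes

    datasets = []
    feature_maps: dict[str, pd.DataFrame] = {}
    missing_real: dict[str, float] = {}
    for li, layer in enumerate(spec.layers):
        counts = rng.integers(
            layer.min_features_per_gene, layer.max_features_per_gene + 1, spec.n_genes
        )
        gene_of_feature = np.repeat(np.arange(spec.n_genes), counts)
        n_feat = gene_of_feature.size
        if layer.max_features_per_gene == 1:
            fids = [f"{layer.name[:1].upper()}_{genes[g]}" for g in gene_of_feature]
        else:
            site = np.concatenate([np.arange(c) for c in counts])
            fids = [
                f"{layer.name[:1].upper()}_{genes[g]}_S{s + 1}"
                for g, s in zip(gene_of_feature, site)
            ]
        layer_offset = rng.normal(0.0, 1.0, n_feat)  # per-feature abundance offset

        concordant = rng.random(spec.n_genes) < spec.concordance
        layer_sign = np.where(concordant | (li == 0), base_sign, -base_sign)
        effect = np.where(is_diff, layer_sign * spec.effect_size * layer.effect_scale, 0.0)
        truth_genes[f"effect_{layer.name}"] = effect

        batch_offsets = rng.normal(0.0, spec.batch_sd, (n_feat, len(plex_levels)))
        x = (
            baselines[gene_of_feature][:, None]
            + layer_offset[:, None]
            + np.where(group_codes[None, :] > 0, effect[gene_of_feature][:, None], 0.0)
            + batch_offsets[:, plex_codes]
            + sample_table["sample_shift"].to_numpy()[None, :]
            + rng.normal(0.0, spec.noise_sd, (n_feat, n_samples))
        )

        # plex-level MAR dropout
        drop = rng.random((n_feat, len(plex_levels))) < spec.mar_rate
        mask = drop[:, plex_codes]
        if spec.intensity_dependent_missing > 0:
            thresh = np.quantile(x, spec.intensity_dependent_missing)
            mask |= (x < thresh) & (rng.random(x.shape) < 0.5)
        x = np.where(mask, np.nan, x)
        missing_real[layer.name] = float(mask.mean())

        # contaminants: flagged rows with unrelated intensities
        n_con = int(round(spec.contaminant_frac * n_feat))
        if n_con:
            con_ids = [f"CON_{layer.name}_{i:04d}" for i in range(n_con)]
            con_x = rng.normal(spec.baseline_mean, spec.baseline_sd, (n_con, n_samples))
            x = np.vstack([x, con_x])
            fids = list(fids) + con_ids
        meta = make_feature_meta(
            fids, [genes[g] for g in gene_of_feature] + [f"CON{i}" for i in range(n_con)]
        )
        meta.loc[meta.index.str.startswith("CON_"), "is_contaminant"] = True

        values = 2.0 ** pd.DataFrame(x, index=meta.index, columns=sample_table.index)
        datasets.append(
            OmicsDataset(
                layer_name=layer.name,
                intensities=values,
                feature_meta=meta,
                sample_meta=sample_table.drop(columns="sample_shift").copy(),
                log_transformed=False,
            )
        )
        feature_maps[layer.name] = pd.DataFrame(
            {"feature_id": fids[: n_feat], "gene": [genes[g] for g in gene_of_feature]}
        )

    annotation = SampleAnnotation(sample_table.drop(columns="sample_shift").copy())
    truth = SyntheticTruth(
        genes=truth_genes,
        feature_maps=feature_maps,
        sample_table=sample_table,
        missing_fraction=missing_real,
        spec=spec,
    )
    return datasets, annotation, truth


def generate_network(
    background_genes: Sequence[str],
    planted_module: Sequence[str],
    p_background_edge: float = 0.02,
    p_module_edge: float = 0.9,
    module_confidence: tuple[float, float] = (0.75, 0.99),
    background_confidence: tuple[float, float] = (0.4, 0.95),
    n_module_anchors: int = 2,
    min_confidence: float = 0.7,
    seed: int = 0,
) -> tuple[InteractionNetwork, dict]:
    """Synthetic interaction network with a densely wired planted module.

    Module gene pairs are wired with probability ``p_module_edge`` at high
    confidence; background pairs sparsely with confidences straddling the
    cutoff so that filtering is exercised.  A few anchor edges tie the
    module into the background.  Returns the confidence-filtered network
    and a truth dict.
    """
    rng = np.random.default_rng(seed)
    module = sorted(set(planted_module))
    background = sorted(set(background_genes) - set(module))
    edges: list[tuple[str, str, float]] = []
    for i, a in enumerate(module):
        for b in module[i + 1:]:
            if rng.random() < p_module_edge:
                edges.append((a, b, float(rng.uniform(*module_confidence))))
    for i, a in enumerate(background):
        for b in background[i + 1:]:
            if rng.random() < p_background_edge:
                edges.append((a, b, float(rng.uniform(*background_confidence))))
    if module and background:
        anchors = rng.choice(len(module), size=min(n_module_anchors, len(module)), replace=False)
        targets = rng.choice(len(background), size=min(n_module_anchors, len(background)), replace=False)
        for ai, bi in zip(anchors, targets):
            edges.append((module[ai], background[bi], float(rng.uniform(*module_confidence))))
    net = build_network(edges, min_confidence=min_confidence)
    truth = {"module": module, "n_raw_edges": len(edges), "n_kept_edges": net.n_edges}
    return net, truth


PROFILES = {
    "tiny": dict(n_genes=200, n_replicates=3, n_plexes=1, mar_rate=0.05, contaminant_frac=0.02),
    "default": dict(n_genes=1200, n_replicates=4, n_plexes=2),
}


def end_to_end_fixture(profile: str = "tiny", seed: int = 7, out_dir: str | Path = "fixtures") -> Path:
    """Write a complete on-disk bundle: matrices, annotation, GMT, edges, truth.

    The bundle is sized so the full pipeline runs quickly on the ``tiny``
    profile; gene sets mix planted genes with decoys so enrichment has
    signal to find.
    """
    if profile not in PROFILES:
        raise InputError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = SyntheticSpec(seed=seed, **PROFILES[profile])
    datasets, annotation, truth = generate_multiomic(spec)

    from . import io as ow_io  # local import to avoid a cycle at module load

    for ds in datasets:
        ow_io.write_matrix(ds, out_dir / f"{ds.layer_name}.tsv")
        truth.feature_maps[ds.layer_name].to_csv(
            out_dir / f"{ds.layer_name}_idmap.tsv", sep="\t", index=False
        )
    annot_out = annotation.table.reset_index()
    annot_out.to_csv(out_dir / "annotation.tsv", sep="\t", index=False)

    rng = np.random.default_rng(spec.seed + 1)
    diff = truth.differential_genes
    all_genes = list(truth.genes.index)
    collection = GeneSetCollection()
    planted_members = diff[: max(5, len(diff) // 2)]
    collection.add(GeneSet("planted_response", "genes with planted effects", tuple(planted_members)))
    for k in range(8):
        members = tuple(rng.choice(all_genes, size=15, replace=False))
        collection.add(GeneSet(f"decoy_set_{k}", "random decoy", members))
    ow_io.write_gmt(collection, out_dir / "sets.gmt")

    module = diff[: min(12, len(diff))]
    background = [g for g in all_genes if g not in set(module)][:80]
    net, net_truth = generate_network(background, module, seed=spec.seed + 2)
    ow_io.write_edge_list(net, out_dir / "edges.tsv")

    with open(out_dir / "truth.json", "w") as fh:
        json.dump(
            {
                "profile": profile,
                "seed": seed,
                "n_genes": spec.n_genes,
                "differential_genes": diff,
                "network_module": net_truth["module"],
                "missing_fraction": truth.missing_fraction,
            },
            fh,
            indent=2,
        )
    truth.genes.reset_index().to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)
    logger.info("fixture bundle (%s profile) written to %s", profile, out_dir)
    return out_dir
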