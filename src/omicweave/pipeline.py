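"""Non-interactive pipeline: preprocess -> diffexp -> integrate -> enrich -> network.

A single :class:`RunConfig` (serialisable to YAML) drives the whole run;
outputs land in stage folders (``Preprocess``, ``DE_Results``,
``Integration``, ``Enrichment``, ``Network_Modules``) beside a resolved
config copy, a machine-readable ``summary.json`` and a plain-text run log.
Any stage failure halts with the stage name and cause; partial outputs are
retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import diffexp as de
from . import enrich as en
from . import io as ow_io
from . import network as nw
from . import preprocess as pp
from . import sscore as ss

logger = logging.getLogger("omicweave")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize_run"]


@dataclass
class LayerConfig:
    name: str
    matrix: str
    dialect: str = "generic"
    weight: float = 1.0
    id_mapping: str | None = None  # 2-column feature_id -> gene_symbol table


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    annotation: str
    layers: list[LayerConfig]
    gmt: str | None = None
    edges: str | None = None
    max_missing_frac: float = 0.30
    normalize: str = "auto"  # method name or "auto" for QC-driven selection
    impute: str = "none"  # "lls" or "none"
    factors: list[str] = field(default_factory=lambda: ["group"])
    covariates: list[str] = field(default_factory=list)
    reference_levels: dict[str, str] = field(default_factory=dict)
    contrast: str | None = None  # coefficient name; default: first factor coefficient
    alpha: float = 0.05
    min_confidence: float = 0.7
    lam: float = 1.0
    mu: float = 0.0
    seed: int = 0
    gsea_n_perm: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        layers = [LayerConfig(**layer) for layer in data.pop("layers")]
        return cls(layers=layers, **data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full workflow; returns the output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "stages": {}}
    config.to_yaml(out_dir / "resolved_config.yaml")
    try:
        logger.info("pipeline start (version %s)", __version__)
        annotation = ow_io.read_annotation(config.annotation)

        # ---- preprocess -------------------------------------------------
        stage = "preprocess"
        try:
            pre_dir = out_dir / "Preprocess"
            pre_dir.mkdir(exist_ok=True)
            processed = {}
            stage_info: dict = {}
            for layer in config.layers:
                ds = ow_io.read_matrix(
                    layer.matrix, dialect=layer.dialect, annotation=annotation,
                    layer_name=layer.name,
                )
                if layer.id_mapping:
                    mapping = pd.read_csv(layer.id_mapping, sep="\t")
                    ds = ow_io.map_ids(ds, mapping)
                n_raw = ds.n_features
                ds = pp.filter_flagged(ds)
                ds = pp.filter_missing(ds, config.max_missing_frac)
                ds = pp.log_transform(ds)
                if config.normalize == "auto":
                    report = pp.evaluate_normalizations(ds)
                    method = report.recommended
                    report.table.to_csv(pre_dir / f"{layer.name}_normalization_report.tsv", sep="\t")
                else:
                    method = config.normalize
                ds = pp.normalize(ds, method) if method != "none" else ds
                if config.impute == "lls":
                    ds = pp.impute_lls(ds)
                ow_io.write_matrix(ds, pre_dir / f"{layer.name}_normalized.tsv")
                processed[layer.name] = ds
                stage_info[layer.name] = {
                    "n_features_raw": n_raw,
                    "n_features_kept": ds.n_features,
                    "normalization": method,
                }
            summary["stages"][stage] = stage_info
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

        # ---- diffexp ----------------------------------------------------
        stage = "diffexp"
        try:
            de_dir = out_dir / "DE_Results"
            de_dir.mkdir(exist_ok=True)
            results = {}
            stage_info = {}
            for layer in config.layers:
                ds = processed[layer.name]
                design = de.build_design(
                    ds.sample_meta, config.factors, config.covariates, config.reference_levels
                )
                contrast_name = config.contrast or design.coef_names[1]
                fit = de.fit_linear_model(ds, design, contrast_name)
                fit = de.ebayes_moderate(fit)
                fit.to_frame().to_csv(de_dir / f"{layer.name}.tsv", sep="\t", index=False)
                results[layer.name] = fit
                n_sig = int((fit.table["adj.P.Val"] < config.alpha).sum())
                stage_info[layer.name] = {
                    "contrast": contrast_name,
                    "n_significant": n_sig,
                    "d0": float(fit.d0) if fit.d0 is not None else None,
                }
            summary["stages"][stage] = stage_info
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

        # ---- integrate --------------------------------------------------
        stage = "integrate"
        try:
            int_dir = out_dir / "Integration"
            int_dir.mkdir(exist_ok=True)
            layer_stats = [
                ss.layer_stats(results[layer.name], layer.name, layer.weight)
                for layer in config.layers
            ]
            table = ss.integrate(layer_stats, alpha=config.alpha)
            table.table.to_csv(int_dir / "sscores.tsv", sep="\t")
            sig = ss.significant_genes(table)
            summary["stages"][stage] = {
                "n_genes": int(len(table.table)),
                "n_significant": len(sig),
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

        # ---- enrich -----------------------------------------------------
        stage = "enrich"
        if config.gmt:
            try:
                enr_dir = out_dir / "Enrichment"
                enr_dir.mkdir(exist_ok=True)
                sets = ow_io.read_gmt(config.gmt)
                universe = [str(g) for g in table.table.index]
                stage_info = {}
                if sig:
                    res = en.ora(sig, universe, sets)
                    res.table.to_csv(enr_dir / "ora.tsv", sep="\t", index=False)
                    stage_info["ora_sets_tested"] = int(len(res.table))
                ranks = ss_rank_series(table)
                gres = en.gsea_preranked(
                    ranks, sets, n_perm=config.gsea_n_perm, seed=config.seed
                )
                gres.table.to_csv(enr_dir / "gsea.tsv", sep="\t", index=False)
                stage_info["gsea_sets_tested"] = int(len(gres.table))
                summary["stages"][stage] = stage_info
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(stage, exc) from exc

        # ---- network ----------------------------------------------------
        stage = "network"
        if config.edges:
            try:
                net_dir = out_dir / "Network_Modules"
                net_dir.mkdir(exist_ok=True)
                net = ow_io.read_edge_list(config.edges, min_confidence=config.min_confidence)
                net = nw.edge_costs(net)
                prizes = nw.assign_prizes(net, table, alpha=config.alpha, mu=config.mu)
                sol = nw.solve_pcsf(net, prizes, lam=config.lam)
                ow_io.write_network(sol, net_dir / "subnetwork.sif", format="sif")
                ow_io.write_network(sol, net_dir / "subnetwork.graphml", format="graphml")
                stage_info = {
                    "n_nodes": len(sol.nodes),
                    "n_edges": len(sol.edges),
                    "objective": sol.objective,
                }
                if len(sol.nodes) >= 2:
                    clusters = nw.cluster_solution(sol)
                    pd.Series(clusters, name="cluster").rename_axis("gene").to_csv(
                        net_dir / "clusters.tsv", sep="\t"
                    )
                    stage_info["n_clusters"] = len(set(clusters.values()))
                    if config.gmt:
                        _, cl_summary = en.enrich_clusters(clusters, universe, sets)
                        cl_summary.to_csv(net_dir / "cluster_enrichment.tsv", sep="\t", index=False)
                if len(sol.nodes) >= 3:
                    nw.rank_hubs(sol).to_csv(net_dir / "hubs.tsv", sep="\t", index=False)
                summary["stages"][stage] = stage_info
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(stage, exc) from exc

        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        logger.info("pipeline finished: %s", out_dir)
        return out_dir
    finally:
        logger.removeHandler(handler)
        handler.close()


def ss_rank_series(table: ss.SScoreTable) -> pd.Series:
    """Gene -> S-score series usable as a preranked GSEA input."""
    return pd.Series(
        table.table["sscore"].to_numpy(), index=[str(g) for g in table.table.index]
    )


def summarize_run(out_dir: str | Path) -> dict:
    """Aggregate per-stage counts from a (possibly partial) run directory."""
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise FileNotFoundError(f"no run directory at {out_dir}")
    summary: dict = {"output_dir": str(out_dir), "stages": {}}
    stage_files = {
        "preprocess": sorted((out_dir / "Preprocess").glob("*_normalized.tsv")),
        "diffexp": sorted((out_dir / "DE_Results").glob("*.tsv")),
        "integrate": sorted((out_dir / "Integration").glob("sscores.tsv")),
        "enrich": sorted((out_dir / "Enrichment").glob("*.tsv")),
        "network": sorted((out_dir / "Network_Modules").glob("*.tsv")),
    }
    for stage, files in stage_files.items():
        if not files:
            summary["stages"][stage] = {"present": False}
            continue
        info: dict = {"present": True, "files": {}}
        for f in files:
            n_rows = sum(1 for _ in open(f)) - 1  # minus header
            info["files"][f.name] = n_rows
        summary["stages"][stage] = info
    md_lines = [f"# Run summary: {out_dir.name}", ""]
    for stage, info in summary["stages"].items():
        if not info.get("present"):
            md_lines.append(f"- {stage}: absent")
        else:
            counts = ", ".join(f"{k}: {v} rows" for k, v in info["files"].items())
            md_lines.append(f"- {stage}: {counts}")
    (out_dir / "summary.md").write_text("\n".join(md_lines) + "\n")
    return summary
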