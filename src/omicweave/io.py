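"""Readers and writers for the external formats the pipeline touches.

Supported inputs: generic feature-by-sample matrices (TSV/CSV), the FragPipe
TMT-report dialects (protein / multi-site abundance tables), sample
annotation tables, GMT gene-set collections, and 3-column interaction edge
lists (optionally on the STRING 0-1000 combined-score scale).  Outputs:
generic matrices, SIF and GraphML network exports, and a plain edge table
with confidences.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    FormatError,
    GeneSet,
    GeneSetCollection,
    InputError,
    InteractionNetwork,
    OmicsDataset,
    SampleAnnotation,
    build_network,
    make_feature_meta,
)

if TYPE_CHECKING:  # pragma: no cover
    from .network import PCSFSolution

logger = logging.getLogger("omicweave")

__all__ = [
    "read_annotation",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "write_network",
    "map_ids",
]

#: default id prefixes flagging decoy/contaminant rows
DEFAULT_CONTAMINANT_PATTERNS = (r"^CON_", r"^contam_")
DEFAULT_REVERSE_PATTERNS = (r"^rev_", r"^REV_")

#: FragPipe tmt-report column conventions
FRAGPIPE_DEFAULTS = {
    "fragpipe_protein": {"id_column": "Index", "gene_column": "Gene"},
    "fragpipe_multisite": {"id_column": "Index", "gene_column": "Gene"},
}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a sample annotation table (TSV/CSV) into a :class:`SampleAnnotation`."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path))
    return SampleAnnotation.from_frame(frame)


def read_matrix(
    path: str | Path,
    dialect: str = "generic",
    annotation: SampleAnnotation | None = None,
    *,
    layer_name: str | None = None,
    zero_as_missing: bool = True,
    id_column: str | None = None,
    gene_column: str | None = None,
    contaminant_patterns: Sequence[str] = DEFAULT_CONTAMINANT_PATTERNS,
    reverse_patterns: Sequence[str] = DEFAULT_REVERSE_PATTERNS,
) -> OmicsDataset:
    """Read an intensity matrix into an :class:`OmicsDataset`.

    Parameters
    ----------
    dialect
        ``"generic"`` (first column holds feature ids, remaining columns are
        samples) or the FragPipe TMT-report dialects ``"fragpipe_protein"`` /
        ``"fragpipe_multisite"`` (configurable index and gene columns, other
        non-sample metadata columns are ignored).
    annotation
        Sample annotation; matrix columns are intersected with its sample
        ids.  Samples present on only one side are logged, an empty
        intersection is an error.
    zero_as_missing
        Treat exact zeros as missing (the TMT reporter-export convention).
    """
    path = Path(path)
    if dialect not in ("generic", "fragpipe_protein", "fragpipe_multisite"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: matrix needs an id column plus >=1 sample column")

    if dialect == "generic":
        id_col = id_column or raw.columns[0]
        gene_col = gene_column
    else:
        defaults = FRAGPIPE_DEFAULTS[dialect]
        id_col = id_column or defaults["id_column"]
        gene_col = gene_column or defaults["gene_column"]
    if id_col not in raw.columns:
        raise FormatError(f"{path}: missing required id column {id_col!r}")
    if gene_col is not None and gene_col not in raw.columns:
        raise FormatError(f"{path}: missing gene column {gene_col!r}")

    feature_ids = raw[id_col].astype(str)
    dup = feature_ids[feature_ids.duplicated()]
    if len(dup):
        raise InputError(f"{path}: duplicate feature ids: {sorted(set(dup))[:10]}")

    meta_cols = {id_col} | ({gene_col} if gene_col else set())
    value_cols = [c for c in raw.columns if c not in meta_cols]

    if annotation is not None:
        wanted = [s for s in annotation.sample_ids if s in value_cols]
        extra_matrix = [c for c in value_cols if c not in set(annotation.sample_ids)]
        extra_annot = [s for s in annotation.sample_ids if s not in set(value_cols)]
        if not wanted:
            raise InputError(
                f"{path}: no overlap between matrix columns and annotation sample ids"
            )
        if extra_annot:
            logger.warning(
                "%s: %d annotated sample(s) absent from matrix: %s",
                path.name, len(extra_annot), extra_annot,
            )
        if extra_matrix and dialect == "generic":
            logger.warning(
                "%s: %d matrix column(s) not in annotation dropped: %s",
                path.name, len(extra_matrix), extra_matrix,
            )
        value_cols = wanted
        sample_meta = annotation.subset(wanted).table
    else:
        sample_meta = pd.DataFrame({"group": ""}, index=pd.Index(value_cols, name="sample_id"))

    values = raw[value_cols].apply(pd.to_numeric, errors="coerce")
    values.index = pd.Index(feature_ids, name="feature_id")
    if zero_as_missing:
        values = values.mask(values == 0.0)

    meta = make_feature_meta(feature_ids)
    if gene_col is not None:
        genes = raw[gene_col].astype(str).str.strip()
        fallback = genes.isin(("", "nan", "NA"))
        meta["gene_symbol"] = np.where(fallback, feature_ids, genes)
    con_re = re.compile("|".join(contaminant_patterns))
    rev_re = re.compile("|".join(reverse_patterns))
    meta["is_contaminant"] = [bool(con_re.search(f)) for f in feature_ids]
    meta["is_reverse"] = [bool(rev_re.search(f)) for f in feature_ids]

    return OmicsDataset(
        layer_name=layer_name or path.stem,
        intensities=values,
        feature_meta=meta,
        sample_meta=sample_meta,
        log_transformed=False,
    )


def write_matrix(ds: OmicsDataset, path: str | Path) -> Path:
    """Write a generic matrix (feature ids in the first column, NaN as empty)."""
    path = Path(path)
    out = ds.intensities.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep=_sep_for(path), na_rep="")
    return path


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, member genes...)."""
    path = Path(path)
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >=3")
            name, description, *members = fields
            members = [m for m in members if m.strip()]
            collection.add(GeneSet(name, description, tuple(members)))
    if len(collection) == 0:
        raise FormatError(f"{path}: no gene sets found")
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")
    return path


def read_edge_list(
    path: str | Path,
    score_scale: str = "auto",
    min_confidence: float = 0.7,
) -> InteractionNetwork:
    """Read a 3-column edge list (nodeA, nodeB, score) into a network.

    ``score_scale``: ``"unit"`` (scores already in [0, 1]), ``"string1000"``
    (STRING combined scores in [0, 1000], divided by 1000), or ``"auto"``
    (string1000 assumed when any score exceeds 1).  Edges below
    ``min_confidence`` are dropped; duplicates keep the maximum confidence.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#", dtype=str)
    if table.shape[1] < 3:
        raise FormatError(f"{path}: edge list needs 3 columns (nodeA, nodeB, score)")
    # tolerate a header row
    first_score = pd.to_numeric(table.iloc[0, 2], errors="coerce")
    if np.isnan(first_score):
        table = table.iloc[1:]
        if table.empty:
            raise FormatError(f"{path}: edge list has no data rows")
    scores = pd.to_numeric(table.iloc[:, 2], errors="raise").to_numpy(float)
    if score_scale == "auto":
        score_scale = "string1000" if np.nanmax(scores) > 1.0 else "unit"
    if score_scale == "string1000":
        if np.any(scores < 0) or np.any(scores > 1000):
            raise FormatError(f"{path}: scores outside [0, 1000] on string1000 scale")
        scores = scores / 1000.0
    elif score_scale == "unit":
        if np.any(scores < 0) or np.any(scores > 1):
            raise FormatError(f"{path}: scores outside [0, 1] on unit scale")
    else:
        raise ValueError(f"unknown score_scale {score_scale!r}")
    edges = list(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str), scores))
    net = build_network(edges, min_confidence=min_confidence)
    logger.info(
        "%s: %d edges read, %d retained at confidence >= %.2f",
        path.name, len(edges), net.n_edges, min_confidence,
    )
    return net


def write_edge_list(net: InteractionNetwork, path: str | Path) -> Path:
    """Write the 3-column (nodeA, nodeB, confidence) table; re-readable."""
    path = Path(path)
    with open(path, "w") as fh:
        for u, v, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['confidence']:.6g}\n")
    return path


def write_network(solution: "PCSFSolution", path: str | Path, format: str = "sif") -> Path:
    """Export a PCSF solution as SIF or GraphML (Cytoscape-importable).

    SIF writes one ``A<TAB>interacts<TAB>B`` line per edge and a bare
    node-id line for isolated prized nodes.  GraphML carries node attributes
    (``prize``, ``sscore``, ``terminal``) and edge attributes (``cost``,
    ``confidence``).
    """
    path = Path(path)
    g = solution.graph
    if format == "sif":
        with open(path, "w") as fh:
            seen: set[str] = set()
            for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
                fh.write(f"{u}\tinteracts\t{v}\n")
                seen.update((u, v))
            for node in sorted(g.nodes()):
                if node not in seen:
                    fh.write(f"{node}\n")
        return path
    if format == "graphml":
        out = nx.Graph()
        for node, d in g.nodes(data=True):
            out.add_node(
                node,
                prize=float(d.get("prize", 0.0)),
                sscore=float(d.get("sscore", 0.0)),
                terminal=bool(d.get("terminal", False)),
            )
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, cost=float(d.get("cost", 0.0)), confidence=float(d.get("confidence", 0.0)))
        nx.write_graphml(out, path)
        return path
    raise ValueError(f"unknown network format {format!r}")


def map_ids(ds: OmicsDataset, mapping: pd.DataFrame | dict[str, str]) -> OmicsDataset:
    """Fill ``gene_symbol`` from a feature_id -> gene_symbol mapping table.

    Unmapped features keep their feature id as symbol; the count is logged.
    """
    if isinstance(mapping, pd.DataFrame):
        if mapping.shape[1] < 2:
            raise FormatError("mapping table needs 2 columns (feature_id, gene_symbol)")
        keys = mapping.iloc[:, 0].astype(str)
        if keys.duplicated().any():
            raise InputError("mapping table has duplicate feature_id keys")
        mapping = dict(zip(keys, mapping.iloc[:, 1].astype(str)))
    out = ds.copy()
    symbols = []
    unmapped = 0
    for fid in out.feature_ids:
        sym = mapping.get(fid)
        if sym is None or not str(sym).strip():
            symbols.append(fid)
            unmapped += 1
        else:
            symbols.append(str(sym))
    out.feature_meta["gene_symbol"] = symbols
    if unmapped:
        logger.info(
            "layer %s: %d/%d features unmapped, feature id kept as symbol",
            out.layer_name, unmapped, out.n_features,
        )
    return out
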