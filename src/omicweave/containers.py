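"""Core in-memory containers shared across the pipeline.

A single omic layer is held as an :class:`OmicsDataset`: a feature-by-sample
intensity matrix (``NaN`` marks missing values) plus aligned feature- and
sample-level metadata tables.  Gene sets and interaction networks get thin
wrappers around a ``dict`` and a :class:`networkx.Graph` respectively so that
loaders can validate invariants once and downstream code can rely on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("omicweave")

__all__ = [
    "OmicsDataset",
    "SampleAnnotation",
    "GeneSet",
    "GeneSetCollection",
    "InteractionNetwork",
    "InputError",
    "FormatError",
]


class InputError(ValueError):
    """Semantically invalid input (empty intersection, duplicates, ...)."""


class FormatError(ValueError):
    """Malformed file or table."""


FEATURE_META_COLUMNS = ("gene_symbol", "is_contaminant", "is_reverse", "annotation")


@dataclass
class OmicsDataset:
    """One omic layer: intensities plus feature and sample metadata.

    Parameters
    ----------
    layer_name
        Short label such as ``"proteome"`` or ``"phospho"``.
    intensities
        Feature-by-sample matrix, indexed by ``feature_id`` with sample ids
        as columns.  ``NaN`` encodes a missing measurement.
    feature_meta
        Indexed by ``feature_id``; carries at least ``gene_symbol``,
        ``is_contaminant``, ``is_reverse`` and free-text ``annotation``.
    sample_meta
        Indexed by ``sample_id``; carries ``group`` and optionally
        ``replicate``, ``batch``, ``plex`` and arbitrary covariates.
    log_transformed
        Whether intensities are already on log scale.
    """

    layer_name: str
    intensities: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.intensities = self.intensities.astype(float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if len(self.feature_meta) != self.intensities.shape[0]:
            raise InputError(
                f"layer {self.layer_name!r}: {len(self.feature_meta)} feature "
                f"records for {self.intensities.shape[0]} matrix rows"
            )
        if len(self.sample_meta) != self.intensities.shape[1]:
            raise InputError(
                f"layer {self.layer_name!r}: {len(self.sample_meta)} sample "
                f"records for {self.intensities.shape[1]} matrix columns"
            )
        if not self.feature_meta.index.equals(self.intensities.index):
            raise InputError("feature_meta index does not match matrix rows")
        if not self.sample_meta.index.equals(self.intensities.columns):
            raise InputError("sample_meta index does not match matrix columns")
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()]
            raise InputError(f"duplicate feature ids: {sorted(set(dups))}")
        if self.intensities.columns.has_duplicates:
            raise InputError("duplicate sample ids")
        for col in FEATURE_META_COLUMNS:
            if col not in self.feature_meta.columns:
                raise InputError(f"feature_meta misses column {col!r}")
        if "group" not in self.sample_meta.columns:
            raise InputError("sample_meta misses column 'group'")

    # -- conveniences ----------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing samples."""
        return self.intensities.isna().mean(axis=1)

    def copy(self) -> "OmicsDataset":
        return OmicsDataset(
            layer_name=self.layer_name,
            intensities=self.intensities.copy(),
            feature_meta=self.feature_meta.copy(),
            sample_meta=self.sample_meta.copy(),
            log_transformed=self.log_transformed,
        )

    def with_matrix(self, matrix: pd.DataFrame, *, log_transformed: bool | None = None) -> "OmicsDataset":
        """Return a copy with a replaced intensity matrix (same shape/labels)."""
        return OmicsDataset(
            layer_name=self.layer_name,
            intensities=matrix,
            feature_meta=self.feature_meta.copy(),
            sample_meta=self.sample_meta.copy(),
            log_transformed=self.log_transformed if log_transformed is None else log_transformed,
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsDataset":
        idx = pd.Index(feature_ids)
        return OmicsDataset(
            layer_name=self.layer_name,
            intensities=self.intensities.loc[idx],
            feature_meta=self.feature_meta.loc[idx],
            sample_meta=self.sample_meta.copy(),
            log_transformed=self.log_transformed,
        )


def make_feature_meta(feature_ids: Sequence[str], gene_symbols: Sequence[str] | None = None) -> pd.DataFrame:
    """Default feature metadata with all flags off."""
    index = pd.Index(feature_ids, name="feature_id")
    return pd.DataFrame(
        {
            "gene_symbol": list(gene_symbols) if gene_symbols is not None else list(feature_ids),
            "is_contaminant": False,
            "is_reverse": False,
            "annotation": "",
        },
        index=index,
    )


@dataclass
class SampleAnnotation:
    """Sample annotation table keyed by sample id.

    The table must contain a ``group`` column; ``replicate``, ``batch`` and
    ``plex`` are recognised when present and every further column is carried
    along as a user covariate.
    """

    table: pd.DataFrame

    # column aliases seen in the wild (FragPipe-style annotation files)
    SAMPLE_ALIASES = ("sample", "sample_id", "channel", "sample_name")
    GROUP_ALIASES = ("group", "treatment", "condition")
    REPLICATE_ALIASES = ("replicate", "rep")
    BATCH_ALIASES = ("batch", "session")
    PLEX_ALIASES = ("plex", "tmt_plex", "plex_id")

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name is None:
            t.index.name = "sample_id"
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()]
            raise InputError(f"duplicate sample ids in annotation: {sorted(set(dups))}")
        if "group" not in t.columns:
            raise InputError("annotation misses a 'group' column")
        if t["group"].isna().any() or (t["group"].astype(str) == "").any():
            raise InputError("annotation 'group' column has empty entries")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleAnnotation":
        """Normalise alias column names and set the sample-id index."""
        frame = frame.copy()
        lower = {c.lower(): c for c in frame.columns}

        def pick(aliases: tuple[str, ...]) -> str | None:
            for a in aliases:
                if a in lower:
                    return lower[a]
            return None

        # canonical columns are added as copies; the original user column
        # names stay available as factors/covariates
        for canonical, aliases in (
            ("group", cls.GROUP_ALIASES),
            ("replicate", cls.REPLICATE_ALIASES),
            ("batch", cls.BATCH_ALIASES),
            ("plex", cls.PLEX_ALIASES),
        ):
            col = pick(aliases)
            if col is not None and canonical not in frame.columns:
                frame[canonical] = frame[col]

        sample_col = pick(cls.SAMPLE_ALIASES)
        if sample_col is None:
            raise FormatError(
                "annotation needs a sample-id column (one of "
                f"{', '.join(cls.SAMPLE_ALIASES)})"
            )
        frame[sample_col] = frame[sample_col].astype(str)
        frame = frame.set_index(sample_col)
        frame.index.name = "sample_id"
        return cls(frame)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, sample_ids: Sequence[str]) -> "SampleAnnotation":
        return SampleAnnotation(self.table.loc[pd.Index(sample_ids)].copy())


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            # dedup while keeping order
            seen: dict[str, None] = {}
            for m in self.members:
                seen.setdefault(m, None)
            object.__setattr__(self, "members", tuple(seen))
        if not self.members:
            raise InputError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Mapping from set name to :class:`GeneSet`."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, gene_set: GeneSet) -> None:
        self.sets[gene_set.name] = gene_set

    def restricted(self, universe: Sequence[str], min_size: int = 1, max_size: int | None = None) -> "GeneSetCollection":
        """Restrict members to ``universe`` and drop sets outside size bounds."""
        uni = set(universe)
        out = GeneSetCollection()
        for gs in self:
            members = tuple(m for m in gs.members if m in uni)
            if len(members) < min_size:
                continue
            if max_size is not None and len(members) > max_size:
                continue
            out.add(GeneSet(gs.name, gs.description, members))
        return out


@dataclass
class InteractionNetwork:
    """Undirected simple interaction graph with per-edge confidence in [0, 1].

    Edge attributes: ``confidence`` (always) and ``cost`` (after
    :func:`omicweave.network.edge_costs`).
    """

    graph: nx.Graph
    min_confidence: float = 0.0

    def __post_init__(self) -> None:
        g = self.graph
        loops = list(nx.selfloop_edges(g))
        if loops:
            g.remove_edges_from(loops)
        for u, v, d in g.edges(data=True):
            conf = d.get("confidence")
            if conf is None or not (0.0 <= conf <= 1.0):
                raise InputError(f"edge {u}-{v} has invalid confidence {conf!r}")
            if conf < self.min_confidence - 1e-12:
                raise InputError(
                    f"edge {u}-{v} confidence {conf} below cutoff {self.min_confidence}"
                )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.copy(), self.min_confidence)


def build_network(
    edges: Mapping[tuple[str, str], float] | Sequence[tuple[str, str, float]],
    min_confidence: float = 0.0,
) -> InteractionNetwork:
    """Build a simple undirected network, keeping max confidence on duplicates."""
    g = nx.Graph()
    items = edges.items() if isinstance(edges, Mapping) else ((a, b, c) for a, b, c in edges)
    if isinstance(edges, Mapping):
        items = (((a, b), c) for (a, b), c in edges.items())
        for (a, b), conf in items:
            _add_edge(g, a, b, conf)
    else:
        for a, b, conf in edges:
            _add_edge(g, a, b, conf)
    drop = [(u, v) for u, v, d in g.edges(data=True) if d["confidence"] < min_confidence]
    g.remove_edges_from(drop)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return InteractionNetwork(g, min_confidence)


def _add_edge(g: nx.Graph, a: str, b: str, conf: float) -> None:
    if a == b:
        return
    if g.has_edge(a, b):
        g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
    else:
        g.add_edge(a, b, confidence=float(conf))
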