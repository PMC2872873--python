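"""Readers, writers and preprocessing for networks, expression matrices and gene sets.

Networks are plain :class:`networkx.Graph` objects over gene-identifier strings,
with co-expression weights stored in the ``"weight"`` edge attribute. Expression
data lives in :class:`ExpressionDataset`, a thin container around a gene x sample
:class:`pandas.DataFrame` plus per-sample ages. Gene identifiers are treated as
case-sensitive opaque strings; no symbol aliasing is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "read_network",
    "write_network",
    "read_expression",
    "filter_missing",
    "normalize",
    "restrict_to_universe",
    "read_gene_sets",
]


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with per-sample numeric ages.

    Parameters
    ----------
    values : DataFrame of shape (n_genes, n_samples)
        Expression values; NaN marks missing cells.
    ages : Series indexed by sample id
        Numeric age per sample (e.g. days), aligned with ``values.columns``.
    mask : DataFrame of bool, optional
        Missing-value mask; defaults to ``values.isna()``.
    """

    values: pd.DataFrame
    ages: pd.Series
    mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.values.isna()
        if len(self.ages) != self.values.shape[1]:
            raise ValueError(
                f"ages has {len(self.ages)} entries but matrix has "
                f"{self.values.shape[1]} samples"
            )
        if not (self.ages.index == self.values.columns).all():
            raise ValueError("ages index must match matrix columns in order")
        if np.unique(self.ages.to_numpy()).size < 2:
            raise ValueError("at least 2 distinct ages are required")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionDataset":
        genes = [g for g in self.genes if g in set(genes)]
        return ExpressionDataset(
            self.values.loc[genes], self.ages, self.mask.loc[genes]
        )

    def subset_samples(self, samples) -> "ExpressionDataset":
        samples = list(samples)
        return ExpressionDataset(
            self.values[samples], self.ages[samples], self.mask[samples]
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with optional per-set descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def restrict(self, universe) -> "GeneSetCollection":
        """Intersect every set with *universe*, dropping emptied sets with a warning."""
        universe = set(universe)
        kept, desc, dropped = {}, {}, []
        for name, members in self.sets.items():
            inter = frozenset(members & universe)
            if inter:
                kept[name] = inter
                if name in self.descriptions:
                    desc[name] = self.descriptions[name]
            else:
                dropped.append(name)
        if dropped:
            warnings.warn(
                f"{len(dropped)} gene set(s) empty after intersection with "
                f"universe and dropped: {sorted(dropped)[:5]}..."
            )
        return GeneSetCollection(kept, desc)


def read_network(path, format: str | None = None) -> nx.Graph:
    """Read an undirected gene network from a TSV edge list or GraphML file.

    Edge-list rows are ``gene_a<TAB>gene_b[<TAB>weight]``; ``#`` comment lines
    are skipped. Reverse-orientation duplicates are merged (first weight wins)
    and self-loop rows are skipped with a single summary warning.
    """
    path = str(path)
    if format is None:
        format = "graphml" if path.endswith((".graphml", ".xml")) else "edge_list"
    if format == "graphml":
        g = nx.read_graphml(path)
        g = nx.Graph(g)  # drop multi-edge/directed remnants
        g.remove_edges_from(nx.selfloop_edges(g))
        return g
    if format != "edge_list":
        raise ValueError(f"unknown network format {format!r}")

    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"malformed edge-list row at line {lineno}: {line!r}")
            a, b = parts[0], parts[1]
            if a == b:
                n_self += 1
                continue
            w = float(parts[2]) if len(parts) > 2 and parts[2] != "" else 1.0
            if not g.has_edge(a, b):
                g.add_edge(a, b, weight=w)
    if n_self:
        warnings.warn(f"skipped {n_self} self-loop row(s)")
    return g


def write_network(g: nx.Graph, path, format: str | None = None) -> None:
    """Write a network as a TSV edge list (full-precision weights) or GraphML."""
    path = str(path)
    if format is None:
        format = "graphml" if path.endswith((".graphml", ".xml")) else "edge_list"
    if format == "graphml":
        nx.write_graphml(g, path)
        return
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\tweight\n")
        for a, b, data in sorted(g.edges(data=True)):
            w = data.get("weight", 1.0)
            fh.write(f"{a}\t{b}\t{w!r}\n")


def read_expression(matrix_path, metadata_path) -> ExpressionDataset:
    """Read a gene x sample TSV matrix plus a sample metadata table.

    The metadata table must contain ``sample_id`` and ``age`` columns; matrix
    columns are reordered to the metadata row order. Missing cells (``NA`` or
    empty) are recorded in the dataset mask.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={0: str})
    for col in ("sample_id", "age"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    values.columns = values.columns.astype(str)
    known = set(meta["sample_id"])
    missing = [s for s in values.columns if s not in known]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    extra = [s for s in meta["sample_id"] if s not in set(values.columns)]
    if extra:
        warnings.warn(f"{len(extra)} metadata row(s) without a matrix column ignored")
        meta = meta[~meta["sample_id"].isin(extra)]
    order = list(meta["sample_id"])
    values = values[order].astype(float)
    try:
        ages = pd.to_numeric(meta["age"], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric age in metadata: {exc}") from exc
    ages.index = order
    return ExpressionDataset(values, ages)


def filter_missing(d: ExpressionDataset, max_frac: float = 0.3) -> ExpressionDataset:
    """Drop genes with too many missing values in any age group; impute the rest.

    A gene is removed iff, for at least one age group, the fraction of missing
    values strictly exceeds ``max_frac``. Remaining missing values are imputed
    by the gene's median over its non-missing samples.
    """
    if not (0.0 <= max_frac <= 1.0):
        raise ValueError("max_frac must lie in [0, 1]")
    mask = d.mask.to_numpy()
    ages = d.ages.to_numpy()
    drop = np.zeros(d.n_genes, dtype=bool)
    for age in np.unique(ages):
        cols = ages == age
        frac = mask[:, cols].mean(axis=1)
        drop |= frac > max_frac
    keep = [g for g, dr in zip(d.genes, drop) if not dr]
    if not keep:
        raise ValueError("empty dataset after filtering")
    values = d.values.loc[keep].copy()
    med = values.median(axis=1, skipna=True)
    values = values.apply(lambda row: row.fillna(med[row.name]), axis=1)
    return ExpressionDataset(values, d.ages)


def normalize(d: ExpressionDataset) -> ExpressionDataset:
    """Standardize each gene row to mean 0, variance 1 (population variance).

    Spearman-based quantities downstream are invariant to any monotone per-gene
    transform, so the exact normalization only matters for mean activities.
    """
    if d.mask.to_numpy().any():
        raise ValueError("missing values present; run filter_missing first")
    arr = d.values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    flat = np.isclose(sd[:, 0], 0.0)
    if flat.any():
        bad = [g for g, f in zip(d.genes, flat) if f]
        raise ValueError(f"zero-variance gene(s) cannot be normalized: {bad}")
    z = (arr - mu) / sd
    return ExpressionDataset(
        pd.DataFrame(z, index=d.values.index, columns=d.values.columns), d.ages
    )


def restrict_to_universe(
    g: nx.Graph, d: ExpressionDataset
) -> tuple[nx.Graph, ExpressionDataset]:
    """Induce the network on measured genes and keep its largest connected component.

    Ties between equal-size components break deterministically in favour of the
    component containing the lexicographically smallest gene. The returned
    dataset is restricted to the surviving genes (the analyzable universe).
    """
    common = set(g.nodes) & set(d.genes)
    if not common:
        raise ValueError("network and expression data share no genes")
    sub = g.subgraph(common)
    comps = list(nx.connected_components(sub))
    # size first; among ties, the component with the lexicographically smallest member
    max_size = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == max_size]
    best = min(tied, key=lambda c: min(c))
    g2 = nx.Graph(g.subgraph(best))
    return g2, d.subset_genes(best)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: per row ``name<TAB>description<TAB>member...``."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT row at line {lineno}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} at line {lineno}")
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise ValueError(f"gene set {name!r} at line {lineno} has no members")
            sets[name] = members
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)
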