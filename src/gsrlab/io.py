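"""Readers and writers for the external formats the functionome pipeline touches.

Supported formats:

* **GMT** (MSigDB): one gene set per line — ``name<TAB>description<TAB>gene1<TAB>...``.
* **Expression matrices**: plain TSV (first column gene/probe identifiers, header row of
  sample ids) and a GEO series-matrix-like TSV in which the numeric table sits between
  ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers.
* **Phenotype tables**: two-column TSV ``sample_id<TAB>group``.
* **GML** graphs for exported interaction networks (via :mod:`networkx`).

Probe rows that share a gene symbol are collapsed by the arithmetic mean; rows with any
missing value are dropped (and counted in the log) before collapsing, mirroring the
"no missing data" inclusion rule applied to the source cohorts.
"""

from __future__ import annotations

import io as _stdio
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "GeneSet",
    "GeneSetCollection",
    "ExpressionMatrix",
    "PhenotypeTable",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "write_gml",
    "read_gml",
]


class ParseError(ValueError):
    """A file does not conform to the expected format."""


@dataclass
class GeneSet:
    """A named collection of gene symbols (a GO term or canonical pathway).

    Duplicate symbols are removed on construction, preserving first occurrence.
    """

    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no genes after de-duplication")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list[GeneSet]
    source_label: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric expression matrix.

    ``data`` is a pandas DataFrame indexed by unique gene symbols with unique sample-id
    columns and no missing values.
    """

    data: pd.DataFrame
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("gene symbols must be unique (collapse probes first)")
        if self.data.columns.has_duplicates:
            raise ValueError("sample ids must be unique")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.data = self.data.astype(float)
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class PhenotypeTable:
    """Sample-to-group assignments (e.g. ``control``, ``I`` .. ``IV``)."""

    assignments: dict[str, str]

    def __getitem__(self, sample_id: str) -> str:
        return self.assignments[sample_id]

    def get(self, sample_id: str, default: str | None = None) -> str | None:
        return self.assignments.get(sample_id, default)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.assignments

    @property
    def labels(self) -> list[str]:
        """Group labels in first-occurrence order."""
        seen: dict[str, None] = {}
        for v in self.assignments.values():
            seen.setdefault(v, None)
        return list(seen)

    def samples(self, label: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == label]


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path: str | Path, source_label: str | None = None) -> GeneSetCollection:
    """Read an MSigDB GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    path = Path(path)
    sets: list[GeneSet] = []
    names: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in names:
                raise ParseError(f"{path.name}:{lineno}: duplicate gene set name {name!r}")
            names.add(name)
            try:
                sets.append(GeneSet(name=name, description=desc, genes=genes))
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
    return GeneSetCollection(sets, source_label=source_label or path.name)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices

def _extract_series_matrix_table(text: str) -> str:
    lines = text.splitlines()
    begin = end = None
    for i, line in enumerate(lines):
        if line.startswith("!series_matrix_table_begin"):
            begin = i
        elif line.startswith("!series_matrix_table_end"):
            end = i
    if begin is None or end is None or end <= begin:
        raise ParseError("series_matrix markers not found or malformed")
    body = [line.replace('"', "") for line in lines[begin + 1 : end]]
    return "\n".join(body)


def read_expression(
    path: str | Path,
    dialect: str = "tsv",
    collapse: str = "mean",
    dataset_id: str | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    Parameters
    ----------
    dialect:
        ``"tsv"`` for a plain tab-separated matrix, ``"series_matrix"`` for a GEO
        series-matrix-style file where the table is fenced by marker lines.
    collapse:
        Rule for rows sharing a gene symbol; only ``"mean"`` is supported.
    """
    path = Path(path)
    if dialect not in {"tsv", "series_matrix"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    if collapse != "mean":
        raise ValueError(f"unsupported collapse rule {collapse!r}")
    text = path.read_text(encoding="utf-8")
    if dialect == "series_matrix":
        text = _extract_series_matrix_table(text)
    df = pd.read_csv(_stdio.StringIO(text), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    # non-numeric cells (other than empty/NA markers) are a parse error
    for col in df.columns:
        if df[col].dtype == object:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{path.name}: non-numeric value in column {col!r}: {exc}") from exc
    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("%s: dropped %d row(s) with missing values", path.name, n_dropped)
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path.name}: empty matrix after filtering")
    return ExpressionMatrix(df, dataset_id=dataset_id or path.stem)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Phenotype tables

def read_phenotype(path: str | Path) -> PhenotypeTable:
    """Read ``sample_id<TAB>group`` rows; an optional ``sample\tgroup`` header is skipped."""
    path = Path(path)
    assignments: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path.name}:{lineno}: expected 2 fields, got {len(fields)}")
            sample, group = fields
            if lineno == 1 and sample.lower() in {"sample", "sample_id"}:
                continue
            if sample in assignments:
                raise ParseError(f"{path.name}:{lineno}: duplicate sample id {sample!r}")
            assignments[sample] = group
    if not assignments:
        raise ParseError(f"{path.name}: no sample assignments found")
    return PhenotypeTable(assignments)


def write_phenotype(phenotypes: PhenotypeTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in phenotypes.assignments.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# GML graphs

def write_gml(
    nodes: Sequence[str],
    edges: Iterable[tuple[str, str, float]],
    path: str | Path,
) -> None:
    """Write an undirected weighted graph in GML, with node ``label`` attributes and
    edge ``weight`` attributes.  ``nodes`` may include isolated nodes."""
    nodes = list(nodes)
    if len(set(nodes)) != len(nodes):
        raise ValueError("duplicate node labels")
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for a, b, w in edges:
        if a not in graph or b not in graph:
            raise ValueError(f"edge endpoint not in node list: {(a, b)}")
        graph.add_edge(a, b, weight=float(w))
    nx.write_gml(graph, str(path))


def read_gml(path: str | Path) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Read a GML graph back as (node labels, weighted edges with a < b)."""
    graph = nx.read_gml(str(path), label="label")
    nodes = sorted(graph.nodes)
    edges = []
    for a, b, attrs in graph.edges(data=True):
        a, b = sorted((a, b))
        edges.append((a, b, float(attrs.get("weight", 1.0))))
    return nodes, sorted(edges)
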