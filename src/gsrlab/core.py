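"""Baseline ordering templates and the gene set regularity (GSR) index.

The GSR index is a rank-conservation score derived from DIRAC-style pairwise ordering
comparisons.  For a gene set with ``m`` usable genes there are ``m*(m-1)/2`` gene pairs.
Among control samples, each pair ``(i, j)`` (``i < j`` in template gene order) receives the
majority orientation: ``"A"`` when ``Pr(E_i < E_j | control) > 0.5`` and ``"B"`` otherwise
(ties in the control fraction therefore encode ``"B"``).  A sample's GSR index for that set
is the fraction of pairs whose observed strict-order relation matches the template, so

* a sample reproducing the control-consensus ordering scores exactly 1,
* a sample reversing every pair scores exactly 0, and
* i.i.d.-random expression scores 0.5 on average.

Because only order relations enter, the index is invariant under any strictly increasing
per-sample transform of the expression values.  Ties in expression values count as
"not less", i.e. they encode ``"B"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, GeneSetCollection, PhenotypeTable

__all__ = [
    "InsufficientGenesError",
    "BaselineTemplate",
    "GSRMatrix",
    "build_baseline_template",
    "build_templates",
    "gsr_index",
    "score_samples",
    "gsr_matrix",
    "write_templates",
    "read_templates",
    "write_gsr",
    "read_gsr",
]

CONTROL_LABEL = "control"


class InsufficientGenesError(ValueError):
    """Fewer than two of the set's genes are present on the platform."""


@dataclass(eq=False)
class BaselineTemplate:
    """Control-majority pair orientations for one gene set.

    ``pairs`` holds index pairs (i, j), i < j, into ``genes_used`` in the canonical order
    (0,1),(0,2),...,(m-2,m-1).  ``control_fraction[p]`` is Pr(E_i < E_j | control) and the
    orientation is "A" iff that fraction exceeds 0.5.
    """

    set_name: str
    genes_used: list[str]
    pairs: np.ndarray
    control_fraction: np.ndarray
    n_controls: int

    def __post_init__(self) -> None:
        m = len(self.genes_used)
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.control_fraction = np.asarray(self.control_fraction, dtype=float)
        if self.pairs.shape != (m * (m - 1) // 2, 2):
            raise ValueError("pairs must enumerate all m*(m-1)/2 combinations")
        if self.control_fraction.shape[0] != self.pairs.shape[0]:
            raise ValueError("one control fraction per pair required")

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    @property
    def template_is_a(self) -> np.ndarray:
        """Boolean per pair: True where the template orientation is "A" (E_i < E_j)."""
        return self.control_fraction > 0.5

    @property
    def orientation(self) -> np.ndarray:
        return np.where(self.template_is_a, "A", "B")


@dataclass(eq=False)
class GSRMatrix:
    """Gene sets x samples matrix of GSR indices in [0, 1]."""

    data: pd.DataFrame
    skipped_sets: list[tuple[str, str]] = field(default_factory=list)
    template_provenance: str = ""

    def __post_init__(self) -> None:
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def set_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def _pair_indices(m: int) -> np.ndarray:
    iu = np.triu_indices(m, k=1)
    return np.column_stack(iu)


def build_baseline_template(
    expr: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    gene_set: GeneSet,
    control_label: str = CONTROL_LABEL,
) -> BaselineTemplate:
    """Estimate the control-majority orientation of every gene pair of one set.

    Raises :class:`InsufficientGenesError` when fewer than two set genes are present in
    ``expr``; raises :class:`ValueError` when no control samples are available.
    """
    controls = [s for s in expr.sample_ids if phenotypes.get(s) == control_label]
    if not controls:
        raise ValueError(f"no samples labelled {control_label!r}")
    present = [g for g in gene_set.genes if g in expr.data.index]
    if len(present) < 2:
        raise InsufficientGenesError(
            f"gene set {gene_set.name!r}: {len(present)} gene(s) present, need >= 2"
        )
    X = expr.data.loc[present, controls].to_numpy(dtype=float)
    pairs = _pair_indices(len(present))
    less = X[pairs[:, 0], :] < X[pairs[:, 1], :]  # strict: ties count as "not less"
    fraction = less.mean(axis=1)
    return BaselineTemplate(
        set_name=gene_set.name,
        genes_used=present,
        pairs=pairs,
        control_fraction=fraction,
        n_controls=len(controls),
    )


def build_templates(
    expr: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    collection: GeneSetCollection,
    control_label: str = CONTROL_LABEL,
) -> tuple[list[BaselineTemplate], list[tuple[str, str]]]:
    """Build templates for every scorable set; unscorable sets are returned with reasons."""
    templates: list[BaselineTemplate] = []
    skipped: list[tuple[str, str]] = []
    for gene_set in collection:
        try:
            templates.append(
                build_baseline_template(expr, phenotypes, gene_set, control_label)
            )
        except InsufficientGenesError:
            skipped.append((gene_set.name, "insufficient_genes"))
    return templates, skipped


def gsr_index(sample_values: np.ndarray, template: BaselineTemplate) -> float:
    """GSR index of one sample vector aligned to ``template.genes_used``."""
    v = np.asarray(sample_values, dtype=float)
    if v.shape != (len(template.genes_used),):
        raise ValueError(
            f"sample vector length {v.shape} does not match genes_used "
            f"({len(template.genes_used)})"
        )
    obs_a = v[template.pairs[:, 0]] < v[template.pairs[:, 1]]
    return float(np.mean(obs_a == template.template_is_a))


def score_samples(
    templates: list[BaselineTemplate],
    expr: ExpressionMatrix,
    template_provenance: str = "",
) -> GSRMatrix:
    """Score every sample of ``expr`` against each template (controls included)."""
    rows = {}
    skipped: list[tuple[str, str]] = []
    for tpl in templates:
        if not all(g in expr.data.index for g in tpl.genes_used):
            skipped.append((tpl.set_name, "missing_genes"))
            continue
        X = expr.data.loc[tpl.genes_used].to_numpy(dtype=float)
        obs_a = X[tpl.pairs[:, 0], :] < X[tpl.pairs[:, 1], :]
        match = obs_a == tpl.template_is_a[:, None]
        rows[tpl.set_name] = match.mean(axis=0)
    if not rows:
        raise ValueError("no scorable gene sets")
    data = pd.DataFrame(rows, index=expr.sample_ids).T
    return GSRMatrix(data, skipped_sets=skipped, template_provenance=template_provenance)


def gsr_matrix(
    expr: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    collection: GeneSetCollection,
    control_label: str = CONTROL_LABEL,
) -> GSRMatrix:
    """Build templates from controls and score all samples in one call."""
    templates, skipped = build_templates(expr, phenotypes, collection, control_label)
    if not templates:
        raise ValueError("no scorable gene sets in collection")
    result = score_samples(templates, expr, template_provenance=expr.dataset_id)
    result.skipped_sets = skipped + result.skipped_sets
    return result


# ---------------------------------------------------------------------------
# Plain-text persistence (one row per gene pair / sets x samples table)

def write_templates(templates: list[BaselineTemplate], path: str | Path) -> None:
    records = []
    for tpl in templates:
        genes = tpl.genes_used
        for (i, j), frac, orient in zip(tpl.pairs, tpl.control_fraction, tpl.orientation):
            records.append((tpl.set_name, genes[i], genes[j], frac, orient, tpl.n_controls))
    frame = pd.DataFrame(
        records,
        columns=["set", "gene_i", "gene_j", "fraction", "orientation", "n_controls"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_templates(path: str | Path) -> list[BaselineTemplate]:
    frame = pd.read_csv(path, sep="\t", dtype={"set": str, "gene_i": str, "gene_j": str})
    templates = []
    for set_name, block in frame.groupby("set", sort=False):
        # canonical pair order makes gene order recoverable from first appearance
        ordered: dict[str, None] = {}
        for g in block["gene_i"]:
            ordered.setdefault(g, None)
        for g in block["gene_j"]:
            ordered.setdefault(g, None)
        genes = list(ordered)
        templates.append(
            BaselineTemplate(
                set_name=set_name,
                genes_used=genes,
                pairs=_pair_indices(len(genes)),
                control_fraction=block["fraction"].to_numpy(dtype=float),
                n_controls=int(block["n_controls"].iloc[0]),
            )
        )
    return templates


def write_gsr(gsr: GSRMatrix, path: str | Path) -> None:
    gsr.data.to_csv(path, sep="\t", index_label="set")


def read_gsr(path: str | Path) -> GSRMatrix:
    data = pd.read_csv(path, sep="\t", index_col="set")
    data.columns = data.columns.astype(str)
    return GSRMatrix(data)
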