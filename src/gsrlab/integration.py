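"""Cross-platform integration and differential expression.

Expression profiles from different microarray platforms are made commensurate by a
per-sample cumulative-proportion transform: each value is replaced by the share of the
sample's total signal carried by the genes expressed strictly below it, so outputs lie in
[0, 1), the lowest gene maps to exactly 0, tied values share one output, and within-sample
ordering is preserved.  Datasets are merged on the intersection of their gene symbols; a
dataset is dropped (greedily, largest-gain first) when the intersection would otherwise
fall below the ``min_common`` threshold (default 4000 genes).

Differentially expressed genes are detected with a two-group linear model whose gene-wise
residual variances are shrunk toward a common prior by empirical Bayes: the prior degrees
of freedom ``d0`` and prior variance ``s0^2`` are estimated by moment-matching the log
sample variances against a scaled-F model, the posterior variance is the convex
combination ``(d0*s0^2 + df*s^2) / (d0 + df)``, and the moderated t uses ``d0 + df``
degrees of freedom, followed by BH adjustment across genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, PhenotypeTable

__all__ = [
    "MergedCohort",
    "ModeratedTResult",
    "cumulative_proportion_transform",
    "transform_matrix",
    "merge_common_genes",
    "moderated_t_test",
]


def cumulative_proportion_transform(sample_values: np.ndarray) -> np.ndarray:
    """Rescale one sample's expression vector to cumulative proportions in [0, 1).

    Negative inputs (log-ratio platforms) are first shifted by the sample minimum.  The
    transformed value of a gene is the fraction of total signal contributed by genes with
    strictly smaller values, so ties share their block's lowest output and the ordering is
    preserved.  The top gene's value approaches but never attains 1.
    """
    v = np.asarray(sample_values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty sample vector")
    if np.min(v) < 0:
        v = v - np.min(v)
    total = float(v.sum())
    if total <= 0:
        raise ValueError("sample has zero total signal")
    asc = np.sort(v)
    csum = np.concatenate([[0.0], np.cumsum(asc)])
    idx = np.searchsorted(asc, v, side="left")  # count of strictly smaller values
    return csum[idx] / total


def transform_matrix(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the cumulative-proportion transform to every sample column."""
    out = np.column_stack(
        [cumulative_proportion_transform(expr.data[c].to_numpy()) for c in expr.data.columns]
    )
    data = pd.DataFrame(out, index=expr.data.index, columns=expr.data.columns)
    return ExpressionMatrix(data, dataset_id=expr.dataset_id)


@dataclass
class MergedCohort:
    """Datasets merged on their common genes, with drop provenance."""

    included: list[str]
    common_genes: list[str]
    min_common: int
    dropped: list[tuple[str, str]]
    merged: ExpressionMatrix
    sample_sources: dict[str, str]


def _intersection(datasets: list[ExpressionMatrix]) -> set[str]:
    genes = set(datasets[0].gene_symbols)
    for d in datasets[1:]:
        genes &= set(d.gene_symbols)
    return genes


def _assemble(datasets: list[ExpressionMatrix], genes: list[str], dropped, min_common):
    columns = {}
    sources = {}
    used_ids = set()
    for d in datasets:
        for s in d.sample_ids:
            sid = s if s not in used_ids else f"{d.dataset_id}:{s}"
            used_ids.add(sid)
            columns[sid] = d.data.loc[genes, s].to_numpy()
            sources[sid] = d.dataset_id
    merged = ExpressionMatrix(
        pd.DataFrame(columns, index=genes), dataset_id="+".join(d.dataset_id for d in datasets)
    )
    return MergedCohort(
        included=[d.dataset_id for d in datasets],
        common_genes=genes,
        min_common=min_common,
        dropped=dropped,
        merged=merged,
        sample_sources=sources,
    )


def merge_common_genes(
    datasets: list[ExpressionMatrix],
    min_common: int = 4000,
    method: str = "greedy",
) -> MergedCohort:
    """Merge datasets on their common gene symbols, dropping datasets if needed.

    ``method="greedy"`` iteratively drops the dataset whose removal most enlarges the
    intersection until the threshold is met (or one dataset remains).
    ``method="exhaustive"`` (practical for small collections) searches all drop subsets
    for the fewest drops, breaking ties by the largest intersection then lexicographic
    retained ids.
    """
    if not datasets:
        raise ValueError("need >= 1 dataset")
    ids = [d.dataset_id for d in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError("dataset ids must be unique")
    if method == "greedy":
        retained = list(datasets)
        dropped: list[tuple[str, str]] = []
        while len(_intersection(retained)) < min_common and len(retained) > 1:
            best_idx, best_size = 0, -1
            for i in range(len(retained)):
                rest = retained[:i] + retained[i + 1 :]
                size = len(_intersection(rest))
                if size > best_size:
                    best_idx, best_size = i, size
            victim = retained.pop(best_idx)
            dropped.append(
                (victim.dataset_id, f"intersection below {min_common} (gain to {best_size})")
            )
    elif method == "exhaustive":
        best = None  # (n_dropped, -n_genes, retained_ids) minimized
        n = len(datasets)
        for n_drop in range(n):
            for keep in combinations(range(n), n - n_drop):
                subset = [datasets[i] for i in keep]
                genes = _intersection(subset)
                if len(genes) >= min_common:
                    key = (n_drop, -len(genes), tuple(datasets[i].dataset_id for i in keep))
                    if best is None or key < best[0]:
                        best = (key, list(keep))
            if best is not None:
                break
        if best is None:
            retained, dropped = [datasets[0]], []  # fall through to the error below
        else:
            keep = set(best[1])
            retained = [d for i, d in enumerate(datasets) if i in keep]
            dropped = [
                (d.dataset_id, f"intersection below {min_common}")
                for i, d in enumerate(datasets)
                if i not in keep
            ]
    else:
        raise ValueError(f"unknown method {method!r}")
    common = sorted(_intersection(retained))
    if len(common) < min_common:
        raise ValueError(
            f"cannot reach {min_common} common genes (best single dataset leaves "
            f"{len(common)})"
        )
    return _assemble(retained, common, dropped, min_common)


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated t

@dataclass
class ModeratedTResult:
    table: pd.DataFrame  # per gene: effect, s2, s2_post, t, df_total, p, q, rank
    d0: float
    s0_sq: float


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log sample variances to a scaled F model; returns (d0, s0^2).

    ``d0 = inf`` indicates no excess dispersion beyond the chi-square expectation, in
    which case every posterior variance equals ``s0^2``.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no dispersion beyond the chi-square expectation: every gene shares one
        # variance, whose natural estimate is the plain average
        d0 = np.inf
        s0_sq = float(np.mean(s2))
    return d0, s0_sq


def moderated_t_test(
    expr: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    case_label: str,
    control_label: str = "control",
    prior_df: float | None = None,
) -> ModeratedTResult:
    """Per-gene two-group moderated t with empirical-Bayes variance shrinkage.

    ``prior_df`` overrides the estimated d0 (0 recovers the ordinary two-sample t).
    Output rows are sorted by gene symbol, so the table is independent of input order.
    """
    case_samples = [s for s in expr.sample_ids if phenotypes.get(s) == case_label]
    ctrl_samples = [s for s in expr.sample_ids if phenotypes.get(s) == control_label]
    n1, n2 = len(case_samples), len(ctrl_samples)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per group, got {n1} and {n2}")
    genes = sorted(expr.gene_symbols)
    X = expr.data.loc[genes, case_samples].to_numpy()
    Y = expr.data.loc[genes, ctrl_samples].to_numpy()
    effect = X.mean(axis=1) - Y.mean(axis=1)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * X.var(axis=1, ddof=1) + (n2 - 1) * Y.var(axis=1, ddof=1)) / df
    if prior_df is None:
        d0, s0_sq = _fit_f_dist(s2, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, float(np.median(s2))
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_f_dist(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0)
    t = np.where((se == 0) & (effect != 0), np.sign(effect) * np.inf, t)
    p_df = df_total if np.isfinite(df_total) else 1e9
    p = 2.0 * stats.t.sf(np.abs(t), df=p_df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    order = sorted(range(len(genes)), key=lambda i: (p[i], genes[i]))
    rank = np.empty(len(genes), dtype=int)
    rank[order] = np.arange(1, len(genes) + 1)
    table = pd.DataFrame(
        {
            "effect": effect,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "df_total": df_total,
            "p": p,
            "q": q,
            "rank": rank,
        },
        index=pd.Index(genes, name="gene"),
    )
    return ModeratedTResult(table=table, d0=float(d0), s0_sq=float(s0_sq))
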