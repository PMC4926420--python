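"""Gene-set deregulation statistics: Mann-Whitney ranking, top-k set analysis and
progressive-ranking selection.

Each stage group is compared against the control group per gene set with a two-sided
Mann-Whitney U test on the GSR indices (exact enumeration for tie-free groups of at most
eight samples, tie-corrected normal approximation otherwise), followed by
Benjamini-Hochberg adjustment across all sets of that comparison.  Sets are ranked by
ascending p with a lexicographic tie-break on the set name so ranks are reproducible
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GSRMatrix
from .io import PhenotypeTable

__all__ = [
    "DeregulationRecord",
    "ProgressiveCriteria",
    "VennCounts",
    "RankPath",
    "bh_adjust",
    "test_deregulation",
    "records_to_frame",
    "top_k_set_analysis",
    "select_progressive",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


@dataclass(frozen=True)
class DeregulationRecord:
    """Per-set test result for one stage-vs-control comparison."""

    set_name: str
    stage_label: str
    p_value: float
    q_value: float
    rank: int


@dataclass(frozen=True)
class ProgressiveCriteria:
    """Selection thresholds for progressively deregulated sets.

    A set qualifies when it is significant at every stage (``p < alpha``), its final-stage
    rank is below ``max_final_rank``, and its rank improves (decreases) by more than
    ``min_rank_drop`` between consecutive stages.
    """

    alpha: float = 0.05
    max_final_rank: int = 200
    min_rank_drop: int = 15

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_final_rank < 1:
            raise ValueError("max_final_rank must be >= 1")
        if self.min_rank_drop < 0:
            raise ValueError("min_rank_drop must be >= 0")


@dataclass
class VennCounts:
    """Exact region counts of the top-k lists of several groups.

    ``region_counts`` maps a region label (member group labels joined by ``+`` in input
    group order) to the number of sets falling in exactly that combination of top-k lists.
    """

    region_counts: dict[str, int]
    k: int
    group_order: list[str]
    common_members: list[str] = field(default_factory=list)

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())


@dataclass(frozen=True)
class RankPath:
    """A set selected by the progressive criteria, with its per-stage ranks."""

    set_name: str
    ranks: tuple[int, ...]
    p_values: tuple[float, ...]


def _mann_whitney_p(case: np.ndarray, ctrl: np.ndarray) -> float:
    pooled = np.concatenate([case, ctrl])
    if np.all(pooled == pooled[0]):
        return 1.0  # no shift detectable
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and min(len(case), len(ctrl)) <= 8:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(case, ctrl, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def test_deregulation(
    gsr: GSRMatrix,
    phenotypes: PhenotypeTable,
    case_label: str,
    control_label: str = "control",
) -> list[DeregulationRecord]:
    """Two-sided Mann-Whitney U per set, BH-adjusted, ranked by ascending p."""
    case_samples = [s for s in gsr.sample_ids if phenotypes.get(s) == case_label]
    ctrl_samples = [s for s in gsr.sample_ids if phenotypes.get(s) == control_label]
    if len(case_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(case_samples)} {case_label!r} "
            f"and {len(ctrl_samples)} {control_label!r}"
        )
    case = gsr.data[case_samples].to_numpy()
    ctrl = gsr.data[ctrl_samples].to_numpy()
    names = gsr.set_names
    p = np.array(
        [_mann_whitney_p(case[i], ctrl[i]) for i in range(len(names))], dtype=float
    )
    q = bh_adjust(p)
    order = sorted(range(len(names)), key=lambda i: (p[i], names[i]))
    rank = np.empty(len(names), dtype=int)
    rank[order] = np.arange(1, len(names) + 1)
    return [
        DeregulationRecord(
            set_name=names[i],
            stage_label=case_label,
            p_value=float(p[i]),
            q_value=float(q[i]),
            rank=int(rank[i]),
        )
        for i in range(len(names))
    ]


def records_to_frame(records: Sequence[DeregulationRecord]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "set": [r.set_name for r in records],
            "stage": [r.stage_label for r in records],
            "p": [r.p_value for r in records],
            "q": [r.q_value for r in records],
            "rank": [r.rank for r in records],
        }
    )
    return frame.sort_values("rank").reset_index(drop=True)


def _ranked_names(entries: Sequence) -> list[str]:
    if entries and isinstance(entries[0], DeregulationRecord):
        return [r.set_name for r in sorted(entries, key=lambda r: r.rank)]
    return list(entries)


def top_k_set_analysis(
    records_by_stage: Mapping[str, Sequence], k: int = 200
) -> VennCounts:
    """Count every non-empty logical region among the groups' top-k set lists."""
    groups = list(records_by_stage)
    top: dict[str, set[str]] = {}
    for g in groups:
        ranked = _ranked_names(records_by_stage[g])
        if len(ranked) < k:
            raise ValueError(f"group {g!r} has only {len(ranked)} sets, k={k}")
        top[g] = set(ranked[:k])
    universe = set().union(*top.values())
    counts: dict[str, int] = {}
    for r in range(1, len(groups) + 1):
        for combo in combinations(groups, r):
            label = "+".join(combo)
            members = set.intersection(*(top[g] for g in combo))
            for g in groups:
                if g not in combo:
                    members -= top[g]
            counts[label] = len(members)
    common = sorted(set.intersection(*top.values())) if groups else []
    venn = VennCounts(region_counts=counts, k=k, group_order=groups, common_members=common)
    assert venn.union_size == len(universe)
    return venn


def select_progressive(
    records_by_stage: Mapping[str, Sequence[DeregulationRecord]],
    criteria: ProgressiveCriteria = ProgressiveCriteria(),
    drop_mode: str = "every",
) -> list[RankPath]:
    """Select sets whose ranking climbs across stages.

    ``drop_mode="every"`` requires the rank drop to exceed ``min_rank_drop`` between every
    consecutive stage pair; ``"any"`` requires it for at least one pair.  Results are
    ordered by final-stage rank.
    """
    if drop_mode not in {"every", "any"}:
        raise ValueError(f"unknown drop_mode {drop_mode!r}")
    stages = list(records_by_stage)
    if len(stages) < 2:
        raise ValueError("need >= 2 stages")
    by_stage: list[dict[str, DeregulationRecord]] = []
    universe: set[str] | None = None
    for g in stages:
        recs = {r.set_name: r for r in records_by_stage[g]}
        if universe is None:
            universe = set(recs)
        elif set(recs) != universe:
            diff = sorted(set(recs) ^ universe)
            raise ValueError(f"stage {g!r} has a different set universe: {diff}")
        by_stage.append(recs)
    selected: list[RankPath] = []
    assert universe is not None
    for name in sorted(universe):
        ranks = tuple(recs[name].rank for recs in by_stage)
        ps = tuple(recs[name].p_value for recs in by_stage)
        if any(p >= criteria.alpha for p in ps):
            continue
        if ranks[-1] >= criteria.max_final_rank:
            continue
        drops = [ranks[i] - ranks[i + 1] for i in range(len(ranks) - 1)]
        ok = all(d > criteria.min_rank_drop for d in drops) if drop_mode == "every" \
            else any(d > criteria.min_rank_drop for d in drops)
        if ok:
            selected.append(RankPath(set_name=name, ranks=ranks, p_values=ps))
    return sorted(selected, key=lambda r: (r.ranks[-1], r.set_name))
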