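"""Pattern-recognition harness for GSR functionome matrices.

Binary and multiclass linear-SVM cross-validation (stratified five-fold, repeated ten
times by default) quantifies how informative the per-sample vector of GSR indices is
about the phenotype.  Metrics are computed from the cumulative confusion counts over all
repeats; the binary AUC pools out-of-fold decision scores across repeats.  GSR features
already live on a common [0, 1] scale, so no standardization is applied and the report is
reproducible from the GSR matrix and the seed alone.

Unsupervised structure among phenotype groups is summarized by complete-linkage
hierarchical clustering of the group-mean GSR vectors (Euclidean distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import GSRMatrix
from .io import PhenotypeTable

__all__ = [
    "ClassificationReport",
    "ClusterResult",
    "svm_cv",
    "cluster_group_means",
]


@dataclass
class ClassificationReport:
    mode: str  # "binary" or "multiclass"
    accuracy: float
    accuracy_sd: float
    n_folds: int
    n_repeats: int
    sensitivity: float | None = None
    specificity: float | None = None
    sensitivity_sd: float | None = None
    specificity_sd: float | None = None
    auc: float | None = None
    confusion: pd.DataFrame | None = None
    per_repeat: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = {"mode": self.mode, "accuracy": self.accuracy, "accuracy_sd": self.accuracy_sd,
                "n_folds": self.n_folds, "n_repeats": self.n_repeats}
        if self.mode == "binary":
            rows.update(
                sensitivity=self.sensitivity, sensitivity_sd=self.sensitivity_sd,
                specificity=self.specificity, specificity_sd=self.specificity_sd,
                auc=self.auc,
            )
        return pd.DataFrame([rows])


@dataclass
class ClusterResult:
    leaf_order: list[str]
    merge_sequence: list[tuple[tuple[str, ...], tuple[str, ...], float]]


def _features(gsr: GSRMatrix, phenotypes: PhenotypeTable, labels: list[str]):
    samples = [s for s in gsr.sample_ids if phenotypes.get(s) in labels]
    X = gsr.data[samples].to_numpy().T  # samples x sets
    y = np.array([phenotypes[s] for s in samples])
    return X, y


def svm_cv(
    gsr: GSRMatrix,
    phenotypes: PhenotypeTable,
    labels: list[str],
    n_folds: int = 5,
    n_repeats: int = 10,
    C: float = 1.0,
    seed: int = 0,
) -> ClassificationReport:
    """Repeated stratified k-fold cross-validation of a linear soft-margin SVM.

    For binary problems ``labels[0]`` is the positive class (sensitivity refers to it).
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need >= 2 class labels")
    X, y = _features(gsr, phenotypes, labels)
    for lab in labels:
        n_lab = int(np.sum(y == lab))
        if n_lab < n_folds:
            raise ValueError(f"class {lab!r} has {n_lab} samples, fewer than {n_folds} folds")
    binary = len(labels) == 2
    positive = labels[0]
    rs = np.random.RandomState(seed)
    per_repeat_rows = []
    cum_confusion = pd.DataFrame(0, index=labels, columns=labels)  # true x predicted
    pooled_scores: list[float] = []
    pooled_truth: list[int] = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rs.randint(2**31)))
        confusion = pd.DataFrame(0, index=labels, columns=labels)
        for train_idx, test_idx in skf.split(X, y):
            clf = SVC(kernel="linear", C=C)
            clf.fit(X[train_idx], y[train_idx])
            pred = clf.predict(X[test_idx])
            for t, p in zip(y[test_idx], pred):
                confusion.loc[t, p] += 1
            if binary:
                score = clf.decision_function(X[test_idx])
                if clf.classes_[1] != positive:  # orient scores toward the positive class
                    score = -score
                pooled_scores.extend(score.tolist())
                pooled_truth.extend((y[test_idx] == positive).astype(int).tolist())
        cum_confusion += confusion
        row = {"repeat": rep, "accuracy": np.trace(confusion.to_numpy()) / confusion.to_numpy().sum()}
        if binary:
            tp = confusion.loc[positive, positive]
            fn = confusion.loc[positive].sum() - tp
            neg = labels[1]
            tn = confusion.loc[neg, neg]
            fp = confusion.loc[neg].sum() - tn
            row["sensitivity"] = tp / (tp + fn)
            row["specificity"] = tn / (tn + fp)
        per_repeat_rows.append(row)
    per_repeat = pd.DataFrame(per_repeat_rows)
    total = cum_confusion.to_numpy().sum()
    accuracy = float(np.trace(cum_confusion.to_numpy()) / total)
    report = ClassificationReport(
        mode="binary" if binary else "multiclass",
        accuracy=accuracy,
        accuracy_sd=float(per_repeat["accuracy"].std(ddof=1)),
        n_folds=n_folds,
        n_repeats=n_repeats,
        confusion=cum_confusion,
        per_repeat=per_repeat,
    )
    if binary:
        tp = cum_confusion.loc[positive, positive]
        fn = cum_confusion.loc[positive].sum() - tp
        neg = labels[1]
        tn = cum_confusion.loc[neg, neg]
        fp = cum_confusion.loc[neg].sum() - tn
        report.sensitivity = float(tp / (tp + fn))
        report.specificity = float(tn / (tn + fp))
        report.sensitivity_sd = float(per_repeat["sensitivity"].std(ddof=1))
        report.specificity_sd = float(per_repeat["specificity"].std(ddof=1))
        report.auc = float(roc_auc_score(pooled_truth, pooled_scores))
    return report


def cluster_group_means(
    gsr: GSRMatrix,
    phenotypes: PhenotypeTable,
    groups: list[str] | None = None,
) -> ClusterResult:
    """Complete-linkage agglomeration of per-group mean GSR vectors."""
    if groups is None:
        groups = [
            g for g in phenotypes.labels
            if any(phenotypes.get(s) == g for s in gsr.sample_ids)
        ]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    means = []
    for g in groups:
        samples = [s for s in gsr.sample_ids if phenotypes.get(s) == g]
        if not samples:
            raise ValueError(f"group {g!r} has no samples")
        means.append(gsr.data[samples].mean(axis=1).to_numpy())
    Z = hierarchy.linkage(np.asarray(means), method="complete", metric="euclidean")
    clusters: dict[int, tuple[str, ...]] = {i: (g,) for i, g in enumerate(groups)}
    merges = []
    for step, (a, b, height, _) in enumerate(Z):
        ca, cb = clusters[int(a)], clusters[int(b)]
        merges.append((ca, cb, float(height)))
        clusters[len(groups) + step] = tuple(sorted(ca + cb))
    leaf_order = [groups[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(leaf_order=leaf_order, merge_sequence=merges)
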