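"""Agreement between cluster labels and reference labels.

Confusion counts treat label 1 as the positive class (the high-score side of
the reference scale). Accuracy is (tp+tn)/n, sensitivity tp/(tp+fn) and
specificity tn/(tn+fp); an empty margin leaves the corresponding rate
undefined (``None``) rather than coercing it to 0, so degenerate
clusterings stay visible in reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

from .clustering import (
    ALL_METHODS,
    BEST_MATCH,
    KMEANS,
    TREE_METHODS,
    ClusterResult,
    assign_polarity,
    hierarchical_two_clusters,
    kmeans_two_clusters,
)
from .errors import AlignmentError, ValidationError
from .features import FeatureMatrix
from .io import LabelTable
from .selection import pca_transform


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class EvalReport:
    """One cluster-vs-reference comparison."""

    method: str
    feature_set: str
    pca: bool
    reference: str
    counts: ConfusionCounts
    acc: float
    tpr: float | None
    tnr: float | None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "feature_set": self.feature_set,
            "pca": self.pca,
            "reference": self.reference,
            "n": self.counts.n,
            **asdict(self.counts),
            "acc": self.acc,
            "tpr": self.tpr,
            "tnr": self.tnr,
        }
        return d


def confusion(predicted: LabelTable, reference: LabelTable) -> ConfusionCounts:
    """2×2 cross-tabulation with label 1 as the positive class."""
    if set(predicted.labels) != set(reference.labels):
        raise AlignmentError("predicted and reference cover different participants")
    tp = fn = tn = fp = 0
    for pid, ref in reference.labels.items():
        pred = predicted.labels[pid]
        if ref == 1:
            tp, fn = (tp + 1, fn) if pred == 1 else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if pred == 0 else (tn, fp + 1)
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def metrics(c: ConfusionCounts) -> tuple[float, float | None, float | None]:
    """(accuracy, sensitivity, specificity); undefined margins give None."""
    if c.n == 0:
        raise ValidationError("empty confusion table")
    acc = (c.tp + c.tn) / c.n
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    tnr = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return acc, tpr, tnr


def compare(
    result: ClusterResult,
    reference: LabelTable,
    feature_set: str = "all",
    pca: bool = False,
) -> EvalReport:
    counts = confusion(result.as_label_table(), reference)
    acc, tpr, tnr = metrics(counts)
    return EvalReport(
        method=result.method, feature_set=feature_set, pca=pca,
        reference=reference.provenance, counts=counts, acc=acc, tpr=tpr, tnr=tnr,
    )


def _cluster(matrix: FeatureMatrix, method: str, seed: int,
             linkage_method: str) -> ClusterResult:
    if method == KMEANS:
        return kmeans_two_clusters(matrix, seed=seed)
    if method in TREE_METHODS:
        return hierarchical_two_clusters(
            matrix, metric=TREE_METHODS[method], linkage_method=linkage_method
        )
    raise ValidationError(f"unknown method {method!r}; choose from {ALL_METHODS}")


def evaluate_pipeline(
    features: FeatureMatrix,
    jaws_labels: LabelTable,
    expert_labels: LabelTable | None = None,
    methods: Sequence[str] = ALL_METHODS,
    pca_options: Sequence[bool] = (False, True),
    feature_sets: dict[str, FeatureMatrix] | None = None,
    seed: int = 0,
    linkage_method: str = "average",
    polarity_rule: str = BEST_MATCH,
) -> list[EvalReport]:
    """Run the method × PCA × feature-set comparison grid.

    Every combination is clustered once and scored against the JAWS
    reference labels, and additionally against expert labels when provided.
    Deterministic for a fixed seed.
    """
    sets = feature_sets if feature_sets is not None else {"all": features}
    reports: list[EvalReport] = []
    for set_name, fm in sets.items():
        for use_pca in pca_options:
            mat = pca_transform(fm) if use_pca else fm
            for method in methods:
                result = _cluster(mat, method, seed, linkage_method)
                for ref in ([jaws_labels] + ([expert_labels] if expert_labels else [])):
                    oriented = assign_polarity(result, ref, rule=polarity_rule)
                    reports.append(compare(oriented, ref, set_name, use_pca))
    return reports


def reports_to_json(reports: Sequence[EvalReport], path: str | Path,
                    extra: dict | None = None) -> None:
    payload = {"reports": [r.to_dict() for r in reports]}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
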