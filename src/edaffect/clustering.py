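"""Two-class participant clustering: agglomerative trees and k-means.

Three row-distance definitions are available for the hierarchical tree —
Euclidean, Spearman distance (1 − rank correlation) and correlation distance
(1 − Pearson r) — and the tree is cut at exactly two clusters. k-means runs
Lloyd iterations from k-means++ starts with a fixed seed. Cluster indices
are arbitrary, so a polarity rule maps them onto reference labels either
as-produced (``fixed``) or by the agreement-maximising permutation
(``best_match``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .errors import AlignmentError, DegeneracyError, ValidationError
from .features import FeatureMatrix
from .io import LabelTable

EUCLIDEAN = "euclidean"
SPEARMAN = "spearman"
CORRELATION = "correlation"
METRICS = (EUCLIDEAN, SPEARMAN, CORRELATION)

TREE_METHODS = {f"tree_{m}": m for m in METRICS}
KMEANS = "kmeans"
ALL_METHODS = tuple(TREE_METHODS) + (KMEANS,)

FIXED = "fixed"
BEST_MATCH = "best_match"


@dataclass(frozen=True)
class ClusterResult:
    """A two-class partition of the participants."""

    labels: Mapping[str, int]
    method: str
    inertia: float | None = None            # kmeans only
    linkage_heights: tuple[float, ...] | None = None  # tree only
    polarity_rule: str = FIXED

    def __post_init__(self) -> None:
        lab = {str(k): int(v) for k, v in dict(self.labels).items()}
        object.__setattr__(self, "labels", lab)
        if any(v not in (0, 1) for v in lab.values()):
            raise ValidationError("cluster labels must be 0/1")
        if len(lab) >= 2 and len(set(lab.values())) != 2:
            raise ValidationError("expected exactly 2 clusters for n >= 2")

    def as_label_table(self) -> LabelTable:
        return LabelTable(self.labels, provenance="cluster")


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel so the cluster of the first participant is 0."""
    return labels if labels[0] == 0 else 1 - labels


def pairwise_distance(matrix: FeatureMatrix, metric: str = EUCLIDEAN) -> np.ndarray:
    """Symmetric participant × participant distance table.

    ``spearman`` ranks each row first and then applies the correlation
    distance, so it equals 1 − Spearman ρ between rows. Constant rows make
    the correlation metrics undefined and raise.
    """
    X = matrix.values()
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 participants")
    if metric == EUCLIDEAN:
        diff = X[:, None, :] - X[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if metric not in (SPEARMAN, CORRELATION):
        raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")
    if X.shape[1] < 2:
        raise ValidationError(f"{metric} distance needs at least 2 features")
    rows = X
    if metric == SPEARMAN:
        rows = np.apply_along_axis(rankdata, 1, X)
    sd = rows.std(axis=1)
    if np.any(sd == 0):
        bad = [matrix.participants[i] for i in np.flatnonzero(sd == 0)]
        raise DegeneracyError(f"correlation undefined for constant rows: {bad}")
    Z = (rows - rows.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = Z @ Z.T / rows.shape[1]
    dist = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def hierarchical_two_clusters(
    matrix: FeatureMatrix, metric: str = EUCLIDEAN, linkage_method: str = "average"
) -> ClusterResult:
    """Agglomerative tree cut at two clusters.

    Merging starts from singletons and proceeds by the chosen linkage
    (single, average or complete) on the requested distance; ties resolve
    deterministically by lowest pair index (scipy's ordering).
    """
    if linkage_method not in ("single", "average", "complete"):
        raise ValidationError(f"unsupported linkage {linkage_method!r}")
    dist = pairwise_distance(matrix, metric)
    n = dist.shape[0]
    if n == 2:
        labels = np.array([0, 1])
        heights: tuple[float, ...] = (float(dist[0, 1]),)
    else:
        Z = linkage(squareform(dist, checks=False), method=linkage_method)
        # cut by merge order (undo the last merge), so tied heights still
        # yield exactly two clusters
        labels = cut_tree(Z, n_clusters=2).ravel()
        heights = tuple(float(h) for h in Z[:, 2])
    labels = _canonical(np.asarray(labels))
    return ClusterResult(
        labels=dict(zip(matrix.participants, labels.tolist())),
        method=f"tree_{metric}",
        linkage_heights=heights,
    )


def kmeans_two_clusters(
    matrix: FeatureMatrix,
    seed: int,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterResult:
    """k-means with k=2, k-means++ starts and the best of ``n_init`` restarts."""
    X = matrix.values()
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 participants")
    if np.unique(X, axis=0).shape[0] < 2:
        raise DegeneracyError("fewer than 2 distinct feature rows")
    km = KMeans(
        n_clusters=2, init="k-means++", n_init=n_init, max_iter=max_iter,
        tol=tol, random_state=seed,
    ).fit(X)
    labels = _canonical(km.labels_.astype(int))
    return ClusterResult(
        labels=dict(zip(matrix.participants, labels.tolist())),
        method=KMEANS,
        inertia=float(km.inertia_),
    )


def agreement(predicted: Mapping[str, int], reference: Mapping[str, int]) -> float:
    ids = list(predicted)
    return float(np.mean([predicted[i] == reference[i] for i in ids]))


def assign_polarity(
    result: ClusterResult, reference: LabelTable, rule: str = BEST_MATCH
) -> ClusterResult:
    """Orient cluster indices against a reference labelling.

    ``fixed`` keeps labels as produced; ``best_match`` flips them if the
    flipped assignment agrees better with the reference.
    """
    if rule not in (FIXED, BEST_MATCH):
        raise ValidationError(f"unknown polarity rule {rule!r}")
    if set(result.labels) != set(reference.labels):
        raise AlignmentError("cluster result and reference cover different ids")
    if rule == FIXED:
        return replace(result, polarity_rule=FIXED)
    flipped = {k: 1 - v for k, v in result.labels.items()}
    if agreement(flipped, reference.labels) > agreement(result.labels, reference.labels):
        return replace(result, labels=flipped, polarity_rule=BEST_MATCH)
    return replace(result, polarity_rule=BEST_MATCH)
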