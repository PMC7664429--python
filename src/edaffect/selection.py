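"""Feature-space reduction: CV filter, univariate two-cluster WCSS filter,
contextual feature sets and the all-components PCA transform.

The coefficient of variation (sample SD over mean) screens out features with
little relative variability; the within-cluster sum of squares of the best
univariate two-cluster split then keeps the features along which the cohort
looks most like two groups. PCA rotates the (optionally standardised)
feature space while keeping every component, so no variance is discarded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DegeneracyError, EmptySelectionError, ValidationError
from .features import FeatureMatrix

CV_REJECT = "cv_reject"
WCSS_REJECT = "wcss_reject"
KEPT = "kept"

#: Published per-exercise feature subsets, for users who want the fixed
#: selections instead of data-driven filtering.
PRESETS: dict[str, tuple[str, ...]] = {
    "paper_ex1": ("standard_deviation", "reg_slope", "n_gsr", "total_sum"),
    "paper_ex2": (
        "standard_deviation", "quartile_deviation", "reg_slope", "gsr_energy",
        "minimum", "moment4", "moment5", "skewness", "reg_rmse", "entropy",
    ),
    "paper_ex3": (
        "standard_deviation", "quartile_deviation", "reg_slope", "n_gsr",
        "gsr_energy", "minimum", "moment4", "moment5", "skewness", "kurtosis",
        "reg_rmse", "entropy", "rms",
    ),
}

#: Contextual sets used to probe which flavour of descriptor drives clustering.
CONTEXTUAL_SETS: dict[str, tuple[str, ...]] = {
    "statistical": ("standard_deviation", "quartile_deviation", "skewness",
                    "kurtosis", "reg_slope"),
    "signal": ("n_gsr", "gsr_energy", "minimum", "total_sum"),
    "error": ("moment4", "moment5", "rms", "entropy"),
}


@dataclass(frozen=True)
class SelectionReport:
    """Per-feature record of filter scores and the keep/reject outcome."""

    cv: Mapping[str, float | None]
    wcss: Mapping[str, float | None]
    kept: Mapping[str, bool]
    reason: Mapping[str, str]
    cv_threshold: float | None = None
    wcss_threshold: float | None = None
    wcss_top_k: int | None = None

    def kept_features(self) -> list[str]:
        return [name for name, keep in self.kept.items() if keep]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cv_threshold": self.cv_threshold,
            "wcss_threshold": self.wcss_threshold,
            "wcss_top_k": self.wcss_top_k,
            "features": {
                name: {
                    "cv": self.cv.get(name),
                    "wcss": self.wcss.get(name),
                    "kept": self.kept[name],
                    "reason": self.reason[name],
                }
                for name in self.kept
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample SD divided by the arithmetic mean. Undefined for zero mean."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValidationError(f"need at least 2 values, got {len(x)}")
    mean = x.mean()
    if mean == 0:
        raise DegeneracyError("coefficient of variation undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def cv_filter(
    matrix: FeatureMatrix, threshold: float = 0.5
) -> tuple[FeatureMatrix, SelectionReport]:
    """Drop features whose |CV| across participants is below ``threshold``.

    Ties at the threshold are kept. Features with zero mean (undefined CV)
    are rejected. Raises if nothing survives.
    """
    if matrix.data.empty:
        raise ValidationError("empty feature matrix")
    cv: dict[str, float | None] = {}
    kept: dict[str, bool] = {}
    reason: dict[str, str] = {}
    for name in matrix.feature_names:
        col = matrix.data[name].to_numpy(dtype=float)
        try:
            value = coefficient_of_variation(col)
        except DegeneracyError:
            value = None
        cv[name] = value
        keep = value is not None and abs(value) >= threshold
        kept[name] = keep
        reason[name] = KEPT if keep else CV_REJECT
    survivors = [n for n in matrix.feature_names if kept[n]]
    if not survivors:
        raise EmptySelectionError("CV filter rejected every feature")
    report = SelectionReport(cv=cv, wcss={}, kept=kept, reason=reason,
                             cv_threshold=threshold)
    return matrix.select(survivors), report


def wcss_1d(values: Sequence[float], k: int = 2) -> float:
    """Minimal within-cluster sum of squares of a 1-D k-clustering.

    The optimum assigns each value to one of ``k`` groups minimising
    Σ(Xi − Yi)² with Yi the group mean; in one dimension the optimal groups
    are contiguous runs of the sorted values, found here by dynamic
    programming over split points.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n < k:
        raise ValidationError(f"need at least k={k} values, got {n}")
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def cost(i: int, j: int) -> float:  # sum of squared deviations of x[i:j]
        m = j - i
        seg1 = s1[j] - s1[i]
        seg2 = s2[j] - s2[i]
        return max(seg2 - seg1 * seg1 / m, 0.0)

    dp = [[np.inf] * (n + 1) for _ in range(k + 1)]
    dp[0][0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, n + 1):
            dp[g][j] = min(dp[g - 1][i] + cost(i, j) for i in range(g - 1, j))
    return float(dp[k][n])


def wcss_filter(
    matrix: FeatureMatrix,
    threshold: float | None = None,
    top_k: int | None = None,
    standardize: bool = False,
) -> tuple[FeatureMatrix, SelectionReport]:
    """Keep features whose univariate two-cluster WCSS is small.

    Either an absolute ``threshold`` (keep wcss <= threshold) or ``top_k``
    (keep the k smallest) must be given. Raw feature scales are used unless
    ``standardize`` is set.
    """
    if (threshold is None) == (top_k is None):
        raise ValidationError("give exactly one of threshold or top_k")
    if threshold is not None and threshold <= 0:
        raise ValidationError("threshold must be > 0")
    if matrix.data.empty:
        raise ValidationError("empty feature matrix")
    wcss: dict[str, float] = {}
    for name in matrix.feature_names:
        col = matrix.data[name].to_numpy(dtype=float)
        if standardize:
            sd = col.std(ddof=1)
            col = (col - col.mean()) / sd if sd > 0 else col - col.mean()
        wcss[name] = wcss_1d(col, k=2)
    if top_k is not None:
        order = sorted(matrix.feature_names, key=lambda n: (wcss[n], n))
        chosen = set(order[: top_k])
        kept = {n: n in chosen for n in matrix.feature_names}
    else:
        kept = {n: wcss[n] <= threshold for n in matrix.feature_names}
    reason = {n: (KEPT if kept[n] else WCSS_REJECT) for n in matrix.feature_names}
    survivors = [n for n in matrix.feature_names if kept[n]]
    if not survivors:
        raise EmptySelectionError("WCSS filter rejected every feature")
    report = SelectionReport(cv={}, wcss=wcss, kept=kept, reason=reason,
                             wcss_threshold=threshold, wcss_top_k=top_k)
    return matrix.select(survivors), report


def contextual_set(matrix: FeatureMatrix, set_id: str) -> FeatureMatrix:
    """Column subset for one of the named contextual sets."""
    if set_id not in CONTEXTUAL_SETS:
        raise ValidationError(
            f"unknown set {set_id!r}; available: {sorted(CONTEXTUAL_SETS)}"
        )
    return matrix.select(CONTEXTUAL_SETS[set_id])


def preset_set(matrix: FeatureMatrix, preset: str) -> FeatureMatrix:
    """Column subset for one of the published per-exercise presets."""
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    return matrix.select(PRESETS[preset])


def pca_transform(matrix: FeatureMatrix, standardize: bool = True) -> FeatureMatrix:
    """Rotate the feature space onto its principal axes, keeping all components.

    Works on the covariance eigendecomposition of the (optionally z-scored)
    matrix so the output always has as many components as input features,
    ordered by decreasing explained variance; total variance is conserved
    and pairwise distances in the standardised space are preserved.
    Constant columns are dropped (with a warning) before z-scoring.
    """
    if len(matrix.participants) < 2:
        raise ValidationError("PCA needs at least 2 participants")
    df = matrix.data
    X = df.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        constant = sd == 0
        if constant.any():
            dropped = [n for n, c in zip(df.columns, constant) if c]
            warnings.warn(f"dropping constant columns before z-scoring: {dropped}",
                          stacklevel=2)
            X = X[:, ~constant]
            if X.shape[1] == 0:
                raise ValidationError("all columns constant; nothing to transform")
            sd = sd[~constant]
        X = (X - X.mean(axis=0)) / sd
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvecs = eigvecs[:, order]
    # deterministic orientation: largest-|loading| entry positive
    for j in range(eigvecs.shape[1]):
        pivot = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    scores = Xc @ eigvecs
    import pandas as pd

    out = pd.DataFrame(
        scores,
        index=df.index,
        columns=[f"PC{j + 1}" for j in range(scores.shape[1])],
    )
    return FeatureMatrix(out, matrix.exercise_id)
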