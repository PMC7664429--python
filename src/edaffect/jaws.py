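"""JAWS questionnaire scoring and questionnaire-derived reference labels.

The 12-item short form of the Job-related Affective Well-being Scale has six
positively and six negatively keyed Likert items (1..5). Two scorings are
used: the global total, which reverse-codes the negative items
(recoded = 6 − raw) before summing, and the positive/negative subscale sums
taken on the raw responses. The identity ``total = pos + 36 − neg`` ties the
three together. Reference class labels come from a one-dimensional two-means
split of the chosen score, with the induced threshold at the midpoint of the
gap between the two clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegeneracyError, ValidationError
from .io import NEGATIVE, POSITIVE, JAWSResponses, LabelTable

SCALES = ("total", "pos", "neg")

#: Score ranges per scale: 12 items in 1..5 → 12..60; 6 items → 6..30.
SCALE_RANGES = {"total": (12, 60), "pos": (6, 30), "neg": (6, 30)}

#: Published dichotomisation thresholds per scale.
PAPER_TABLE1_THRESHOLDS = {"total": 44.5, "pos": 18.5, "neg": 10.0}


@dataclass(frozen=True)
class JAWSScores:
    """Derived total and subscale sums for one participant."""

    participant_id: str
    total: int
    pos: int
    neg: int

    def __post_init__(self) -> None:
        if not 12 <= self.total <= 60:
            raise ValidationError(f"total {self.total} outside 12..60")
        if not 6 <= self.pos <= 30 or not 6 <= self.neg <= 30:
            raise ValidationError("subscale sums must lie in 6..30")
        if self.total != self.pos + 36 - self.neg:
            raise ValidationError("total must equal pos + 36 - neg")

    def on_scale(self, scale: str) -> int:
        if scale not in SCALES:
            raise ValidationError(f"unknown scale {scale!r}")
        return getattr(self, scale if scale != "total" else "total")


def score_jaws(resp: JAWSResponses) -> JAWSScores:
    """Score one response row: subscale sums plus the reverse-coded total."""
    pos = sum(v for v, i in zip(resp.items, range(1, 13))
              if resp.polarity[i] == POSITIVE)
    neg = sum(v for v, i in zip(resp.items, range(1, 13))
              if resp.polarity[i] == NEGATIVE)
    return JAWSScores(resp.participant_id, total=pos + 36 - neg, pos=pos, neg=neg)


def score_cohort(responses: Sequence[JAWSResponses]) -> list[JAWSScores]:
    return [score_jaws(r) for r in responses]


def write_scores_csv(scores: Sequence[JAWSScores], path: str | Path) -> None:
    pd.DataFrame(
        [{"participant_id": s.participant_id, "total": s.total,
          "pos": s.pos, "neg": s.neg} for s in scores]
    ).to_csv(path, index=False)


def two_means_split(values: np.ndarray) -> np.ndarray:
    """Boolean mask of the high cluster under the optimal 1-D two-means split.

    In one dimension the optimal two-cluster partition is contiguous in
    sorted order; all split points are scanned and the one with minimal
    within-cluster sum of squares wins (first such split on ties).
    """
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    best_cost, best_split = np.inf, None
    for s in range(1, n):
        lo, hi = xs[:s], xs[s:]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_split = cost, s
    mask = np.zeros(n, dtype=bool)
    mask[order[best_split:]] = True
    return mask


def reference_labels(
    scores: Sequence[float],
    participant_ids: Sequence[str] | None = None,
    provenance: str = "jaws",
) -> tuple[LabelTable, float]:
    """Two-means reference labelling of a score sequence.

    Returns the label table (1 = high-score cluster) and the induced
    threshold: the midpoint between the maximum of the low cluster and the
    minimum of the high cluster.
    """
    x = np.asarray(scores, dtype=float)
    if len(x) < 2:
        raise ValidationError("need at least 2 scores")
    if np.all(x == x[0]):
        raise DegeneracyError("all scores equal; no two-class structure")
    if participant_ids is None:
        participant_ids = [f"P{i + 1:03d}" for i in range(len(x))]
    if len(participant_ids) != len(x):
        raise ValidationError("ids and scores must have equal length")
    high = two_means_split(x)
    threshold = float((x[~high].max() + x[high].min()) / 2.0)
    table = LabelTable(
        {pid: int(h) for pid, h in zip(participant_ids, high)}, provenance
    )
    return table, threshold


def dichotomize(
    scores: Sequence[JAWSScores], scale: str, threshold: float
) -> LabelTable:
    """Label 1 iff the chosen score strictly exceeds ``threshold``.

    For ``scale='neg'`` label 1 therefore means negative-dominant.
    """
    if scale not in SCALES:
        raise ValidationError(f"unknown scale {scale!r}")
    lo, hi = SCALE_RANGES[scale]
    if not lo <= threshold <= hi:
        raise ValidationError(f"threshold {threshold} outside [{lo}, {hi}]")
    return LabelTable(
        {s.participant_id: int(s.on_scale(scale) > threshold) for s in scores},
        provenance="jaws",
    )


def positivity_ratio(mean_pos: float, mean_neg: float) -> float:
    """Losada-style positivity ratio: mean positive over mean negative affect."""
    if mean_neg <= 0:
        raise ValidationError("mean_neg must be > 0")
    return mean_pos / mean_neg
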