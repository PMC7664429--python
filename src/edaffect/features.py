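"""GSR event detection and the per-segment feature battery.

A skin-conductance response (GSR/SCR) is detected as a positive local maximum
in the first difference of the phasic component; the event's amplitude is the
phasic value at the next phasic local maximum, and events above 1.5 µS count
as *significant*. On top of the event features, each segment gets a battery
of distributional, regression-line and entropy descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocessing import Segment, TonicPhasic

SIGNIFICANCE_THRESHOLD_US = 1.5
#: Conventional minimum SCR amplitude; deflections below this are treated as
#: noise rather than events.
MIN_AMPLITUDE_US = 0.05
ENTROPY_BINS = 16

#: Canonical feature order: distributional statistics, higher moments,
#: signal/regression descriptors, then the GSR event block.
FEATURE_NAMES: tuple[str, ...] = (
    "mean", "standard_deviation", "median", "variance", "p25", "p75",
    "quartile_deviation", "minimum", "maximum", "moment4", "moment5",
    "skewness", "kurtosis", "rms", "total_sum", "entropy",
    "reg_slope", "reg_intercept", "reg_mean_abs_residual", "reg_rmse",
    "n_crossings",
    "n_gsr", "rpm", "gsr_energy", "n_sig_gsr", "sig_gsr_energy",
)


@dataclass(frozen=True)
class GSREvent:
    """One detected skin-conductance response."""

    trigger_index: int   # local maximum of the phasic first difference
    peak_index: int      # following phasic local maximum (or last sample)
    amplitude: float     # µS, phasic value at peak_index
    energy: float        # µS², squared peak amplitude
    significant: bool    # amplitude > 1.5 µS

    def __post_init__(self) -> None:
        if self.trigger_index > self.peak_index:
            raise ValidationError("trigger_index must not exceed peak_index")
        if self.amplitude <= 0:
            raise ValidationError("event amplitude must be positive")


@dataclass(frozen=True)
class FeatureMatrix:
    """Participants × named features for one exercise."""

    data: pd.DataFrame  # index = participant_id, columns = feature names
    exercise_id: int | None = None

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate feature names")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate participant ids")
        if self.data.isna().any().any():
            raise ValidationError("feature matrix must have no missing cells")

    @property
    def participants(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValidationError(f"features not present: {missing}")
        return FeatureMatrix(self.data.loc[:, list(names)], self.exercise_id)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.data.rename_axis("participant_id").to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, exercise_id: int | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="participant_id")
        df.index = df.index.astype(str)
        return cls(df, exercise_id)


def _local_maxima(a: np.ndarray) -> list[int]:
    """Interior local maxima; a plateau counts once, at its first sample."""
    out = []
    n = len(a)
    for i in range(1, n - 1):
        if a[i] > a[i - 1]:
            j = i + 1
            while j < n and a[j] == a[i]:
                j += 1
            if j < n and a[j] < a[i]:
                out.append(i)
    return out


def detect_gsr_events(
    phasic: np.ndarray,
    fs: float,
    sig_threshold: float = SIGNIFICANCE_THRESHOLD_US,
    min_amplitude: float = MIN_AMPLITUDE_US,
) -> list[GSREvent]:
    """Detect GSR events on a phasic trace.

    Triggers are strict interior local maxima of the first-difference
    sequence with positive value; the event peak is the first subsequent
    phasic local maximum (the last sample if the trace ends rising). Events
    whose peak amplitude does not exceed ``min_amplitude`` (the conventional
    SCR floor, 0.05 µS by default; pass 0 to count every positive
    deflection) are discarded as noise.
    """
    phasic = np.asarray(phasic, dtype=float)
    n = len(phasic)
    if n < 3:
        raise ValidationError(f"need at least 3 samples, got {n}")
    deriv = np.diff(phasic)
    triggers = [i for i in _local_maxima(deriv) if deriv[i] > 0]
    peaks = _local_maxima(phasic)
    events = []
    for trig in triggers:
        peak = next((p for p in peaks if p > trig), n - 1)
        amp = phasic[peak]
        if amp <= 0 or amp < min_amplitude:
            continue
        events.append(
            GSREvent(trig, peak, float(amp), float(amp**2), bool(amp > sig_threshold))
        )
    return events


def gsr_features(events: Sequence[GSREvent], duration: float) -> dict[str, float]:
    """Aggregate event counts, rate per minute, and energies over a segment."""
    if duration <= 0:
        raise ValidationError(f"duration must be > 0, got {duration}")
    sig = [e for e in events if e.significant]
    return {
        "n_gsr": float(len(events)),
        "rpm": len(events) * 60.0 / duration,
        "gsr_energy": float(sum(e.energy for e in events)),
        "n_sig_gsr": float(len(sig)),
        "sig_gsr_energy": float(sum(e.energy for e in sig)),
    }


def _shannon_entropy(x: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    lo, hi = x.min(), x.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / len(x)
    return float(-(p * np.log2(p)).sum())


def statistical_features(samples: np.ndarray) -> dict[str, float]:
    """Compute the distributional / regression / entropy feature block.

    Conventions: sample (n−1) variance and SD; percentiles by linear
    interpolation; 4th/5th central moments and population skewness/kurtosis
    (kurtosis non-excess, 3 for a Gaussian); Shannon entropy (base 2) of a
    16-bin histogram over [min, max]; regression features from OLS of the
    samples against sample index; ``n_crossings`` counts residual sign
    changes. A constant segment takes skewness = kurtosis = entropy = 0.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 4:
        raise ValidationError(f"need at least 4 samples, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    centred = x - mean
    m2 = float((centred**2).mean())
    m3 = float((centred**3).mean())
    m4 = float((centred**4).mean())
    m5 = float((centred**5).mean())
    if m2 > 0:
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2  # non-excess
    else:
        skewness = kurtosis = 0.0
    p25, p75 = np.percentile(x, [25, 75])
    t = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    resid = x - (slope * t + intercept)
    signs = np.sign(resid)
    signs = signs[signs != 0]
    n_crossings = int(np.sum(signs[1:] != signs[:-1])) if signs.size else 0
    return {
        "mean": mean,
        "standard_deviation": sd,
        "median": float(np.median(x)),
        "variance": float(x.var(ddof=1)),
        "p25": float(p25),
        "p75": float(p75),
        "quartile_deviation": float((p75 - p25) / 2.0),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "moment4": m4,
        "moment5": m5,
        "skewness": float(skewness),
        "kurtosis": float(kurtosis),
        "rms": float(np.sqrt((x**2).mean())),
        "total_sum": float(x.sum()),
        "entropy": _shannon_entropy(x),
        "reg_slope": float(slope),
        "reg_intercept": float(intercept),
        "reg_mean_abs_residual": float(np.abs(resid).mean()),
        "reg_rmse": float(np.sqrt((resid**2).mean())),
        "n_crossings": float(n_crossings),
    }


def feature_vector(
    segment: Segment,
    decomposition: TonicPhasic,
    events: Sequence[GSREvent],
) -> dict[str, float]:
    """Full 26-value feature map for one participant-exercise segment."""
    out = statistical_features(segment.samples)
    out.update(gsr_features(events, segment.duration))
    return {name: out[name] for name in FEATURE_NAMES}


def extract_feature_matrix(
    cohort: Sequence[tuple[Segment, TonicPhasic, Sequence[GSREvent]]],
) -> FeatureMatrix:
    """Stack per-participant feature vectors for one exercise."""
    if not cohort:
        raise ValidationError("cannot build a feature matrix from an empty cohort")
    exercise_ids = {seg.exercise_id for seg, _, _ in cohort}
    if len(exercise_ids) != 1:
        raise ValidationError(f"mixed exercise ids: {sorted(exercise_ids)}")
    ids = [seg.participant_id for seg, _, _ in cohort]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate participant in cohort")
    rows = [feature_vector(seg, tp, ev) for seg, tp, ev in cohort]
    df = pd.DataFrame(rows, index=pd.Index(ids, name="participant_id"),
                      columns=list(FEATURE_NAMES))
    return FeatureMatrix(df, exercise_id=exercise_ids.pop())
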