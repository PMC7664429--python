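"""Segmentation, wavelet denoising and tonic/phasic decomposition.

The analysis cuts each recording into exercise segments at the wristband's
event markers, denoises with a Symlet wavelet whose decomposition depth is
capped as ``floor(log2 n)`` but never more than 10 levels, and splits each
segment into a slow tonic trend plus a fast phasic remainder. Skin
conductance responses are later detected on the phasic component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ValidationError
from .io import EDASession

LEVEL_CAP = 10

LINEAR = "linear"
MOVING_MEDIAN = "moving_median"


@dataclass(frozen=True)
class Segment:
    """One exercise window of a session."""

    participant_id: str
    exercise_id: int
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.exercise_id < 1:
            raise ValidationError(f"exercise_id must be >= 1, got {self.exercise_id}")
        if self.samples.size == 0:
            raise ValidationError("segment must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("segment samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Segment":
        return Segment(self.participant_id, self.exercise_id, self.fs, samples)


@dataclass(frozen=True)
class TonicPhasic:
    """Additive split of a segment: ``tonic + phasic == samples``."""

    tonic: np.ndarray
    phasic: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if len(self.tonic) != len(self.phasic):
            raise ValidationError("tonic and phasic must have equal length")


def segment_by_markers(session: EDASession) -> list[Segment]:
    """Cut a session into exercise segments at begin/end marker pairs.

    Markers must come in consecutive (begin, end) pairs in protocol order;
    the sample window is half-open, ``begin <= t < end`` with sample ``i``
    at ``start_time + i/fs``.
    """
    markers = session.markers
    if len(markers) % 2 != 0:
        raise ValidationError(
            f"markers must form begin/end pairs, got odd count {len(markers)}"
        )
    segments = []
    for k in range(0, len(markers), 2):
        begin, end = markers[k], markers[k + 1]
        if end < begin:
            raise ValidationError(f"pair {k // 2 + 1}: end {end} before begin {begin}")
        i0 = int(np.ceil((begin - session.start_time) * session.fs - 1e-9))
        i1 = int(np.ceil((end - session.start_time) * session.fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, len(session.samples))
        if i1 <= i0:
            raise ValidationError(f"pair {k // 2 + 1}: empty sample window")
        segments.append(
            Segment(session.participant_id, k // 2 + 1, session.fs,
                    session.samples[i0:i1])
        )
    return segments


def max_decomposition_level(n: int) -> int:
    """Deepest admissible wavelet level for a segment of ``n`` samples.

    ``floor(log2 n)`` when that is below 10, otherwise the cap 10. A level
    must be a whole number, hence the floor for non-powers of two.
    """
    if n < 2:
        raise ValidationError(f"need at least 2 samples, got {n}")
    level = int(np.floor(np.log2(n)))
    # guard against float underestimation at exact powers of two
    while 2 ** (level + 1) <= n:
        level += 1
    if 2 ** level > n:
        level -= 1
    return min(level, LEVEL_CAP)


def wavelet_denoise(
    segment: Segment, wavelet_name: str = "sym4", level: int | None = None
) -> Segment:
    """Symlet wavelet denoising with per-level universal soft thresholds.

    Each detail band is soft-thresholded at ``sigma_j * sqrt(2 ln n_j)`` where
    ``sigma_j`` is the robust MAD noise estimate of that band. The level
    defaults to (and may never exceed) :func:`max_decomposition_level`.
    """
    if not wavelet_name.startswith("sym"):
        raise ValidationError(f"expected a Symlet wavelet, got {wavelet_name!r}")
    x = segment.samples
    n = len(x)
    cap = max_decomposition_level(n)
    if level is None:
        level = cap
    if level > cap:
        raise ValidationError(f"level {level} exceeds cap {cap} for n={n}")
    if level < 1:
        raise ValidationError("level must be >= 1")
    wavelet = pywt.Wavelet(wavelet_name)
    if n < wavelet.dec_len:
        raise ValidationError(
            f"segment of {n} samples shorter than {wavelet_name} support "
            f"({wavelet.dec_len})"
        )
    # pywt caps usable depth by filter length; respect both caps
    level = min(level, pywt.dwt_max_level(n, wavelet.dec_len))
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        if detail.size == 0:
            out.append(detail)
            continue
        sigma = np.median(np.abs(detail)) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(max(detail.size, 2)))
        out.append(pywt.threshold(detail, thr, mode="soft"))
    rec = pywt.waverec(out, wavelet, mode="symmetric")[:n]
    return segment.with_samples(rec)


def decompose_tonic_phasic(
    segment: Segment, method: str = LINEAR, window: float = 4.0
) -> TonicPhasic:
    """Split a segment into tonic trend and phasic remainder.

    ``linear`` fits an ordinary least-squares line over the segment (the
    trend the slope features are built on); ``moving_median`` uses a centred
    rolling median of ``window`` seconds. Either way ``phasic = samples −
    tonic`` so the reconstruction is exact.
    """
    x = segment.samples
    n = len(x)
    if method == LINEAR:
        t = np.arange(n, dtype=float)
        if n == 1:
            tonic = x.copy()
        else:
            slope, intercept = np.polyfit(t, x, 1)
            tonic = slope * t + intercept
    elif method == MOVING_MEDIAN:
        w = int(round(window * segment.fs))
        if w < 2:
            raise ValidationError(f"window of {window}s is under 2 samples at fs={segment.fs}")
        if w > n:
            raise ValidationError(f"window of {w} samples longer than segment ({n})")
        half = w // 2
        tonic = np.empty(n)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            tonic[i] = np.median(x[lo:hi])
    else:
        raise ValidationError(f"unknown decomposition method {method!r}")
    return TonicPhasic(tonic=tonic, phasic=x - tonic, method=method)
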