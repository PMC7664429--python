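"""Readers and writers for the Empatica-E4 CSV dialect, JAWS tables and label files.

The EDA dialect is the wristband's documented export: line 1 is the session
start time (seconds since epoch), line 2 the sampling rate in Hz, and every
following line one skin-conductance sample in microsiemens. Event markers
("tags") live in a companion CSV with one epoch timestamp per line.

JAWS responses are one row per participant with twelve Likert items in 1..5;
item polarity (which six items are positively and which negatively keyed) is
supplied by the caller, typically from a YAML config.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ValidationError

POSITIVE = "positive"
NEGATIVE = "negative"

#: Item polarity used by the synthetic generator and as a documented default:
#: items 1-6 positively keyed, items 7-12 negatively keyed.
DEFAULT_POSITIVE_ITEMS: tuple[int, ...] = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class EDASession:
    """One participant's conductance trace with sample rate and markers.

    Sample ``i`` occurs at ``start_time + i / fs`` (sample-start convention).
    Markers are epoch seconds and must fall inside the recording.
    """

    participant_id: str
    start_time: float
    fs: float
    samples: np.ndarray
    markers: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if self.samples.size == 0:
            raise ValidationError("samples must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must all be finite")
        mk = tuple(float(m) for m in self.markers)
        object.__setattr__(self, "markers", mk)
        if any(b < a for a, b in zip(mk, mk[1:])):
            raise ValidationError("markers must be non-decreasing")
        end = self.start_time + len(self.samples) / self.fs
        for m in mk:
            if not (self.start_time <= m <= end):
                raise ValidationError(
                    f"marker {m} outside recording [{self.start_time}, {end}]"
                )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def with_markers(self, markers: Sequence[float]) -> "EDASession":
        return replace(self, markers=tuple(float(m) for m in markers))


@dataclass(frozen=True)
class JAWSResponses:
    """Raw 12-item Likert row for one participant plus item polarity.

    ``items`` maps positionally to item indices 1..12; ``polarity`` assigns
    each index "positive" or "negative", exactly six of each.
    """

    participant_id: str
    items: tuple[int, ...]
    polarity: Mapping[int, str]

    def __post_init__(self) -> None:
        items = tuple(int(v) for v in self.items)
        object.__setattr__(self, "items", items)
        if len(items) != 12:
            raise ValidationError(
                f"{self.participant_id}: expected 12 items, got {len(items)}"
            )
        for i, v in enumerate(items, start=1):
            if not 1 <= v <= 5:
                raise ValidationError(
                    f"{self.participant_id}: item {i} value {v} outside 1..5"
                )
        pol = dict(self.polarity)
        object.__setattr__(self, "polarity", pol)
        if sorted(pol) != list(range(1, 13)):
            raise ValidationError("polarity must cover item indices 1..12")
        n_pos = sum(1 for v in pol.values() if v == POSITIVE)
        n_neg = sum(1 for v in pol.values() if v == NEGATIVE)
        if n_pos != 6 or n_neg != 6:
            raise ValidationError(
                f"polarity must have 6 positive and 6 negative items, got {n_pos}/{n_neg}"
            )


@dataclass(frozen=True)
class LabelTable:
    """Binary class labels per participant with provenance."""

    labels: Mapping[str, int]
    provenance: str  # cluster | jaws | expert | truth

    _PROVENANCES = frozenset({"cluster", "jaws", "expert", "truth"})

    def __post_init__(self) -> None:
        lab = {str(k): int(v) for k, v in dict(self.labels).items()}
        object.__setattr__(self, "labels", lab)
        if any(v not in (0, 1) for v in lab.values()):
            raise ValidationError("labels must be binary (0/1)")
        if self.provenance not in self._PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def participants(self) -> list[str]:
        return list(self.labels)

    def aligned_with(self, other: "LabelTable") -> None:
        if set(self.labels) != set(other.labels):
            raise AlignmentError("participant sets differ between label tables")


def polarity_from_positive_items(positive_items: Iterable[int]) -> dict[int, str]:
    """Build a full polarity map from the six positively keyed item indices."""
    pos = {int(i) for i in positive_items}
    if not pos <= set(range(1, 13)) or len(pos) != 6:
        raise ValidationError("positive_items must be 6 distinct indices in 1..12")
    return {i: (POSITIVE if i in pos else NEGATIVE) for i in range(1, 13)}


# ---------------------------------------------------------------------------
# EDA / tags


def _parse_float(token: str, path: Path, lineno: int, what: str) -> float:
    try:
        # E4 exports occasionally carry a trailing comma on header lines
        return float(token.strip().rstrip(",").split(",")[0])
    except ValueError:
        raise FormatError(f"{path}: line {lineno}: cannot parse {what}: {token!r}")


def read_eda_csv(path: str | Path, participant_id: str | None = None) -> EDASession:
    """Read one EDA recording in the E4 dialect.

    Header line 1 = start epoch seconds, line 2 = sampling rate (Hz), then one
    µS value per line. The participant id defaults to the parent directory
    name (the E4 export layout keeps one directory per session).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise FormatError(f"{path}: expected a 2-line header (start time, fs)")
    start_time = _parse_float(lines[0], path, 1, "start timestamp")
    fs = _parse_float(lines[1], path, 2, "sampling rate")
    if fs <= 0:
        raise FormatError(f"{path}: line 2: sampling rate must be > 0, got {fs}")
    data = lines[2:]
    if not data:
        raise FormatError(f"{path}: no data lines after header")
    samples = np.empty(len(data))
    for i, ln in enumerate(data):
        samples[i] = _parse_float(ln, path, i + 3, "sample")
    if participant_id is None:
        participant_id = path.parent.name or path.stem
    return EDASession(participant_id, start_time, fs, samples)


def write_eda_csv(session: EDASession, path: str | Path) -> None:
    """Serialise a session in the E4 dialect at full float precision."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{session.start_time!r}\n{session.fs!r}\n")
        for v in session.samples:
            fh.write(f"{float(v)!r}\n")


def read_tags_csv(path: str | Path) -> list[float]:
    """Read event-marker timestamps (one epoch-second value per line)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        warnings.warn(f"{path}: no markers found", stacklevel=2)
        return []
    out = [_parse_float(ln, path, i + 1, "marker") for i, ln in enumerate(lines)]
    if any(b < a for a, b in zip(out, out[1:])):
        raise FormatError(f"{path}: marker timestamps must be non-decreasing")
    return out


def write_tags_csv(markers: Sequence[float], path: str | Path) -> None:
    Path(path).write_text("".join(f"{float(m)!r}\n" for m in markers))


def read_session_dir(path: str | Path) -> EDASession:
    """Read ``EDA.csv`` + ``tags.csv`` from one session directory."""
    path = Path(path)
    session = read_eda_csv(path / "EDA.csv", participant_id=path.name)
    markers = read_tags_csv(path / "tags.csv")
    return session.with_markers(markers)


# ---------------------------------------------------------------------------
# JAWS / labels


def read_jaws_csv(
    path: str | Path, polarity: Mapping[int, str]
) -> list[JAWSResponses]:
    """Read a JAWS table with header ``participant_id,item1..item12``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    expected = ["participant_id"] + [f"item{i}" for i in range(1, 13)]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    out = []
    for _, row in df.iterrows():
        pid = row["participant_id"]
        items = []
        for i in range(1, 13):
            v = row[f"item{i}"]
            if not (isinstance(v, (int, np.integer)) or float(v).is_integer()):
                raise FormatError(f"{path}: {pid}: item{i} is not an integer: {v}")
            items.append(int(v))
        try:
            out.append(JAWSResponses(pid, tuple(items), polarity))
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return out


def write_jaws_csv(responses: Sequence[JAWSResponses], path: str | Path) -> None:
    rows = [
        {"participant_id": r.participant_id,
         **{f"item{i}": r.items[i - 1] for i in range(1, 13)}}
        for r in responses
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels_csv(path: str | Path, provenance: str) -> LabelTable:
    """Read a ``participant_id,label`` table of binary labels."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    if list(df.columns) != ["participant_id", "label"]:
        raise FormatError(f"{path}: expected columns participant_id,label")
    if df["participant_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate participant ids")
    labels = dict(zip(df["participant_id"], df["label"].astype(int)))
    return LabelTable(labels, provenance)


def write_labels_csv(table: LabelTable, path: str | Path) -> None:
    pd.DataFrame(
        {"participant_id": list(table.labels), "label": list(table.labels.values())}
    ).to_csv(path, index=False)
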