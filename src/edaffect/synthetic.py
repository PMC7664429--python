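"""Synthetic cohorts of paired EDA sessions and JAWS responses.

The generator emulates the study conditions the pipeline was designed for:
41 participants, a 4 Hz wristband trace covering three exercises of 60, 10
and 10 seconds (with begin/end markers), and a 12-item Likert questionnaire.
Each participant carries a latent binary emotion class that drives both the
skin-conductance-response rate/amplitude and the questionnaire answers, so
label-recovery experiments have a ground truth.

Signal model per session::

    eda(t) = baseline + drift * t + sum_k A_k * h(t - t_k) + noise(t)

with Poisson event times ``t_k``, lognormal peak amplitudes ``A_k`` and a
Bateman-type biexponential kernel ``h`` (rise 0.75 s, decay 4 s) normalised
to unit peak, the standard SCR shape. A ``separation`` dial interpolates the
two classes' parameters toward their common mean: 1 reproduces the default
(strong) contrast, 0 makes the classes indistinguishable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io import (
    DEFAULT_POSITIVE_ITEMS,
    EDASession,
    JAWSResponses,
    LabelTable,
    polarity_from_positive_items,
    write_eda_csv,
    write_jaws_csv,
    write_labels_csv,
    write_tags_csv,
)

#: class 0 = negative-dominant / high arousal, class 1 = positive-dominant / low arousal
CLASS_NEGATIVE, CLASS_POSITIVE = 0, 1


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level generator parameters (defaults = study conditions)."""

    n_participants: int = 41
    fs: float = 4.0
    exercise_durations: tuple[float, ...] = (60.0, 10.0, 10.0)
    class_proportions: tuple[float, float] = (0.5, 0.5)
    #: SCR events per minute, (class 0, class 1)
    scr_rates_per_min: tuple[float, float] = (8.0, 1.0)
    #: median SCR peak amplitude in µS, (class 0, class 1); lognormal sigma below
    scr_amplitudes_us: tuple[float, float] = (2.0, 0.5)
    amplitude_sigma: float = 0.4
    tonic_baseline_us: tuple[float, float] = (2.0, 6.0)   # uniform range
    drift_slope_us_per_s: tuple[float, float] = (-0.002, 0.008)
    noise_sd_us: float = 0.02
    kernel_rise_s: float = 0.75
    kernel_decay_s: float = 4.0
    pad_s: float = 10.0       # lead-in/out around the exercise block
    rest_s: float = 5.0       # gap between exercises
    #: JAWS latent-trait class means (class 0, class 1), scaled by separation
    jaws_class_means: tuple[float, float] = (-1.0, 1.0)
    jaws_trait_sd: float = 0.5
    item_trait_correlation: float = 0.8
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValidationError("need at least 2 participants")
        if self.fs <= 0 or self.noise_sd_us < 0:
            raise ValidationError("fs must be > 0 and noise SD >= 0")
        if any(d <= 0 for d in self.exercise_durations):
            raise ValidationError("exercise durations must be positive")
        if any(r <= 0 for r in self.scr_rates_per_min) or any(
            a <= 0 for a in self.scr_amplitudes_us
        ):
            raise ValidationError("SCR rates and amplitudes must be positive")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValidationError("class proportions must sum to 1")
        if not 0 <= self.item_trait_correlation <= 1:
            raise ValidationError("item_trait_correlation must be in [0, 1]")
        if self.kernel_rise_s <= 0 or self.kernel_decay_s <= self.kernel_rise_s:
            raise ValidationError("need 0 < rise < decay time constants")

    # --- class parameters after applying the separation dial -------------
    def _blend(self, pair: tuple[float, float], class_id: int) -> float:
        centre = (pair[0] + pair[1]) / 2.0
        return centre + self.separation * (pair[class_id] - centre)

    def rate_per_min(self, class_id: int) -> float:
        return max(self._blend(self.scr_rates_per_min, class_id), 1e-6)

    def amplitude_us(self, class_id: int) -> float:
        return max(self._blend(self.scr_amplitudes_us, class_id), 1e-6)

    def jaws_mean(self, class_id: int) -> float:
        return self.separation * self.jaws_class_means[class_id]


@dataclass(frozen=True)
class SynthCohort:
    sessions: list[EDASession]
    responses: list[JAWSResponses]
    truth: LabelTable
    config: SynthConfig

    def __post_init__(self) -> None:
        ids = [s.participant_id for s in self.sessions]
        if ids != [r.participant_id for r in self.responses] or set(ids) != set(
            self.truth.labels
        ):
            raise ValidationError("sessions, responses and truth must share ids")


def scr_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Biexponential SCR shape normalised to unit peak; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    raw = np.where(t >= 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return raw / peak


def simulate_session(
    participant_id: str, class_id: int, cfg: SynthConfig, rng: np.random.Generator
) -> EDASession:
    """One wristband recording: tonic ramp + Poisson SCR train + noise.

    Markers are begin/end pairs for each configured exercise, separated by
    rest gaps and padded at both ends.
    """
    total = cfg.pad_s + sum(cfg.exercise_durations) + \
        cfg.rest_s * (len(cfg.exercise_durations) - 1) + cfg.pad_s
    n = int(round(total * cfg.fs))
    t = np.arange(n) / cfg.fs
    baseline = rng.uniform(*cfg.tonic_baseline_us)
    drift = rng.uniform(*cfg.drift_slope_us_per_s)
    x = baseline + drift * t

    rate_per_s = cfg.rate_per_min(class_id) / 60.0
    n_events = rng.poisson(rate_per_s * total)
    event_times = np.sort(rng.uniform(0.0, total, size=n_events))
    median_amp = cfg.amplitude_us(class_id)
    amps = rng.lognormal(mean=np.log(median_amp), sigma=cfg.amplitude_sigma,
                         size=n_events)
    for t_k, a_k in zip(event_times, amps):
        x += a_k * scr_kernel(t - t_k, cfg.kernel_rise_s, cfg.kernel_decay_s)

    if cfg.noise_sd_us > 0:
        x += rng.normal(0.0, cfg.noise_sd_us, size=n)
    x = np.maximum(x, 0.01)  # conductance stays positive

    start_time = 1_600_000_000.0
    markers = []
    cursor = cfg.pad_s
    for dur in cfg.exercise_durations:
        markers += [start_time + cursor, start_time + cursor + dur]
        cursor += dur + cfg.rest_s
    return EDASession(participant_id, start_time, cfg.fs, x, tuple(markers))


def simulate_jaws(
    participant_id: str, class_id: int, cfg: SynthConfig, rng: np.random.Generator
) -> JAWSResponses:
    """Item responses from a one-factor latent-trait model.

    The latent trait is the class mean plus Gaussian noise; each item mixes
    the trait with item noise at the configured correlation (negative items
    load on the negated trait) and is discretised through equal-width cuts
    at −1.5, −0.5, 0.5, 1.5 onto the 1..5 Likert scale.
    """
    trait = cfg.jaws_mean(class_id) + rng.normal(0.0, cfg.jaws_trait_sd)
    rho = cfg.item_trait_correlation
    polarity = polarity_from_positive_items(DEFAULT_POSITIVE_ITEMS)
    cuts = np.array([-1.5, -0.5, 0.5, 1.5])
    items = []
    for i in range(1, 13):
        loading = trait if polarity[i] == "positive" else -trait
        y = rho * loading + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal()
        items.append(int(np.searchsorted(cuts, y) + 1))
    return JAWSResponses(participant_id, tuple(items), polarity)


def simulate_cohort(cfg: SynthConfig) -> SynthCohort:
    """Full cohort: sessions, questionnaire rows and ground-truth labels."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    n_pos = int(np.floor(cfg.class_proportions[CLASS_POSITIVE] * n + 0.5))
    classes = np.array([CLASS_POSITIVE] * n_pos +
                       [CLASS_NEGATIVE] * (n - n_pos))
    rng.shuffle(classes)
    ids = [f"P{i + 1:03d}" for i in range(n)]
    sessions, responses, truth = [], [], {}
    for pid, cls in zip(ids, classes):
        sessions.append(simulate_session(pid, int(cls), cfg, rng))
        responses.append(simulate_jaws(pid, int(cls), cfg, rng))
        truth[pid] = int(cls)
    return SynthCohort(sessions, responses, LabelTable(truth, "truth"), cfg)


def write_cohort(cohort: SynthCohort, out_dir: str | Path) -> None:
    """Write the directory tree the readers expect.

    ``P###/EDA.csv`` + ``P###/tags.csv`` per participant, plus ``jaws.csv``,
    ``truth.csv`` and ``synth_meta.json`` recording every generator
    parameter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for session in cohort.sessions:
        d = out / session.participant_id
        d.mkdir(exist_ok=True)
        write_eda_csv(session, d / "EDA.csv")
        write_tags_csv(session.markers, d / "tags.csv")
    write_jaws_csv(cohort.responses, out / "jaws.csv")
    write_labels_csv(cohort.truth, out / "truth.csv")
    meta = asdict(cohort.config)
    (out / "synth_meta.json").write_text(json.dumps(meta, indent=2))
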