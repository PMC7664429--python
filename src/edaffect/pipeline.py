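"""End-to-end orchestration: ingest → preprocess → features → select →
cluster → score → evaluate, driven by a strict YAML config.

Every run is deterministic for a fixed seed, and each JSON artefact embeds
the SHA-256 hash of the canonicalised config that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import clustering, evaluation, jaws as jaws_mod, preprocessing, selection
from .errors import ValidationError
from .features import FeatureMatrix, detect_gsr_events, extract_feature_matrix
from .io import (
    EDASession,
    LabelTable,
    polarity_from_positive_items,
    read_jaws_csv,
    read_labels_csv,
    read_session_dir,
)

logger = logging.getLogger("edaffect")

_SCHEMA: dict[str, set[str]] = {
    "": {"paths", "preprocessing", "features", "selection", "clustering",
         "jaws", "evaluation", "seed", "output_dir"},
    "paths": {"sessions_dir", "jaws_file", "expert_labels_file", "positive_items"},
    "preprocessing": {"wavelet", "denoise", "decomposition"},
    "preprocessing.decomposition": {"method", "window_s"},
    "preprocessing.denoise": {"enabled"},
    "features": {"sig_threshold", "statistics_on"},
    "selection": {"cv_threshold", "wcss_threshold", "wcss_top_k", "preset",
                  "standardize"},
    "clustering": {"methods", "linkage", "polarity_rule"},
    "jaws": {"scale", "threshold"},
    "evaluation": {"pca", "feature_sets"},
}

DEFAULTS: dict[str, Any] = {
    "preprocessing": {
        "wavelet": "sym4",
        "denoise": {"enabled": True},
        "decomposition": {"method": "linear", "window_s": 4.0},
    },
    "features": {"sig_threshold": 1.5, "statistics_on": "raw"},
    "selection": {"cv_threshold": 0.5, "wcss_top_k": 13},
    "clustering": {"methods": list(clustering.ALL_METHODS), "linkage": "average",
                   "polarity_rule": clustering.BEST_MATCH},
    "jaws": {"scale": "total", "threshold": "auto"},
    "evaluation": {"pca": [False, True], "feature_sets": ["all"]},
    "seed": 0,
}


def _check_keys(mapping: dict, section: str) -> None:
    allowed = _SCHEMA[section]
    for key in mapping:
        if key not in allowed:
            where = section or "top level"
            raise ValidationError(f"unknown config key {key!r} in {where}")
        sub = f"{section}.{key}" if section else key
        if sub in _SCHEMA and isinstance(mapping[key], dict):
            _check_keys(mapping[key], sub)


def _merge(defaults: Any, user: Any) -> Any:
    if isinstance(defaults, dict) and isinstance(user, dict):
        out = dict(defaults)
        for k, v in user.items():
            out[k] = _merge(defaults.get(k), v)
        return out
    return user if user is not None else defaults


def load_config(path: str | Path) -> dict:
    """Read and validate a pipeline config, merging in defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError("config must be a YAML mapping")
    _check_keys(raw, "")
    if "paths" not in raw or "sessions_dir" not in raw["paths"]:
        raise ValidationError("config must set paths.sessions_dir")
    cfg = _merge(DEFAULTS, raw)
    cfg.setdefault("output_dir", "edaffect_out")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def compute_features(
    sessions: Sequence[EDASession],
    wavelet: str = "sym4",
    denoise: bool = True,
    decomposition_method: str = "linear",
    window_s: float = 4.0,
    sig_threshold: float = 1.5,
    statistics_on: str = "raw",
) -> dict[int, FeatureMatrix]:
    """Per-exercise feature matrices for a cohort of marked sessions.

    Statistical features are computed on the raw segment by default
    (``statistics_on="denoised"`` switches them to the denoised one); GSR
    events are always detected on the phasic component of the (optionally
    denoised) segment.
    """
    if statistics_on not in ("raw", "denoised"):
        raise ValidationError(f"statistics_on must be raw|denoised, got {statistics_on!r}")
    per_exercise: dict[int, list] = {}
    for session in sessions:
        for seg in preprocessing.segment_by_markers(session):
            work = preprocessing.wavelet_denoise(seg, wavelet) if denoise else seg
            tp = preprocessing.decompose_tonic_phasic(
                work, method=decomposition_method, window=window_s
            )
            events = detect_gsr_events(tp.phasic, seg.fs, sig_threshold)
            stats_seg = work if statistics_on == "denoised" else seg
            per_exercise.setdefault(seg.exercise_id, []).append(
                (stats_seg, tp, events)
            )
    return {
        ex: extract_feature_matrix(cohort)
        for ex, cohort in sorted(per_exercise.items())
    }


def select_features(
    matrix: FeatureMatrix, cfg: dict
) -> tuple[FeatureMatrix, selection.SelectionReport, selection.SelectionReport]:
    """Apply the preset or the CV → WCSS cascade per the selection config."""
    preset = cfg.get("preset")
    if preset:
        reduced = selection.preset_set(matrix, preset)
        dummy = selection.SelectionReport(
            cv={}, wcss={}, kept={n: True for n in reduced.feature_names},
            reason={n: selection.KEPT for n in reduced.feature_names},
        )
        return reduced, dummy, dummy
    after_cv, cv_report = selection.cv_filter(matrix, cfg["cv_threshold"])
    after_wcss, wcss_report = selection.wcss_filter(
        after_cv,
        threshold=cfg.get("wcss_threshold"),
        top_k=cfg.get("wcss_top_k") if cfg.get("wcss_threshold") is None else None,
        standardize=bool(cfg.get("standardize", False)),
    )
    return after_wcss, cv_report, wcss_report


def label_recovery_accuracy(
    seed: int,
    separation: float = 1.0,
    exercise: int = 1,
    n_participants: int = 41,
) -> float:
    """Ground-truth recovery accuracy of the default pipeline on one cohort.

    Simulates a cohort at the given class separation, extracts features for
    the chosen exercise (the 60 s first exercise by default, which carries
    most of the event-rate signal), applies the default CV → WCSS selection,
    PCA, k-means, and scores best-match accuracy against the latent classes.
    """
    from . import synthetic
    from .clustering import assign_polarity, kmeans_two_clusters
    from .evaluation import confusion, metrics

    cohort = synthetic.simulate_cohort(
        synthetic.SynthConfig(n_participants=n_participants,
                              separation=separation, seed=seed)
    )
    matrices = compute_features(cohort.sessions)
    reduced, _, _ = select_features(
        matrices[exercise], {"cv_threshold": 0.5, "wcss_top_k": 13}
    )
    rotated = selection.pca_transform(reduced)
    result = kmeans_two_clusters(rotated, seed=seed)
    result = assign_polarity(result, cohort.truth)
    acc, _, _ = metrics(confusion(result.as_label_table(), cohort.truth))
    return acc


def run(config_path: str | Path) -> Path:
    """Execute the full pipeline; returns the output directory."""
    cfg = load_config(config_path)
    chash = config_hash(cfg)
    seed = int(cfg["seed"])
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logger.info("config %s (hash %s), seed %d", config_path, chash, seed)

    paths = cfg["paths"]
    base = Path(config_path).parent
    sessions_dir = (base / paths["sessions_dir"]).resolve() \
        if not Path(paths["sessions_dir"]).is_absolute() else Path(paths["sessions_dir"])
    session_dirs = sorted(
        p for p in sessions_dir.iterdir()
        if p.is_dir() and (p / "EDA.csv").exists()
    )
    sessions = [read_session_dir(p) for p in session_dirs]
    if not sessions:
        raise ValidationError(f"no session directories under {sessions_dir}")
    logger.info("read %d sessions", len(sessions))

    pre = cfg["preprocessing"]
    matrices = compute_features(
        sessions,
        wavelet=pre["wavelet"],
        denoise=bool(pre["denoise"]["enabled"]),
        decomposition_method=pre["decomposition"]["method"],
        window_s=float(pre["decomposition"]["window_s"]),
        sig_threshold=float(cfg["features"]["sig_threshold"]),
        statistics_on=cfg["features"]["statistics_on"],
    )

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    polarity_items = paths.get("positive_items", list(range(1, 7)))
    polarity = polarity_from_positive_items(polarity_items)
    responses = read_jaws_csv(_resolve(paths["jaws_file"]), polarity)
    scores = jaws_mod.score_cohort(responses)
    jaws_mod.write_scores_csv(scores, out / "jaws_scores.csv")

    scale = cfg["jaws"]["scale"]
    threshold_cfg = cfg["jaws"]["threshold"]
    values = [s.on_scale(scale) for s in scores]
    ids = [s.participant_id for s in scores]
    if threshold_cfg == "auto":
        jaws_labels, threshold = jaws_mod.reference_labels(values, ids)
    else:
        threshold = float(threshold_cfg)
        jaws_labels = jaws_mod.dichotomize(scores, scale, threshold)
    logger.info("JAWS reference on scale %s, threshold %.3f", scale, threshold)

    expert_labels = None
    if paths.get("expert_labels_file"):
        expert_labels = read_labels_csv(_resolve(paths["expert_labels_file"]),
                                        provenance="expert")

    all_reports = {}
    for ex, matrix in matrices.items():
        matrix.to_csv(out / f"features_ex{ex}.csv")
        reduced, cv_rep, wcss_rep = select_features(matrix, cfg["selection"])
        cv_rep.to_json(out / f"selection_cv_ex{ex}.json")
        wcss_rep.to_json(out / f"selection_wcss_ex{ex}.json")
        reduced.to_csv(out / f"features_selected_ex{ex}.csv")

        sets = {"all": reduced}
        for name in cfg["evaluation"]["feature_sets"]:
            if name != "all":
                sets[name] = selection.contextual_set(matrix, name)
        reports = evaluation.evaluate_pipeline(
            reduced,
            jaws_labels,
            expert_labels,
            methods=cfg["clustering"]["methods"],
            pca_options=[bool(v) for v in cfg["evaluation"]["pca"]],
            feature_sets=sets,
            seed=seed,
            linkage_method=cfg["clustering"]["linkage"],
            polarity_rule=cfg["clustering"]["polarity_rule"],
        )
        all_reports[ex] = [r.to_dict() for r in reports]
        logger.info("exercise %d: %d reports", ex, len(reports))

    payload = {
        "config_hash": chash,
        "seed": seed,
        "jaws_scale": scale,
        "jaws_threshold": threshold,
        "exercises": all_reports,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    return out
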