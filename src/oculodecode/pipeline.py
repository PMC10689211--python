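"""End-to-end orchestration, configuration and reproducibility manifest.

``run_pipeline`` composes the full analysis: simulate the study, extract
session features, decode the injection state (LOOCV + pairwise +
cross-subject transfer), analyse the auditory oddball epochs, and write a
manifest recording the config hash and seed so the run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aep import average_aep, mmn_index, peak_to_trough, pointwise_ranksum_mask
from .decoder import assemble, cross_subject_accuracy, loocv_accuracy
from .events import DetectionParams, detect_saccades
from .io import FEATURE_KEYS, SessionFeatures, write_features, write_trace_file
from .metrics import extract_session_features, speed_accuracy_correlation
from .synth import (
    AEPParams,
    GeneratorConfig,
    MainSequenceParams,
    SessionScatter,
    StateEffects,
    SubjectProfile,
    TrialCounts,
    simulate_aep_epochs,
    simulate_study,
)

logger = logging.getLogger(__name__)


@dataclass
class DecoderSettings:
    k: int = 3
    svm_c: float = 1.0
    global_pca: bool = False


@dataclass
class AEPWindows:
    baseline_ms: tuple = (-100.0, 0.0)
    p2t_ms: tuple = (0.0, 300.0)
    mmn_ms: tuple = (100.0, 200.0)
    n_epochs: int = 400


@dataclass
class PipelineConfig:
    """Fully resolved pipeline configuration (one reproducibility unit)."""

    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    decoder: DecoderSettings = field(default_factory=DecoderSettings)
    aep: AEPWindows = field(default_factory=AEPWindows)

    def __post_init__(self):
        # one root seed governs every stage
        self.generator = dataclasses.replace(self.generator, seed=self.seed)


def _plain(obj):
    """Recursively convert dataclasses/tuples/numpy scalars to plain YAML/JSON
    types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _strict(cls, data: dict, **converted):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    kwargs = {k: v for k, v in data.items() if k not in converted}
    kwargs.update({k: v for k, v in converted.items() if k in data})
    return cls(**kwargs)


def _tuplify(v):
    return tuple(tuple(x) if isinstance(x, list) else x for x in v)


def generator_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    conv = {}
    if "trials" in d:
        conv["trials"] = _strict(TrialCounts, d["trials"])
    if "subjects" in d:
        conv["subjects"] = {
            k: _strict(
                SubjectProfile, v,
                gaze_centers=_tuplify(v.get("gaze_centers", [(0.0, 0.0)])),
            )
            for k, v in d["subjects"].items()
        }
    if "states" in d:
        conv["states"] = {k: _strict(StateEffects, v) for k, v in d["states"].items()}
    if "main_seq" in d:
        conv["main_seq"] = _strict(MainSequenceParams, d["main_seq"])
    if "scatter" in d:
        conv["scatter"] = _strict(SessionScatter, d["scatter"])
    if "aep" in d:
        conv["aep"] = _strict(
            AEPParams, d["aep"],
            components=_tuplify(d["aep"].get("components", [])),
            intensity_gains=_tuplify(d["aep"].get("intensity_gains", [])),
            pitch_gains=_tuplify(d["aep"].get("pitch_gains", [])),
        )
    if "tasks" in d:
        conv["tasks"] = tuple(d["tasks"])
    return _strict(GeneratorConfig, d, **conv)


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    conv = {}
    if "generator" in d:
        conv["generator"] = generator_from_dict(d["generator"])
    if "detection" in d:
        conv["detection"] = _strict(DetectionParams, d["detection"])
    if "decoder" in d:
        conv["decoder"] = _strict(DecoderSettings, d["decoder"])
    if "aep" in d:
        conv["aep"] = _strict(
            AEPWindows, d["aep"],
            baseline_ms=tuple(d["aep"].get("baseline_ms", (-100.0, 0.0))),
            p2t_ms=tuple(d["aep"].get("p2t_ms", (0.0, 300.0))),
            mmn_ms=tuple(d["aep"].get("mmn_ms", (100.0, 200.0))),
        )
    return _strict(PipelineConfig, d, **conv)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(cfg), fh, sort_keys=True)


def config_hash(cfg: PipelineConfig) -> str:
    canon = yaml.safe_dump(_plain(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small, fast configuration for demos and smoke runs."""
    gen = GeneratorConfig(
        seed=seed,
        sessions_per_state=10,
        trials=TrialCounts(
            anti=10, pro=8, delayed=8, linear=2, lissajous=2, fixation=3, freeview=1
        ),
        fv_dur_s=8.0,
        linear_dur_s=6.0,
        lis_dur_s=8.0,
    )
    return PipelineConfig(seed=seed, generator=gen)


# ---------------------------------------------------------------------------
# stages


def study_features(
    cfg: PipelineConfig, sessions=None
) -> tuple[list[SessionFeatures], list]:
    """Simulate (or accept) sessions and extract their feature vectors."""
    if sessions is None:
        sessions = simulate_study(cfg.generator)
    feats = [
        extract_session_features(s.trials, cfg.detection) for s in sessions
    ]
    return feats, sessions


def events_table(trials, det_params: DetectionParams) -> pd.DataFrame:
    """Detect saccades for every trial and tabulate them (one row/event)."""
    rows = []
    for trace, meta in trials:
        mode = (
            "adaptive" if meta.task in ("fixation", "free_viewing") else "fixed"
        )
        for ev in detect_saccades(trace, det_params, mode=mode):
            rows.append(
                {
                    "session_id": meta.session_id,
                    "trial_id": meta.trial_id,
                    "task": meta.task,
                    **{k: getattr(ev, k) for k in (
                        "onset_ms", "offset_ms", "duration_ms", "amplitude_deg",
                        "peak_vel_deg_s", "mean_vel_deg_s", "avg_vel_deg_s",
                        "direction_deg", "angle_from_horizontal_deg",
                        "is_downward", "is_microsaccade",
                    )},
                }
            )
    return pd.DataFrame(rows)


def aep_summary(cfg: PipelineConfig) -> dict:
    """Oddball AEP stage: per-state peak-to-trough, contrast masks, MMN."""
    gen = cfg.generator
    n = cfg.aep.n_epochs
    out: dict = {"peak_to_trough_uv": {}, "mmn_index_uv": {}}
    waves = {}
    for state in gen.states:
        es = simulate_aep_epochs(gen, state, 80, 1500, "standard", n)
        waves[state] = es
        out["peak_to_trough_uv"][state] = peak_to_trough(
            average_aep(es, cfg.aep.baseline_ms), cfg.aep.p2t_ms
        )
        dev = simulate_aep_epochs(gen, state, 80, 1500, "deviant", n, block="A")
        std = simulate_aep_epochs(gen, state, 80, 1500, "standard", n, block="B")
        _, idx = mmn_index(
            average_aep(dev, cfg.aep.baseline_ms),
            average_aep(std, cfg.aep.baseline_ms),
            cfg.aep.mmn_ms,
        )
        out["mmn_index_uv"][state] = idx
    for drug in ("pcp", "ketamine"):
        if drug in waves:
            mask, _ = pointwise_ranksum_mask(
                waves[drug], waves["saline"], baseline_window=cfg.aep.baseline_ms
            )
            out[f"{drug}_vs_saline_sig_frac"] = float(np.mean(mask))
    return out


def report_text(features: list[SessionFeatures]) -> str:
    """Plain-text summary: per-state feature means and drug-effect signs."""
    states = sorted({f.state for f in features})
    lines = [f"{'feature':<18}" + "".join(f"{s:>12}" for s in states) + "   drug-saline"]
    for key in FEATURE_KEYS:
        means = {}
        for s in states:
            vals = [
                f.features[key] for f in features
                if f.state == s and np.isfinite(f.features.get(key, np.nan))
            ]
            means[s] = np.mean(vals) if vals else np.nan
        direction = ""
        if "saline" in means and len(states) > 1:
            drugs = [means[s] for s in states if s != "saline"]
            if np.all(np.isfinite(drugs)):
                delta = np.mean(drugs) - means["saline"]
                direction = "+" if delta > 0 else "-"
        lines.append(
            f"{key:<18}"
            + "".join(f"{means[s]:>12.3f}" for s in states)
            + f"   {direction}"
        )
    return "\n".join(lines)


def run_pipeline(
    cfg: PipelineConfig, out_dir, write_traces: bool = False
) -> dict:
    """Execute simulate -> detect -> features -> classify -> aep -> report.

    Writes features.tsv, confusion.tsv, loadings.tsv, metrics.json,
    report.txt and manifest.json into ``out_dir`` and returns the metrics
    dict.  Identical config (hash) reproduces identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats, sessions = study_features(cfg)
    write_features(feats, out / "features.tsv")
    if write_traces:
        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        for s in sessions:
            write_trace_file(s.trials, tdir / f"{s.session_id}.tsv")

    fm = assemble(feats)
    res = loocv_accuracy(
        fm, k=cfg.decoder.k, svm_c=cfg.decoder.svm_c,
        global_pca=cfg.decoder.global_pca,
    )
    cross = {}
    for subj in sorted(set(fm.subjects)):
        others = sorted(set(fm.subjects) - {subj})
        if others:
            cross[f"train_{subj}"] = cross_subject_accuracy(
                fm, subj, k=cfg.decoder.k, svm_c=cfg.decoder.svm_c
            )
    corr = speed_accuracy_correlation(feats)
    aep_res = aep_summary(cfg)

    pd.DataFrame(
        res.confusion, index=res.class_labels, columns=res.class_labels
    ).to_csv(out / "confusion.tsv", sep="\t")
    pd.DataFrame(
        res.loadings, columns=fm.feature_names
    ).to_csv(out / "loadings.tsv", sep="\t", index_label="pc")
    (out / "report.txt").write_text(report_text(feats))

    metrics = {
        "n_sessions": res.n_sessions,
        "n_dropped": fm.n_dropped,
        "accuracy": res.accuracy,
        "pairwise": res.pairwise,
        "cross_subject": cross,
        "selected_pcs": list(res.selected_pcs),
        "pc_pvalues": [float(p) for p in res.pc_pvalues[:15]],
        "top_features": res.top_features,
        "speed_accuracy_r": corr,
        "aep": aep_res,
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(_plain(metrics), fh, indent=2)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "stages": ["simulate", "features", "classify", "aep", "report"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return metrics


def make_fixtures(seed: int = 0) -> dict:
    """Small deterministic dataset for tests: a few trials of every task
    for each subject/state, plus one AEP standard/deviant epoch pair."""
    gen = GeneratorConfig(
        seed=seed,
        sessions_per_state=1,
        trials=TrialCounts(
            anti=4, pro=3, delayed=3, linear=1, lissajous=1, fixation=2, freeview=1
        ),
        fv_dur_s=6.0,
        linear_dur_s=5.0,
        lis_dur_s=6.0,
    )
    sessions = simulate_study(gen)
    aep_std = simulate_aep_epochs(gen, "saline", 80, 1500, "standard", 30)
    aep_dev = simulate_aep_epochs(gen, "saline", 80, 1500, "deviant", 30, block="B")
    return {
        "config": gen,
        "sessions": sessions,
        "aep_standard": aep_std,
        "aep_deviant": aep_dev,
    }
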