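"""End-to-end orchestration: synth -> preprocess -> features -> train ->
fuse -> evaluate, with per-stage caching.

Each stage writes its outputs plus a ``.hash`` sidecar holding a digest
of the stage configuration and its input digests; a rerun with an
unchanged configuration skips the stage and reuses the cached output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import cwt_features, ecg_io, late_fusion, preprocess, synth_ecg
from .evaluate import MetricsReport, confusion_matrix
from .fusion_models import (FusionModelSpec, TrainConfig, build_model,
                            predict_proba, train_model)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed and working directory."""

    workdir: str = "pipeline_out"
    seed: int = 0
    # synth
    n_beats: int = 500
    class_mix: tuple = (0.6, 0.1, 0.15, 0.05, 0.1)
    noise_sd: float = 0.02
    baseline_wander_amp: float = 0.1
    # preprocess
    fs_out: float = 250.0
    band: tuple = (5.0, 20.0)
    # features
    n_scales: int = 180
    omega0: float = 6.0
    n_cycles: float = 6.0
    image_size: int = 224
    # train
    strategies: tuple = ("S1",)
    width_scale: float = 1.0
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-4
    patience: int = 5
    test_fraction: float = 0.2
    # fuse
    late_methods: tuple = ()

    @classmethod
    def from_yaml(cls, path):
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise StageError("config", f"unknown config keys: {sorted(unknown)}")
        for key in ("class_mix", "band", "strategies", "late_methods"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _cached(path: Path, key: str) -> bool:
    side = path.with_suffix(path.suffix + ".hash")
    return path.exists() and side.exists() and side.read_text() == key


def _mark(path: Path, key: str):
    path.with_suffix(path.suffix + ".hash").write_text(key)


def stage_synth(cfg: PipelineConfig, workdir: Path) -> Path:
    out = workdir / "synth" / "synth.hea"
    key = _digest(["synth", cfg.n_beats, cfg.class_mix, cfg.noise_sd,
                   cfg.baseline_wander_amp, cfg.seed])
    if _cached(out, key):
        logger.info("synth: cached")
        return out
    rc = synth_ecg.SynthRecordConfig(
        n_beats=cfg.n_beats, class_mix=cfg.class_mix, noise_sd=cfg.noise_sd,
        baseline_wander_amp=cfg.baseline_wander_amp, seed=cfg.seed)
    record = synth_ecg.generate_record(rc)
    ecg_io.write_wfdb_record(record, out.parent, name="synth")
    _mark(out, key)
    return out


def stage_preprocess(cfg: PipelineConfig, workdir: Path, header: Path) -> Path:
    out = workdir / "beats.npz"
    key = _digest(["preprocess", str(header), cfg.fs_out, cfg.band,
                   header.stat().st_mtime])
    if _cached(out, key):
        logger.info("preprocess: cached")
        return out
    if not header.exists():
        raise StageError("preprocess", f"missing input {header}")
    record = ecg_io.read_wfdb_record(header)
    beats = preprocess.extract_beats(record, fs_out=cfg.fs_out,
                                     low=cfg.band[0], high=cfg.band[1])
    if not beats:
        raise StageError("preprocess", "no beats recovered")
    np.savez_compressed(
        out,
        samples=np.stack([b.samples for b in beats]),
        labels=np.array([b.class_label for b in beats]),
        peaks=np.array([b.source[1] for b in beats]))
    _mark(out, key)
    return out


def stage_features(cfg: PipelineConfig, workdir: Path, beats_path: Path) -> Path:
    out = workdir / "features.npz"
    key = _digest(["features", cfg.n_scales, cfg.omega0, cfg.n_cycles,
                   cfg.image_size, beats_path.stat().st_mtime])
    if _cached(out, key):
        logger.info("features: cached")
        return out
    data = np.load(beats_path, allow_pickle=False)
    params = cwt_features.MorletParams(omega0=cfg.omega0,
                                       n_cycles=cfg.n_cycles)
    scal, phas = [], []
    for beat in data["samples"]:
        s, p = cwt_features.beat_to_images(
            beat, params=params, fs=cfg.fs_out, n_scales=cfg.n_scales,
            size=cfg.image_size)
        scal.append(s)
        phas.append(p)
    np.savez_compressed(out, scalogram=np.stack(scal),
                        phasogram=np.stack(phas), labels=data["labels"])
    _mark(out, key)
    return out


def _model_inputs(strategy, scal, phas):
    if strategy == "S1":
        return scal[..., None].astype(np.float32)
    if strategy == "S2":
        return phas[..., None].astype(np.float32)
    return np.stack([scal, phas], axis=-1).astype(np.float32)


def stage_train_eval(cfg: PipelineConfig, workdir: Path, features: Path):
    data = np.load(features, allow_pickle=False)
    scal = data["scalogram"]
    phas = data["phasogram"]
    labels = data["labels"]
    train_idx, test_idx = ecg_io.stratified_split(
        labels, test_fraction=cfg.test_fraction, seed=cfg.seed)

    tc = TrainConfig(learning_rate=cfg.learning_rate,
                     batch_size=cfg.batch_size, max_epochs=cfg.epochs,
                     patience_epochs=min(cfg.patience, cfg.epochs),
                     seed=cfg.seed)
    reports = {}
    needed = set(cfg.strategies) | ({"S1", "S2"} if cfg.late_methods else set())
    trained = {}
    for strategy in sorted(needed):
        model_path = workdir / f"model_{strategy}.pkl"
        key = _digest(["train", strategy, cfg.width_scale, asdict_t(tc),
                       features.stat().st_mtime])
        if _cached(model_path, key):
            logger.info("train %s: cached", strategy)
            with open(model_path, "rb") as fh:
                model, history = pickle.load(fh)
        else:
            spec = FusionModelSpec(strategy=strategy,
                                   input_size=cfg.image_size,
                                   width_scale=cfg.width_scale,
                                   seed=cfg.seed)
            model = build_model(spec)
            x_train = _model_inputs(strategy, scal[train_idx],
                                    phas[train_idx])
            model, history = train_model(model, x_train, labels[train_idx], tc)
            with open(model_path, "wb") as fh:
                pickle.dump((model, history), fh)
            _mark(model_path, key)
            pd_history(history, workdir / f"history_{strategy}.csv")
        trained[strategy] = model
        if strategy in cfg.strategies:
            x_test = _model_inputs(strategy, scal[test_idx], phas[test_idx])
            proba = predict_proba(model, x_test)
            pred = [late_fusion.CLASSES[i] for i in proba.argmax(1)]
            reports[strategy] = MetricsReport(
                confusion_matrix(labels[test_idx], pred))

    letter = {"mean": "a", "svm": "b", "tree": "c", "forest": "d",
              "logreg": "e", "nb": "f", "knn": "g", "ridge": "h"}
    for method in cfg.late_methods:
        name = "S7" + letter.get(method, f"-{method}")
        p1_tr = predict_proba(trained["S1"],
                              _model_inputs("S1", scal[train_idx],
                                            phas[train_idx]))
        p2_tr = predict_proba(trained["S2"],
                              _model_inputs("S2", scal[train_idx],
                                            phas[train_idx]))
        p1_te = predict_proba(trained["S1"],
                              _model_inputs("S1", scal[test_idx],
                                            phas[test_idx]))
        p2_te = predict_proba(trained["S2"],
                              _model_inputs("S2", scal[test_idx],
                                            phas[test_idx]))
        test_pairs = late_fusion.make_pairs(p1_te, p2_te)
        if method == "mean":
            pred = [late_fusion.fuse_mean(p)[0] for p in test_pairs]
        else:
            train_pairs = late_fusion.make_pairs(p1_tr, p2_tr,
                                                 list(labels[train_idx]))
            comb = late_fusion.train_combiner(method, train_pairs,
                                              seed=cfg.seed)
            pred = late_fusion.predict_combiner(comb, test_pairs)
        reports[name] = MetricsReport(confusion_matrix(labels[test_idx], pred))
    return reports


def asdict_t(tc: TrainConfig):
    return {k: getattr(tc, k) for k in tc.__dataclass_fields__}


def pd_history(history, path):
    import pandas as pd
    pd.DataFrame(history).to_csv(path, index_label="epoch")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns and writes the summary report."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    try:
        header = stage_synth(config, workdir)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("synth", str(exc)) from exc
    try:
        beats = stage_preprocess(config, workdir, header)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc
    try:
        features = stage_features(config, workdir, beats)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("features", str(exc)) from exc
    try:
        reports = stage_train_eval(config, workdir, features)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("train", str(exc)) from exc

    summary = {
        "config": {k: getattr(config, k)
                   for k in config.__dataclass_fields__},
        "strategies": {name: json.loads(rep.to_json())
                       for name, rep in reports.items()},
    }
    with open(workdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
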