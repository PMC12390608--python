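"""End-to-end registration-phase pipeline with a structured config.

One YAML/dict config carries every stage parameter (filter edges, epoch
window, group size, bands, PSD channels, model, split fraction, seed) with
defaults equal to the study's stated values; unknown keys are rejected.
``run_pipeline`` executes simulate/load -> preprocess -> epoch -> features
-> split -> train -> evaluate, writes a deterministic artifact tree
(resolved config, features CSV, report JSON, confusion matrix CSV,
learning-curve table/plot for the CNN) and logs per-stage counts. All
randomness flows from the single ``seed`` (the simulator uses it directly;
split and training use deterministic offsets of it).
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import epoching, eval_metrics, features, models, preprocess, signal_io
from . import synthetic_data as synth

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "simulate": None,          # dict of SyntheticConfig overrides, or None
    "recording": None,         # path to EDF/CSV recording (real-data mode)
    "events": None,            # path to events CSV
    "recording_sfreq": None,   # required for delimited recordings
    "l_freq": 0.1,
    "h_freq": 30.0,
    "l_trans": 0.1,
    "h_trans": 7.5,
    "average_ref": True,
    "tmin": -0.1,
    "tmax": 0.9,
    "baseline": False,
    "epochs_per_sample": 10,
    "erp_channels": list(features.DEFAULT_ERP_CHANNELS),
    "psd_channels": list(features.DEFAULT_PSD_CHANNELS),
    "bands": {k: list(v) for k, v in features.DEFAULT_BANDS.items()},
    "model": "rf",             # cnn | svm | rf | gb | knn | dt | nb | lr
    "train_frac": 0.8,
    "seed": 0,
}

# distinct exit codes per failing stage (used by the CLI)
STAGE_EXIT_CODES = {"config": 2, "io": 3, "preprocess": 4, "epoch": 5,
                    "features": 6, "train": 7, "evaluate": 8}


class StageError(RuntimeError):
    """A pipeline failure attributed to a named stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def resolve_config(config: dict | str | Path | None) -> dict:
    """Merge a user config (dict or YAML path) over the defaults; unknown
    keys are rejected so typos fail loudly."""
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise StageError("config", f"unknown config keys {sorted(unknown)}")
    merged = {**DEFAULT_CONFIG, **config}
    return merged


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("preprocess")
def _preprocess(rec, cfg):
    spec = preprocess.design_bandpass_fir(
        cfg["l_freq"], cfg["h_freq"], rec.sfreq,
        l_trans=cfg["l_trans"], h_trans=cfg["h_trans"])
    rec = preprocess.apply_zero_phase(rec, spec)
    if cfg["average_ref"]:
        rec = preprocess.average_reference(rec)
    return rec


@_stage("epoch")
def _epoch(rec, events, cfg):
    ep = epoching.segment(rec, events, tmin=cfg["tmin"], tmax=cfg["tmax"])
    if cfg["baseline"]:
        ep = epoching.baseline_correct(ep)
    return ep


def run_pipeline(config: dict | str | Path | None = None,
                 out_dir: str | Path | None = None
                 ) -> eval_metrics.MetricsReport:
    """Run the full registration-phase chain and return the test report.

    With ``simulate`` set (a dict of simulator overrides, possibly empty)
    data is generated; otherwise ``recording`` and ``events`` paths are
    read. Artifacts are written under ``out_dir`` when given.
    """
    cfg = resolve_config(config)
    counts: dict[str, int] = {}

    if cfg["simulate"] is not None:
        sim_over = dict(cfg["simulate"])
        sim_over.setdefault("seed", cfg["seed"])
        try:
            sim_cfg = synth.SyntheticConfig(**sim_over)
        except TypeError as exc:
            raise StageError("config", f"bad simulate overrides: {exc}")
        recordings, event_tables, _ = synth.generate_dataset(sim_cfg)
        pairs = [(recordings[s], event_tables[s]) for s in recordings]
        counts["events_read"] = sum(len(e) for _, e in pairs)
    else:
        if not cfg["recording"] or not cfg["events"]:
            raise StageError("config",
                             "need 'recording' and 'events' paths, or 'simulate'")
        try:
            rec = signal_io.read_recording(cfg["recording"],
                                           sfreq=cfg["recording_sfreq"])
            events = signal_io.read_events(cfg["events"])
        except Exception as exc:
            raise StageError("io", str(exc)) from exc
        pairs = [(rec, events)]
        counts["events_read"] = len(events)

    epoch_sets = []
    for rec, events in pairs:
        rec = _preprocess(rec, cfg)
        epoch_sets.append(_epoch(rec, events, cfg))
    epochs = synth.merge_epoch_sets(epoch_sets)
    counts["epochs_kept"] = epochs.n_epochs
    counts["epochs_dropped"] = epochs.n_dropped

    try:
        samples = features.build_samples(
            epochs, epochs_per_sample=cfg["epochs_per_sample"],
            erp_channels=tuple(cfg["erp_channels"]) if cfg["erp_channels"]
            else None,
            psd_channels=tuple(cfg["psd_channels"]),
            bands={k: tuple(v) for k, v in cfg["bands"].items()})
        X, y = features.feature_matrix(samples)
        y = np.asarray(y)
    except Exception as exc:
        raise StageError("features", str(exc)) from exc
    counts["samples_built"] = len(y)

    try:
        tr, te = models.stratified_split(X, y, train_frac=cfg["train_frac"],
                                         seed=cfg["seed"])
        model = models.train_classifier(X[tr], y[tr], cfg["model"],
                                        seed=cfg["seed"])
    except Exception as exc:
        raise StageError("train", str(exc)) from exc
    counts["n_train"], counts["n_test"] = len(tr), len(te)

    try:
        report = eval_metrics.evaluate_model(model, X[te], y[te])
    except Exception as exc:
        raise StageError("evaluate", str(exc)) from exc
    report.extra.update(counts)
    report.extra["model"] = model

    for stage, n in counts.items():
        logger.info("pipeline: %s = %d", stage, n)

    if out_dir is not None:
        _write_artifacts(Path(out_dir), cfg, X, y, model, report, counts)
    return report


def _write_artifacts(out: Path, cfg, X, y, model, report, counts) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    signal_io.write_feature_matrix(X, list(y), out / "features.csv")
    payload = {**report.as_dict(), "counts": counts}
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    pd.DataFrame(report.confusion,
                 index=list(model.classes),
                 columns=list(model.classes)).to_csv(out / "confusion.csv")
    if model.history is not None:
        tbl = eval_metrics.learning_curves(model.history)
        tbl.to_csv(out / "learning_curves.csv", index=False)
        eval_metrics.plot_learning_curves(model.history,
                                          out / "learning_curves.png")
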