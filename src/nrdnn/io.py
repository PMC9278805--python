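"""Dataset containers, checkpoints and report writers.

The trial container is a single ``.npz`` holding, per dataset: a
``(n_trials, m, t)`` float array, labels (and optionally 1-9 ratings),
subject identifiers, ordered channel labels and the sampling rate.  A
JSON manifest written next to it records the full generating
configuration and seed so any container can be reproduced bit-for-bit.

Checkpoints store every model parameter array (including batch-norm
running statistics) plus a JSON-encoded model configuration under a
versioned layout key.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .backbone import BackboneConfig
from .exceptions import DataError, ShapeError
from .metrics import EvalReport
from .model import NRDNNModel
from .montage import EEGTrial, RegionMap

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "reports_to_frame",
    "write_reports",
    "load_deap_mat",
]

CHECKPOINT_LAYOUT = 1


def save_dataset(trials: Sequence[EEGTrial], path) -> None:
    """Write same-montage trials to a ``.npz`` container."""
    if not trials:
        raise DataError("no trials to save")
    channels = trials[0].channels
    srate = trials[0].srate
    t = trials[0].n_samples
    for tr in trials:
        if tr.channels != channels or tr.srate != srate or tr.n_samples != t:
            raise DataError("container trials must share montage, rate and length")
    data = np.stack([tr.data for tr in trials])
    labels = np.array([0 if tr.label is None else tr.label for tr in trials])
    ratings = np.array([np.nan if tr.rating is None else tr.rating for tr in trials])
    subjects = np.array([tr.subject for tr in trials])
    np.savez(
        path, data=data, labels=labels, ratings=ratings, subjects=subjects,
        channels=np.array(channels), srate=np.array(srate),
    )


def load_dataset(path) -> List[EEGTrial]:
    """Read a ``.npz`` trial container back into EEGTrial objects."""
    with np.load(path, allow_pickle=False) as npz:
        data = npz["data"]
        labels = npz["labels"]
        ratings = npz["ratings"]
        subjects = npz["subjects"]
        channels = tuple(str(c) for c in npz["channels"])
        srate = float(npz["srate"])
    trials = []
    for i in range(data.shape[0]):
        trials.append(EEGTrial(
            data=data[i], srate=srate, channels=channels,
            subject=str(subjects[i]),
            rating=None if np.isnan(ratings[i]) else float(ratings[i]),
            label=None if labels[i] == 0 else int(labels[i]),
        ))
    return trials


def save_checkpoint(model: NRDNNModel, path, extra: Optional[dict] = None) -> None:
    """Serialize model parameters + configuration to a ``.npz`` checkpoint."""
    meta = {
        "layout": CHECKPOINT_LAYOUT,
        "backbone": asdict(model.cfg),
        "regions": [[name, list(chs)] for name, chs in model.region_map.regions],
        "n_samples": model.n_samples,
        "attention": model.attention,
        "r": model.r,
        "C": model.clf.C,
        "tau": model.clf.tau,
        "extra": extra or {},
    }
    arrays = model.parameter_arrays()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> NRDNNModel:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    if meta.get("layout") != CHECKPOINT_LAYOUT:
        raise ShapeError(
            f"unsupported checkpoint layout {meta.get('layout')!r}; "
            f"this build reads layout {CHECKPOINT_LAYOUT}"
        )
    region_map = RegionMap(tuple(
        (name, tuple(chs)) for name, chs in meta["regions"]
    ))
    model = NRDNNModel(
        region_map, n_samples=meta["n_samples"],
        backbone_cfg=BackboneConfig(**meta["backbone"]),
        C=meta["C"], tau=meta["tau"], r=meta["r"],
        attention=meta["attention"], seed=0,
    )
    model.load_parameter_arrays(arrays)
    return model


def reports_to_frame(reports: Sequence[EvalReport],
                     region_names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """One row per held-out subject: metrics, chosen (C, tau), mean u."""
    rows = []
    for r in reports:
        row = {
            "subject": r.subject, "n_test": r.n_test,
            "tp": r.tp, "fn": r.fn, "fp": r.fp, "tn": r.tn,
            "acc": r.acc, "f1": r.f1, "auc": r.auc,
            "C": r.chosen_C, "tau": r.chosen_tau,
        }
        if r.mean_u is not None:
            names = list(region_names or []) + ["Global"]
            if len(names) != len(r.mean_u):
                names = [f"region{j}" for j in range(len(r.mean_u) - 1)] + ["Global"]
            for name, val in zip(names, r.mean_u):
                row[f"u_{name}"] = float(val)
        rows.append(row)
    return pd.DataFrame(rows)


def write_reports(reports: Sequence[EvalReport], csv_path, json_path=None,
                  region_names: Optional[Sequence[str]] = None) -> None:
    """Write the per-subject CSV and an aggregate JSON summary."""
    frame = reports_to_frame(reports, region_names)
    frame.to_csv(csv_path, index=False)
    if json_path is not None:
        aucs = [r.auc for r in reports if r.auc is not None]
        summary = {
            "n_subjects": len(reports),
            "mean_acc": float(frame["acc"].mean()),
            "mean_f1": float(frame["f1"].mean()),
            "mean_auc": float(np.mean(aucs)) if aucs else None,
        }
        Path(json_path).write_text(json.dumps(summary, indent=2))


def load_deap_mat(path, channels: Sequence[str], srate: float = 128.0,
                  subject: str = "S01", drop_baseline_s: float = 3.0
                  ) -> List[EEGTrial]:
    """Optional reader for a DEAP-style preprocessed MATLAB file.

    Expects variables ``data`` (40 trials x >=32 channels x samples) and
    ``labels`` (40 x 4 ratings, valence first).  Only the first
    ``len(channels)`` rows (the EEG channels) are kept.  The recording's
    pre-trial baseline segment is dropped by default (``drop_baseline_s``
    seconds); pass 0 to keep it.
    """
    from scipy.io import loadmat

    mat = loadmat(path)
    if "data" not in mat or "labels" not in mat:
        raise DataError("expected 'data' and 'labels' variables in the file")
    data, ratings = mat["data"], mat["labels"]
    skip = int(round(drop_baseline_s * srate))
    trials = []
    for i in range(data.shape[0]):
        trials.append(EEGTrial(
            data=np.asarray(data[i][: len(channels), skip:], dtype=np.float64),
            srate=srate, channels=tuple(channels), subject=subject,
            rating=float(ratings[i][0]),
        ))
    return trials
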