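"""Serialization: epoch archives, trained-model archives, EEG-format import.

Epoch blocks are stored as compressed numpy archives (``.npz``) holding the
data cube, labels, sampling rate and channel names.  Trained models are
stored with joblib (they contain a fitted scikit-learn SVM) together with a
format version stamp and an echo of the training configuration.  Import
from standard EEG epoch formats (GDF/EDF, e.g. the BCI competition IV IIa
recordings) is available through a thin adapter over MNE.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import joblib
import numpy as np

from .containers import EpochArray
from .pipeline import TrainedModel
from .synthetic import SyntheticDataset

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_model",
    "load_model",
    "save_ground_truth",
    "epochs_from_raw_file",
]

MODEL_FORMAT_VERSION = 1


def save_epochs(epochs: EpochArray, path) -> None:
    """Write an epoch block as a compressed ``.npz`` archive."""
    names = epochs.channel_names
    np.savez_compressed(
        path,
        data=epochs.data,
        labels=epochs.labels,
        fs=np.float64(epochs.fs),
        channel_names=np.array(names if names is not None else [], dtype=object),
        has_channel_names=np.bool_(names is not None),
    )


def load_epochs(path) -> EpochArray:
    with np.load(path, allow_pickle=True) as f:
        names = list(f["channel_names"]) if bool(f["has_channel_names"]) else None
        return EpochArray(f["data"], f["labels"], float(f["fs"]), names)


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model (joblib archive with a version stamp)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "package": "utfbssp",
        "config": dataclasses.asdict(model.config),
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model archive version {version} "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    return payload["model"]


def save_ground_truth(dataset: SyntheticDataset, path) -> None:
    """JSON sidecar with the generator's ground truth for a synthetic set."""
    cfg = dataset.config
    payload = {
        "n_channels": cfg.n_channels,
        "n_trials_per_class": cfg.n_trials_per_class,
        "fs": cfg.fs,
        "trial_duration": cfg.trial_duration,
        "noise_std": cfg.noise_std,
        "mixing_seed": cfg.mixing_seed,
        "trial_seed": cfg.trial_seed,
        "sources": [
            {
                "low_hz": s.band.low_hz,
                "high_hz": s.band.high_hz,
                "class1_std": s.class1_std,
                "class2_std": s.class2_std,
            }
            for s in cfg.sources
        ],
        "mixing": dataset.mixing.tolist(),
        "planted_band_indices": [idx.tolist() for idx in dataset.planted_band_indices],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def epochs_from_raw_file(
    path,
    tmin: float,
    tmax: float,
    event_id: dict[str, int],
    label_map: dict[int, int],
    picks: list[str] | None = None,
) -> EpochArray:
    """Import epochs from a GDF/EDF/BDF recording via MNE.

    Parameters
    ----------
    path : str
        Recording file; the reader is chosen by extension.
    tmin, tmax : float
        Epoch window in seconds around each event.
    event_id : dict
        Annotation-description to event-code mapping passed to MNE.
    label_map : dict
        Event code to class label (1 = movement imagery, 2 = rest).
    picks : list of str, optional
        Channel names to keep (default: all EEG channels).
    """
    import mne

    path = str(path)
    if path.lower().endswith(".gdf"):
        raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    elif path.lower().endswith((".edf", ".bdf")):
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG file format: {path}")
    events, _ = mne.events_from_annotations(raw, event_id=event_id, verbose="error")
    ep = mne.Epochs(raw, events, tmin=tmin, tmax=tmax, baseline=None,
                    preload=True, picks=picks or "eeg", verbose="error")
    labels = np.array([label_map[int(code)] for code in ep.events[:, 2]])
    return EpochArray(ep.get_data(), labels, float(ep.info["sfreq"]),
                      list(ep.ch_names))
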