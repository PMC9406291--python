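"""Diagnostics: ERD time-frequency maps, spatial-filter topographies,
per-rhythm accuracy breakdowns and 2-D feature views.

These computations back the usual motor-imagery sanity checks: does the
task suppress band power relative to baseline (ERD), over which scalp
locations does the discriminative source project, which classical rhythm
(theta/alpha/beta/gamma) carries the class information, and how separable
are the per-band CSP features.  All functions return plain arrays/frames;
rendering (scalp interpolation, image plots) is left to the caller's
plotting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochArray
from .filterbank import FrequencyBand, bandpass_epochs
from .pipeline import TrainedModel, csp_svm_baseline, predict
from .spatial import features_from_covariances, trial_covariances

__all__ = [
    "RHYTHMS",
    "TimeFrequencyMap",
    "tf_map",
    "rhythm_band_accuracies",
    "filter_topography",
    "feature_scatter",
]

#: canonical EEG rhythm bands (Hz) as delimited in motor-imagery work
RHYTHMS: dict[str, FrequencyBand] = {
    "theta": FrequencyBand(4.0, 8.0),
    "alpha": FrequencyBand(8.0, 13.0),
    "beta": FrequencyBand(14.0, 30.0),
    "gamma": FrequencyBand(30.0, 42.0),
}


@dataclass
class TimeFrequencyMap:
    """Baseline-normalized trial-average time-frequency power.

    ``power`` is (n_freqs, n_times), expressed as dB relative to the mean
    power in the baseline window of each frequency row.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    baseline: tuple[float, float]
    mode: str = "dB"


def tf_map(
    epochs: EpochArray,
    channel: int,
    freqs: np.ndarray | None = None,
    baseline: tuple[float, float] = (0.0, 0.5),
    n_cycles: float | np.ndarray = 5.0,
    labels: int | None = None,
    detrend: bool = True,
) -> TimeFrequencyMap:
    """Morlet-wavelet time-frequency map, trial-averaged and baseline-normed.

    Per-trial wavelet power is averaged over trials (optionally restricted
    to one class via ``labels``), then each frequency row is expressed in
    dB relative to its mean over the ``baseline`` window.  A negative value
    after the baseline therefore indicates event-related desynchronization.

    Parameters
    ----------
    channel : int
        Channel index to analyze.
    freqs : ndarray, optional
        Frequencies of interest (Hz); default 4..42 Hz in 1 Hz steps.
    baseline : (start, end)
        Window in seconds (trial-relative) used as the reference power.
    n_cycles : float or ndarray
        Wavelet cycles (scalar or per frequency).
    labels : int, optional
        Restrict the average to trials of this class.
    detrend : bool
        Remove each trial's channel mean first (DC offsets carry no rhythm
        information and would otherwise leak into low frequencies).
    """
    from mne.time_frequency import tfr_array_morlet

    if not (0 <= channel < epochs.n_channels):
        raise ValueError(f"channel {channel} out of range")
    if freqs is None:
        freqs = np.arange(4.0, 43.0, 1.0)
    freqs = np.asarray(freqs, dtype=np.float64)
    t_end = epochs.n_samples / epochs.fs
    if not (0 <= baseline[0] < baseline[1] <= t_end + 1e-9):
        raise ValueError(f"baseline {baseline} outside the epoch [0, {t_end:.3f}] s")

    data = epochs.data[:, [channel], :]
    if labels is not None:
        mask = epochs.labels == labels
        if not mask.any():
            raise ValueError(f"no trials with label {labels}")
        data = data[mask]
    if detrend:
        data = data - data.mean(axis=-1, keepdims=True)

    power = tfr_array_morlet(
        data, sfreq=epochs.fs, freqs=freqs, n_cycles=n_cycles, output="avg_power",
        zero_mean=True,
    )[0]  # (n_freqs, n_times)
    times = np.arange(epochs.n_samples) / epochs.fs
    bmask = (times >= baseline[0]) & (times < baseline[1])
    ref = power[:, bmask].mean(axis=1, keepdims=True)
    ref = np.where(ref > 0, ref, np.finfo(float).tiny)
    power_db = 10.0 * np.log10(np.maximum(power, np.finfo(float).tiny) / ref)
    return TimeFrequencyMap(power=power_db, freqs=freqs, times=times,
                            baseline=tuple(baseline))


def rhythm_band_accuracies(
    epochs: EpochArray,
    window: tuple[float, float],
    n_filters: int = 4,
    n_folds: int = 5,
    seed: int = 0,
    rhythms: dict[str, FrequencyBand] | None = None,
    svm_c: float = 1.0,
) -> dict[str, float]:
    """Cross-validated CSP+SVM accuracy restricted to each classical rhythm.

    Runs the plain single-band baseline inside a stratified K-fold on each
    rhythm band and returns the pooled accuracy in percent per rhythm.
    Reveals which frequency range carries the class information.
    """
    from sklearn.model_selection import StratifiedKFold

    if rhythms is None:
        rhythms = RHYTHMS
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(epochs.n_trials), epochs.labels))
    out: dict[str, float] = {}
    for name, band in rhythms.items():
        correct = 0
        for train_idx, val_idx in folds:
            tr = EpochArray(epochs.data[train_idx], epochs.labels[train_idx],
                            epochs.fs, epochs.channel_names)
            va = EpochArray(epochs.data[val_idx], epochs.labels[val_idx],
                            epochs.fs, epochs.channel_names)
            model = csp_svm_baseline(tr, band, n_filters, window, svm_c=svm_c,
                                     seed=seed)
            pred, _ = predict(model, va)
            correct += int(np.sum(pred == va.labels))
        out[name] = 100.0 * correct / epochs.n_trials
    return out


def filter_topography(model: TrainedModel, band_index: int) -> pd.DataFrame:
    """Spatial filters and activation patterns of one sub-band, per channel.

    The filters ``W`` are backward-model weights; the corresponding forward
    patterns ``A = C W (W' C W)^{-1}`` (``C`` the pooled covariance) are the
    physiologically interpretable scalp projections of the extracted
    sources.  Returns a frame with one row per channel and columns
    ``filter_k`` / ``pattern_k``.
    """
    import warnings as _warnings

    if not (0 <= band_index < len(model.spec)):
        raise ValueError(f"band_index {band_index} not in the model's filter bank")
    filt = model.band_filters[band_index]
    cov = model.band_covariances[band_index]
    W = filt.filters
    C = 0.5 * (cov.C1 + cov.C2)
    M = W.T @ C @ W
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        _warnings.warn("W' C W singular; using pseudo-inverse for patterns")
        Minv = np.linalg.pinv(M)
    A = C @ W @ Minv
    df = pd.DataFrame(index=pd.RangeIndex(W.shape[0], name="channel"))
    for k in range(W.shape[1]):
        df[f"filter_{k}"] = W[:, k]
    for k in range(W.shape[1]):
        df[f"pattern_{k}"] = A[:, k]
    return df


def feature_scatter(
    model: TrainedModel, epochs: EpochArray, bands: np.ndarray | None = None
) -> dict[int, pd.DataFrame]:
    """2-D CSP feature coordinates per trial for each selected sub-band.

    For every requested band the two most discriminative feature dimensions
    are returned: the filters of the largest and the smallest generalized
    eigenvalue (first and last column of the band's filter matrix).  Each
    frame has columns ``x`` (largest-eigenvalue filter), ``y``
    (smallest-eigenvalue filter) and ``label``.
    """
    if model.n_filters < 2:
        raise ValueError("need at least 2 CSP filters per band for a 2-D view")
    if bands is None:
        bands = model.selected_bands
    cfg = model.config
    ep = epochs.crop(*cfg.window)
    out: dict[int, pd.DataFrame] = {}
    for gi in np.asarray(bands):
        gi = int(gi)
        band = model.spec[gi]
        fe = bandpass_epochs(ep, band, cfg.filter_order, cfg.zero_phase)
        sc = trial_covariances(fe, center=cfg.center_trials, normalize_trace=False)
        filt = model.band_filters[gi]
        z = features_from_covariances(filt, sc, cfg.log_transform)
        # column 0 carries the largest generalized eigenvalue; the smallest
        # sits wherever its (descending-order) index is maximal
        j_small = int(np.argmax(filt.selected))
        out[gi] = pd.DataFrame(
            {"x": z[:, 0], "y": z[:, j_small], "label": ep.labels}
        )
    return out
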