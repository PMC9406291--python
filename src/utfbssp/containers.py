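"""In-memory containers for epoched EEG data.

The package operates on fixed-length, two-class epoched EEG: a real array of
shape ``(n_trials, n_channels, n_samples)`` with per-trial integer labels
(1 = movement imagery, 2 = rest), a sampling rate in Hz and optional channel
names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EpochArray"]


@dataclass
class EpochArray:
    """Epoched multichannel EEG block.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Real-valued signal; each trial houses an ``N x L`` channel-by-time
        matrix.
    labels : ndarray, shape (n_trials,)
        Integer class per trial. By convention class 1 is movement imagery
        and class 2 is rest; any two distinct integers are accepted.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str, optional
        One identifier per channel.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples); got shape {self.data.shape}"
            )
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels must have one entry per trial; got {self.labels.shape} "
                f"for {self.data.shape[0]} trials"
            )
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_names is not None and len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique labels present."""
        return np.unique(self.labels)

    def crop(self, tmin: float, tmax: float) -> "EpochArray":
        """Return a copy restricted to the time window ``[tmin, tmax)`` seconds.

        ``tmin`` is relative to the first sample of each trial.
        """
        lo = int(round(tmin * self.fs))
        hi = int(round(tmax * self.fs))
        if not (0 <= lo < hi <= self.n_samples):
            raise ValueError(
                f"window ({tmin}, {tmax}) s maps to samples [{lo}, {hi}) outside "
                f"[0, {self.n_samples})"
            )
        return EpochArray(
            self.data[:, :, lo:hi].copy(), self.labels.copy(), self.fs, self.channel_names
        )

    def copy(self) -> "EpochArray":
        return EpochArray(
            self.data.copy(),
            self.labels.copy(),
            self.fs,
            list(self.channel_names) if self.channel_names is not None else None,
        )
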