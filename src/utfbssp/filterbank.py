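"""Upper-triangle filter bank construction and band-pass filtering of epochs.

The decoder decomposes the 4-42 Hz range into every sub-band obtainable by
sliding the lower edge in steps of 2 Hz and widening the band in steps of
4 Hz starting from a 4 Hz minimum width, keeping the upper edge at or below
42 Hz.  Arranged by lower edge this enumeration forms an upper triangle of
(lower edge, width) combinations; with the default parameters it contains
exactly 90 sub-bands, the first being 4-8 Hz and the last 38-42 Hz.  The
overlapping sub-bands jointly cover the theta (4-8 Hz), alpha (8-13 Hz),
beta (14-30 Hz) and gamma (30-42 Hz) rhythms relevant to motor imagery.

Filtering uses zero-phase Butterworth band-passes realised as cascaded
second-order sections, which keeps narrow high-order bands numerically
stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochArray

__all__ = [
    "FrequencyBand",
    "FilterBankSpec",
    "build_utfb",
    "bandpass_epochs",
    "apply_filterbank",
    "filterbank_to_csv",
]


@dataclass(frozen=True)
class FrequencyBand:
    """A band-pass interval [low_hz, high_hz] in Hz."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError(
                f"invalid band: need 0 <= low < high, got ({self.low_hz}, {self.high_hz})"
            )

    @property
    def width(self) -> float:
        return self.high_hz - self.low_hz

    def overlap(self, low: float, high: float) -> float:
        """Length in Hz of the intersection with [low, high]."""
        return max(0.0, min(self.high_hz, high) - max(self.low_hz, low))


@dataclass(frozen=True)
class FilterBankSpec:
    """An ordered collection of sub-bands plus the rule that generated it."""

    bands: tuple[FrequencyBand, ...]
    f_min: float
    f_max: float
    lower_step: float
    width_step: float
    min_width: float

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, i: int) -> FrequencyBand:
        return self.bands[i]


def build_utfb(
    f_min: float = 4.0,
    f_max: float = 42.0,
    lower_step: float = 2.0,
    width_step: float = 4.0,
    min_width: float = 4.0,
) -> FilterBankSpec:
    """Enumerate the upper-triangle filter bank.

    For each lower edge ``L`` in ``{f_min, f_min + lower_step, ...}`` up to
    ``f_max - min_width``, the upper edges are
    ``L + min_width, L + min_width + width_step, ...`` capped at ``f_max``.
    Bands are ordered row-major by ``(L, U)``.

    With the defaults (4, 42, 2, 4, 4) this yields exactly 90 sub-bands.

    Returns
    -------
    FilterBankSpec

    Raises
    ------
    ValueError
        If the range is empty or a step is not positive.
    """
    if not (f_min < f_max):
        raise ValueError(f"need f_min < f_max, got ({f_min}, {f_max})")
    if lower_step <= 0 or width_step <= 0 or min_width <= 0:
        raise ValueError("lower_step, width_step and min_width must all be positive")
    if f_min + min_width > f_max + 1e-9:
        raise ValueError(
            f"min_width {min_width} does not fit into the range ({f_min}, {f_max})"
        )

    eps = 1e-9
    bands: list[FrequencyBand] = []
    n_low = int(np.floor((f_max - min_width - f_min) / lower_step + eps))
    for i in range(n_low + 1):
        low = f_min + i * lower_step
        n_up = int(np.floor((f_max - (low + min_width)) / width_step + eps))
        for j in range(n_up + 1):
            high = low + min_width + j * width_step
            bands.append(FrequencyBand(float(low), float(high)))
    return FilterBankSpec(
        tuple(bands),
        float(f_min),
        float(f_max),
        float(lower_step),
        float(width_step),
        float(min_width),
    )


def _design_bandpass(band: FrequencyBand, fs: float, order: int) -> np.ndarray:
    nyq = fs / 2.0
    if band.high_hz >= nyq:
        raise ValueError(
            f"band upper edge {band.high_hz} Hz at or above Nyquist {nyq} Hz (fs={fs})"
        )
    return signal.butter(
        order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos"
    )


def bandpass_epochs(
    epochs: EpochArray,
    band: FrequencyBand,
    order: int = 4,
    zero_phase: bool = True,
    padlen: int | None = None,
) -> EpochArray:
    """Butterworth band-pass each trial and channel of an epoch block.

    Parameters
    ----------
    epochs : EpochArray
    band : FrequencyBand
        Pass-band edges; must lie below the Nyquist frequency.
    order : int
        Butterworth order of the one-way filter (default 4). With
        ``zero_phase`` the forward-backward pass doubles the effective order
        and squares the magnitude response.
    zero_phase : bool
        Apply the filter forward and backward (no group delay); otherwise a
        single causal pass.
    padlen : int, optional
        Edge padding length in samples for the zero-phase pass
        (odd-reflection padding). Defaults to scipy's
        ``3 * (number of second-order sections * 2 + 1)``.

    Returns
    -------
    EpochArray of identical shape.
    """
    sos = _design_bandpass(band, epochs.fs, order)
    if zero_phase:
        default_padlen = 3 * (2 * sos.shape[0] + 1)
        use_padlen = default_padlen if padlen is None else padlen
        if epochs.n_samples <= use_padlen:
            raise ValueError(
                f"epochs of {epochs.n_samples} samples are too short for "
                f"zero-phase filtering: need more than {use_padlen} samples "
                f"(reduce order or padlen)"
            )
        out = signal.sosfiltfilt(sos, epochs.data, axis=-1, padlen=use_padlen)
    else:
        out = signal.sosfilt(sos, epochs.data, axis=-1)
    return EpochArray(
        np.ascontiguousarray(out), epochs.labels.copy(), epochs.fs, epochs.channel_names
    )


def apply_filterbank(
    epochs: EpochArray,
    spec: FilterBankSpec,
    order: int = 4,
    zero_phase: bool = True,
    padlen: int | None = None,
) -> list[EpochArray]:
    """Band-pass the epochs through every sub-band of a filter bank.

    Returns one filtered :class:`EpochArray` per band, in spec order.
    Errors raised for an individual band are annotated with its index.
    """
    out: list[EpochArray] = []
    for i, band in enumerate(spec.bands):
        try:
            out.append(bandpass_epochs(epochs, band, order, zero_phase, padlen))
        except ValueError as exc:
            raise ValueError(f"band {i} ({band.low_hz}-{band.high_hz} Hz): {exc}") from exc
    return out


def filterbank_to_csv(spec: FilterBankSpec, path) -> None:
    """Write the band list as CSV with columns index, low_hz, high_hz."""
    pd.DataFrame(
        {
            "index": np.arange(len(spec.bands)),
            "low_hz": [b.low_hz for b in spec.bands],
            "high_hz": [b.high_hz for b in spec.bands],
        }
    ).to_csv(path, index=False)
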