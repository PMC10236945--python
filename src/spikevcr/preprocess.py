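"""Epoching, the zero-phase FIR filterbank and instantaneous phase.

The recording is filtered as a *continuous* signal (a margin of
``pad_seconds`` of real data around every epoch replaces explicit
padding) with a linear-phase Hamming-window FIR bandpass applied
forward and backward, then cut into [-1, 1) s epochs around each spike
onset.  Phase is the angle of the analytic signal, computed per epoch.

Two-pass application is implemented as a single convolution with the
self-convolved kernel: for a symmetric (linear-phase) kernel ``h``,
forward-backward filtering equals convolution with ``h * h``, which is
itself symmetric, so a centred 'same' convolution is exactly zero-phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .bundle import SpikeCatalog
from .config import BROADBAND, BandDefinition, PipelineConfig

__all__ = [
    "BandEpochs",
    "PhaseEpochs",
    "design_zero_phase_bandpass",
    "two_pass_filter",
    "filterbank",
    "broadband",
    "epoch",
    "instantaneous_phase",
]


@dataclass
class BandEpochs:
    """Band-limited spike-locked epochs, (trials, sources, time)."""

    values: np.ndarray
    fs: float
    band: BandDefinition | None = None
    epoch_window: tuple[float, float] = (-1.0, 1.0)

    @property
    def onset_index(self) -> int:
        """Epoch sample index holding the spike onset (t = 0)."""
        return int(round(-self.epoch_window[0] * self.fs))


@dataclass
class PhaseEpochs:
    """Instantaneous phase in radians, wrapped to (-pi, pi]; same shape."""

    values: np.ndarray
    fs: float
    band: BandDefinition | None = None
    epoch_window: tuple[float, float] = (-1.0, 1.0)


def design_zero_phase_bandpass(
    band: BandDefinition, fs: float, order: int = 1500
) -> np.ndarray:
    """Linear-phase FIR bandpass kernel (``order + 1`` taps, Hamming).

    The application contract is forward-backward (two-pass), so the
    effective magnitude response is the square of this kernel's response
    and the net phase is zero.
    """
    if band.high >= fs / 2:
        raise ValueError(
            f"band {band.low}-{band.high} Hz exceeds the Nyquist rate {fs / 2} Hz"
        )
    if order % 2:
        raise ValueError("filter order must be even for a symmetric kernel")
    return signal.firwin(
        order + 1, [band.low, band.high], pass_zero=False, window="hamming", fs=fs
    )


def two_pass_filter(x: np.ndarray, kernel: np.ndarray, axis: int = -1) -> np.ndarray:
    """Apply ``kernel`` forward and backward along ``axis`` (zero net phase).

    Samples within ``len(kernel) - 1`` of either edge see implicit zeros
    beyond the signal; callers guarantee a sufficient real-data margin.
    """
    h2 = np.convolve(kernel, kernel)  # symmetric, odd length
    h2 = h2.astype(np.result_type(x.dtype, np.float32), copy=False)
    shape = [1] * x.ndim
    shape[axis] = len(h2)
    return signal.oaconvolve(x, h2.reshape(shape), mode="same", axes=axis)


def _required_length(config: PipelineConfig, fs: float) -> int:
    epoch_len = config.epoch_window[1] - config.epoch_window[0]
    return int(round((2 * config.pad_seconds + epoch_len) * fs))


def filterbank(
    recording: np.ndarray, config: PipelineConfig, fs: float
) -> dict[int, np.ndarray]:
    """Filter the continuous recording into every analysis band.

    Returns ``{band.index: (sources, time) array}``.  Prefer
    :func:`filter_band` when bands can be processed one at a time —
    holding all 12 band signals for a long recording is memory-hungry.
    """
    _check_length(recording, config, fs)
    return {
        band.index: filter_band(recording, band, config, fs)
        for band in config.band_table
    }


def filter_band(
    recording: np.ndarray, band: BandDefinition, config: PipelineConfig, fs: float
) -> np.ndarray:
    """Two-pass bandpass of the continuous recording for one band."""
    _check_length(recording, config, fs)
    kernel = design_zero_phase_bandpass(band, fs, config.filter_order)
    return two_pass_filter(recording, kernel, axis=-1)


def _check_length(recording: np.ndarray, config: PipelineConfig, fs: float) -> None:
    need = _required_length(config, fs)
    if recording.shape[-1] <= need:
        raise ValueError(
            f"recording of {recording.shape[-1]} samples is too short: "
            f"need more than {need} samples "
            f"(2 x {config.pad_seconds} s padding plus the epoch length)"
        )


def broadband(recording: np.ndarray, config: PipelineConfig, fs: float) -> np.ndarray:
    """Continuous 2–55 Hz signal used for spike-amplitude ranking."""
    band = BandDefinition(0, "broadband", *BROADBAND)
    return filter_band(recording, band, config, fs)


def epoch(
    signals: np.ndarray,
    spikes: SpikeCatalog,
    window: tuple[float, float] = (-1.0, 1.0),
    band: BandDefinition | None = None,
) -> BandEpochs:
    """Cut spike-locked epochs out of continuous (sources, time) signals.

    Trial ``t``, time index ``k`` holds the signal at sample
    ``onset_t + round(window[0] * fs) + k``; with the default window the
    onset lands exactly at epoch index ``fs``.  Onsets too close to a
    recording edge are skipped with a warning.
    """
    fs = spikes.fs
    start_off = int(round(window[0] * fs))
    length = int(round((window[1] - window[0]) * fs))
    n_samples = signals.shape[-1]
    trials = []
    skipped = 0
    for onset in spikes.onsets:
        a = int(onset) + start_off
        b = a + length
        if a < 0 or b > n_samples:
            skipped += 1
            continue
        trials.append(signals[..., a:b])
    if skipped:
        warnings.warn(
            f"skipped {skipped} of {spikes.n_spikes} onsets too close to a "
            "recording edge",
            stacklevel=2,
        )
    if not trials:
        raise ValueError("no onset admits the requested epoch window")
    return BandEpochs(
        values=np.stack(trials, axis=0), fs=fs, band=band, epoch_window=window
    )


def instantaneous_phase(band_epochs: BandEpochs) -> PhaseEpochs:
    """Phase of the analytic signal, per trial, source and sample.

    The Hilbert transform is taken over each 2 s epoch; both analysis
    windows sit >= 0.65 s from the epoch edges, outside the transform's
    edge-distortion zone.
    """
    x = band_epochs.values
    flat = np.abs(x).max(axis=-1) == 0
    if np.any(flat):
        t, s = np.argwhere(flat)[0]
        raise ValueError(
            f"phase undefined for all-zero signal (trial {t}, source {s})"
        )
    analytic = signal.hilbert(x, axis=-1)
    return PhaseEpochs(
        values=np.angle(analytic),
        fs=band_epochs.fs,
        band=band_epochs.band,
        epoch_window=band_epochs.epoch_window,
    )
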