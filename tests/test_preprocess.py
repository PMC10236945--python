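"""Filterbank contract, epoching arithmetic and phase extraction."""

import warnings

import numpy as np
import pytest

from spikevcr.bundle import SpikeCatalog
from spikevcr.config import BandDefinition, PipelineConfig, default_bands
from spikevcr.preprocess import (
    BandEpochs,
    broadband,
    design_zero_phase_bandpass,
    epoch,
    filter_band,
    instantaneous_phase,
    two_pass_filter,
)

FS = 1000.0
BANDS = {b.index: b for b in default_bands()}


def two_pass_gain(kernel: np.ndarray, freq: float, fs: float = FS) -> float:
    """Magnitude response of the forward-backward application at one tone."""
    h2 = np.convolve(kernel, kernel)
    k = np.arange(len(h2))
    return float(np.abs(np.sum(h2 * np.exp(-2j * np.pi * freq * k / fs))))


class TestFilterDesign:
    def test_two_pass_impulse_response_is_symmetric(self):
        kernel = design_zero_phase_bandpass(BANDS[8], FS)
        x = np.zeros(12001)
        x[6000] = 1.0
        y = two_pass_filter(x, kernel)
        np.testing.assert_allclose(y, y[::-1], atol=1e-12)

    def test_passband_center_gain_within_one_percent(self):
        kernel = design_zero_phase_bandpass(BANDS[8], FS)  # 85-95 Hz
        assert abs(two_pass_gain(kernel, 90.0) - 1.0) < 0.01
        # steady-state check on an actual tone
        t = np.arange(int(10 * FS)) / FS
        y = two_pass_filter(np.sin(2 * np.pi * 90.0 * t), kernel)
        mid = slice(4000, 6000)
        assert abs(np.abs(y[mid]).max() - 1.0) < 0.01

    def test_out_of_band_attenuation_at_least_40_db(self):
        kernel = design_zero_phase_bandpass(BANDS[8], FS)
        assert two_pass_gain(kernel, 20.0) < 10 ** (-40 / 20)

    def test_band_above_nyquist_rejected(self):
        band = BandDefinition(99, "bad", 200.0, 600.0)
        with pytest.raises(ValueError, match="Nyquist"):
            design_zero_phase_bandpass(band, FS)

    def test_zero_phase_cross_correlation_peak_at_zero_lag(self):
        rng = np.random.default_rng(0)
        kernel = design_zero_phase_bandpass(BANDS[3], FS)  # 15-30 Hz
        # narrowband burst: windowed in-band tone
        t = np.arange(int(12 * FS)) / FS
        burst = np.sin(2 * np.pi * 22.0 * t) * np.exp(-((t - 6.0) ** 2) / 0.1)
        y = two_pass_filter(burst, kernel)
        xc = np.correlate(y, burst, mode="full")
        assert np.argmax(np.abs(xc)) == len(burst) - 1  # zero lag


class TestFilterbank:
    def test_band1_separates_a_tone_mixture(self):
        config = PipelineConfig()
        t = np.arange(int(12 * FS)) / FS
        x = (np.sin(2 * np.pi * 6.0 * t) + np.sin(2 * np.pi * 100.0 * t))[None, :]
        y = filter_band(x, BANDS[1], config, FS)[0]
        mid = y[4000:8000]
        spec = np.abs(np.fft.rfft(mid * np.hanning(len(mid))))
        f = np.fft.rfftfreq(len(mid), 1 / FS)
        p6 = spec[np.argmin(np.abs(f - 6.0))]
        p100 = spec[np.argmin(np.abs(f - 100.0))]
        assert p100 < p6 * 10 ** (-40 / 20)

    def test_zero_input_gives_zero_output(self):
        config = PipelineConfig()
        x = np.zeros((2, int(12 * FS)))
        y = filter_band(x, BANDS[5], config, FS)
        assert np.all(y == 0)

    def test_linearity(self):
        config = PipelineConfig()
        rng = np.random.default_rng(1)
        x1 = rng.standard_normal((1, int(8 * FS)))
        x2 = rng.standard_normal((1, int(8 * FS)))
        band = BANDS[4]
        lhs = filter_band(3.0 * x1 - 2.0 * x2, band, config, FS)
        rhs = 3.0 * filter_band(x1, band, config, FS) - 2.0 * filter_band(
            x2, band, config, FS
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_interior_samples_invariant_to_edge_extension(self):
        config = PipelineConfig()
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(8 * FS))
        pad = rng.standard_normal(int(2 * FS))
        y = filter_band(x[None, :], BANDS[6], config, FS)[0]
        ext = np.concatenate([pad, x, pad[::-1]])
        y_ext = filter_band(ext[None, :], BANDS[6], config, FS)[0]
        n_pad = len(pad)
        core = slice(int(2 * FS), int(6 * FS))
        np.testing.assert_allclose(
            y[core], y_ext[n_pad:][: len(x)][core], rtol=0, atol=1e-9
        )

    def test_too_short_recording_reports_required_length(self):
        config = PipelineConfig()
        with pytest.raises(ValueError, match="samples"):
            filter_band(np.zeros((1, 100)), BANDS[1], config, FS)


class TestBroadband:
    def test_30_hz_tone_passes(self):
        config = PipelineConfig()
        t = np.arange(int(10 * FS)) / FS
        y = broadband(np.sin(2 * np.pi * 30.0 * t)[None, :], config, FS)[0]
        assert abs(np.abs(y[4000:6000]).max() - 1.0) < 0.01

    def test_100_hz_tone_attenuated(self):
        config = PipelineConfig()
        t = np.arange(int(10 * FS)) / FS
        y = broadband(np.sin(2 * np.pi * 100.0 * t)[None, :], config, FS)[0]
        assert np.abs(y[4000:6000]).max() < 10 ** (-40 / 20)

    def test_zero_input(self):
        config = PipelineConfig()
        y = broadband(np.zeros((1, int(10 * FS))), config, FS)
        assert np.all(y == 0)


class TestEpoch:
    def test_window_arithmetic(self):
        spikes = SpikeCatalog(onsets=[5000], fs=FS)
        x = np.arange(10000, dtype=float)[None, :]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # low spike count
            ep = epoch(x, spikes)
        assert ep.values.shape == (1, 1, 2000)
        assert ep.values[0, 0, 0] == 4000
        assert ep.values[0, 0, -1] == 5999
        # onset lands exactly at epoch index fs
        assert ep.values[0, 0, ep.onset_index] == 5000

    def test_edge_onset_skipped_with_warning(self):
        spikes = SpikeCatalog(onsets=[500, 5000], fs=FS)
        x = np.zeros((1, 10000))
        with pytest.warns(UserWarning, match="skipped 1"):
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                ep = epoch(x, spikes)
        assert ep.values.shape[0] == 1


class TestInstantaneousPhase:
    def _epochs(self, x: np.ndarray) -> BandEpochs:
        return BandEpochs(values=x[None, None, :], fs=FS)

    def test_phase_slope_matches_tone_frequency(self):
        t = np.arange(2000) / FS
        phases = instantaneous_phase(self._epochs(np.cos(2 * np.pi * 10.0 * t)))
        unwrapped = np.unwrap(phases.values[0, 0, 200:1800])
        slope = np.polyfit(t[200:1800], unwrapped, 1)[0]
        assert abs(slope - 2 * np.pi * 10.0) / (2 * np.pi * 10.0) < 1e-3

    def test_quadrature_pair_has_constant_half_pi_difference(self):
        t = np.arange(2000) / FS
        x = np.stack([np.cos(2 * np.pi * 11.0 * t),
                      np.cos(2 * np.pi * 11.0 * t - np.pi / 2)])
        phases = instantaneous_phase(BandEpochs(values=x[None, :, :], fs=FS))
        diff = phases.values[0, 0, 300:1700] - phases.values[0, 1, 300:1700]
        diff = np.angle(np.exp(1j * diff))
        np.testing.assert_allclose(diff, np.pi / 2, atol=1e-6)

    def test_amplitude_modulation_leaves_slope_unchanged(self):
        t = np.arange(2000) / FS
        env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.7 * t)
        phases = instantaneous_phase(
            self._epochs(env * np.cos(2 * np.pi * 13.0 * t))
        )
        unwrapped = np.unwrap(phases.values[0, 0, 300:1700])
        slope = np.polyfit(t[300:1700], unwrapped, 1)[0]
        assert abs(slope - 2 * np.pi * 13.0) / (2 * np.pi * 13.0) < 5e-3

    def test_all_zero_trial_is_an_error_naming_the_cell(self):
        x = np.ones((2, 2, 100))
        x[1, 0] = 0.0
        with pytest.raises(ValueError, match="trial 1, source 0"):
            instantaneous_phase(BandEpochs(values=x, fs=FS))


def test_filter_then_epoch_commutes_with_epoch_then_filter():
    """Padding adequacy: both orders agree at interior epoch samples."""
    config = PipelineConfig()
    rng = np.random.default_rng(5)
    x = rng.standard_normal((1, int(14 * FS)))
    spikes = SpikeCatalog(onsets=[7000], fs=FS)
    band = BANDS[7]
    cont = filter_band(x, band, config, FS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ep_cont = epoch(cont, spikes).values
        # epoch extended by the 2 s margin, filter, crop
        ext = epoch(x, spikes, window=(-3.0, 3.0)).values
    kernel = design_zero_phase_bandpass(band, FS, config.filter_order)
    ep_filt = two_pass_filter(ext, kernel, axis=-1)[..., 2000:-2000]
    scale = np.abs(ep_cont).max()
    np.testing.assert_allclose(ep_cont, ep_filt, atol=1e-6 * scale)
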