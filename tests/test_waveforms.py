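import numpy as np
import pytest
from scipy import signal

from tangentia.errors import (
    DecompositionError,
    DegenerateWaveformError,
    EmptyInputError,
)
from tangentia.probe_io import ProbeLayout, SortedUnits, Unit, make_probe_layout
from tangentia.synth import (
    axon_spec,
    make_template,
    render_recording,
    soma_spec,
)
from tangentia.waveforms import (
    MultiChannelWaveform,
    classify_unit,
    correct_adc_offsets,
    estimate_propagation_speed,
    extract_mcw,
    split_af_df,
    waveform_metrics,
)


def _norank_layout(n=8):
    """Layout with all ADC ranks zero (no stagger)."""
    base = make_probe_layout(n)
    return ProbeLayout(n, base.x, base.y, base.adc_group,
                       np.zeros(n, dtype=int), base.vertical_pitch_um,
                       base.n_columns)


class TestExtractMcw:
    def test_noise_free_recovery(self, layout64):
        spec = soma_spec(30, 12)
        tmpl = make_template(spec, layout64)
        times = np.array([0.1, 0.25, 0.4])
        rec = render_recording(SortedUnits([Unit(0, times, 30)]), {0: spec},
                               layout64, noise_sd_uv=0.0, duration_s=0.5)
        mcw = extract_mcw(rec, times)
        assert mcw.n_spikes_used == 3
        assert mcw.peak_channel == 30
        assert np.abs(mcw.values - tmpl.values).max() < 1e-3

    def test_residual_scales_with_spike_count(self):
        # averaging N snippets of noise SD sigma leaves sigma/sqrt(N) RMS
        layout = make_probe_layout(16)
        spec = soma_spec(8, 10)
        tmpl = make_template(spec, layout)
        rng = np.random.default_rng(11)
        n, sigma = 500, 5.0
        times = np.sort(rng.uniform(0.1, 9.9, n))
        rec = render_recording(SortedUnits([Unit(0, times, 8)]), {0: spec},
                               layout, noise_sd_uv=sigma, duration_s=10.0,
                               seed=rng)
        mcw = extract_mcw(rec, times)
        rms = float(np.sqrt(np.mean((mcw.values - tmpl.values) ** 2)))
        assert rms == pytest.approx(sigma / np.sqrt(n), rel=0.2)

    def test_subsample_cap_is_deterministic(self):
        layout = make_probe_layout(4)
        rec_samples = np.zeros((4, 30000), dtype=np.float32)
        from tangentia.probe_io import RawRecording
        rec = RawRecording(rec_samples, 30000.0, layout)
        times = np.linspace(0.2, 0.8, 120)
        a = extract_mcw(rec, times, max_spikes=50, seed=3)
        b = extract_mcw(rec, times, max_spikes=50, seed=3)
        assert a.n_spikes_used == 50
        assert np.array_equal(a.values, b.values)

    def test_no_usable_spikes(self):
        from tangentia.probe_io import RawRecording
        layout = make_probe_layout(4)
        rec = RawRecording(np.zeros((4, 300)), 30000.0, layout)
        with pytest.raises(EmptyInputError):
            extract_mcw(rec, np.array([0.005]))  # window exceeds recording


class TestAdcCorrection:
    def test_identity_when_all_ranks_zero(self):
        layout = _norank_layout(8)
        x = np.random.default_rng(0).normal(size=(8, 300))
        assert np.allclose(correct_adc_offsets(x, layout, 30000.0), x)

    def test_stagger_roundtrip_on_sine(self):
        # stagger a common 1 kHz sine, correct it, compare to the original
        layout = make_probe_layout(8)
        fs = 30000.0
        t = np.arange(3000) / fs
        common = np.sin(2 * np.pi * 1000 * t)
        off_s = layout.sample_offsets_us() * 1e-6
        staggered = np.stack([np.sin(2 * np.pi * 1000 * (t + o))
                              for o in off_s])
        corrected = correct_adc_offsets(staggered, layout, fs)
        resid = corrected - common[None, :]
        rms = np.sqrt(np.mean(resid[:, 100:-100] ** 2))
        assert rms < 0.01  # < 1% of unit amplitude

    def test_post_correction_lag_below_half_microsecond(self):
        layout = make_probe_layout(8)
        fs = 30000.0
        t = np.arange(4096) / fs
        off_s = layout.sample_offsets_us() * 1e-6
        staggered = np.stack([np.sin(2 * np.pi * 1000 * (t + o))
                              for o in off_s])
        corrected = correct_adc_offsets(staggered, layout, fs)
        # cross-correlation lag on 128x upsampled traces
        up = 128
        ref = signal.resample(corrected[0], corrected.shape[1] * up)
        worst = 0.0
        for c in range(1, 8):
            other = signal.resample(corrected[c], corrected.shape[1] * up)
            xc = signal.correlate(other - other.mean(), ref - ref.mean(),
                                  mode="same")
            lag = (np.argmax(xc) - xc.size // 2) / (fs * up)
            worst = max(worst, abs(lag))
        assert worst < 0.5e-6


class TestMetrics:
    def test_exact_spread_count(self, layout128):
        # peak at the tip row: channel distances are distinct, so the
        # constructed profile puts exactly 30 channels above 0.1
        mcw = make_template(soma_spec(0, spread_channels=30), layout128)
        m = waveform_metrics(mcw, layout128)
        # independent brute-force count
        profile = mcw.values.max(axis=1) - mcw.values.min(axis=1)
        assert int((profile / profile.max() > 0.1).sum()) == 30
        assert m.spread_channels == 30

    def test_all_zero_rejected(self, layout64):
        mcw = MultiChannelWaveform(np.zeros((64, 301)), (-5, 5), 30000.0, 1, 0)
        with pytest.raises(DegenerateWaveformError):
            waveform_metrics(mcw, layout64)

    def test_soma_population_mean_amplitudes_recovered(self, layout64):
        mcw = make_template(soma_spec(30, 12, neg_amp_uv=-54.9,
                                      pos_amp_uv=24.6), layout64)
        m = waveform_metrics(mcw, layout64)
        assert m.neg_peak_uv == pytest.approx(-54.9, abs=0.01)
        assert m.pos_peak_uv == pytest.approx(24.6, abs=0.01)

    def test_spread_um_counts_single_row_as_one_pitch(self, layout64):
        values = np.zeros((64, 301))
        values[10, 150] = -50.0
        values[10, 160] = 10.0
        mcw = MultiChannelWaveform(values, (-5, 5), 30000.0, 1, 10)
        m = waveform_metrics(mcw, layout64)
        assert m.spread_channels == 1
        assert m.spread_um == layout64.vertical_pitch_um


class TestClassification:
    def test_axon_is_tca(self, layout128):
        mcw = make_template(axon_spec(40, 15, 1.5), layout128)
        assert classify_unit(waveform_metrics(mcw, layout128)) == "TCA"

    def test_soma_is_v1n(self, layout128):
        mcw = make_template(soma_spec(40, 12), layout128)
        m = waveform_metrics(mcw, layout128)
        assert m.rebound_duration_ms < 1.0  # overshoot, not a long rebound
        assert classify_unit(m) == "V1N"

    def test_narrow_spread_rebound_is_not_tca(self, layout128):
        # long rebound but over too few channels fails the spread criterion
        mcw = make_template(axon_spec(40, spread_channels=6,
                                      rebound_duration_ms=1.5,
                                      af_spread_channels=4), layout128)
        m = waveform_metrics(mcw, layout128)
        assert m.rebound_duration_ms > 1.0
        assert m.rebound_spread_channels <= 10
        assert classify_unit(m) != "TCA"

    def test_subthreshold_amplitude_unclassified(self, layout128):
        mcw = make_template(soma_spec(40, 12, neg_amp_uv=-5.0,
                                      pos_amp_uv=2.0), layout128)
        assert classify_unit(waveform_metrics(mcw, layout128)) == "unclassified"


class TestAfDfDecomposition:
    def test_axon_splits_into_trough_and_rebound(self, layout128):
        mcw = make_template(axon_spec(40, 18, 1.5, af_spread_channels=6),
                            layout128)
        af, df = split_af_df(mcw)
        # trough carries a ~0.5 µV leak from the DF rebound tail
        assert af.values.min() == pytest.approx(-26.1, abs=0.7)
        assert df.values.max() == pytest.approx(12.1, abs=0.2)

    def test_df_spread_exceeds_af_spread_by_construction(self, layout128):
        m = waveform_metrics(
            make_template(axon_spec(40, 20, 1.5, af_spread_channels=6),
                          layout128), layout128)
        assert m.af_metrics is not None and m.df_metrics is not None
        assert m.df_metrics.spread_channels > m.af_metrics.spread_channels

    def test_soma_refused(self, layout128):
        mcw = make_template(soma_spec(40, 12), layout128)
        with pytest.raises(DecompositionError):
            split_af_df(mcw)


class TestPropagationSpeed:
    def _mcw(self, layout, speed, seed, noise=0.3):
        spec = axon_spec(layout.n_channels - 2, 15, 1.5,
                         conduction_speed_m_per_s=speed,
                         af_spread_channels=layout.n_channels)
        mcw = make_template(spec, layout)
        rng = np.random.default_rng(seed)
        mcw.values = mcw.values + rng.normal(0, noise, mcw.values.shape)
        return mcw

    def test_multi_speed_recovery_unbiased(self, layout128):
        # median relative error < 10% across physiological speeds
        for speed in (0.3, 0.92, 2.0):
            errs = []
            for seed in range(10):
                est = estimate_propagation_speed(self._mcw(layout128, speed,
                                                           seed), layout128)
                assert est is not None
                errs.append(abs(est - speed) / speed)
            assert np.median(errs) < 0.10

    def test_simultaneous_arrival_gives_none(self, layout128):
        # infinite conduction speed: every channel peaks at the same time
        spec = axon_spec(126, 15, 1.5, conduction_speed_m_per_s=None,
                         af_spread_channels=128)
        mcw = make_template(spec, layout128)
        rng = np.random.default_rng(5)
        mcw.values = mcw.values + rng.normal(0, 0.3, mcw.values.shape)
        assert estimate_propagation_speed(mcw, layout128) is None

    def test_heavy_noise_gives_none(self, layout128):
        mcw = self._mcw(layout128, 0.92, seed=1, noise=15.0)
        assert estimate_propagation_speed(mcw, layout128) is None

    def test_short_window_rejected(self, layout64):
        mcw = MultiChannelWaveform(np.zeros((64, 90)), (-1, 2), 30000.0, 1, 0)
        with pytest.raises(ValueError):
            estimate_propagation_speed(mcw, layout64)
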