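import numpy as np
import pytest

from tangentia.probe_io import SortedUnits, Unit, make_probe_layout
from tangentia.synth import axon_spec, make_template, render_recording, soma_spec
from tangentia.waveforms import classify_unit, extract_mcw, waveform_metrics


@pytest.fixture(scope="session")
def layout64():
    return make_probe_layout(64)


@pytest.fixture(scope="session")
def layout128():
    return make_probe_layout(128)


def render_unit_batch(layout, specs, n_spikes=2000, noise_sd_uv=10.0,
                      rate_hz=80.0, seed=0):
    """Render one recording holding several units (one template spec per
    peak channel), extract each unit's MCW and classify it.

    Returns the list of labels in the order of ``specs``.
    """
    rng = np.random.default_rng(seed)
    duration = n_spikes / rate_hz + 0.5
    units = []
    for i, spec in enumerate(specs):
        t = np.sort(rng.uniform(0.1, duration - 0.1, n_spikes))
        units.append(Unit(i, t, spec.peak_channel))
    rec = render_recording(SortedUnits(units), dict(enumerate(specs)), layout,
                           noise_sd_uv=noise_sd_uv, seed=rng,
                           duration_s=duration)
    labels = []
    for u in units:
        mcw = extract_mcw(rec, u.spike_times_s)
        labels.append(classify_unit(waveform_metrics(mcw, rec.layout)))
    return labels


def varied_axon_specs(rng, peak_channels):
    """A bank of axonal templates scattered around the population means."""
    specs = []
    for ch in peak_channels:
        specs.append(axon_spec(
            int(ch),
            spread_channels=int(rng.integers(13, 21)),
            rebound_duration_ms=float(rng.uniform(1.2, 2.2)),
            neg_amp_uv=float(rng.uniform(-35, -18)),
            pos_amp_uv=float(rng.uniform(8, 16)),
        ))
    return specs


def varied_soma_specs(rng, peak_channels):
    """A bank of somatic templates scattered around the population means."""
    specs = []
    for ch in peak_channels:
        specs.append(soma_spec(
            int(ch),
            spread_channels=int(rng.integers(8, 16)),
            neg_amp_uv=float(rng.uniform(-80, -30)),
            pos_amp_uv=float(rng.uniform(12, 38)),
        ))
    return specs
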