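"""Ground-truth simulator.

Generates the ingredients the analysis pipeline assumes it will find in a
tangential layer-4 recording: Poisson-with-refractoriness spike trains,
probabilistic monosynaptic transmission with a fixed delay plus Gaussian
jitter, compact biphasic somatic templates, wide low-amplitude multipeaked
axonal templates with finite conduction speed, per-ADC sample-time stagger,
and additive Gaussian noise.  Every stochastic step is driven by an explicit
seed so fixtures are byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dsp import fractional_shift
from .probe_io import (
    DEFAULT_GAIN_UV_PER_BIT,
    ProbeLayout,
    RawRecording,
    SortedUnits,
    Unit,
)
from .waveforms import MultiChannelWaveform

# population-mean amplitudes used as the realistic default regime for fixtures
SOMA_NEG_AMP_UV = -54.9
SOMA_POS_AMP_UV = 24.6
AF_NEG_AMP_UV = -26.1
AF_POS_AMP_UV = 12.8
DF_POS_AMP_UV = 12.1


@dataclass(frozen=True)
class ConnectionSpec:
    """A planted monosynaptic connection: each presynaptic spike evokes,
    with probability ``prob``, one extra postsynaptic spike at
    ``delay_ms`` + N(0, ``jitter_sd_ms``)."""

    pre_id: int
    post_id: int
    prob: float
    delay_ms: float
    jitter_sd_ms: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.prob <= 1):
            raise ValueError(f"transmission prob must be in (0, 1], got {self.prob}")
        if self.delay_ms <= 0:
            raise ValueError(f"connection delay must be positive, got {self.delay_ms}")
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter SD must be non-negative")


@dataclass
class PlantedConnection:
    """Bookkeeping of one realised connection: ``transmitted[i]`` is True
    iff base presynaptic spike i produced an evoked postsynaptic spike that
    landed inside the recording."""

    spec: ConnectionSpec
    transmitted: np.ndarray
    evoked_times_s: np.ndarray

    @property
    def n_transmitted(self) -> int:
        return int(self.transmitted.sum())


@dataclass(frozen=True)
class TemplateSpec:
    """Parameters of one unit's extracellular template.

    For somata, ``spread_channels`` is the number of channels whose
    peak-to-peak profile exceeds 0.1 of the maximum.  For axons it is the
    spread of the late rebound (the synaptic/dendritic contact field, DF);
    ``af_spread_channels`` controls the early narrow axonal field (AF) and
    defaults to roughly half the DF spread.
    """

    kind: str  # "soma" | "axon"
    peak_channel: int
    neg_amp_uv: float
    pos_amp_uv: float
    spread_channels: int
    rebound_duration_ms: float = 0.0
    conduction_speed_m_per_s: float | None = None
    af_df_offset_rows: int = 0
    af_spread_channels: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("soma", "axon"):
            raise ValueError(f"kind must be 'soma' or 'axon', got {self.kind!r}")
        if not (self.neg_amp_uv <= 0 <= self.pos_amp_uv):
            raise ValueError("need neg_amp_uv <= 0 <= pos_amp_uv")
        if self.spread_channels < 1:
            raise ValueError("spread_channels must be >= 1")
        if self.rebound_duration_ms < 0:
            raise ValueError("rebound_duration_ms must be >= 0")


def soma_spec(peak_channel: int, spread_channels: int = 12,
              neg_amp_uv: float = SOMA_NEG_AMP_UV,
              pos_amp_uv: float = SOMA_POS_AMP_UV) -> TemplateSpec:
    """Somatic template at the population-mean amplitude regime."""
    return TemplateSpec("soma", peak_channel, neg_amp_uv, pos_amp_uv, spread_channels)


def axon_spec(peak_channel: int, spread_channels: int = 15,
              rebound_duration_ms: float = 1.5,
              neg_amp_uv: float = AF_NEG_AMP_UV,
              pos_amp_uv: float = DF_POS_AMP_UV,
              conduction_speed_m_per_s: float | None = None,
              af_df_offset_rows: int = 0,
              af_spread_channels: int | None = None) -> TemplateSpec:
    """Thalamocortical-axon template at the population-mean amplitude regime."""
    return TemplateSpec("axon", peak_channel, neg_amp_uv, pos_amp_uv,
                        spread_channels, rebound_duration_ms,
                        conduction_speed_m_per_s, af_df_offset_rows,
                        af_spread_channels)


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    connections: list[PlantedConnection] = field(default_factory=list)
    templates: dict[int, TemplateSpec] = field(default_factory=dict)
    duration_s: float = 0.0

    def connection(self, pre_id: int, post_id: int) -> PlantedConnection:
        for c in self.connections:
            if c.spec.pre_id == pre_id and c.spec.post_id == post_id:
                return c
        raise KeyError(f"no planted connection {pre_id}->{post_id}")

    def edge_set(self) -> set[tuple[int, int]]:
        return {(c.spec.pre_id, c.spec.post_id) for c in self.connections}


def _poisson_refractory(rng: np.random.Generator, rate_hz: float,
                        duration_s: float, refractory_ms: float) -> np.ndarray:
    """Homogeneous Poisson train thinned by an absolute dead time."""
    n = rng.poisson(rate_hz * duration_s)
    t = np.sort(rng.uniform(0.0, duration_s, n))
    if refractory_ms <= 0 or t.size < 2:
        return t
    dead = refractory_ms / 1e3
    keep = np.empty(t.size, dtype=bool)
    last = -np.inf
    for i, ti in enumerate(t):
        ok = (ti - last) >= dead
        keep[i] = ok
        if ok:
            last = ti
    return t[keep]


def simulate_trains(
    rates_hz: Mapping[int, float],
    duration_s: float,
    connections: Sequence[ConnectionSpec] = (),
    refractory_ms: float = 1.0,
    seed: int | np.random.Generator = 0,
    labels: Mapping[int, str] | None = None,
    peak_channels: Mapping[int, int] | None = None,
) -> tuple[SortedUnits, GroundTruth]:
    """Simulate connected spike trains.

    Each unit fires as a homogeneous Poisson process thinned by an absolute
    refractory period.  For every connection, each presynaptic spike
    independently evokes (probability ``prob``) one extra postsynaptic spike
    at ``delay_ms`` + N(0, jitter); evoked spikes bypass the refractoriness
    of the target unit, so the transmission efficacy equals ``prob`` exactly
    in expectation.  Unless explicit ``labels`` are given, presynaptic units
    of planted connections are labelled TCA, postsynaptic units V1N, and the
    rest left unclassified.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if refractory_ms < 0:
        raise ValueError("refractory_ms must be non-negative")
    for uid, r in rates_hz.items():
        if r < 0:
            raise ValueError(f"negative rate for unit {uid}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    base: dict[int, np.ndarray] = {}
    for uid in sorted(rates_hz):
        base[uid] = _poisson_refractory(rng, rates_hz[uid], duration_s, refractory_ms)

    extra: dict[int, list[np.ndarray]] = {uid: [] for uid in base}
    planted: list[PlantedConnection] = []
    for spec in connections:
        if spec.pre_id not in base or spec.post_id not in base:
            raise ValueError(f"connection references unknown unit: {spec}")
        pre = base[spec.pre_id]
        fire = rng.random(pre.size) < spec.prob
        idx = np.flatnonzero(fire)
        evoked = (pre[idx] + spec.delay_ms / 1e3
                  + rng.normal(0.0, spec.jitter_sd_ms / 1e3, idx.size))
        inside = (evoked >= 0) & (evoked < duration_s)
        transmitted = np.zeros(pre.size, dtype=bool)
        transmitted[idx[inside]] = True
        evoked = evoked[inside]
        extra[spec.post_id].append(evoked)
        planted.append(PlantedConnection(spec, transmitted, np.sort(evoked)))

    auto_labels: dict[int, str] = {uid: "unclassified" for uid in base}
    for spec in connections:
        auto_labels[spec.pre_id] = "TCA"
        auto_labels[spec.post_id] = "V1N"
    if labels:
        auto_labels.update(labels)
    peaks = dict(peak_channels or {})

    units = []
    for uid in sorted(base):
        t = np.sort(np.concatenate([base[uid], *extra[uid]])) if extra[uid] else base[uid]
        units.append(Unit(unit_id=uid, spike_times_s=t,
                          peak_channel=peaks.get(uid, 0),
                          label=auto_labels[uid]))
    gt = GroundTruth(connections=planted, duration_s=duration_s)
    return SortedUnits(units=units, duration_s=duration_s), gt


# ---------------------------------------------------------------------------
# templates


def _spatial_weights(layout: ProbeLayout, center_xy: tuple[float, float],
                     n_supra: int, power: int = 2,
                     supra_level: float = 0.1) -> np.ndarray:
    """Per-channel weights w = exp(-(d/s)^power / 2) with the scale chosen
    so that exactly ``n_supra`` channels (the nearest ones) exceed
    ``supra_level`` — up to exact distance ties on the grid."""
    if not (0 < supra_level < 1):
        raise ValueError("supra_level must be in (0, 1)")
    d = np.hypot(layout.x - center_xy[0], layout.y - center_xy[1])
    ds = np.sort(d)
    if n_supra > layout.n_channels:
        raise ValueError(
            f"requested spread of {n_supra} channels exceeds the "
            f"{layout.n_channels}-channel probe span"
        )
    if n_supra == layout.n_channels:
        # full-probe spread: keep the profile nearly flat across the probe
        d_mid = 2.0 * ds[-1] + layout.vertical_pitch_um
    else:
        d_mid = 0.5 * (ds[n_supra - 1] + ds[n_supra])
        if d_mid == 0:
            d_mid = 0.5 * layout.vertical_pitch_um
    # solve exp(-(d_mid/s)^power / 2) = supra_level
    s = d_mid / (2.0 * math.log(1.0 / supra_level)) ** (1.0 / power)
    return np.exp(-0.5 * (d / s) ** power)


def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


# temporal shape constants (ms); trough and overshoot Gaussians are kept
# far enough apart that their overlap is < 1e-5 of either amplitude, so the
# nominal amplitudes are recovered exactly by peak measurements
_SOMA_TROUGH_SD = 0.08
_SOMA_OVERSHOOT_MU = 0.6
_SOMA_OVERSHOOT_SD = 0.12
_AF_TROUGH_SD = 0.08
_AF_OVERSHOOT_MU = 0.35
_AF_OVERSHOOT_SD = 0.12
# the AF's own positive overshoot stays well below the DF rebound so the
# late rebound dominates the positive excursions of an axonal waveform
_AF_OVERSHOOT_FRACTION = 0.35
_HALF_HEIGHT_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = factor * sd


def make_template(spec: TemplateSpec, layout: ProbeLayout,
                  window_ms: tuple[float, float] = (-5.0, 5.0),
                  sampling_rate_hz: float = 30_000.0) -> MultiChannelWaveform:
    """Render a noise-free multichannel template.

    Somata are compact biphasic waveforms (narrow trough at t = 0, small
    overshoot < 1 ms) whose Gaussian spatial decay places exactly
    ``spread_channels`` channels above 0.1 of the normalised peak-to-peak
    profile.  Axons combine a narrow early axonal field (AF, flat-top
    spatial profile along the probe) with a broad positive rebound (DF)
    whose half-height duration equals ``rebound_duration_ms``, centred
    ``af_df_offset_rows`` rows away.  A finite conduction speed shifts the
    AF per channel by (vertical distance)/(speed), channels nearer the tip
    leading.
    """
    if not (0 <= spec.peak_channel < layout.n_channels):
        raise ValueError(f"peak_channel {spec.peak_channel} outside layout")
    pre, post = window_ms
    n_t = int(round((post - pre) * 1e-3 * sampling_rate_hz)) + 1
    t = pre + np.arange(n_t) / sampling_rate_hz * 1e3  # ms
    cx = float(layout.x[spec.peak_channel])
    cy = float(layout.y[spec.peak_channel])

    if spec.kind == "soma":
        shape = (spec.neg_amp_uv * _gauss(t, 0.0, _SOMA_TROUGH_SD)
                 + spec.pos_amp_uv * _gauss(t, _SOMA_OVERSHOOT_MU, _SOMA_OVERSHOOT_SD))
        w = _spatial_weights(layout, (cx, cy), spec.spread_channels, power=2)
        values = w[:, None] * shape[None, :]
    else:
        af_pos = _AF_OVERSHOOT_FRACTION * spec.pos_amp_uv
        af_w = _spatial_weights(
            layout, (cx, cy),
            spec.af_spread_channels or max(3, spec.spread_channels // 2),
            power=4,
        )
        if spec.conduction_speed_m_per_s is not None:
            um_per_ms = spec.conduction_speed_m_per_s * 1e3
            shift = (layout.y - cy) / um_per_ms  # ms; below peak -> earlier
        else:
            shift = np.zeros(layout.n_channels)
        tt = t[None, :] - shift[:, None]
        af = af_w[:, None] * (spec.neg_amp_uv * _gauss(tt, 0.0, _AF_TROUGH_SD)
                              + af_pos * _gauss(tt, _AF_OVERSHOOT_MU, _AF_OVERSHOOT_SD))
        values = af
        if spec.rebound_duration_ms > 0 and spec.pos_amp_uv != 0:
            sd_t = spec.rebound_duration_ms / _HALF_HEIGHT_FACTOR
            mu_t = 0.7 + 1.4 * sd_t
            df_cy = cy + spec.af_df_offset_rows * layout.vertical_pitch_um
            df_w = _spatial_weights(layout, (cx, df_cy), spec.spread_channels, power=2)
            values = values + (df_w[:, None]
                               * spec.pos_amp_uv * _gauss(t, mu_t, sd_t)[None, :])

    return MultiChannelWaveform(
        values=values,
        window_ms=(pre, post),
        sampling_rate_hz=sampling_rate_hz,
        n_spikes_used=1,
        peak_channel=spec.peak_channel,
    )


# ---------------------------------------------------------------------------
# rendering


def inject_waveform(samples: np.ndarray, values: np.ndarray,
                    times_s: np.ndarray, t0_ms: float,
                    sampling_rate_hz: float) -> None:
    """Add ``values`` (channels x time, first column at ``t0_ms`` relative
    to each event) into ``samples`` in place at every event time.  Events
    whose window sticks out of the recording are clipped."""
    n_ch, n_t = values.shape
    n_samples = samples.shape[1]
    v32 = values.astype(samples.dtype, copy=False)
    starts = np.rint(np.asarray(times_s) * sampling_rate_hz).astype(np.int64)
    starts += int(round(t0_ms * 1e-3 * sampling_rate_hz))
    for s0 in starts:
        a, b = max(s0, 0), min(s0 + n_t, n_samples)
        if a >= b:
            continue
        samples[:, a:b] += v32[:, a - s0:b - s0]


def render_recording(
    units: SortedUnits,
    templates: Mapping[int, TemplateSpec],
    layout: ProbeLayout,
    noise_sd_uv: float = 10.0,
    seed: int | np.random.Generator = 0,
    duration_s: float | None = None,
    sampling_rate_hz: float = 30_000.0,
    gain_uv_per_bit: float = DEFAULT_GAIN_UV_PER_BIT,
    window_ms: tuple[float, float] = (-5.0, 5.0),
) -> RawRecording:
    """Render a spike-band recording by linear superposition of templates.

    Per-channel ADC sampling offsets (``adc_rank`` x 2.78 µs) are emulated
    by band-limited fractional resampling of the clean signal, then i.i.d.
    Gaussian noise of ``noise_sd_uv`` is added.  Deterministic for a fixed
    seed.
    """
    for u in units:
        if u.unit_id not in templates:
            raise ValueError(f"no template for unit {u.unit_id}")
    if duration_s is None:
        last = max((u.spike_times_s[-1] for u in units if u.n_spikes), default=0.0)
        duration_s = last + 2 * abs(window_ms[0]) * 1e-3 + 0.01
    n_samples = int(round(duration_s * sampling_rate_hz))
    for u in units:
        if u.n_spikes and u.spike_times_s[-1] >= duration_s:
            raise ValueError(
                f"unit {u.unit_id} spikes beyond the {duration_s:.3f}-s recording"
            )

    clean = np.zeros((layout.n_channels, n_samples), dtype=np.float32)
    # ADC stagger is a per-channel linear time shift and the noise is
    # i.i.d. (invariant under resampling), so applying the shift to each
    # unit's template once before injection is exact and cheap: a channel
    # of rank r is digitised r x 2.78 µs late, so its stored trace leads
    # by that amount
    offsets_samples = layout.sample_offsets_us() * 1e-6 * sampling_rate_hz
    for u in units:
        if not u.n_spikes:
            continue
        tmpl = make_template(templates[u.unit_id], layout, window_ms,
                             sampling_rate_hz)
        values = fractional_shift(tmpl.values, -offsets_samples)
        inject_waveform(clean, values, u.spike_times_s, window_ms[0],
                        sampling_rate_hz)

    if noise_sd_uv > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        for c in range(layout.n_channels):  # chunked: bounded peak memory
            clean[c] += rng.normal(0.0, noise_sd_uv, n_samples).astype(np.float32)

    return RawRecording(samples=clean, sampling_rate_hz=sampling_rate_hz,
                        layout=layout, gain_uv_per_bit=gain_uv_per_bit)


# ---------------------------------------------------------------------------
# visual stimulation


def simulate_visual_responses(
    baseline_rate_hz: float,
    gain_map: np.ndarray,
    n_trials: int,
    frame_ms: float = 100.0,
    targets_per_frame: int = 2,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Simulate sparse-noise responses of one unit.

    Each trial presents every pixel of the grid once (``targets_per_frame``
    pixels per 100-ms frame, random order); during a frame the unit fires
    as an inhomogeneous Poisson process at baseline + sum of the gains of
    the shown pixels (Hz).  Returns ``(stimulus_log, spike_times_s,
    trial_onsets_s)``; the log has one row per shown target with columns
    frame_onset_s, pixel_row, pixel_col, polarity, trial.
    """
    gain_map = np.asarray(gain_map, dtype=float)
    if np.any(gain_map < 0):
        raise ValueError("pixel gains must be non-negative")
    if baseline_rate_hz < 0:
        raise ValueError("baseline rate must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rows, cols = gain_map.shape
    pix = np.arange(rows * cols)
    n_frames = pix.size // targets_per_frame
    frame_s = frame_ms / 1e3
    trial_dur = n_frames * frame_s

    log_rows = []
    spikes = []
    trial_onsets = np.arange(n_trials) * trial_dur
    for trial in range(n_trials):
        order = rng.permutation(pix)[: n_frames * targets_per_frame]
        shown = order.reshape(n_frames, targets_per_frame)
        onsets = trial_onsets[trial] + np.arange(n_frames) * frame_s
        rates = baseline_rate_hz + gain_map.ravel()[shown].sum(axis=1)
        counts = rng.poisson(rates * frame_s)
        for f in range(n_frames):
            if counts[f]:
                spikes.append(onsets[f] + np.sort(rng.uniform(0, frame_s, counts[f])))
            for k in range(targets_per_frame):
                log_rows.append((onsets[f], shown[f, k] // cols,
                                 shown[f, k] % cols, 1, trial))
    log = pd.DataFrame(log_rows, columns=["frame_onset_s", "pixel_row",
                                          "pixel_col", "polarity", "trial"])
    spike_times = (np.concatenate(spikes) if spikes else np.empty(0))
    return log, spike_times, trial_onsets
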