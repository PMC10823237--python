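"""Multichannel waveform (MCW) extraction and metrics.

An MCW is the spike-triggered average of the spike-band signal across all
probe channels for one unit.  This module computes it (with ADC sample-time
correction), measures amplitudes, spatial spreads and the late rebound,
classifies units as thalamocortical axons (TCA) versus cortical somata
(V1N), decomposes axonal waveforms into the early axonal field (AF) and the
late dendritic/synaptic contact field (DF), and estimates conduction speed
from threshold-crossing times along probe columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .dsp import fractional_shift
from .errors import DecompositionError, DegenerateWaveformError, EmptyInputError
from .probe_io import ProbeLayout, RawRecording

#: default cap on the number of spikes averaged into an MCW
MAX_SPIKES_PER_MCW = 50_000

#: fraction of the peak-to-peak profile a channel must exceed to count
#: toward the spatial spread
SPREAD_PROFILE_LEVEL = 0.1

# TCA classification rule: rebound longer than 1 ms over more than 10 channels
TCA_REBOUND_MIN_MS = 1.0
TCA_REBOUND_MIN_CHANNELS = 10

#: minimum trough magnitude for a clear somatic waveform (µV)
V1N_MIN_TROUGH_UV = 15.0


@dataclass
class MultiChannelWaveform:
    """Spike-triggered average, channels x time, in µV."""

    values: np.ndarray
    window_ms: tuple[float, float]
    sampling_rate_hz: float
    n_spikes_used: int
    peak_channel: int

    @property
    def n_channels(self) -> int:
        return int(self.values.shape[0])

    @property
    def times_ms(self) -> np.ndarray:
        n_t = self.values.shape[1]
        return self.window_ms[0] + np.arange(n_t) / self.sampling_rate_hz * 1e3


@dataclass
class SegmentMetrics:
    """Amplitudes and spread of one temporal segment (AF or DF)."""

    pos_peak_uv: float
    neg_peak_uv: float
    spread_channels: int
    spread_um: float


@dataclass
class WaveformMetrics:
    pos_peak_uv: float
    neg_peak_uv: float
    spread_channels: int
    spread_um: float
    rebound_amp_uv: float
    rebound_duration_ms: float
    rebound_spread_channels: int
    af_metrics: SegmentMetrics | None = None
    df_metrics: SegmentMetrics | None = None


def correct_adc_offsets(values: np.ndarray, layout: ProbeLayout,
                        sampling_rate_hz: float) -> np.ndarray:
    """Undo the per-channel ADC sampling stagger.

    A channel of rank r is digitised r x 2.78 µs after rank 0, so spike
    features appear earlier on its stored trace; the correction applies the
    compensating band-limited fractional delay.  Identity when all ranks
    are 0.
    """
    shift = layout.sample_offsets_us() * 1e-6 * sampling_rate_hz
    return fractional_shift(values, shift)


def extract_mcw(rec: RawRecording, spike_times_s: np.ndarray,
                max_spikes: int = MAX_SPIKES_PER_MCW,
                window_ms: tuple[float, float] = (-5.0, 5.0),
                seed: int | np.random.Generator = 0) -> MultiChannelWaveform:
    """Average peri-spike snippets of the raw spike band into an MCW.

    Spikes whose window sticks out of the recording are dropped; when more
    than ``max_spikes`` remain, a seed-deterministic random subsample is
    used.  ADC offset correction (a per-channel linear time shift, which
    commutes with averaging over spikes) is applied to the mean snippet.
    The peak channel is the one with the largest trough, ties resolved to
    the lowest index.
    """
    fs = rec.sampling_rate_hz
    pre = int(round(-window_ms[0] * 1e-3 * fs))
    post = int(round(window_ms[1] * 1e-3 * fs))
    centers = np.rint(np.asarray(spike_times_s) * fs).astype(np.int64)
    centers = centers[(centers - pre >= 0) & (centers + post < rec.n_samples)]
    if centers.size == 0:
        raise EmptyInputError("no spike fits fully inside the recording")
    if centers.size > max_spikes:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        centers = np.sort(rng.choice(centers, size=max_spikes, replace=False))
    acc = np.zeros((rec.layout.n_channels, pre + post + 1), dtype=np.float64)
    for c in centers:
        acc += rec.samples[:, c - pre:c + post + 1]
    mean = acc / centers.size
    mean = correct_adc_offsets(mean, rec.layout, fs)
    peak_channel = int(np.argmin(mean.min(axis=1)))
    return MultiChannelWaveform(values=mean, window_ms=window_ms,
                                sampling_rate_hz=fs,
                                n_spikes_used=int(centers.size),
                                peak_channel=peak_channel)


def _spread(values: np.ndarray, layout: ProbeLayout) -> tuple[int, float]:
    """Channel count and vertical extent of the supra-threshold profile."""
    profile = values.max(axis=1) - values.min(axis=1)
    m = profile.max()
    if m <= 0:
        return 0, 0.0
    supra = profile / m > SPREAD_PROFILE_LEVEL
    n = int(supra.sum())
    ys = layout.y[supra]
    # a single supra-threshold row spans one pitch, not zero
    extent = float(ys.max() - ys.min() + layout.vertical_pitch_um) if n else 0.0
    return n, extent


def _rebound(values: np.ndarray, peak_channel: int,
             dt_ms: float) -> tuple[float, float, slice]:
    """Largest positive excursion (any channel) after the peak-channel
    trough; duration measured at half height on the rebound channel.

    Returns (height µV, duration ms, half-height index slice)."""
    trough = int(np.argmin(values[peak_channel]))
    tail = values[:, trough:]
    ch, rb_rel = np.unravel_index(int(np.argmax(tail)), tail.shape)
    height = float(tail[ch, rb_rel])
    if height <= 0:
        return 0.0, 0.0, slice(0, 0)
    half = height / 2.0
    above = tail[ch] >= half
    lo = int(rb_rel)
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = int(rb_rel)
    while hi + 1 < above.size and above[hi + 1]:
        hi += 1
    duration = (hi - lo + 1) * dt_ms
    return height, duration, slice(trough + lo, trough + hi + 1)


def waveform_metrics(mcw: MultiChannelWaveform, layout: ProbeLayout,
                     decompose: bool = True) -> WaveformMetrics:
    """Amplitudes, spreads and rebound measurements of an MCW.

    The spatial profile is the per-channel peak-to-peak amplitude of the
    mean waveform normalised to its maximum; the spread is the number of
    channels above 0.1 and the vertical extent they cover.  The rebound is
    the largest positive excursion after the trough at the peak channel,
    its duration measured at half height and its spread from the profile of
    the half-height time window.  When the rebound satisfies the TCA rule
    and ``decompose`` is set, AF/DF segment metrics are filled in.
    """
    if not np.any(mcw.values):
        raise DegenerateWaveformError("all-zero waveform")
    trace = mcw.values[mcw.peak_channel]
    dt_ms = 1e3 / mcw.sampling_rate_hz
    spread_n, spread_um = _spread(mcw.values, layout)
    height, duration, rb_slice = _rebound(mcw.values, mcw.peak_channel, dt_ms)
    if height > 0:
        rb_win = mcw.values[:, rb_slice]
        rb_profile = rb_win.max(axis=1)
        rb_spread = int((rb_profile / rb_profile.max() > SPREAD_PROFILE_LEVEL).sum()) \
            if rb_profile.max() > 0 else 0
    else:
        rb_spread = 0
    metrics = WaveformMetrics(
        pos_peak_uv=float(trace.max()),
        neg_peak_uv=float(trace.min()),
        spread_channels=spread_n,
        spread_um=spread_um,
        rebound_amp_uv=height,
        rebound_duration_ms=duration,
        rebound_spread_channels=rb_spread,
    )
    if (decompose and duration > TCA_REBOUND_MIN_MS
            and rb_spread > TCA_REBOUND_MIN_CHANNELS):
        try:
            af, df = split_af_df(mcw)
        except DecompositionError:
            pass
        else:
            metrics.af_metrics = _segment_metrics(af, layout)
            metrics.df_metrics = _segment_metrics(df, layout)
    return metrics


def _segment_metrics(seg: MultiChannelWaveform, layout: ProbeLayout) -> SegmentMetrics:
    n, um = _spread(seg.values, layout)
    return SegmentMetrics(
        pos_peak_uv=float(seg.values.max()),
        neg_peak_uv=float(seg.values.min()),
        spread_channels=n,
        spread_um=um,
    )


def classify_unit(metrics: WaveformMetrics,
                  rebound_min_ms: float = TCA_REBOUND_MIN_MS,
                  rebound_min_channels: int = TCA_REBOUND_MIN_CHANNELS,
                  min_trough_uv: float = V1N_MIN_TROUGH_UV) -> str:
    """Label a unit TCA, V1N or unclassified.

    TCA requires a second large rebound peak longer than ``rebound_min_ms``
    spread over more than ``rebound_min_channels`` channels; failing that, a
    clear somatic trough (|trough| >= ``min_trough_uv``) gives V1N;
    otherwise the unit stays unclassified.
    """
    if (metrics.rebound_duration_ms > rebound_min_ms
            and metrics.rebound_spread_channels > rebound_min_channels):
        return "TCA"
    if -metrics.neg_peak_uv >= min_trough_uv:
        return "V1N"
    return "unclassified"


def split_af_df(mcw: MultiChannelWaveform) -> tuple[MultiChannelWaveform,
                                                    MultiChannelWaveform]:
    """Split an axonal MCW at the zero crossing between the first trough and
    the rebound peak on the peak channel: the earlier segment is the axonal
    field (AF), the later the dendritic/synaptic contact field (DF)."""
    dt_ms = 1e3 / mcw.sampling_rate_hz
    height, duration, _ = _rebound(mcw.values, mcw.peak_channel, dt_ms)
    if height <= 0:
        raise DecompositionError("no positive rebound after the trough")
    if duration <= TCA_REBOUND_MIN_MS:
        raise DecompositionError(
            f"rebound lasts only {duration:.2f} ms: compact somatic waveform, "
            "AF/DF decomposition refused"
        )
    trace = mcw.values[mcw.peak_channel]
    trough = int(np.argmin(trace))
    tail = trace[trough:]
    rb = trough + int(np.argmax(tail))
    if trace[rb] <= 0 or rb <= trough:
        raise DecompositionError("no positive rebound on the peak channel")
    cross = None
    for i in range(trough, rb + 1):
        if trace[i] >= 0:
            cross = i
            break
    if cross is None:
        raise DecompositionError("no zero crossing between trough and rebound")
    t = mcw.times_ms
    af = MultiChannelWaveform(mcw.values[:, :cross],
                              (mcw.window_ms[0], float(t[cross - 1])),
                              mcw.sampling_rate_hz, mcw.n_spikes_used,
                              mcw.peak_channel)
    df_vals = mcw.values[:, cross:]
    df_peak = int(np.argmin(df_vals.min(axis=1)))
    df = MultiChannelWaveform(df_vals, (float(t[cross]), mcw.window_ms[1]),
                              mcw.sampling_rate_hz, mcw.n_spikes_used, df_peak)
    return af, df


def estimate_propagation_speed(
    mcw: MultiChannelWaveform,
    layout: ProbeLayout,
    baseline_window_ms: tuple[float, float] = (-5.0, -2.5),
    detect_window_ms: tuple[float, float] = (-2.5, -0.1),
    thresh_sd: float = 4.0,
    min_r: float = 0.725,
    min_gap_channels: int = 5,
    min_points: int = 5,
) -> float | None:
    """Axonal conduction speed from per-channel threshold-crossing times.

    Per probe column, the AP arrival time on each channel is the first
    sample inside ``detect_window_ms`` whose magnitude reaches
    ``thresh_sd`` standard deviations of that channel's baseline
    (``baseline_window_ms``); channels within ``min_gap_channels`` of the
    peak channel or of the probe tip are excluded.  A line is fitted to
    position-versus-time per column and the best column with correlation
    above ``min_r`` gives the speed in m/s; returns None when no column
    qualifies (e.g. simultaneous peaks on all channels).
    """
    t = mcw.times_ms
    if t[0] > baseline_window_ms[0] + 1e-9:
        raise ValueError(
            f"MCW window starts at {t[0]:.2f} ms; propagation analysis needs "
            f"{baseline_window_ms[0]} ms of pre-spike baseline"
        )
    base_mask = (t >= baseline_window_ms[0]) & (t < baseline_window_ms[1])
    det_mask = (t >= detect_window_ms[0]) & (t < detect_window_ms[1])
    det_times = t[det_mask]
    peak_y = layout.y[mcw.peak_channel]

    best: tuple[float, float] | None = None  # (|r|, speed)
    for _, col in layout.columns().items():
        ys = layout.y[col]
        near_peak = int(np.argmin(np.abs(ys - peak_y)))
        xs, ts = [], []
        for pos, ch in enumerate(col):
            if pos < min_gap_channels or abs(pos - near_peak) < min_gap_channels:
                continue
            trace = mcw.values[ch]
            sd = float(np.std(trace[base_mask]))
            if sd == 0:
                continue
            seg = np.abs(trace[det_mask])
            thr = thresh_sd * sd
            hits = np.flatnonzero(seg >= thr)
            if hits.size == 0 or hits[0] == 0:
                # no crossing, or already supra-threshold at the window
                # start (the AP arrived earlier: censored, unusable)
                continue
            h = int(hits[0])
            # sub-sample crossing time by linear interpolation
            frac = (thr - seg[h - 1]) / (seg[h] - seg[h - 1])
            dt = det_times[h] - det_times[h - 1]
            xs.append(float(ys[pos]))
            ts.append(float(det_times[h - 1] + frac * dt))
        if len(xs) < min_points:
            continue
        ts_arr = np.asarray(ts)
        if np.ptp(ts_arr) == 0:  # simultaneous arrival: infinite-slope fit
            continue
        fit = stats.linregress(ts_arr, np.asarray(xs))
        r = abs(float(fit.rvalue))
        if r <= min_r:
            continue
        speed = abs(float(fit.slope)) / 1e3  # µm/ms -> m/s
        if best is None or r > best[0]:
            best = (r, speed)
    return best[1] if best else None
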