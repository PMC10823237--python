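"""Spike-triggered-average (STA) axonal footprints.

Averaging the spike-band signal of a second probe on the spike times of a
presynaptic neuron reveals the extracellular field of its axon at the site
of its synaptic contacts: thalamocortical axons leave a measurable negative
footprint across many channels, long-range cortico-cortical axons do not.
Presynaptic triggers falling within ±1 ms of a postsynaptic spike are
excluded so the postsynaptic soma does not contaminate the average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError
from .probe_io import RawRecording

#: default cap on the number of presynaptic triggers
MAX_STA_TRIGGERS = 20_000

#: STA amplitude threshold (µV) a channel must cross (negatively) to count
#: toward the footprint width
STA_WIDTH_THRESH_UV = -0.75

#: the axonal response is read 1 ms before the CCG peak lag
RESPONSE_LAG_OFFSET_MS = 1.0


@dataclass
class StaMap:
    """Trigger-averaged spike-band signal, channels x lag, in µV."""

    values: np.ndarray
    window_ms: tuple[float, float]
    sampling_rate_hz: float
    n_spikes_used: int
    excluded_spikes: int

    @property
    def lags_ms(self) -> np.ndarray:
        n_t = self.values.shape[1]
        return self.window_ms[0] + np.arange(n_t) / self.sampling_rate_hz * 1e3


@dataclass
class StaFootprint:
    """Amplitude and width of the axonal response at the contact site."""

    amplitude_uv: float
    width_channels: int
    detected: bool
    response_lag_ms: float


def compute_sta(rec_post: RawRecording, pre_times_s: np.ndarray,
                post_times_s: np.ndarray | None = None,
                n_max: int = MAX_STA_TRIGGERS,
                exclusion_ms: float = 1.0,
                window_ms: tuple[float, float] = (-5.0, 10.0),
                seed: int | np.random.Generator = 0) -> StaMap:
    """Average the postsynaptic-probe spike band on presynaptic spike times.

    Presynaptic spikes within ``exclusion_ms`` of any postsynaptic spike
    are dropped first; of the remainder a seed-deterministic random
    subsample of at most ``n_max`` triggers the average.
    """
    pre = np.sort(np.asarray(pre_times_s, dtype=float))
    n_before = pre.size
    if post_times_s is not None and len(post_times_s) and exclusion_ms > 0:
        post = np.sort(np.asarray(post_times_s, dtype=float))
        idx = np.searchsorted(post, pre)
        d_prev = np.where(idx > 0, pre - post[np.clip(idx - 1, 0, post.size - 1)],
                          np.inf)
        d_next = np.where(idx < post.size,
                          post[np.clip(idx, 0, post.size - 1)] - pre, np.inf)
        near = np.minimum(d_prev, d_next) <= exclusion_ms / 1e3
        pre = pre[~near]
    excluded = n_before - pre.size

    fs = rec_post.sampling_rate_hz
    lag0 = int(round(window_ms[0] * 1e-3 * fs))
    lag1 = int(round(window_ms[1] * 1e-3 * fs))
    centers = np.rint(pre * fs).astype(np.int64)
    centers = centers[(centers + lag0 >= 0) & (centers + lag1 < rec_post.n_samples)]
    if centers.size == 0:
        raise EmptyInputError("no usable presynaptic triggers after exclusion")
    if centers.size > n_max:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        centers = np.sort(rng.choice(centers, size=n_max, replace=False))
    acc = np.zeros((rec_post.layout.n_channels, lag1 - lag0 + 1), dtype=np.float64)
    for c in centers:
        acc += rec_post.samples[:, c + lag0:c + lag1 + 1]
    return StaMap(values=acc / centers.size, window_ms=window_ms,
                  sampling_rate_hz=fs, n_spikes_used=int(centers.size),
                  excluded_spikes=int(excluded))


def sta_footprint(sta: StaMap, post_peak_channel: int, ccg_peak_lag_ms: float,
                  thresh_uv: float = STA_WIDTH_THRESH_UV) -> StaFootprint:
    """Measure the axonal footprint at the postsynaptic contact site.

    The response is read at lag = CCG peak lag - 1 ms (rounded to the
    nearest sample): the amplitude at the postsynaptic peak channel, and
    the width as the number of channels below ``thresh_uv`` at that lag.
    Width 0 means no detectable footprint (n.d.).
    """
    lag_ms = ccg_peak_lag_ms - RESPONSE_LAG_OFFSET_MS
    if not (sta.window_ms[0] <= lag_ms <= sta.window_ms[1]):
        raise ValueError(
            f"response lag {lag_ms:.2f} ms outside STA window {sta.window_ms}"
        )
    k = int(round((lag_ms - sta.window_ms[0]) * 1e-3 * sta.sampling_rate_hz))
    k = min(k, sta.values.shape[1] - 1)
    column = sta.values[:, k]
    width = int((column < thresh_uv).sum())
    return StaFootprint(
        amplitude_uv=float(column[post_peak_channel]),
        width_channels=width,
        detected=width > 0,
        response_lag_ms=lag_ms,
    )
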