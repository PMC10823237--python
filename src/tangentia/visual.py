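"""Visual-response characterisation: sparse-noise receptive fields with an
SNR quality filter, and the Fano factor of trial-repeated spike counts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyInputError

DEFAULT_GRID_SHAPE = (36, 22)
DEFAULT_FRAME_MS = 100.0
RF_SNR_THRESHOLD = 15.0


@dataclass
class ReceptiveField:
    """Sparse-noise receptive field: per-pixel evoked spike counts."""

    grid: np.ndarray
    interp_grid: np.ndarray
    snr: float
    passes: bool


def compute_rf(spike_times_s: np.ndarray, stimulus_log: pd.DataFrame,
               grid_shape: tuple[int, int] = DEFAULT_GRID_SHAPE,
               frame_ms: float = DEFAULT_FRAME_MS,
               latency_ms: float = 0.0,
               snr_threshold: float = RF_SNR_THRESHOLD) -> ReceptiveField:
    """Receptive field from a sparse-noise stimulus log.

    For every shown target the spikes inside its frame window (optionally
    shifted by ``latency_ms``) are summed onto the target's pixel and
    accumulated over repeats.  The map is cubic-interpolated at 2x
    resolution and its SNR computed as 1/SD of the peak-normalised map;
    the unit passes the quality filter when SNR exceeds
    ``snr_threshold``.
    """
    if stimulus_log.empty:
        raise EmptyInputError("stimulus log contains no frames")
    spikes = np.sort(np.asarray(spike_times_s, dtype=float))
    onsets = stimulus_log["frame_onset_s"].to_numpy(float) + latency_ms / 1e3
    rows = stimulus_log["pixel_row"].to_numpy(int)
    cols = stimulus_log["pixel_col"].to_numpy(int)
    counts = (np.searchsorted(spikes, onsets + frame_ms / 1e3)
              - np.searchsorted(spikes, onsets))
    grid = np.zeros(grid_shape, dtype=float)
    np.add.at(grid, (rows, cols), counts)

    interp = ndimage.zoom(grid, 2, order=3)
    peak = grid.max()
    if peak > 0:
        sd = float(np.std(grid / peak))
        snr = 1.0 / sd if sd > 0 else float("inf")
    else:
        snr = 0.0
    return ReceptiveField(grid=grid, interp_grid=interp, snr=snr,
                          passes=snr > snr_threshold)


def trial_counts(spike_times_s: np.ndarray, trial_onsets_s: np.ndarray,
                 window_s: float = 1.0) -> np.ndarray:
    """Spike counts per repeated trial window."""
    spikes = np.sort(np.asarray(spike_times_s, dtype=float))
    onsets = np.asarray(trial_onsets_s, dtype=float)
    return (np.searchsorted(spikes, onsets + window_s)
            - np.searchsorted(spikes, onsets))


def fano_factor(counts: np.ndarray) -> float | None:
    """Trial-to-trial variability: unbiased variance of the counts divided
    by their mean; None when the mean is zero (undefined)."""
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("Fano factor needs at least 2 trials")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    m = c.mean()
    if m == 0:
        return None
    return float(c.var(ddof=1) / m)
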