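"""Monosynaptic connectivity inference from spike trains.

The chain is: cross-correlogram (CCG) of post-minus-pre lags, subtraction
of a surrogate CCG obtained by randomising spike times within consecutive
10-ms wall-clock windows (interval jitter, which removes co-modulation
slower than the window while preserving millisecond synchrony), detection
of a peak of at least 4 consecutive 0.1-ms bins exceeding 3 baseline SD
inside the 0.5-4 ms monosynaptic window, and the spike transmission
efficacy: the evoked mass under the corrected peak per presynaptic spike.

Interval jitter spreads a connection's own evoked coincidences uniformly at
density 1/W over the jitter window W, so the corrected peak retains only a
fraction (1 - w/W) of the true evoked mass (w = integration window).  The
efficacy estimator divides by this factor, which makes planted transmission
probabilities recoverable without bias; see docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .probe_io import ProbeLayout, SortedUnits

DEFAULT_BIN_MS = 0.1
DEFAULT_MAX_LAG_MS = 10.0
DEFAULT_JITTER_WINDOW_MS = 10.0
DEFAULT_N_SURROGATES = 50
DEFAULT_SD_THRESH = 3.0
DEFAULT_MIN_BINS = 4
DEFAULT_PEAK_WINDOW_MS = (0.5, 4.0)
BASELINE_WINDOW_MS = (-4.5, 0.5)
EFFICACY_EXTEND_SD = 1.0
#: fixed margin added to the efficacy window beyond the supra-1-SD run;
#: corrected bins are zero-mean under the null, so the margin captures the
#: peak's tails at the cost of variance, not bias
EFFICACY_MARGIN_MS = 0.4


@dataclass
class CCG:
    """Raw cross-correlogram: counts of (post - pre) lags per bin."""

    lags_ms: np.ndarray  # bin centers
    counts: np.ndarray
    bin_ms: float
    n_pre: int
    n_post: int


@dataclass
class CorrectedCCG:
    """Jitter-corrected CCG; ``corrected + jitter_mean == raw`` exactly."""

    lags_ms: np.ndarray
    raw_counts: np.ndarray
    jitter_mean: np.ndarray
    corrected: np.ndarray
    baseline_sd: float
    n_pre: int
    n_post: int
    bin_ms: float
    jitter_window_ms: float
    baseline_window_ms: tuple[float, float] = BASELINE_WINDOW_MS


@dataclass
class Connection:
    """A detected putative monosynaptic connection."""

    pre_id: int
    post_id: int
    peak_lag_ms: float
    peak_height_sd: float
    significant_bins: np.ndarray
    efficacy: float | None = None
    distance_um: float | None = None


def _lag_bins(max_lag_ms: float, bin_ms: float) -> tuple[int, np.ndarray]:
    n_bins = int(round(2 * max_lag_ms / bin_ms))
    centers = -max_lag_ms + (np.arange(n_bins) + 0.5) * bin_ms
    return n_bins, centers


def _pair_diffs_ms(pre_s: np.ndarray, post_s: np.ndarray,
                   max_diff_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """All (pre index, post index) pairs with |post - pre| <= max_diff_ms.

    Returns (pre_idx, post_idx); both trains must be sorted."""
    w = max_diff_ms / 1e3
    lo = np.searchsorted(post_s, pre_s - w, side="left")
    hi = np.searchsorted(post_s, pre_s + w, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    pre_idx = np.repeat(np.arange(pre_s.size), counts)
    offsets = np.concatenate(([0], np.cumsum(counts)))[:-1]
    post_idx = (np.arange(total) - np.repeat(offsets, counts)
                + np.repeat(lo, counts))
    return pre_idx, post_idx


def _bin_lags(d_ms: np.ndarray, max_lag_ms: float, bin_ms: float,
              n_bins: int) -> np.ndarray:
    idx = np.floor((d_ms + max_lag_ms) / bin_ms).astype(np.int64)
    ok = (idx >= 0) & (idx < n_bins)
    return np.bincount(idx[ok], minlength=n_bins).astype(float)


def compute_ccg(pre_times_s: np.ndarray, post_times_s: np.ndarray,
                bin_ms: float = DEFAULT_BIN_MS,
                max_lag_ms: float = DEFAULT_MAX_LAG_MS) -> CCG:
    """Histogram of (post - pre) spike-time lags over [-max_lag, +max_lag)
    with half-open bins [lo, hi)."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    pre = np.asarray(pre_times_s, dtype=float)
    post = np.asarray(post_times_s, dtype=float)
    n_bins, centers = _lag_bins(max_lag_ms, bin_ms)
    if pre.size == 0:
        warnings.warn("empty presynaptic train: all-zero CCG", stacklevel=2)
        return CCG(centers, np.zeros(n_bins), bin_ms, 0, post.size)
    pre_idx, post_idx = _pair_diffs_ms(pre, post, max_lag_ms + bin_ms)
    d_ms = (post[post_idx] - pre[pre_idx]) * 1e3
    return CCG(centers, _bin_lags(d_ms, max_lag_ms, bin_ms, n_bins),
               bin_ms, pre.size, post.size)


def jitter_correct(pre_times_s: np.ndarray, post_times_s: np.ndarray,
                   jitter_window_ms: float = DEFAULT_JITTER_WINDOW_MS,
                   n_surrogates: int = DEFAULT_N_SURROGATES,
                   bin_ms: float = DEFAULT_BIN_MS,
                   max_lag_ms: float = DEFAULT_MAX_LAG_MS,
                   seed: int | Sequence[int] | np.random.Generator = 0) -> CorrectedCCG:
    """Jitter-corrected CCG.

    Each of ``n_surrogates`` surrogates redraws every postsynaptic spike
    uniformly within its own fixed wall-clock window [k*W, (k+1)*W); the
    surrogate-average CCG is subtracted from the raw CCG.  Only the post
    train is jittered (equivalent in expectation, half the cost).
    Deterministic for a fixed seed.
    """
    if jitter_window_ms <= bin_ms:
        raise ValueError("jitter window must exceed the CCG bin width")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pre = np.asarray(pre_times_s, dtype=float)
    post = np.asarray(post_times_s, dtype=float)
    n_bins, centers = _lag_bins(max_lag_ms, bin_ms)
    W = jitter_window_ms / 1e3

    if pre.size == 0 or post.size == 0:
        if pre.size == 0:
            warnings.warn("empty presynaptic train: all-zero CCG", stacklevel=2)
        z = np.zeros(n_bins)
        return CorrectedCCG(centers, z.copy(), z.copy(), z.copy(), 0.0,
                            pre.size, post.size, bin_ms, jitter_window_ms)

    # pair superset: a jittered post spike moves < W, so every pair that can
    # ever land within max_lag is within max_lag + W of the raw times
    pre_idx, post_idx = _pair_diffs_ms(pre, post, max_lag_ms + jitter_window_ms)
    d_raw_ms = (post[post_idx] - pre[pre_idx]) * 1e3
    raw = _bin_lags(d_raw_ms, max_lag_ms, bin_ms, n_bins)

    win_start = np.floor(post / W) * W
    acc = np.zeros(n_bins)
    pre_sel = pre[pre_idx]
    for _ in range(n_surrogates):
        jit = win_start + rng.random(post.size) * W
        d_ms = (jit[post_idx] - pre_sel) * 1e3
        acc += _bin_lags(d_ms, max_lag_ms, bin_ms, n_bins)
    jitter_mean = acc / n_surrogates
    corrected = raw - jitter_mean

    base = ((centers >= BASELINE_WINDOW_MS[0])
            & (centers < BASELINE_WINDOW_MS[1]))
    baseline_sd = float(np.std(corrected[base], ddof=1))
    return CorrectedCCG(centers, raw, jitter_mean, corrected, baseline_sd,
                        pre.size, post.size, bin_ms, jitter_window_ms)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    out = []
    i = 0
    while i < mask.size:
        if mask[i]:
            j = i
            while j < mask.size and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_connection(ccg: CorrectedCCG,
                      sd_thresh: float = DEFAULT_SD_THRESH,
                      min_bins: int = DEFAULT_MIN_BINS,
                      window_ms: tuple[float, float] = DEFAULT_PEAK_WINDOW_MS,
                      pre_id: int = -1, post_id: int = -1) -> Connection | None:
    """Detect a monosynaptic peak in a corrected CCG.

    A connection requires at least ``min_bins`` consecutive bins inside the
    monosynaptic lag window whose corrected counts exceed ``sd_thresh``
    baseline standard deviations.  Returns None when no such run exists.
    """
    if ccg.baseline_sd == 0:
        if not np.any(ccg.corrected):
            return None  # nothing to detect in an all-zero CCG
        raise ValueError("degenerate CCG: zero baseline SD with nonzero counts")
    in_win = (ccg.lags_ms >= window_ms[0]) & (ccg.lags_ms <= window_ms[1])
    sig = in_win & (ccg.corrected > sd_thresh * ccg.baseline_sd)
    best_run = None
    for start, stop in _runs(sig):
        if stop - start >= min_bins:
            if best_run is None or (ccg.corrected[start:stop].max()
                                    > ccg.corrected[best_run[0]:best_run[1]].max()):
                best_run = (start, stop)
    if best_run is None:
        return None
    start, stop = best_run
    bins = np.arange(start, stop)
    peak_bin = int(bins[np.argmax(ccg.corrected[bins])])
    return Connection(
        pre_id=pre_id,
        post_id=post_id,
        peak_lag_ms=float(ccg.lags_ms[peak_bin]),
        peak_height_sd=float(ccg.corrected[peak_bin] / ccg.baseline_sd),
        significant_bins=bins,
    )


def efficacy(ccg: CorrectedCCG, connection: Connection,
             margin_ms: float = EFFICACY_MARGIN_MS) -> float | None:
    """Spike transmission efficacy of a detected connection.

    The corrected counts are summed over the significant run extended to
    adjacent bins above 1 baseline SD plus a fixed ``margin_ms`` on each
    side (tail capture), rescaled by 1/(1 - w/W) to undo the interval-jitter
    self-subtraction (w = window width, W = jitter window), divided by the
    presynaptic spike count, and clipped at zero.  None when the
    presynaptic train is empty.
    """
    if ccg.n_pre == 0:
        return None
    lo = int(connection.significant_bins[0])
    hi = int(connection.significant_bins[-1])
    level = EFFICACY_EXTEND_SD * ccg.baseline_sd
    while lo > 0 and ccg.corrected[lo - 1] > level:
        lo -= 1
    while hi + 1 < ccg.corrected.size and ccg.corrected[hi + 1] > level:
        hi += 1
    pad = int(round(margin_ms / ccg.bin_ms))
    lo = max(lo - pad, 0)
    hi = min(hi + pad, ccg.corrected.size - 1)
    mass = float(ccg.corrected[lo:hi + 1].sum())
    w_ms = (hi - lo + 1) * ccg.bin_ms
    shrink = 1.0 - w_ms / ccg.jitter_window_ms
    if shrink <= 0.05:  # peak nearly as wide as the jitter window: unreliable
        warnings.warn("efficacy window spans the jitter window; not corrected",
                      stacklevel=2)
        shrink = 1.0
    return max(0.0, mass / shrink / ccg.n_pre)


def pair_distance(layout: ProbeLayout, peak_ch_a: int, peak_ch_b: int) -> float:
    """Euclidean distance in µm between two units' peak channels."""
    return layout.distance(peak_ch_a, peak_ch_b)


def detection_probability_pct(n_detected: int, n_tested: int) -> float:
    """Connection-detection probability as a percentage of tested pairs."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return 100.0 * n_detected / n_tested


def mean_connections_per_recording(n_connections: int, n_recordings: int) -> float:
    if n_recordings <= 0:
        raise ValueError("n_recordings must be positive")
    return n_connections / n_recordings


def connectivity_map(
    units: SortedUnits,
    layout: ProbeLayout | None = None,
    bin_ms: float = DEFAULT_BIN_MS,
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
    jitter_window_ms: float = DEFAULT_JITTER_WINDOW_MS,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    sd_thresh: float = DEFAULT_SD_THRESH,
    min_bins: int = DEFAULT_MIN_BINS,
    window_ms: tuple[float, float] = DEFAULT_PEAK_WINDOW_MS,
    seed: int = 0,
) -> tuple[list[Connection], dict]:
    """Test every TCA -> V1N pair and summarise the detected graph.

    Per-pair seeds are derived deterministically from (seed, pre_id,
    post_id), so adding units never perturbs other pairs.  The summary
    carries the tested/detected counts, the detection probability,
    per-unit divergence/convergence (and their means over connected
    units), and median efficacy/distance of the detected connections.
    """
    tcas = units.with_label("TCA")
    v1ns = units.with_label("V1N")
    summary: dict = {
        "n_tca": len(tcas), "n_v1n": len(v1ns),
        "n_tested": len(tcas) * len(v1ns), "n_detected": 0,
        "detection_pct": 0.0, "divergence": {}, "convergence": {},
        "mean_divergence": None, "mean_convergence": None,
        "median_efficacy": None, "median_distance_um": None,
    }
    if not tcas or not v1ns:
        warnings.warn("no TCA or no V1N units: empty connectivity map",
                      stacklevel=2)
        return [], summary

    detected: list[Connection] = []
    for pre in tcas:
        for post in v1ns:
            rng = np.random.default_rng([seed, pre.unit_id, post.unit_id])
            ccg = jitter_correct(pre.spike_times_s, post.spike_times_s,
                                 jitter_window_ms, n_surrogates, bin_ms,
                                 max_lag_ms, seed=rng)
            try:
                conn = detect_connection(ccg, sd_thresh, min_bins, window_ms,
                                         pre_id=pre.unit_id,
                                         post_id=post.unit_id)
            except ValueError:
                conn = None
            if conn is None:
                continue
            conn.efficacy = efficacy(ccg, conn)
            if layout is not None:
                conn.distance_um = pair_distance(layout, pre.peak_channel,
                                                 post.peak_channel)
            detected.append(conn)

    div = {u.unit_id: 0 for u in tcas}
    conv = {u.unit_id: 0 for u in v1ns}
    for c in detected:
        div[c.pre_id] += 1
        conv[c.post_id] += 1
    connected_div = [v for v in div.values() if v > 0]
    connected_conv = [v for v in conv.values() if v > 0]
    effs = [c.efficacy for c in detected if c.efficacy is not None]
    dists = [c.distance_um for c in detected if c.distance_um is not None]
    summary.update(
        n_detected=len(detected),
        detection_pct=detection_probability_pct(len(detected),
                                                summary["n_tested"]),
        divergence=div,
        convergence=conv,
        mean_divergence=float(np.mean(connected_div)) if connected_div else None,
        mean_convergence=float(np.mean(connected_conv)) if connected_conv else None,
        median_efficacy=float(np.median(effs)) if effs else None,
        median_distance_um=float(np.median(dists)) if dists else None,
    )
    return detected, summary
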