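"""Probe geometry, flat-binary recording I/O and sorted-units tables.

The on-disk dialect mirrors the de-facto standard of high-density probe
acquisition systems: a frame-interleaved little-endian int16 binary
(``.bin``) accompanied by a ``key=value`` text meta file (``.meta``), and
sorted-spike output as two tab-separated tables (per-spike and per-unit).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

#: sampling interval between neighbouring channels served by one ADC, in µs
ADC_STAGGER_US = 2.78

#: default conversion gain of the acquisition chain, µV per int16 count
DEFAULT_GAIN_UV_PER_BIT = 0.195

VALID_LABELS = ("TCA", "V1N", "unclassified")

_PRESETS = ("two-column-stagger", "four-column")


@dataclass(frozen=True)
class ProbeLayout:
    """Geometry and ADC multiplexing of a high-density probe.

    ``x``/``y`` are channel positions in µm, y increasing away from the
    probe tip.  ``adc_group`` and ``adc_rank`` describe the time-multiplexed
    sampling: channels of the same group are digitised sequentially, the
    channel of rank *r* lagging rank 0 by ``r * ADC_STAGGER_US`` µs.
    """

    n_channels: int
    x: np.ndarray
    y: np.ndarray
    adc_group: np.ndarray
    adc_rank: np.ndarray
    vertical_pitch_um: float
    n_columns: int
    preset: str = "custom"

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("a probe needs at least 2 channels")
        pos = set(zip(self.x.tolist(), self.y.tolist()))
        if len(pos) != self.n_channels:
            raise ValueError("channel positions must be distinct")
        if np.any(self.adc_rank < 0):
            raise ValueError("adc_rank must be non-negative")

    @property
    def positions(self) -> np.ndarray:
        """(n_channels, 2) array of (x, y) in µm."""
        return np.column_stack([self.x, self.y])

    def distance(self, a: int, b: int) -> float:
        """Euclidean distance in µm between two channels."""
        if not (0 <= a < self.n_channels and 0 <= b < self.n_channels):
            raise ValueError(f"channel out of range: {a}, {b}")
        return float(math.hypot(self.x[a] - self.x[b], self.y[a] - self.y[b]))

    def vertical_span_um(self) -> float:
        return float(self.y.max() - self.y.min())

    def columns(self) -> dict[float, np.ndarray]:
        """Channels grouped by x position, each sorted by y (tip upward)."""
        out: dict[float, np.ndarray] = {}
        for xv in np.unique(self.x):
            idx = np.flatnonzero(self.x == xv)
            out[float(xv)] = idx[np.argsort(self.y[idx])]
        return out

    def sample_offsets_us(self) -> np.ndarray:
        """Per-channel acquisition-time offset (µs) caused by ADC multiplexing."""
        return self.adc_rank.astype(float) * ADC_STAGGER_US


def make_probe_layout(n_channels: int, preset: str = "two-column-stagger") -> ProbeLayout:
    """Build a deterministic probe layout.

    ``two-column-stagger`` places two channels per 20-µm row with the row
    x-positions alternating between (0, 32) and (16, 48) µm, the familiar
    checkerboard of 384-channel probes; ``four-column`` places four channels
    per row at x = 0, 16, 32, 48 µm.
    """
    if n_channels < 2 or n_channels % 2:
        raise ValueError(f"n_channels must be even and >= 2, got {n_channels}")
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {_PRESETS}")

    pitch = 20.0
    if preset == "two-column-stagger":
        rows = np.arange(n_channels) // 2
        odd_row = rows % 2
        col = np.arange(n_channels) % 2
        x = col * 32.0 + odd_row * 16.0
        y = rows * pitch
    else:  # four-column
        if n_channels % 4:
            raise ValueError("four-column preset needs n_channels divisible by 4")
        rows = np.arange(n_channels) // 4
        x = (np.arange(n_channels) % 4) * 16.0
        y = rows * pitch

    ch = np.arange(n_channels)
    # Neuropixels-style multiplexing: even and odd channels of each
    # 24-channel block go to one ADC each; neighbours on the same ADC are
    # sampled ADC_STAGGER_US apart.
    adc_group = 2 * (ch // 24) + (ch % 2)
    adc_rank = (ch // 2) % 12
    n_columns = int(np.unique(x).size)
    return ProbeLayout(
        n_channels=n_channels,
        x=x,
        y=y,
        adc_group=adc_group,
        adc_rank=adc_rank,
        vertical_pitch_um=pitch,
        n_columns=n_columns,
        preset=preset,
    )


@dataclass
class RawRecording:
    """Spike-band recording in µV: ``samples`` is (n_channels, n_samples).

    Values are stored in memory as float µV but are defined only up to the
    16-bit quantisation grid of ``gain_uv_per_bit`` once written to disk.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    layout: ProbeLayout
    gain_uv_per_bit: float = DEFAULT_GAIN_UV_PER_BIT

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"samples shape {self.samples.shape} inconsistent with "
                f"{self.layout.n_channels}-channel layout"
            )
        if self.gain_uv_per_bit <= 0:
            raise ValueError("gain must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def counts(self) -> np.ndarray:
        """int16 counts actually stored on disk (rounded, clipped)."""
        c = np.rint(self.samples / self.gain_uv_per_bit)
        return np.clip(c, -32768, 32767).astype(np.int16)

    def quantized(self) -> "RawRecording":
        """Copy whose samples sit exactly on the 16-bit grid."""
        return replace(self, samples=self.counts().astype(np.float32) * self.gain_uv_per_bit)


def write_raw(rec: RawRecording, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.bin`` (frame-interleaved int16) and ``<path>.meta``.

    Returns the pair of paths written.  ``read_raw(write_raw(rec))``
    reproduces the counts array bit-exactly.
    """
    base = Path(path)
    bin_path = base.with_suffix(".bin")
    meta_path = base.with_suffix(".meta")
    counts = rec.counts()
    # frame interleaved: all channels of sample 0, then sample 1, ...
    counts.T.astype("<i2").tofile(bin_path)
    meta = {
        "n_channels": rec.layout.n_channels,
        "n_samples": rec.n_samples,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "gain_uv_per_bit": rec.gain_uv_per_bit,
        "layout_preset": rec.layout.preset,
    }
    meta_path.write_text("".join(f"{k}={v}\n" for k, v in meta.items()))
    return bin_path, meta_path


def _parse_meta(meta_path: Path) -> dict[str, str]:
    if not meta_path.exists():
        raise FormatError(f"missing meta file: {meta_path}")
    out: dict[str, str] = {}
    for line in meta_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"malformed meta line: {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_raw(path: str | Path) -> RawRecording:
    """Read a ``.bin``/``.meta`` pair written by :func:`write_raw`."""
    base = Path(path)
    bin_path = base.with_suffix(".bin")
    meta_path = base.with_suffix(".meta")
    meta = _parse_meta(meta_path)
    try:
        n_channels = int(meta["n_channels"])
        fs = float(meta["sampling_rate_hz"])
        gain = float(meta["gain_uv_per_bit"])
        preset = meta.get("layout_preset", "two-column-stagger")
    except KeyError as e:  # pragma: no cover - defensive
        raise FormatError(f"meta file missing key: {e}") from e
    if not bin_path.exists():
        raise FormatError(f"missing binary file: {bin_path}")
    raw = np.fromfile(bin_path, dtype="<i2")
    if raw.size % n_channels:
        raise FormatError(
            f"binary size {raw.size} samples is not a multiple of "
            f"{n_channels} channels"
        )
    n_samples = raw.size // n_channels
    if "n_samples" in meta and int(meta["n_samples"]) != n_samples:
        raise FormatError(
            f"meta declares {meta['n_samples']} samples, binary holds {n_samples}"
        )
    layout = make_probe_layout(n_channels, preset)
    samples = raw.reshape(n_samples, n_channels).T.astype(np.float32) * gain
    return RawRecording(samples=samples, sampling_rate_hz=fs, layout=layout,
                        gain_uv_per_bit=gain)


@dataclass
class Unit:
    """One sorted unit: spike times in seconds, sorted ascending."""

    unit_id: int
    spike_times_s: np.ndarray
    peak_channel: int = 0
    label: str = "unclassified"

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        if np.any(np.diff(self.spike_times_s) < 0):
            self.spike_times_s = np.sort(self.spike_times_s)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    def firing_rate_hz(self, duration_s: float) -> float:
        return self.n_spikes / duration_s if duration_s > 0 else float("nan")


@dataclass
class SortedUnits:
    """Spike-sorter output consumed by every analysis stage."""

    units: list[Unit] = field(default_factory=list)
    duration_s: float | None = None

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(ids) != len(set(ids)):
            raise ValueError("unit_ids must be unique")

    def __iter__(self):
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)

    def by_id(self, unit_id: int) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(f"no unit {unit_id}")

    def with_label(self, label: str) -> list[Unit]:
        return [u for u in self.units if u.label == label]

    def labels(self) -> dict[int, str]:
        return {u.unit_id: u.label for u in self.units}


def write_sorted(units: SortedUnits, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.spikes.tsv`` (spike_time_s, unit_id) and
    ``<path>.units.tsv`` (unit_id, peak_channel, label, n_spikes)."""
    base = Path(path)
    spikes_path = base.parent / (base.name + ".spikes.tsv")
    units_path = base.parent / (base.name + ".units.tsv")
    rows = []
    for u in units:
        rows.append(pd.DataFrame({"spike_time_s": u.spike_times_s,
                                  "unit_id": u.unit_id}))
    spikes = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=["spike_time_s", "unit_id"]))
    spikes.to_csv(spikes_path, sep="\t", index=False)
    per_unit = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "peak_channel": [u.peak_channel for u in units],
            "label": [u.label for u in units],
            "n_spikes": [u.n_spikes for u in units],
        }
    )
    per_unit.to_csv(units_path, sep="\t", index=False)
    return spikes_path, units_path


def read_sorted(path: str | Path) -> SortedUnits:
    """Read the table pair written by :func:`write_sorted`.

    Spike times are returned sorted per unit regardless of row order in the
    file; NaN spike times are a format error.
    """
    base = Path(path)
    spikes_path = base.parent / (base.name + ".spikes.tsv")
    units_path = base.parent / (base.name + ".units.tsv")
    if not spikes_path.exists():
        raise FormatError(f"missing spikes table: {spikes_path}")
    spikes = pd.read_csv(spikes_path, sep="\t")
    for col in ("spike_time_s", "unit_id"):
        if col not in spikes.columns:
            raise FormatError(f"spikes table missing column {col!r}")
    if spikes["spike_time_s"].isna().any():
        raise FormatError("spikes table contains NaN spike times")
    meta: Mapping[int, tuple[int, str]] = {}
    if units_path.exists():
        per_unit = pd.read_csv(units_path, sep="\t")
        meta = {
            int(r.unit_id): (int(r.peak_channel), str(r.label))
            for r in per_unit.itertuples()
        }
    units = []
    for uid, grp in spikes.groupby("unit_id", sort=True):
        peak, label = meta.get(int(uid), (0, "unclassified"))
        units.append(
            Unit(
                unit_id=int(uid),
                spike_times_s=np.sort(grp["spike_time_s"].to_numpy(float)),
                peak_channel=peak,
                label=label,
            )
        )
    # units listed in the per-unit table but without spikes
    for uid, (peak, label) in meta.items():
        if not any(u.unit_id == uid for u in units):
            warnings.warn(f"unit {uid} has no spikes", stacklevel=2)
            units.append(Unit(uid, np.empty(0), peak, label))
    return SortedUnits(units=units)
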