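"""End-to-end orchestration: from a simulation scene (or files on disk) to
a connectivity report.

A run is described by a single config mapping (usually loaded from YAML)
with a master ``seed``; every stochastic stage draws from a substream
derived from (seed, crc32(stage name)), so adding a stage never perturbs
the others and identical config + seed reproduces every table bit for bit.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import connectivity, quality, waveforms
from .probe_io import (
    ProbeLayout,
    RawRecording,
    SortedUnits,
    Unit,
    make_probe_layout,
    read_raw,
    read_sorted,
    write_raw,
    write_sorted,
)
from .synth import (
    ConnectionSpec,
    GroundTruth,
    TemplateSpec,
    render_recording,
    simulate_trains,
)

STAGES = ("simulate", "render", "qc", "mcw", "classify", "connect")


def stage_seed(master_seed: int, stage: str) -> np.random.Generator:
    """Named-substream RNG: deterministic in (master seed, stage name)."""
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF,
                                  zlib.crc32(stage.encode())])


def _unit_from_cfg(cfg: Mapping[str, Any]) -> dict:
    return dict(unit_id=int(cfg["unit_id"]), rate_hz=float(cfg["rate_hz"]),
                label=str(cfg.get("label", "unclassified")),
                peak_channel=int(cfg.get("peak_channel", 0)))


def build_scene(sim_cfg: Mapping[str, Any], seed: int) -> tuple[SortedUnits, GroundTruth]:
    """Simulate the spike trains of a configured scene."""
    unit_cfgs = [_unit_from_cfg(u) for u in sim_cfg["units"]]
    rates = {u["unit_id"]: u["rate_hz"] for u in unit_cfgs}
    labels = {u["unit_id"]: u["label"] for u in unit_cfgs}
    peaks = {u["unit_id"]: u["peak_channel"] for u in unit_cfgs}
    conns = [ConnectionSpec(int(c["pre_id"]), int(c["post_id"]),
                            float(c["prob"]), float(c["delay_ms"]),
                            float(c.get("jitter_sd_ms", 0.2)))
             for c in sim_cfg.get("connections", [])]
    units, gt = simulate_trains(
        rates, float(sim_cfg["duration_s"]), conns,
        refractory_ms=float(sim_cfg.get("refractory_ms", 1.0)),
        seed=stage_seed(seed, "simulate"),
        labels=labels, peak_channels=peaks,
    )
    for ucfg in sim_cfg["units"]:
        if "template" in ucfg:
            t = ucfg["template"]
            gt.templates[int(ucfg["unit_id"])] = TemplateSpec(
                kind=t["kind"], peak_channel=int(ucfg.get("peak_channel", 0)),
                neg_amp_uv=float(t["neg_amp_uv"]),
                pos_amp_uv=float(t["pos_amp_uv"]),
                spread_channels=int(t["spread_channels"]),
                rebound_duration_ms=float(t.get("rebound_duration_ms", 0.0)),
                conduction_speed_m_per_s=t.get("conduction_speed_m_per_s"),
                af_df_offset_rows=int(t.get("af_df_offset_rows", 0)),
            )
    return units, gt


def _units_table(units: SortedUnits, duration_s: float | None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "label": [u.label for u in units],
            "peak_channel": [u.peak_channel for u in units],
            "n_spikes": [u.n_spikes for u in units],
            "firing_rate_hz": [
                round(u.firing_rate_hz(duration_s), 4) if duration_s else np.nan
                for u in units
            ],
        }
    ).sort_values("unit_id", ignore_index=True)


def run_pipeline(config: Mapping[str, Any],
                 outdir: str | Path | None = None) -> dict[str, Any]:
    """Execute the full analysis chain and return the report bundle.

    Stages, in order: scene simulation (or table loading), optional raw
    rendering + MCW extraction + waveform classification, per-unit quality
    control (failing units are excluded from connectivity testing), and the
    TCA -> V1N connectivity map with its headline summary.  When ``outdir``
    is given, the per-stage tables and a plain-text summary are written
    there.
    """
    seed = int(config.get("seed", 0))
    report: dict[str, Any] = {"seed": seed}

    sim_cfg = config.get("simulate")
    if sim_cfg is not None:
        units, gt = build_scene(sim_cfg, seed)
        duration = float(sim_cfg["duration_s"])
        report["ground_truth"] = gt
        layout = None
        if "layout" in sim_cfg:
            lcfg = sim_cfg["layout"]
            layout = make_probe_layout(int(lcfg["n_channels"]),
                                       lcfg.get("preset", "two-column-stagger"))
        rec = None
        if sim_cfg.get("render") and layout is not None:
            rec = render_recording(
                units, gt.templates, layout,
                noise_sd_uv=float(sim_cfg.get("noise_sd_uv", 10.0)),
                seed=stage_seed(seed, "render"), duration_s=duration,
            )
    elif "inputs" in config:
        paths = config["inputs"]
        units = read_sorted(paths["sorted"])
        rec = read_raw(paths["raw"]) if "raw" in paths else None
        layout = rec.layout if rec is not None else None
        duration = (rec.duration_s if rec is not None else
                    max((u.spike_times_s[-1] for u in units if u.n_spikes),
                        default=0.0))
    else:
        raise ValueError("config needs either a 'simulate' scene or 'inputs'")

    qc_cfg = dict(config.get("qc", {}))
    # qc.gate=false keeps the QC table but does not exclude failing units
    # (useful for simulated scenes, where the transmission model injects
    # evoked spikes without refractoriness and would trip the ISI rule)
    qc_gate = bool(qc_cfg.get("gate", True))
    qc_rows = []
    passed_units = []
    for u in units:
        rep = quality.quality_report(
            u.unit_id, u.spike_times_s,
            refractory_ms=float(qc_cfg.get("refractory_ms",
                                           quality.ISI_REFRACTORY_MS)),
            isi_max_pct=float(qc_cfg.get("isi_max_pct", quality.ISI_MAX_PCT)),
            isolation_min=float(qc_cfg.get("isolation_min",
                                           quality.ISOLATION_MIN)),
            doublecount_ms=float(qc_cfg.get("doublecount_ms",
                                            quality.DOUBLECOUNT_WINDOW_MS)),
        )
        qc_rows.append(
            {
                "unit_id": u.unit_id,
                "isi_violation_pct": (round(rep.isi_violation_pct, 6)
                                      if rep.isi_violation_pct is not None
                                      else np.nan),
                "n_double_counted_removed": rep.n_double_counted_removed,
                "passed": rep.passed,
            }
        )
        if rep.passed or not qc_gate:
            passed_units.append(u)
    qc_table = pd.DataFrame(qc_rows).sort_values("unit_id", ignore_index=True)
    report["qc"] = qc_table

    metrics_rows = []
    if rec is not None:
        mcw_seed = stage_seed(seed, "mcw")
        relabelled = []
        for u in passed_units:
            mcw = waveforms.extract_mcw(rec, u.spike_times_s, seed=mcw_seed)
            m = waveforms.waveform_metrics(mcw, rec.layout)
            label = waveforms.classify_unit(m)
            relabelled.append(Unit(u.unit_id, u.spike_times_s,
                                   mcw.peak_channel, label))
            metrics_rows.append(
                {
                    "unit_id": u.unit_id, "label": label,
                    "peak_channel": mcw.peak_channel,
                    "pos_peak_uv": round(m.pos_peak_uv, 3),
                    "neg_peak_uv": round(m.neg_peak_uv, 3),
                    "spread_channels": m.spread_channels,
                    "rebound_duration_ms": round(m.rebound_duration_ms, 3),
                    "rebound_spread_channels": m.rebound_spread_channels,
                }
            )
        passed_units = relabelled
    report["metrics"] = pd.DataFrame(metrics_rows)

    survivors = SortedUnits(units=passed_units, duration_s=duration)
    report["units"] = _units_table(survivors, duration)
    conn_cfg = dict(config.get("ccg", {}))
    det_cfg = dict(config.get("detect", {}))
    detected, summary = connectivity.connectivity_map(
        survivors, layout,
        bin_ms=float(conn_cfg.get("bin_ms", connectivity.DEFAULT_BIN_MS)),
        max_lag_ms=float(conn_cfg.get("max_lag_ms",
                                      connectivity.DEFAULT_MAX_LAG_MS)),
        jitter_window_ms=float(conn_cfg.get("jitter_ms",
                                            connectivity.DEFAULT_JITTER_WINDOW_MS)),
        n_surrogates=int(conn_cfg.get("n_surrogates",
                                      connectivity.DEFAULT_N_SURROGATES)),
        sd_thresh=float(det_cfg.get("sd_thresh", connectivity.DEFAULT_SD_THRESH)),
        min_bins=int(det_cfg.get("min_bins", connectivity.DEFAULT_MIN_BINS)),
        window_ms=tuple(det_cfg.get("window_ms",
                                    connectivity.DEFAULT_PEAK_WINDOW_MS)),
        seed=seed,
    )
    conn_table = pd.DataFrame(
        {
            "pre_id": [c.pre_id for c in detected],
            "post_id": [c.post_id for c in detected],
            "peak_lag_ms": [round(c.peak_lag_ms, 4) for c in detected],
            "peak_height_sd": [round(c.peak_height_sd, 3) for c in detected],
            "efficacy": [round(c.efficacy, 6) if c.efficacy is not None
                         else np.nan for c in detected],
            "distance_um": [round(c.distance_um, 2) if c.distance_um is not None
                            else np.nan for c in detected],
        }
    ).sort_values(["pre_id", "post_id"], ignore_index=True)
    report["connections"] = conn_table
    report["summary"] = summary

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report["units"].to_csv(outdir / "units.tsv", sep="\t", index=False)
        qc_table.to_csv(outdir / "qc.tsv", sep="\t", index=False)
        if metrics_rows:
            report["metrics"].to_csv(outdir / "waveform_metrics.tsv",
                                     sep="\t", index=False)
        conn_table.to_csv(outdir / "connections.tsv", sep="\t", index=False)
        (outdir / "summary.txt").write_text(format_summary(summary, config))
    return report


def format_summary(summary: Mapping[str, Any],
                   config: Mapping[str, Any] | None = None) -> str:
    """Plain-text headline summary (parameter echo included)."""
    lines = []
    for key in ("n_tca", "n_v1n", "n_tested", "n_detected"):
        lines.append(f"{key}={summary[key]}")
    lines.append(f"detection_pct={summary['detection_pct']:.4f}")
    for key in ("mean_divergence", "mean_convergence", "median_efficacy",
                "median_distance_um"):
        v = summary.get(key)
        lines.append(f"{key}={'na' if v is None else f'{v:.4f}'}")
    if config is not None:
        for section in ("ccg", "detect", "qc"):
            for k, v in sorted(dict(config.get(section, {})).items()):
                lines.append(f"param.{section}.{k}={v}")
        lines.append(f"param.seed={config.get('seed', 0)}")
    return "\n".join(lines) + "\n"


def simulate_to_files(sim_cfg: Mapping[str, Any], seed: int,
                      out_base: str | Path) -> dict[str, Path]:
    """Run a scene and write .bin/.meta (if rendering), the sorted tables
    and the ground-truth connection table next to ``out_base``."""
    out_base = Path(out_base)
    out_base.parent.mkdir(parents=True, exist_ok=True)
    units, gt = build_scene(sim_cfg, seed)
    paths: dict[str, Path] = {}
    spikes_p, units_p = write_sorted(units, out_base)
    paths["spikes"], paths["units"] = spikes_p, units_p
    gt_table = pd.DataFrame(
        {
            "pre_id": [c.spec.pre_id for c in gt.connections],
            "post_id": [c.spec.post_id for c in gt.connections],
            "prob": [c.spec.prob for c in gt.connections],
            "delay_ms": [c.spec.delay_ms for c in gt.connections],
            "jitter_sd_ms": [c.spec.jitter_sd_ms for c in gt.connections],
            "n_transmitted": [c.n_transmitted for c in gt.connections],
        }
    )
    gt_path = out_base.parent / (out_base.name + ".ground_truth.tsv")
    gt_table.to_csv(gt_path, sep="\t", index=False)
    paths["ground_truth"] = gt_path
    if sim_cfg.get("render") and "layout" in sim_cfg:
        lcfg = sim_cfg["layout"]
        layout = make_probe_layout(int(lcfg["n_channels"]),
                                   lcfg.get("preset", "two-column-stagger"))
        rec = render_recording(
            units, gt.templates, layout,
            noise_sd_uv=float(sim_cfg.get("noise_sd_uv", 10.0)),
            seed=stage_seed(seed, "render"),
            duration_s=float(sim_cfg["duration_s"]),
        )
        bin_p, meta_p = write_raw(rec, out_base)
        paths["bin"], paths["meta"] = bin_p, meta_p
    return paths
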