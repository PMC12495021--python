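"""Seeded end-to-end orchestration: segments -> rates/outliers -> Cox
connectivity -> graph metrics -> motifs -> P1 -> activity report.

A run is driven by a single JSON/YAML configuration (see
:class:`RunConfig`).  Input is either a recorded spike table plus stimulus
schedule, or a synthetic block describing a session to simulate with known
ground truth.  Each stimulus is processed independently; a failure in one
stimulus is recorded in the report and does not abort the others.  All
outputs are plain CSV/JSON written atomically, and a ``manifest.json``
records the configuration, seed, and produced files so every number in the
report is recomputable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import activity, cox, metrics, motifs, p1, spike_trains, synthetic
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Synthetic-session block: study-scale defaults (29 channels, 6 stimuli,
    20 x 6 s trials per stimulus, sparse coupling)."""

    n_nodes: int = 29
    n_stimuli: int = 6
    density: float = 0.10
    weight_min: float = 0.8
    weight_max: float = 1.5
    isi_family: str = "gamma"
    gamma_shape: float = 2.0
    rate_hz: float = 8.0
    tau_s: float = 0.01
    n_trials: int = 20
    trial_s: float = 6.0
    gap_s: float = 1.0


@dataclass
class RunConfig:
    spikes_path: str | None = None
    schedule_path: str | None = None
    synthetic: SyntheticConfig | None = None
    tau_s: float = 0.01
    alpha_level: float = 0.05
    correction: str = "none"
    split_isis_at_boundaries: bool = False
    min_events: int = 30
    outlier_ceiling_hz: float = 20.0
    outlier_floor_hz: float = 0.0
    motif_n_null: int = 1000
    motif_swap_factor: int = 100
    p1_tol: float = 1e-6
    p1_max_iter: int = 500
    out_dir: str = "spikegraph_out"
    seed: int = 0
    log_level: str = "INFO"


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}
_KNOWN_SYN_KEYS = {f.name for f in dataclasses.fields(SyntheticConfig)}


def validate_config(path: str | Path) -> RunConfig:
    """Load and schema-check a JSON/YAML run configuration.

    Unknown keys and out-of-range values are collected and reported as one
    itemized error; defaults are filled for absent keys.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    problems: list[str] = []
    for key in raw:
        if key not in _KNOWN_KEYS:
            problems.append(f"unknown key {key!r}")
    syn = None
    if raw.get("synthetic") is not None:
        syn_raw = raw["synthetic"]
        if not isinstance(syn_raw, dict):
            problems.append("synthetic: must be a mapping")
            syn_raw = {}
        for key in syn_raw:
            if key not in _KNOWN_SYN_KEYS:
                problems.append(f"synthetic: unknown key {key!r}")
        syn = SyntheticConfig(**{k: v for k, v in syn_raw.items() if k in _KNOWN_SYN_KEYS})
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in _KNOWN_KEYS and k != "synthetic"},
                    synthetic=syn)

    if cfg.synthetic is None and (cfg.spikes_path is None or cfg.schedule_path is None):
        problems.append("either a synthetic block or spikes_path+schedule_path is required")
    if cfg.spikes_path and not Path(cfg.spikes_path).exists():
        problems.append(f"spikes_path: file not found: {cfg.spikes_path}")
    if cfg.schedule_path and not Path(cfg.schedule_path).exists():
        problems.append(f"schedule_path: file not found: {cfg.schedule_path}")
    if cfg.tau_s <= 0:
        problems.append("tau_s: must be positive")
    if not 0 < cfg.alpha_level < 1:
        problems.append("alpha_level: must be in (0, 1)")
    if cfg.correction not in ("none", "bonferroni", "bh"):
        problems.append(f"correction: unknown value {cfg.correction!r}")
    if cfg.motif_n_null < 100:
        problems.append("motif_n_null: must be >= 100")
    if cfg.outlier_ceiling_hz <= cfg.outlier_floor_hz:
        problems.append("outlier_ceiling_hz must exceed outlier_floor_hz")
    if syn is not None:
        if syn.n_nodes < 2:
            problems.append("synthetic.n_nodes: must be >= 2")
        if not 0 <= syn.density <= 1:
            problems.append("synthetic.density: must be in [0, 1]")
        if syn.tau_s <= 0:
            problems.append("synthetic.tau_s: must be positive")
    if problems:
        raise ConfigError(f"{path}: invalid configuration:\n  - " + "\n  - ".join(problems))
    return cfg


def _write_atomic(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _json_default(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class StimulusReport:
    adjacency: pd.DataFrame | None = None
    metrics: metrics.GraphMetricsReport | None = None
    motif_census: motifs.MotifCensus | None = None
    p1_fit: p1.P1Fit | None = None
    error: str | None = None


@dataclass
class RunReport:
    per_stimulus: dict[int, StimulusReport] = field(default_factory=dict)
    rate_table: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    outliers: set[int] = field(default_factory=set)
    manifest: dict = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return any(r.error for r in self.per_stimulus.values())


def _prepare_inputs(cfg: RunConfig, out: Path):
    if cfg.synthetic is not None:
        syn = cfg.synthetic
        rng = np.random.default_rng(cfg.seed)
        truths = {
            stim: synthetic.make_ground_truth_graph(
                syn.n_nodes, syn.density, (syn.weight_min, syn.weight_max),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            for stim in range(1, syn.n_stimuli + 1)
        }
        baseline = synthetic.BaselineConfig(
            isi_family=syn.isi_family, target_rate_hz=syn.rate_hz, gamma_shape=syn.gamma_shape
        )
        spikes, schedule = synthetic.simulate_stimulus_session(
            truths, baseline, synthetic.KernelConfig(tau_s=syn.tau_s),
            n_trials=syn.n_trials, trial_s=syn.trial_s, gap_s=syn.gap_s,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        spike_trains.write_spike_table(spikes, out / "spikes.csv")
        spike_trains.write_schedule(schedule, out / "schedule.csv")
        for stim, truth in truths.items():
            truth.to_edge_list().to_csv(out / f"truth_stim{stim}.csv", index=False)
        return spikes, schedule
    spikes = spike_trains.read_spike_table(cfg.spikes_path)
    schedule = spike_trains.read_schedule(cfg.schedule_path)
    return spikes, schedule


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full per-stimulus analysis under one seed.

    Returns the in-memory report; CSV/JSON artifacts and ``manifest.json``
    are written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report = RunReport()
    files: list[str] = []

    spikes, schedule = _prepare_inputs(config, out)
    stimuli = schedule.stimulus_ids
    segments = {
        stim: spike_trains.extract_stimulus_segments(spikes, schedule, stim) for stim in stimuli
    }

    table = activity.rate_table(segments)
    report.outliers = spike_trains.flag_outlier_channels(
        table, config.outlier_ceiling_hz, config.outlier_floor_hz
    )
    if report.outliers:
        logger.info("outlier channels excluded: %s", sorted(report.outliers))
        segments = {s: spike_trains.drop_channels(seg, report.outliers)
                    for s, seg in segments.items()}
        table = activity.rate_table(segments)
    report.rate_table = table
    report.correlations = activity.stimulus_correlations(table)
    table.to_csv(out / "rates.csv")
    report.correlations.to_csv(out / "activity_correlations.csv")
    files += ["rates.csv", "activity_correlations.csv"]

    kernel = cox.InfluenceKernel(tau_s=config.tau_s)
    rng = np.random.default_rng(config.seed + 1)
    for stim in stimuli:
        sr = StimulusReport()
        report.per_stimulus[stim] = sr
        try:
            split = (
                spike_trains.segment_boundaries(schedule, stim)
                if config.split_isis_at_boundaries
                else None
            )
            adj, fits = cox.estimate_connectivity(
                segments[stim], kernel,
                alpha_level=config.alpha_level, correction=config.correction,
                min_events=config.min_events, split_at=split,
            )
            sr.adjacency = adj
            spike_trains.write_adjacency(adj, out / f"adjacency_stim{stim}.csv")
            pd.concat(
                [f.to_frame().assign(target=t) for t, f in fits.items()], ignore_index=True
            ).to_csv(out / f"cox_fits_stim{stim}.csv", index=False)
            sr.metrics = metrics.compute_report(adj)
            _write_atomic(
                out / f"metrics_stim{stim}.json",
                json.dumps(sr.metrics.summary(), indent=2, default=_json_default),
            )
            sr.metrics.per_node.to_csv(out / f"node_metrics_stim{stim}.csv")
            sr.motif_census = motifs.motif_significance(
                adj, n_null=config.motif_n_null, swap_factor=config.motif_swap_factor,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sr.motif_census.to_frame().to_csv(out / f"motifs_stim{stim}.csv", index=False)
            sr.p1_fit = p1.fit_p1(adj, tol=config.p1_tol, max_iter=config.p1_max_iter)
            sr.p1_fit.to_frame().to_csv(out / f"p1_stim{stim}.csv")
            _write_atomic(
                out / f"p1_params_stim{stim}.json",
                json.dumps(
                    {"theta": sr.p1_fit.theta, "rho": sr.p1_fit.rho,
                     "converged": sr.p1_fit.converged, "n_iter": sr.p1_fit.n_iter},
                    indent=2, default=_json_default,
                ),
            )
            files += [
                f"adjacency_stim{stim}.csv", f"cox_fits_stim{stim}.csv",
                f"metrics_stim{stim}.json", f"node_metrics_stim{stim}.csv",
                f"motifs_stim{stim}.csv", f"p1_stim{stim}.csv", f"p1_params_stim{stim}.json",
            ]
        except Exception as exc:  # noqa: BLE001 - per-stimulus isolation is the contract
            logger.exception("stimulus %s failed", stim)
            sr.error = f"{type(exc).__name__}: {exc}"

    manifest = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "synthetic"},
            "synthetic": dataclasses.asdict(config.synthetic) if config.synthetic else None,
        },
        "seed": config.seed,
        "stimuli": stimuli,
        "outlier_channels": sorted(report.outliers),
        "files": files,
        "errors": {s: r.error for s, r in report.per_stimulus.items() if r.error},
    }
    report.manifest = manifest
    _write_atomic(out / "manifest.json", json.dumps(manifest, indent=2, default=_json_default))
    return report
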