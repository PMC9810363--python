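"""Staged pipeline: simulate -> preprocess -> connectivity -> motifs -> report.

Every stage reads its inputs from, and writes its outputs into, a single run
directory, so the pipeline can be driven end to end (:func:`run`) or stage
by stage (each ``stage_*`` function; the CLI maps one subcommand to each).
A manifest records the configuration hash, seed, and every artifact written;
rerunning with the same configuration reproduces the deterministic stages
bit for bit.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import EpochNetworkMetrics
from .exceptions import ConfigurationError
from .io import BAND_TABLE, Band, Recording, load_recording
from .motifs import (
    build_edge_series,
    count_changed_edges,
    dpte_dpte_correlation,
    dpte_plv_correlation,
    metrics_for_state,
    shuffle_surrogate_null,
    state_contrast,
    EdgeMetricSeries,
)
from .simulate import SimulationConfig, generate_recording, save_simulation

__all__ = ["PipelineConfig", "run"]

#: Reporting thresholds for the standard analysis.
DEFAULT_THRESHOLDS = {
    "edge_change": 0.02,  # |mean dPTE change| counted as a changed edge
    "network_p": 1e-3,  # per-edge significance for contrast network schematics
    "motif_dpte_p": 1e-10,  # dPTE x dPTE correlation display threshold
    "motif_plv_p": 1e-7,  # dPTE x PLV correlation display threshold
    "transition_p": 1e-2,  # transition-vs-state contrast threshold
}


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    out_dir: str = "edgeflow_run"
    simulation: SimulationConfig | None = None
    input_path: str | None = None
    band: str = "theta"
    epoch_length: float = 10.0
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("EPM", "RS"), ("EPM", "RS2")]
    )
    contrast_test: str = "two-sample"
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    n_shuffles: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in self.thresholds.items():
            if name != "edge_change" and not (0.0 < value < 1.0):
                raise ConfigurationError(f"threshold {name!r} must be in (0, 1)")
        if self.thresholds.get("edge_change", 0.02) <= 0:
            raise ConfigurationError("edge_change threshold must be positive")
        if self.epoch_length <= 0:
            raise ConfigurationError("epoch_length must be positive")
        if self.band not in BAND_TABLE:
            raise ConfigurationError(
                f"unknown band {self.band!r}; known: {sorted(BAND_TABLE)}"
            )

    @property
    def band_spec(self) -> Band:
        return BAND_TABLE[self.band]

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "input_path": self.input_path,
            "band": self.band,
            "epoch_length": self.epoch_length,
            "contrasts": [list(c) for c in self.contrasts],
            "contrast_test": self.contrast_test,
            "thresholds": dict(self.thresholds),
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation"):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        d["contrasts"] = [tuple(c) for c in d.get("contrasts", [])]
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


class _Manifest:
    def __init__(self, run_dir: Path, config: PipelineConfig):
        self.path = run_dir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "config": config.to_dict(),
                "stages": {},
            }
        if self.data["config_hash"] != config.config_hash():
            raise ConfigurationError(
                "run directory was created with a different configuration"
            )

    def record(self, stage: str, outputs: list[str]) -> None:
        self.data["stages"][stage] = sorted(outputs)
        self.path.write_text(json.dumps(self.data, indent=1))


def _run_dir(config: PipelineConfig) -> Path:
    d = Path(config.out_dir)
    d.mkdir(parents=True, exist_ok=True)
    return d


def _load_run_recording(config: PipelineConfig, run_dir: Path) -> Recording:
    path = run_dir / "recording.h5"
    if not path.exists():
        raise ConfigurationError(
            f"no recording in {run_dir}; run the simulate stage or provide input_path"
        )
    return load_recording(path, format="container")


def stage_simulate(config: PipelineConfig) -> Path:
    """Materialize the input recording (simulated or copied from input_path)."""
    run_dir = _run_dir(config)
    manifest = _Manifest(run_dir, config)
    if config.simulation is not None:
        recording, truth = generate_recording(config.simulation)
        save_simulation(recording, truth, run_dir)
        outputs = [
            "recording.h5",
            "ground_truth_strengths.csv",
            "ground_truth_latents.csv",
            "simulation_config.json",
        ]
    elif config.input_path is not None:
        rec = load_recording(config.input_path, format="container")
        from .io import save_recording

        save_recording(rec, run_dir / "recording.h5", format="container")
        outputs = ["recording.h5"]
    else:
        raise ConfigurationError("neither a simulation config nor an input_path given")
    manifest.record("simulate", outputs)
    return run_dir


def stage_preprocess(config: PipelineConfig) -> pd.DataFrame:
    """Index the analysis epochs of every state (counts, boundaries)."""
    run_dir = _run_dir(config)
    manifest = _Manifest(run_dir, config)
    rec = _load_run_recording(config, run_dir)
    win = int(round(config.epoch_length * rec.sampling_rate))
    rows = []
    for state in rec.states:
        index = 0
        for start, end in rec.intervals_of(state):
            for k in range((end - start) // win):
                rows.append(
                    {
                        "state": state,
                        "epoch_index": index,
                        "start_sample": start + k * win,
                        "end_sample": start + (k + 1) * win,
                    }
                )
                index += 1
    frame = pd.DataFrame(rows)
    frame.to_csv(run_dir / "epochs_index.csv", index=False)
    manifest.record("preprocess", ["epochs_index.csv"])
    return frame


def stage_connectivity(config: PipelineConfig) -> pd.DataFrame:
    """Per-epoch all-pairs dPTE and PLV, written in long format."""
    run_dir = _run_dir(config)
    manifest = _Manifest(run_dir, config)
    rec = _load_run_recording(config, run_dir)
    metrics: list[EpochNetworkMetrics] = []
    for state in rec.states:
        metrics.extend(
            metrics_for_state(rec, config.band_spec, state, config.epoch_length)
        )
    series = build_edge_series(metrics)
    frame = series.to_frame()
    frame.to_csv(run_dir / "per_epoch_metrics.csv", index=False)
    manifest.record("connectivity", ["per_epoch_metrics.csv"])
    return frame


def _series_from_csv(run_dir: Path) -> EdgeMetricSeries:
    path = run_dir / "per_epoch_metrics.csv"
    if not path.exists():
        raise ConfigurationError("connectivity stage has not been run")
    frame = pd.read_csv(path)
    regions = sorted(set(frame.source) | set(frame.target))
    dpte = frame[frame.metric == "dpte"]
    plv = frame[frame.metric == "plv"]
    key = ["state", "epoch_index"]
    epochs = dpte[key].drop_duplicates().reset_index(drop=True)
    order = {r: i for i, r in enumerate(regions)}
    directed = sorted(
        {(a, b) for a, b in zip(dpte.source, dpte.target)},
        key=lambda e: (order[e[0]], order[e[1]]),
    )
    undirected = sorted(
        {(a, b) for a, b in zip(plv.source, plv.target)},
        key=lambda e: (order[e[0]], order[e[1]]),
    )
    d_piv = dpte.pivot_table(
        index=key, columns=["source", "target"], values="value", sort=False
    )
    p_piv = plv.pivot_table(
        index=key, columns=["source", "target"], values="value", sort=False
    )
    idx = pd.MultiIndex.from_frame(epochs[key])
    return EdgeMetricSeries(
        regions=regions,
        directed_edges=directed,
        undirected_edges=undirected,
        dpte=d_piv.loc[idx, directed].to_numpy(),
        plv=p_piv.loc[idx, undirected].to_numpy(),
        states=list(epochs.state),
        epoch_indices=list(epochs.epoch_index),
    )


def stage_motifs(config: PipelineConfig) -> list[str]:
    """dPTE x dPTE and dPTE x PLV correlation matrices per state."""
    run_dir = _run_dir(config)
    manifest = _Manifest(run_dir, config)
    series = _series_from_csv(run_dir)
    outputs = []
    for state in dict.fromkeys(series.states):
        for kind, fn in (
            ("dpte_dpte", dpte_dpte_correlation),
            ("dpte_plv", dpte_plv_correlation),
        ):
            corr = fn(series, state)
            name = f"motif_{kind}_{state}.csv"
            corr.to_frame().to_csv(run_dir / name, index=False)
            outputs.append(name)
    manifest.record("motifs", outputs)
    return outputs


def stage_contrast(config: PipelineConfig) -> dict:
    """State contrasts with changed-edge counts and thresholded networks."""
    run_dir = _run_dir(config)
    manifest = _Manifest(run_dir, config)
    series = _series_from_csv(run_dir)
    outputs = []
    summary: dict[str, dict] = {}
    available = set(series.states)
    for state_a, state_b in config.contrasts:
        if state_a not in available or state_b not in available:
            continue
        tag = f"{state_a}-{state_b}"
        entry: dict = {}
        for metric in ("dpte", "plv"):
            contrast = state_contrast(
                series, state_a, state_b, metric=metric, test=config.contrast_test
            )
            name = f"contrast_{metric}_{tag}.csv"
            contrast.to_frame().to_csv(run_dir / name, index=False)
            outputs.append(name)
            if metric == "dpte":
                entry["changed_edges"] = count_changed_edges(
                    contrast, config.thresholds["edge_change"]
                )
                net = contrast.thresholded_network(config.thresholds["network_p"])
                net_name = f"network_{tag}.csv"
                net.to_csv(run_dir / net_name, index=False)
                outputs.append(net_name)
                entry["significant_edges"] = int(len(net))
        summary[tag] = entry
    (run_dir / "contrast_summary.json").write_text(json.dumps(summary, indent=1))
    outputs.append("contrast_summary.json")
    manifest.record("contrast", outputs)
    return summary


def stage_surrogate(config: PipelineConfig) -> dict:
    """Segment-shuffle null distributions for dPTE and PLV."""
    run_dir = _run_dir(config)
    manifest = _Manifest(run_dir, config)
    rec = _load_run_recording(config, run_dir)
    frames = {}
    for metric in ("dpte", "plv"):
        null = shuffle_surrogate_null(
            rec,
            config.band_spec,
            metric=metric,
            n_shuffles=config.n_shuffles,
            seed=config.seed,
            epoch_length=config.epoch_length,
        )
        frames[metric] = null.values
    frame = pd.DataFrame(frames)
    frame.to_csv(run_dir / "surrogate_null.csv", index=False)
    stats = {
        m: {"mean": float(v.mean()), "p95": float(np.percentile(v, 95))}
        for m, v in frames.items()
    }
    (run_dir / "surrogate_summary.json").write_text(json.dumps(stats, indent=1))
    manifest.record("surrogate", ["surrogate_null.csv", "surrogate_summary.json"])
    return stats


def stage_report(config: PipelineConfig) -> dict:
    """Collate stage summaries into a single report JSON."""
    run_dir = _run_dir(config)
    manifest = _Manifest(run_dir, config)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    for name in ("contrast_summary.json", "surrogate_summary.json"):
        path = run_dir / name
        if path.exists():
            report[name.removesuffix(".json")] = json.loads(path.read_text())
    path = run_dir / "per_epoch_metrics.csv"
    if path.exists():
        frame = pd.read_csv(path)
        report["epoch_counts"] = (
            frame[frame.metric == "dpte"]
            .groupby("state")
            .epoch_index.nunique()
            .to_dict()
        )
    (run_dir / "report.json").write_text(json.dumps(report, indent=1))
    manifest.record("report", ["report.json"])
    return report


def run(config: PipelineConfig, surrogate: bool = True) -> dict:
    """Execute every stage in order; returns the final report dict."""
    stages = [
        ("simulate", stage_simulate),
        ("preprocess", stage_preprocess),
        ("connectivity", stage_connectivity),
        ("motifs", stage_motifs),
        ("contrast", stage_contrast),
    ]
    if surrogate:
        stages.append(("surrogate", stage_surrogate))
    for name, fn in stages:
        try:
            fn(config)
        except Exception as exc:
            raise type(exc)(f"stage {name!r}: {exc}") from exc
    return stage_report(config)
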