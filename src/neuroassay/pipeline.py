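"""End-to-end orchestration: simulate -> detect -> metrics -> report.

Every run is driven by a single :class:`RunConfig` with explicit seeds, and
every stage writes plain files (CSV/JSON) so stages can be re-run or
inspected independently.  A manifest capturing the package version, the full
configuration and a hash of it is written alongside the outputs; two runs of
the same config produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from . import __version__
from .bursts import BurstDetectionParams, burst_metrics, compute_tsr, detect_bursts
from .calcium import TransientDetectionParams, calcium_metrics, detect_transients
from .spikes import SpikeDetectionParams, bandpass_filter, detect_spikes
from .stats import build_report, format_report_table, save_report
from .synthetic import generate_calcium_data, generate_mea_events, \
    generate_mea_recording, scenario_names, scenario_preset
from .viability import ViabilityCounts, viability_ratio


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for a full multi-scenario run.

    ``render_signals`` decides whether MEA activity is rendered to voltage
    and passed through filtering + spike detection (the full chain) or kept
    as spike rasters (orders of magnitude cheaper; appropriate for long
    recordings where burst/rate statistics are the object of interest).
    """

    scenarios: list = field(default_factory=lambda: ["sham", "hypoxia"])
    seeds: list = field(default_factory=lambda: [0, 1, 2])
    out_dir: str = "run"
    mea_duration: float = 60.0  # s per replicate
    ca_duration: float = 300.0  # s per replicate
    n_channels: int | None = None  # None = preset value (64)
    n_cells: int | None = None  # None = preset value (100)
    render_signals: bool = False
    spike_params: SpikeDetectionParams = field(default_factory=SpikeDetectionParams)
    burst_params: BurstDetectionParams = field(default_factory=BurstDetectionParams)
    transient_params: TransientDetectionParams = field(
        default_factory=TransientDetectionParams
    )
    tsr_bin_ms: float = 50.0

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("at least one seed is required")
        unknown = [s for s in self.scenarios if s not in scenario_names()]
        if unknown:
            raise ValueError(f"unknown scenario(s): {', '.join(unknown)}")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d


def _child_seed(base_seed: int, scenario_idx: int) -> int:
    """Stable per-(seed, scenario) RNG seed below 2**31."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(scenario_idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _run_mea(cfg: RunConfig, preset, seed: int):
    mea_cfg = replace(preset.mea, duration=cfg.mea_duration, seed=seed)
    if cfg.n_channels is not None:
        mea_cfg = replace(mea_cfg, n_channels=cfg.n_channels)
    if cfg.render_signals:
        rec, gt = generate_mea_recording(mea_cfg)
        filtered = bandpass_filter(rec, cfg.spike_params.band)
        events = detect_spikes(filtered, cfg.spike_params)
    else:
        events, gt = generate_mea_events(mea_cfg)
    tsr = compute_tsr(events, bin_width=cfg.tsr_bin_ms)
    bursts = detect_bursts(tsr, cfg.burst_params, events=events)
    metrics = burst_metrics(bursts, events=events)
    return events, bursts, metrics, gt


def _run_calcium(cfg: RunConfig, preset, seed: int):
    ca_cfg = replace(preset.calcium, duration=cfg.ca_duration, seed=seed)
    if cfg.n_cells is not None:
        ca_cfg = replace(ca_cfg, n_cells=cfg.n_cells)
    data = generate_calcium_data(ca_cfg)
    transients = detect_transients(data.traces, cfg.transient_params)
    metrics = calcium_metrics(transients)
    return data, transients, metrics


def _run_viability(preset, rng):
    p = preset.viability.n_dead / preset.viability.n_total
    n_total = preset.viability.n_total
    n_dead = int(rng.binomial(n_total, p))
    counts = ViabilityCounts(n_dead=n_dead, n_total=n_total)
    return {
        "n_dead": counts.n_dead,
        "n_total": counts.n_total,
        "percent_dead": viability_ratio(counts),
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Per scenario and seed: simulate MEA activity, detect spikes (when
    rendering) and bursts, simulate and detect calcium transients, sample
    dual-stain viability counts; then aggregate the per-replicate metrics
    into the group-comparison report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario_metrics = {}
    for si, scen in enumerate(config.scenarios):
        preset = scenario_preset(scen)
        per_metric = {
            "bursts_per_min": [],
            "population_spikes_per_s": [],
            "ca_osc_per_min": [],
            "ca_active_fraction": [],
            "percent_dead": [],
        }
        for seed in config.seeds:
            sdir = out / scen / f"seed_{seed}"
            sdir.mkdir(parents=True, exist_ok=True)
            child = _child_seed(seed, si)
            try:
                events, bursts, m_mea, gt = _run_mea(config, preset, child)
            except Exception as e:  # noqa: BLE001
                raise PipelineError("mea", f"{scen}/seed {seed}: {e}") from e
            try:
                data, transients, m_ca = _run_calcium(config, preset, child)
            except Exception as e:  # noqa: BLE001
                raise PipelineError("calcium", f"{scen}/seed {seed}: {e}") from e
            try:
                rng = np.random.default_rng(child + 1)
                m_via = _run_viability(preset, rng)
            except Exception as e:  # noqa: BLE001
                raise PipelineError("viability", f"{scen}/seed {seed}: {e}") from e
            events.to_csv(sdir / "spikes.csv")
            bursts.to_csv(sdir / "bursts.csv")
            transients.to_csv(sdir / "transients.csv")
            with open(sdir / "metrics.json", "w") as f:
                json.dump({"mea": m_mea, "calcium": m_ca, "viability": m_via},
                          f, indent=2, sort_keys=True)
            per_metric["bursts_per_min"].append(m_mea["bursts_per_min"])
            per_metric["population_spikes_per_s"].append(
                m_mea["population_spikes_per_s"]
            )
            per_metric["ca_osc_per_min"].append(m_ca["osc_per_min_active"])
            per_metric["ca_active_fraction"].append(m_ca["active_fraction"])
            per_metric["percent_dead"].append(m_via["percent_dead"])
        scenario_metrics[scen] = per_metric
    with open(out / "scenario_metrics.json", "w") as f:
        json.dump(scenario_metrics, f, indent=2, sort_keys=True)
    if len(config.scenarios) >= 2:
        try:
            report = build_report(scenario_metrics)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("report", str(e)) from e
        save_report(report, out / "report.json")
        with open(out / "report.txt", "w") as f:
            f.write(format_report_table(report) + "\n")
    cfg_json = json.dumps(config.to_jsonable(), sort_keys=True)
    manifest = {
        "package": "neuroassay",
        "version": __version__,
        "config": config.to_jsonable(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "scenarios": config.scenarios,
        "seeds": config.seeds,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return out
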