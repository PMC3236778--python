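"""Reproducible pipeline runs: configuration, stage driver, manifest.

A run ties the stages together: simulate -> drift correction / QC / BM ->
calibration -> unwinding detection -> cohort kinetics.  A single global seed
spawns independent per-stage substreams, so re-running with the same config
and seed reproduces every stochastic output bit-identically; the manifest
records the config snapshot, seed, output checksums and package version.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as smio
from .detection import UnwindingDetector, events_table
from .kinetics import VelocityCohort, bootstrap_mean, disappearance_curve
from .processing import BMAnalyzer, DriftCorrector, SymmetryFilter, calibrate, population_bm
from .simulate import SimulationConfig, simulate_cohort, simulate_population
from .substrate import fork_ac90

__all__ = [
    "RunConfig",
    "RunManifest",
    "run_pipeline",
    "analyze_unwinding_cohort",
    "load_config",
]

_PKG_VERSION = "0.1.0"


def _strict_kwargs(cls, payload: dict, context: str) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return payload


@dataclass
class PopulationSpec:
    n: int
    bm_mean: float
    bm_sd: float


@dataclass
class CohortSpec:
    label: str
    v_true: float
    n: int


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run_output"
    stages: List[str] = field(default_factory=lambda: ["simulate", "bm", "unwind", "kinetics"])
    simulator: Dict = field(default_factory=dict)
    populations: Dict[str, PopulationSpec] = field(default_factory=dict)
    cohorts: List[CohortSpec] = field(default_factory=list)
    delta_bp: int = 71
    bm: Dict = field(default_factory=dict)          # window_frames, stride, drift_window_s, qc_frames
    detection: Dict = field(default_factory=dict)   # UnwindingDetector parameters
    bootstrap_resamples: int = 100

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        _strict_kwargs(cls, payload, "run config")
        pops = {
            name: PopulationSpec(**_strict_kwargs(PopulationSpec, dict(p), f"populations.{name}"))
            for name, p in payload.get("populations", {}).items()
        }
        cohorts = [
            CohortSpec(**_strict_kwargs(CohortSpec, dict(c), "cohorts entry"))
            for c in payload.get("cohorts", [])
        ]
        payload["populations"] = pops
        payload["cohorts"] = cohorts
        known_stages = {"simulate", "bm", "unwind", "kinetics"}
        bad = set(payload.get("stages", [])) - known_stages
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        return cls(**payload)


@dataclass
class RunManifest:
    config: dict
    seed: int
    outputs: Dict[str, str]   # path -> sha256
    version: str
    timestamp: str

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    payload = yaml.safe_load(text)
    return RunConfig.from_dict(payload)


def analyze_unwinding_cohort(
    trajs,
    c: float,
    bm_params: Optional[dict] = None,
    detector_params: Optional[dict] = None,
    label: str = "cohort",
):
    """Trajectories -> per-molecule events and a velocity cohort.

    Applies drift correction and windowed BM analysis, runs the unwinding
    detector on each bead, and collects ``v_slope`` of qualifying,
    non-paused molecules into a :class:`VelocityCohort`.
    """
    bm_params = dict(bm_params or {})
    drift_window_s = bm_params.pop("drift_window_s", 10.0)
    corrector = DriftCorrector(drift_window_s)
    analyzer = BMAnalyzer(**bm_params)
    detector = UnwindingDetector(c=c, **(detector_params or {}))
    events = []
    for traj in trajs:
        series = analyzer.transform(corrector.transform(traj))
        detector.fit(series, disappeared=traj.disappeared)
        events.append(detector.event(bead_id=traj.bead_id))
    df = events_table(events)
    keep = df[(df.qualifies) & (~df.paused)]
    cohort = VelocityCohort(label, keep["v_slope_bp_s"].to_numpy()) if len(keep) else None
    return df, cohort


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages; write per-stage outputs and a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}
    root_ss = np.random.SeedSequence(config.seed)
    # fixed substream layout keeps stages independently reproducible
    ss_pop, ss_cohort, ss_boot = root_ss.spawn(3)

    sim_cfg = SimulationConfig(**_strict_kwargs(SimulationConfig, dict(config.simulator), "simulator"))
    substrate = fork_ac90()

    populations = {}
    cohort_trajs = {}
    if "simulate" in config.stages:
        for (name, spec), ss in zip(sorted(config.populations.items()),
                                    ss_pop.spawn(max(1, len(config.populations)))):
            trajs = simulate_population(
                sim_cfg, spec.n, spec.bm_mean, spec.bm_sd,
                rng=np.random.default_rng(ss),
            )
            populations[name] = trajs
            path = out / f"population_{name}.csv"
            smio.write_trajectories(trajs, path)
            outputs[str(path)] = smio.sha256_file(path)
        for spec, ss in zip(config.cohorts, ss_cohort.spawn(max(1, len(config.cohorts)))):
            cfg = dataclasses.replace(sim_cfg, v_true=spec.v_true)
            trajs = simulate_cohort(cfg, spec.n, substrate=substrate,
                                    rng=np.random.default_rng(ss), all_unwind=True)
            cohort_trajs[spec.label] = trajs
            path = out / f"cohort_{spec.label}.csv"
            smio.write_trajectories(trajs, path)
            smio.write_truth(trajs, out / f"cohort_{spec.label}_truth.json")
            outputs[str(path)] = smio.sha256_file(path)
            outputs[str(out / f"cohort_{spec.label}_truth.json")] = smio.sha256_file(
                out / f"cohort_{spec.label}_truth.json")

    calibration = None
    if "bm" in config.stages and {"fork", "mimic"} <= set(populations):
        qc_frames = config.bm.get("qc_frames", 1000)
        pop_fork = population_bm(populations["fork"], n_frames=qc_frames)
        pop_mimic = population_bm(populations["mimic"], n_frames=qc_frames)
        calibration = calibrate(pop_fork, pop_mimic, config.delta_bp)
        path = out / "calibration.json"
        path.write_text(json.dumps(asdict(calibration), indent=1))
        outputs[str(path)] = smio.sha256_file(path)

    results_rows = []
    cohorts: Dict[str, VelocityCohort] = {}
    if "unwind" in config.stages and cohort_trajs:
        c = calibration.c if calibration is not None else sim_cfg.c_true
        bm_params = {k: v for k, v in config.bm.items() if k != "qc_frames"}
        for label, trajs in cohort_trajs.items():
            df, cohort = analyze_unwinding_cohort(
                trajs, c, bm_params=bm_params,
                detector_params=config.detection, label=label,
            )
            path = out / f"events_{label}.tsv"
            smio.write_events(df, path)
            outputs[str(path)] = smio.sha256_file(path)
            if cohort is not None:
                cohorts[label] = cohort

    if "kinetics" in config.stages and cohorts:
        ref = next(iter(cohorts.values()))
        for (label, cohort), ss in zip(cohorts.items(), ss_boot.spawn(len(cohorts))):
            bs = bootstrap_mean(
                cohort, resamples=config.bootstrap_resamples,
                seed=int(ss.generate_state(1)[0] % (2**31)),
            )
            results_rows.append(
                {
                    "condition": label,
                    "n": cohort.n,
                    "v_mean_bp_s": cohort.mean,
                    "v_sd_bp_s": cohort.sd,
                    "boot_mean_bp_s": bs.mean,
                    "boot_sd_bp_s": bs.sd,
                    "fold_vs_ref": cohort.mean / ref.mean,
                }
            )
        report = pd.DataFrame(results_rows)
        path = out / "kinetics_report.tsv"
        smio.write_report(report, path)
        outputs[str(path)] = smio.sha256_file(path)

        loss_times = [
            t.truth.t_release
            for trajs in cohort_trajs.values()
            for t in trajs
            if t.truth is not None and t.truth.t_release is not None
        ]
        total = sum(len(v) for v in cohort_trajs.values())
        if loss_times:
            dc = disappearance_curve(loss_times, total)
            path = out / "disappearance.json"
            path.write_text(
                json.dumps(
                    {
                        "total": dc.total,
                        "n_events": len(dc.times),
                        "y0": dc.y0,
                        "amplitude": dc.amplitude,
                        "t_const_s": dc.t_const,
                    },
                    indent=1,
                )
            )
            outputs[str(path)] = smio.sha256_file(path)

    manifest = RunManifest(
        config=_config_snapshot(config),
        seed=config.seed,
        outputs=outputs,
        version=_PKG_VERSION,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out / "manifest.json")
    return manifest


def _config_snapshot(config: RunConfig) -> dict:
    snap = asdict(config)
    return snap
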