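"""Config-driven runs: a validated RunConfig, stage registry, and manifest.

A run is a YAML (or dict) configuration naming a seed, an output directory
and a list of stages with their parameters.  Each stage draws its seed from
one spawned stream, writes its outputs under the run directory, and
contributes a summary to the JSON manifest.  The manifest echoes every
parameter, so identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import inspect
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import kinetics, synthetic
from .force import TrapCalibration, analyze_force_trace
from .kymograph import residence_time, trace_spot
from .photobleach import count_fluorophores, estimate_unit_intensity

log = logging.getLogger("mtcoupler")

__all__ = ["RunConfig", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# --------------------------------------------------------------------------
# stages


def _stage_simulate_residence(
    out_dir: Path, seed: int, valence: int = 3, k_on: float = 2.6,
    k_off: float = 0.62, n_runs: int = 1000,
) -> dict:
    rts = kinetics.simulate_residence(
        kinetics.KineticParams(valence=valence, k_off=k_off, k_on=k_on), n_runs, seed
    )
    path = out_dir / f"residence_valence{valence}.csv"
    rts.to_csv(path)
    return {
        "csv": path.name,
        "valence": valence,
        "n_runs": n_runs,
        "mean_residence_s": rts.mean(),
        "closed_form_mean_s": kinetics.mean_residence_closed_form(
            kinetics.KineticParams(valence=valence, k_off=k_off, k_on=k_on)
        ),
    }


def _stage_fit_kon(
    out_dir: Path, seed: int, k_off: float = 0.62, k_on_true: float = 2.6,
    valences: list = (2, 3, 4), n_per_valence: int = 1000,
    grid_min: float = 0.1, grid_max: float = 10.0, grid_step: float = 0.05,
) -> dict:
    sets = synthetic.gen_residence_dataset(k_on_true, k_off, list(valences), n_per_valence, seed)
    grid = np.arange(grid_min, grid_max + 1e-9, grid_step)
    fit = kinetics.fit_kon(sets, k_off, grid=grid)
    path = out_dir / "fit_kon.json"
    kinetics.save_fit(fit, path, seed=seed)
    return {"json": path.name, "k_on_fit": fit["k_on"], "k_on_true": k_on_true}


def _stage_trace_kymograph(
    out_dir: Path, seed: int, frames: int = 60, n_px: int = 64,
    px_size_nm: float = 160.0, frame_dt_s: float = 1.1,
    spot_position_px: float = 30.0, peak_photons: float = 100.0,
    tip_velocity_nm_s: float = 0.0,
) -> dict:
    spot = synthetic.SpotModel(position_px=spot_position_px, peak_photons=peak_photons)
    kymo, _mt, truth = synthetic.gen_kymograph(
        frames, n_px=n_px, px_size_nm=px_size_nm, frame_dt_s=frame_dt_s,
        spot=spot, tip_velocity_nm_s=tip_velocity_nm_s, seed=seed,
    )
    track = trace_spot(kymo, (truth.landing_frame, spot_position_px))
    path = out_dir / "spot_track.csv"
    track.to_frame().to_csv(path, index=False)
    tau, censored = residence_time(track, frame_dt_s)
    return {
        "csv": path.name,
        "n_frames_tracked": int(track.frames.size),
        "residence_s": tau,
        "left_censored": bool(censored),
    }


def _stage_count_fluorophores(
    out_dir: Path, seed: int, n_traces: int = 50, n_fluor: int = 3,
    unit: float = 100.0, noise_sd: float = 15.0, bleach_rate: float = 0.1,
) -> dict:
    seeds = np.random.SeedSequence(seed).generate_state(n_traces) & 0x7FFFFFFF
    traces = [
        synthetic.gen_bleach_trace(
            n_fluor, unit=unit, bleach_rate=bleach_rate, noise_sd=noise_sd, seed=int(s)
        )[0]
        for s in seeds
    ]
    unit_est = estimate_unit_intensity(traces)
    counts = [count_fluorophores(t, unit_est, allow_no_step=True) for t in traces]
    path = out_dir / "fluorophore_counts.csv"
    np.savetxt(path, counts, fmt="%d", header="count", comments="")
    exact = float(np.mean(np.asarray(counts) == n_fluor))
    return {
        "csv": path.name,
        "unit_estimate_au": unit_est.value,
        "unit_true_au": unit,
        "exact_recovery_fraction": exact,
    }


def _stage_analyze_force(
    out_dir: Path, seed: int, kappa_pn_nm: float = 0.03, plateau_nm: float = 100.0,
    stall_duration_s: float = 1.5, outcome: str = "detachment",
    duration_s: float = 10.0, rate_hz: float = 10000.0,
) -> dict:
    truth = synthetic.TrapGroundTruth(
        kappa_pn_nm=kappa_pn_nm,
        stalls=(synthetic.StallSegment(3.0, plateau_nm, stall_duration_s, outcome),),
    )
    trace = synthetic.gen_qpd_trace(truth, duration_s, rate_hz, seed)
    calib = TrapCalibration(kappa_pn_nm=kappa_pn_nm, corner_frequency_hz=1.0)
    event = analyze_force_trace(trace, calib, baseline_window_s=(0.0, 2.0))
    if event is None:
        return {"stall_detected": False}
    return {
        "stall_detected": True,
        "force_pn": event.force_pn,
        "duration_s": event.duration_s,
        "outcome": event.outcome,
        "programmed_force_pn": kappa_pn_nm * plateau_nm,
    }


_STAGES = {
    "simulate_residence": _stage_simulate_residence,
    "fit_kon": _stage_fit_kon,
    "trace_kymograph": _stage_trace_kymograph,
    "count_fluorophores": _stage_count_fluorophores,
    "analyze_force": _stage_analyze_force,
}


# --------------------------------------------------------------------------
# config


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` is a list of dicts, each with a ``stage`` key naming a
    registered stage plus that stage's keyword parameters.  Unknown top-level
    keys, unknown stages and unknown stage parameters are all rejected.
    """

    seed: int = 0
    out_dir: str = "results/run"
    stages: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for spec in self.stages:
            name = spec.get("stage")
            if name not in _STAGES:
                raise ValueError(f"unknown stage {name!r}; known: {sorted(_STAGES)}")
            allowed = set(inspect.signature(_STAGES[name]).parameters) - {"out_dir", "seed"}
            extra = set(spec) - allowed - {"stage"}
            if extra:
                raise ValueError(f"unknown parameter(s) {sorted(extra)} for stage {name!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"seed", "out_dir", "stages"}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config key(s): {sorted(extra)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: RunConfig | dict | str | Path) -> dict:
    """Execute the configured stages and write a JSON manifest.

    Returns the manifest dict (also written to ``<out_dir>/manifest.json``):
    package version, seed, echoed parameters and per-stage outputs.  The
    manifest carries no wall-clock state, so identical config and seed give
    an identical manifest.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_seeds = np.random.SeedSequence(config.seed).generate_state(
        max(len(config.stages), 1)
    ) & 0x7FFFFFFF

    manifest = {
        "package": "mtcoupler",
        "version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    for spec, stage_seed in zip(config.stages, stage_seeds):
        name = spec["stage"]
        params = {k: v for k, v in spec.items() if k != "stage"}
        t0 = time.perf_counter()
        try:
            outputs = _STAGES[name](out_dir, int(stage_seed), **params)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage=%s seed=%d elapsed=%.2fs", name, stage_seed, time.perf_counter() - t0)
        manifest["stages"].append(
            {"stage": name, "seed": int(stage_seed), "params": params, "outputs": outputs}
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
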