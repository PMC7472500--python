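"""End-to-end orchestration: trials in, angle/peak/validity tables out.

Two entry points:

``run_validation``
    The dummy-rig study: simulate single-plane sweeps at both end plates,
    run the marker pipeline for each requested model, and tabulate Pearson
    validity plus Bland-Altman agreement per (model, joint, plane) cell.

``run_pipeline``
    Living-body style processing of recorded trials: filter -> segment
    frames -> joint angles -> static-baseline subtraction -> task peaks,
    with every parameter logged so a run can be re-executed exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .agreement import validity_report
from .config import RunConfig, TrialBundle
from .core import TrajectorySet
from .dummy import (
    DummyGeometry,
    SweepProtocol,
    default_geometry,
    measured_sweep_angles,
    simulate_sweep,
)
from .kinematics import (
    COMPONENTS,
    PLANE_COMPONENT,
    compute_baseline,
    extract_peaks,
    filter_angles,
    filter_trajectories,
    joint_angles,
    subtract_baseline,
)
from .models import register_model

__all__ = ["run_validation", "validation_cells", "run_pipeline", "rig_joints"]

PLANES = ("frontal", "transverse", "sagittal")


def rig_joints(model_id: str) -> tuple[str, ...]:
    """Joints measurable on the three-plate rig for a given model."""
    spec = register_model(model_id)
    return tuple(j for j in spec.joint_names if j.startswith(("Met_Hal", "Cal_Met")))


def validation_cells(
    models=("new", "new_2", "rizzoli"),
    planes=PLANES,
    geometry: DummyGeometry | None = None,
    grid: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    placement_sigma: float = 0.0,
    seed: int | None = None,
    subtract_neutral: bool = True,
):
    """Yield (model, joint, plane, measured, truth) for every study cell.

    One sweep simulation per (moving end, plane) is shared by all models.
    ``measured`` is the swept-plane component of the model's joint angles;
    ``truth`` is the imposed plate grid.
    """
    geometry = geometry or default_geometry()
    kwargs = dict(
        noise_sigma=noise_sigma, placement_sigma=placement_sigma, seed=seed
    )
    if grid is not None:
        kwargs["grid"] = grid
    sweeps = {
        (end, plane): simulate_sweep(
            geometry, SweepProtocol(moving_plate=end, plane=plane, **kwargs)
        )
        for end in ("A", "C")
        for plane in planes
    }
    for model in models:
        for joint in rig_joints(model):
            end = "A" if joint.startswith("Met_Hal") else "C"
            for plane in planes:
                sweep = sweeps[(end, plane)]
                series = measured_sweep_angles(
                    sweep, model, joint=joint, subtract_neutral=subtract_neutral
                )
                measured = series.component(PLANE_COMPONENT[plane])
                yield model, joint, plane, measured, sweep.truth.grid


def run_validation(
    models=("new", "new_2", "rizzoli"),
    planes=PLANES,
    geometry: DummyGeometry | None = None,
    grid: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    placement_sigma: float = 0.0,
    seed: int | None = None,
    subtract_neutral: bool = True,
) -> pd.DataFrame:
    """Full simulated validity study; returns the tidy agreement table."""
    return validity_report(
        validation_cells(
            models=models, planes=planes, geometry=geometry, grid=grid,
            noise_sigma=noise_sigma, placement_sigma=placement_sigma,
            seed=seed, subtract_neutral=subtract_neutral,
        )
    )


def _load_trial(trial: TrialBundle) -> TrajectorySet:
    traj = fio.read_trajectories(trial.path, rate=trial.rate)
    if trial.side == "left":
        # left feet are mirrored into right-foot convention (negate lab Z)
        traj = TrajectorySet(
            {n: a * np.array([1.0, 1.0, -1.0]) for n, a in traj.markers.items()},
            traj.rate,
        )
    return traj


def run_pipeline(
    config: RunConfig, trials: list[TrialBundle], out_dir: str | Path | None = None
) -> dict:
    """Process recorded trials per the configured protocol.

    The static trial (if any) supplies the baseline for every dynamic
    trial.  Writes per-trial angle CSVs, a peaks JSON and a parameter log;
    returns the artifact paths and in-memory results.  Deterministic given
    (config, seed, inputs).
    """
    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = register_model(config.model)

    def process(trial: TrialBundle):
        traj = _load_trial(trial)
        config.validate(rate=traj.rate)
        if config.filter_stage == "markers":
            traj = filter_trajectories(traj, config.filter_cutoff_hz, config.filter_order)
        angles = joint_angles(traj, spec, convention=config.euler_convention)
        if config.filter_stage == "angles":
            angles = {
                j: filter_angles(s, config.filter_cutoff_hz, config.filter_order)
                for j, s in angles.items()
            }
        return angles

    statics = [t for t in trials if t.trial_type == "static"]
    baseline = None
    if config.baseline == "static" and statics:
        baseline = compute_baseline(process(statics[0]))

    artifacts: dict = {"angles": {}, "peaks": {}, "files": []}
    peaks_doc = []
    for idx, trial in enumerate(trials):
        name = f"{trial.trial_type}_{idx:02d}"
        try:
            angles = process(trial)
        except Exception as exc:
            raise RuntimeError(f"[{name}] {type(exc).__name__}: {exc}") from exc
        if baseline is not None and trial.trial_type != "static":
            angles = {j: subtract_baseline(s, baseline) for j, s in angles.items()}
        artifacts["angles"][name] = angles
        path = fio.write_angles_csv(angles, out / f"angles_{name}.csv", trial=name)
        artifacts["files"].append(str(path))
        if trial.trial_type in ("calf_raise", "drop_jump", "gait"):
            for joint, series in angles.items():
                pk = extract_peaks(series, trial.window, task=trial.trial_type)
                artifacts["peaks"][(name, joint)] = pk
                peaks_doc.append(
                    {
                        "trial": name, "joint": joint, "task": pk.task,
                        "window": list(pk.window),
                        **{f"max_{c}": pk.maxima[i] for i, c in enumerate(COMPONENTS)},
                        **{f"min_{c}": pk.minima[i] for i, c in enumerate(COMPONENTS)},
                    }
                )

    (out / "peaks.json").write_text(json.dumps(peaks_doc, indent=2))
    log = {
        "config": asdict(config),
        "trials": [asdict(t) for t in trials],
        "baseline_joints": sorted(baseline) if baseline else [],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    artifacts["files"] += [str(out / "peaks.json"), str(out / "run_log.json")]
    return artifacts
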