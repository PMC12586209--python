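"""End-to-end pipeline driver.

Runs the full chain — synthetic cohort, standing-TSTT conversion,
phantom strength simulation, age trajectories, risk classification —
and writes a manifest recording the seed, a config hash and per-stage
status, so outputs from different runs are never silently mixed.

Seeding: one master seed; per-stage seeds are derived from it by a fixed
counter scheme (SeedSequence spawn order: cohort=0, phantom=1,
trajectories=2), so every stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import CohortParams, cohort_to_frame, generate_cohort
from .fe import FallConfig, assign_contact_sets, pose_femur, solve_strength
from .io import load_config, save_density_volume, write_cohort, write_vtk
from .materials import CalibrationParams, map_to_elements
from .mesh import mesh_from_volume
from .phantom import FemurPhantomSpec, generate_femur_phantom, project_abmd
from .risk import RiskThresholds, cross_tabulate
from .stats import trajectories_by_group
from .tstt import TSTTCoefficients, add_standing_tstt

TRAJECTORY_VARIABLES = ("abmd", "frax_hfp", "tstt_standing", "strength")


@dataclass
class PipelineConfig:
    """Driver configuration; any section may be None to use defaults."""

    out_dir: str
    seed: int
    cohort: dict | None = None
    phantom: dict | None = None
    calibration: dict | None = None
    fall: dict | None = None
    thresholds: dict | None = None
    n_override: int | None = None
    mesh_target_edge: float = 6.0
    verbosity: int = 1
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        data = load_config(path)
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = {k: data.pop(k) for k in list(data) if k not in known}
        return cls(extra=extra, **data)


def _build(section: dict | None, cls):
    obj = cls(**(section or {}))
    obj.validate()
    return obj


def _config_hash(cfg: PipelineConfig) -> str:
    """Hash of the scientific configuration (output location and
    verbosity excluded), so outputs of different runs are detectable."""
    payload = dataclasses.asdict(cfg)
    payload.pop("out_dir", None)
    payload.pop("verbosity", None)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Eagerly validates every config section before any compute.  A stage
    failure is recorded in the manifest with its error; earlier outputs
    are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = _build(cfg.cohort, CohortParams)
    spec = _build(cfg.phantom, FemurPhantomSpec)
    cal = _build(cfg.calibration, CalibrationParams)
    fall = _build(cfg.fall, FallConfig)
    th = _build(cfg.thresholds, RiskThresholds)
    coeffs = TSTTCoefficients()
    coeffs.validate()

    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(cfg.seed).spawn(3)]
    chash = _config_hash(cfg)
    manifest = {"package": "femfall", "version": __version__, "seed": cfg.seed,
                "config_hash": chash, "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "stages": {}}

    def stage(name, fn):
        try:
            info = fn() or {}
            manifest["stages"][name] = {"status": "ok", **info}
        except Exception as e:  # recorded, partial outputs retained
            manifest["stages"][name] = {"status": "error", "error": f"{type(e).__name__}: {e}"}
        _write_manifest(out, manifest)

    state: dict = {}

    def run_cohort():
        records = generate_cohort(params, n_override=cfg.n_override, seed=seeds[0])
        add_standing_tstt(records, coeffs)
        state["records"] = records
        df = cohort_to_frame(records)
        df["config_hash"] = chash
        write_cohort(df, out / "cohort.csv")
        return {"n_subjects": len(records)}

    def run_strength():
        vol = generate_femur_phantom(spec, seed=seeds[1])
        save_density_volume(vol, out / "phantom.nii")
        mesh = mesh_from_volume(vol, target_edge=cfg.mesh_target_edge)
        mat = map_to_elements(vol, mesh, cal)
        posed = pose_femur(mesh, fall)
        assign_contact_sets(posed, fall)
        result = solve_strength(posed, mat, fall)
        write_vtk(out / "phantom_mesh.vtk", posed.nodes, posed.elements,
                  cell_data={"young_modulus": mat.young_modulus})
        payload = {
            "config_hash": chash,
            "strength_kN": result.femoral_strength,
            "projected_abmd": project_abmd(vol, "y"),
            "displacement_mm": result.displacement.tolist(),
            "head_force_N": result.head_force.tolist(),
            "converged": [bool(c) for c in result.converged],
            "yield_fraction": result.yield_fraction.tolist(),
        }
        (out / "strength.json").write_text(json.dumps(payload, indent=1))
        return {"strength_kN": result.femoral_strength, "n_elements": mesh.n_elements}

    def run_trajectories():
        df = cohort_to_frame(state["records"])
        fits = trajectories_by_group(df, TRAJECTORY_VARIABLES, n_boot=0, seed=seeds[2])
        for fit in fits:
            name = f"trajectory_{fit.variable}_{fit.sex}_{fit.ethnicity}.csv"
            import pandas as pd
            pd.DataFrame({"age": fit.ages, "fitted": fit.fitted}).assign(
                config_hash=chash).to_csv(out / name, index=False)
        return {"n_trajectories": len(fits)}

    def run_classify():
        table = cross_tabulate(state["records"], th)
        payload = {"config_hash": chash,
                   "strata": {f"{sex}/{eth}": v for (sex, eth), v in table.items()}}
        (out / "risk_summary.json").write_text(json.dumps(payload, indent=1))
        return {"n_strata": len(table)}

    stage("cohort", run_cohort)
    if "records" in state:
        stage("trajectories", run_trajectories)
        stage("classification", run_classify)
    stage("strength", run_strength)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
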