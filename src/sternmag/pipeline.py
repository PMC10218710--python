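"""End-to-end runners: schedule -> simulate -> fit, and the dosimetry bundle.

Every run writes a manifest (seeds, config hash, package and library
versions) sufficient to reproduce the outputs bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dissociation, dosimetry, scheduler, synthetic_rt
from .config import RunConfig, config_hash, config_to_dict

log = logging.getLogger("sternmag")


def _seeds(config: RunConfig) -> dict[str, int]:
    root = np.random.SeedSequence(config.seed)
    kids = root.spawn(4)
    names = ("assignment", "pools", "cohort", "profiles")
    return {n: int(k.generate_state(1)[0] % 2**31) for n, k in zip(names, kids)}


def _write_manifest(out: Path, config: RunConfig, seeds: dict[str, int], outputs) -> None:
    manifest = {
        "package": "sternmag",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_sha256": config_hash(config),
        "config": config_to_dict(config),
        "seeds": seeds,
        "outputs": sorted(outputs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Simulate the cohort, fit both dissociation models, write all outputs.

    Writes trials.csv, rt_records.csv, fit.json (both model fits plus the
    derived exposure effects), cell_means.csv, homogeneity.csv,
    error_omission.csv and manifest.json into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(config)
    log.info("pipeline seeds: %s", seeds)

    n = config.n_exposed + config.n_sham
    ids = [f"S{i:03d}" for i in range(1, n + 1)]
    plan = scheduler.assign_groups(ids, config.n_exposed, seeds["assignment"])
    pools = scheduler.make_symbol_pools(
        seeds["pools"],
        n_target=config.scheduler.n_target_pool,
        n_foil=config.scheduler.n_foil_pool,
    )
    records, sessions = synthetic_rt.simulate_cohort(
        plan, config.generator, seed=seeds["cohort"], pools=pools, return_sessions=True
    )
    scheduler.write_sessions_csv(sessions, out / "trials.csv")
    synthetic_rt.write_records_csv(records, out / "rt_records.csv")

    fit2 = dissociation.fit_sternberg(records, "eq2")
    sham = records[records["exposed"] == 0]
    fit1 = dissociation.fit_sternberg(sham, "eq1")
    effects = dissociation.derived_effects(fit2)
    fit_report = {
        "eq1": fit1.to_dict(),
        "eq2": fit2.to_dict(),
        "derived_effects": effects.to_dict(),
    }
    (out / "fit.json").write_text(json.dumps(fit_report, indent=2))

    dissociation.cell_means(records).to_csv(out / "cell_means.csv", index=False)
    profiles = synthetic_rt.generate_profiles(plan, seed=seeds["profiles"])
    dissociation.compare_groups(profiles).to_csv(out / "homogeneity.csv", index=False)
    eo = dissociation.error_omission_summary(records)
    eo_cmp = dissociation.error_omission_comparisons(records)
    eo.to_csv(out / "error_omission.csv", index=False)
    if len(eo_cmp):
        eo_cmp.to_csv(out / "error_omission_tests.csv", index=False)

    outputs = [p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"]
    _write_manifest(out, config, seeds, outputs)
    return {
        "plan": plan,
        "records": records,
        "fit_eq1": fit1,
        "fit_eq2": fit2,
        "derived_effects": effects,
        "out_dir": out,
    }


def run_dosimetry(config: RunConfig, out_dir: str | Path) -> dict:
    """Compute the head field map, plane slices, drive current and eddy power."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dc = config.dosimetry
    grid_points = dosimetry.make_grid(dc.grid.x_mm, dc.grid.y_mm, dc.grid.z_mm)
    grid = dosimetry.head_field_map(
        drive=dc.drive,
        spec=dc.solenoid,
        head_width=dc.head_width_m,
        coils_per_side=dc.coils_per_side,
        segments_per_turn=dc.segments_per_turn,
        grid_points=grid_points,
    )
    grid.to_frame().to_csv(out / "field_grid.csv", index=False)
    mid_z = dc.head_width_m * 1e3 / 2.0
    slices = {
        "slice_xy_z0.csv": ("z", 0.0),
        "slice_zx_y0.csv": ("y", 0.0),
        "slice_xy_zmid.csv": ("z", mid_z),
    }
    for name, (axis, value) in slices.items():
        dosimetry.plane_slice(grid, axis, value).to_csv(out / name, index=False)

    current = dosimetry.solenoid_current(dc.solenoid, dc.drive)
    mid_point = np.array([[0.0, 0.0, dc.head_width_m / 2.0]])
    mid = dosimetry.biot_savart(
        dosimetry.build_head_coil_array(
            dc.solenoid, dc.head_width_m, dc.coils_per_side, segments_per_turn=dc.segments_per_turn
        ),
        current,
        mid_point,
    )
    mid_b = float(mid.magnitude[0])
    summary = {
        "current_A": current,
        "frequency_Hz": dc.drive.frequency,
        "voltage_V": dc.drive.voltage_amplitude,
        "mid_head_B_T": mid_b,
        "mid_head_B_uT": mid_b * 1e6,
        "eddy_power_W_per_kg": dosimetry.eddy_power_density(
            mid_b, dc.tissue, dc.drive.frequency
        ),
    }
    (out / "dosimetry_summary.json").write_text(json.dumps(summary, indent=2))
    outputs = [p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"]
    _write_manifest(out, config, {}, outputs)
    return {"grid": grid, "summary": summary, "out_dir": out}
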