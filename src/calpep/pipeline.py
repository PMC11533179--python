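"""Configuration-driven orchestration of the full analysis chain.

A run is described by one flat YAML config with two optional stages:

``spectra``
    synthesize linear + time-domain 2D data, build 2D spectra, run the
    CLS analysis, the relaxation kinetics and the decay-time map.
``trajectory``
    synthesize a toy trajectory, categorize binding states, compute the
    Ca-O RDF, the hydration table and the binding-state-resolved VDOS.

Every default is echoed into the run manifest together with the seed, so
each numeric output is traceable to config + seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from calpep import cls as cls_mod
from calpep import io as cio
from calpep import linear_ir, spectra2d, traj_analysis, ver
from calpep.synth_spectra import AcquisitionParams, BandParams, make_2d_timedomain, make_linear_spectrum
from calpep.synth_traj import TrajectoryConfig, make_trajectory

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "calpep_run",
    "stages": ["spectra", "trajectory"],
    "spectra": {
        "bands": [
            {
                "center": 1590.0,
                "sigma_inhom": 8.0,
                "sigma_hom": 9.0,
                "tau_corr": 1.0,
                "tau_ver": 0.46,
                "heat_fraction": 0.2,
            },
            {
                "center": 1660.0,
                "sigma_inhom": 9.0,
                "sigma_hom": 8.0,
                "tau_corr": 1.4,
                "tau_ver": 0.67,
                "heat_fraction": 0.2,
            },
        ],
        "waiting_times": [0.0, 0.2, 0.4, 0.6, 0.8, 1.2, 1.6, 2.0, 3.0, 4.0],
        "noise_rms": 0.005,
        "cls_fit_window": 0.8,
        "cls_band_window": [1550.0, 1630.0],
        "decay_map_block": 5,
        "mask_fraction": 0.10,
    },
    "trajectory": {
        "n_frames": 600,
        "state_fractions": {"1Ca@COO": 0.26, "2Ca@COO": 0.26, "1Ca@CO": 0.02,
                            "1Ca@COO+1Ca@CO": 0.13},
        "rdf_dr": 0.05,
        "ca_cutoff": 3.0,
        "hydration_cutoff": 2.4,
    },
}

_KNOWN_KEYS = {
    "": {"seed", "out_dir", "stages", "spectra", "trajectory", "inputs"},
    "spectra": {
        "bands", "waiting_times", "noise_rms", "cls_fit_window",
        "cls_band_window", "decay_map_block", "mask_fraction",
    },
    "trajectory": {
        "n_frames", "state_fractions", "rdf_dr", "ca_cutoff",
        "hydration_cutoff", "xyz_file",
    },
}


def validate_config(cfg: dict) -> dict:
    """Merge over defaults after rejecting unknown keys (listed explicitly)."""
    bad = []
    for key in cfg:
        if key not in _KNOWN_KEYS[""]:
            bad.append(key)
    for section in ("spectra", "trajectory"):
        for key in cfg.get(section, {}) or {}:
            if key not in _KNOWN_KEYS[section]:
                bad.append(f"{section}.{key}")
    if bad:
        raise ValueError(f"unknown config keys: {', '.join(sorted(bad))}")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in cfg.items():
        if key in ("spectra", "trajectory") and isinstance(val, dict):
            merged[key].update(val)
        else:
            merged[key] = val
    xyz = (merged.get("trajectory") or {}).get("xyz_file")
    if xyz is not None and not Path(xyz).exists():
        raise ValueError(f"referenced trajectory file does not exist: {xyz}")
    return merged


def _run_spectra_stage(cfg: dict, out: Path, seed: int) -> dict:
    sc = cfg["spectra"]
    bands = [BandParams(**b) for b in sc["bands"]]
    acq = AcquisitionParams(
        waiting_times=tuple(sc["waiting_times"]),
        noise_rms=sc["noise_rms"],
        seed=seed,
    )
    linear = make_linear_spectrum(
        bands, np.arange(1500.0, 1750.0, 1.0), noise_rms=sc["noise_rms"] * 0.1,
        seed=seed,
    )
    cio.write_linear_csv(linear, out / "linear_spectrum.csv")
    td = make_2d_timedomain(bands, acq)
    cio.write_timedomain(td, out / "timedomain")
    series = [spectra2d.build_spectrum(td, t2) for t2 in acq.waiting_times]

    fit = linear_ir.fit_bands(
        linear_ir.correct_background(linear), 2, [b.center for b in bands]
    )
    cls_res = cls_mod.cls_decay(
        series,
        fit_window=sc["cls_fit_window"],
        mask_fraction=sc["mask_fraction"],
        excitation_window=sc["cls_band_window"],
    )
    integrals = [ver.integrate_bleach(s) for s in series]
    kin = ver.fit_kinetics(np.asarray(acq.waiting_times), np.asarray(integrals))
    dmap = ver.decay_map(series, block=sc["decay_map_block"],
                         mask_fraction=sc["mask_fraction"])

    np.savetxt(
        out / "cls_vs_t2.csv",
        np.column_stack([cls_res.waiting_times, cls_res.cls_values]),
        delimiter=",", header="T2_ps,CLS", comments="",
    )
    np.savetxt(out / "decay_map.csv", dmap.tau, delimiter=",")
    return {
        "band_centers_fit": [c[0] for c in fit.components],
        "cls_zero": cls_res.cls_zero,
        "k_cls": cls_res.k_cls,
        "tau_ver_ps": kin.tau_ver,
        "v_heat_over_v_exc": kin.v_heat / kin.v_exc if kin.v_exc else None,
        "decay_map_cells": int(dmap.mask.sum()),
    }


def _run_trajectory_stage(cfg: dict, out: Path, seed: int) -> dict:
    tc = cfg["trajectory"]
    if tc.get("xyz_file"):
        traj = cio.read_extxyz(tc["xyz_file"])
    else:
        traj = make_trajectory(
            TrajectoryConfig(
                n_frames=tc["n_frames"],
                state_fractions=tc["state_fractions"],
                seed=seed,
            )
        )
        cio.write_extxyz(traj, out / "trajectory.xyz", out / "trajectory_truth.yaml")
    states, fractions = traj_analysis.categorize_frames(traj, tc["ca_cutoff"])
    g = traj_analysis.rdf(traj, "Ca", "O_coo1", dr=tc["rdf_dr"])
    hyd = traj_analysis.hydration_numbers(traj, states, cutoff=tc["hydration_cutoff"])
    cvd = traj_analysis.categorized_vdos(traj, states)

    np.savetxt(
        out / "rdf_ca_ocoo.csv", np.column_stack([g.r, g.g]),
        delimiter=",", header="r_A,g", comments="",
    )
    hyd.to_csv(out / "hydration_numbers.csv")
    for label, v in cvd.items():
        safe = label.replace("@", "_at_").replace("+", "_plus_")
        np.savetxt(
            out / f"vdos_{safe}.csv",
            np.column_stack([v.frequencies, v.density]),
            delimiter=",", header="wavenumber_cm-1,density", comments="",
        )
    return {
        "category_fractions": fractions,
        "rdf_first_peak_A": g.first_peak(),
        "hydration": hyd["mean_water_count"].to_dict(),
        "vdos_peaks_cm-1": {k: v.peak_frequency() for k, v in cvd.items()},
    }


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the configured stages; returns (and writes) the run manifest."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = validate_config(config)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    results: dict = {}
    if "spectra" in cfg["stages"]:
        results["spectra"] = _run_spectra_stage(cfg, out, seed)
    if "trajectory" in cfg["stages"]:
        results["trajectory"] = _run_trajectory_stage(cfg, out, seed)

    manifest = {"config": cfg, "seed": seed, "results": results}
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str)
    )
    return manifest
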