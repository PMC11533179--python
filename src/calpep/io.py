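"""Plain-text readers/writers for the package's data containers.

* Linear spectra: two-column CSV (wavenumber, absorbance) with ``#``
  comment header carrying JSON metadata.
* Time-domain 2D data: one CSV matrix (t1 x detection) per waiting time
  plus a JSON manifest listing axes and acquisition parameters.
* Trajectories: extended-XYZ with per-atom role and velocity columns and a
  Lattice/Time comment line, plus an optional YAML side-car with the
  ground-truth schedule.  (Written by hand: the installed MD readers do not
  round-trip per-atom velocities through XYZ.)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from calpep.synth_spectra import LinearSpectrum, TimeDomain2D
from calpep.synth_traj import Trajectory

__all__ = [
    "write_linear_csv",
    "read_linear_csv",
    "write_timedomain",
    "read_timedomain",
    "write_extxyz",
    "read_extxyz",
]


def write_linear_csv(spec: LinearSpectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# metadata: " + json.dumps(spec.metadata, default=str) + "\n")
        fh.write("# wavenumber_cm-1,absorbance_OD\n")
        for nu, a in zip(spec.wavenumbers, spec.absorbance):
            fh.write(f"{nu:.6f},{a:.10g}\n")


def read_linear_csv(path: str | Path) -> LinearSpectrum:
    path = Path(path)
    meta: dict = {}
    rows = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            if line.startswith("# metadata:"):
                meta = json.loads(line[len("# metadata:"):])
            continue
        if line.strip():
            nu, a = line.split(",")
            rows.append((float(nu), float(a)))
    arr = np.asarray(rows)
    return LinearSpectrum(arr[:, 0], arr[:, 1], meta)


def write_timedomain(td: TimeDomain2D, directory: str | Path) -> Path:
    """Write one CSV per waiting time plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, t2 in enumerate(td.waiting_times):
        name = f"timedomain_t2_{i:03d}.csv"
        np.savetxt(directory / name, td.signal[i], delimiter=",")
        files.append({"waiting_time_ps": float(t2), "file": name})
    manifest = {
        "format": "calpep-timedomain-v1",
        "t1_values_fs": td.t1_values.tolist(),
        "detection_axis_cm-1": td.detection_axis.tolist(),
        "rotating_frame_cm-1": td.rotating_frame,
        "waiting_times": files,
        "metadata": td.metadata,
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, default=str))
    return mpath


def read_timedomain(manifest_path: str | Path) -> TimeDomain2D:
    manifest_path = Path(manifest_path)
    man = json.loads(manifest_path.read_text())
    if man.get("format") != "calpep-timedomain-v1":
        raise ValueError(f"{manifest_path} is not a calpep time-domain manifest")
    base = manifest_path.parent
    t2s = [e["waiting_time_ps"] for e in man["waiting_times"]]
    signal = np.stack(
        [
            np.loadtxt(base / e["file"], delimiter=",")
            for e in man["waiting_times"]
        ]
    )
    return TimeDomain2D(
        np.asarray(man["t1_values_fs"]),
        np.asarray(man["detection_axis_cm-1"]),
        np.asarray(t2s),
        signal,
        man["rotating_frame_cm-1"],
        man.get("metadata", {}),
    )


def write_extxyz(
    traj: Trajectory, path: str | Path, sidecar: str | Path | None = None
) -> None:
    """Extended-XYZ with species, role, position and velocity columns."""
    path = Path(path)
    L = traj.box_edge
    props = "Properties=species:S:1:role:S:1:pos:R:3:vel:R:3"
    lattice = f'Lattice="{L} 0.0 0.0 0.0 {L} 0.0 0.0 0.0 {L}"'
    n_atoms = traj.positions.shape[1]
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n_atoms}\n")
            fh.write(f"{lattice} {props} Time={f * traj.dt:.4f} dt={traj.dt}\n")
            for i in range(n_atoms):
                x, y, z = traj.positions[f, i]
                vx, vy, vz = traj.velocities[f, i]
                fh.write(
                    f"{traj.elements[i]} {traj.roles[i]} "
                    f"{x:.6f} {y:.6f} {z:.6f} {vx:.8e} {vy:.8e} {vz:.8e}\n"
                )
    if sidecar is not None:
        Path(sidecar).write_text(
            yaml.safe_dump(traj.metadata, default_flow_style=False)
        )


def read_extxyz(path: str | Path, sidecar: str | Path | None = None) -> Trajectory:
    path = Path(path)
    lines = path.read_text().splitlines()
    frames_pos = []
    frames_vel = []
    roles: list = []
    elements: list = []
    box = None
    dt = None
    i = 0
    first = True
    while i < len(lines):
        n = int(lines[i].strip())
        header = lines[i + 1]
        if box is None:
            lat = header.split('Lattice="')[1].split('"')[0].split()
            box = float(lat[0])
        if dt is None and "dt=" in header:
            dt = float(header.split("dt=")[1].split()[0])
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if first:
                elements.append(parts[0])
                roles.append(parts[1])
            pos[k] = [float(v) for v in parts[2:5]]
            vel[k] = [float(v) for v in parts[5:8]]
        frames_pos.append(pos)
        frames_vel.append(vel)
        first = False
        i += 2 + n
    meta = {}
    if sidecar is not None and Path(sidecar).exists():
        meta = yaml.safe_load(Path(sidecar).read_text()) or {}
    return Trajectory(
        np.stack(frames_pos),
        np.stack(frames_vel),
        roles,
        elements,
        box,
        dt if dt is not None else 8.0,
        metadata=meta,
    )
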