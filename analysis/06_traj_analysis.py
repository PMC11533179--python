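#!/usr/bin/env python
"""MD analytics on the toy trajectory: RDFs, motifs, hydration, VDOS.

Reads the extended-XYZ trajectory written by 05_simulate_trajectory.py,
categorizes frames by Ca2+ occupancy of the carboxylate and amide sites,
computes the Ca-O and water-O RDFs, the hydration-number table and the
binding-state-resolved carboxylate CO VDOS, writing tables under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from calpep import categorize_frames, categorized_vdos, hydration_numbers, rdf
from calpep.io import read_extxyz

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)
xyz = ROOT / "scratch" / "trajectory.xyz"
if not xyz.exists():
    raise SystemExit("run analysis/05_simulate_trajectory.py first")

traj = read_extxyz(xyz, sidecar=ROOT / "scratch" / "trajectory_truth.yaml")

states, fractions = categorize_frames(traj, ca_cutoff=3.0)
print("binding-motif fractions (%):",
      {k: round(100 * v, 1) for k, v in fractions.items()})
pd.Series(fractions, name="fraction").to_csv(OUT / "motif_fractions.csv")

g_ca = rdf(traj, "Ca", "O_coo1", dr=0.05)
g_w = rdf(traj, "H_w", "O_coo1", dr=0.05)
print(f"Ca-O(carboxylate) RDF first maximum: {g_ca.first_peak():.2f} A")
np.savetxt(OUT / "rdf_ca_ocoo.csv", np.column_stack([g_ca.r, g_ca.g]),
           delimiter=",", header="r_A,g", comments="")

table = hydration_numbers(traj, states, cutoff=2.4)
print(table)
table.to_csv(OUT / "hydration_numbers.csv")

cvd = categorized_vdos(traj, states, bond=("C_coo", "O_coo1"))
peaks = {k: v.peak_frequency() for k, v in cvd.items()}
print("carboxylate CO VDOS peaks (cm^-1):",
      {k: round(v, 1) for k, v in peaks.items()})
pd.Series(peaks, name="peak_cm-1").to_csv(OUT / "vdos_peaks.csv")
print(f"wrote tables under {OUT}")
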