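#!/usr/bin/env python
"""Linear-IR band analysis: salt-free vs high-CaCl2 synthetic spectra.

Emulates the concentration series phenomenology: at high CaCl2 the
carboxylate band (1590 cm^-1) loses amplitude and a blueshifted shoulder
grows at 1620 cm^-1, while the amide I band (1660 cm^-1) redshifts by
7 cm^-1.  The script background-corrects, normalizes, forms the difference
spectrum and decomposes both spectra into Gaussian components, writing the
fitted centers to results/linear_band_fits.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from calpep import (
    BandParams,
    correct_background,
    difference_spectrum,
    fit_bands,
    make_linear_spectrum,
    normalize_integral,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

axis = np.arange(1500.0, 1750.0, 0.5)

salt_free = make_linear_spectrum(
    [
        BandParams(center=1590, sigma_inhom=12, sigma_hom=12, amplitude=1.0),
        BandParams(center=1660, sigma_inhom=11, sigma_hom=11, amplitude=0.8),
    ],
    axis, baseline_slope=4e-4, baseline_offset=-0.55, noise_rms=0.002, seed=1,
)
high_salt = make_linear_spectrum(
    [
        BandParams(center=1588, sigma_inhom=12, sigma_hom=12, amplitude=0.75),
        BandParams(center=1620, sigma_inhom=9, sigma_hom=9, amplitude=0.45),
        BandParams(center=1653, sigma_inhom=11, sigma_hom=11, amplitude=0.95),
    ],
    axis, baseline_slope=4e-4, baseline_offset=-0.55, noise_rms=0.002, seed=2,
)

rows = []
processed = {}
for label, spec, ncomp, guesses in (
    ("0M", salt_free, 2, [1590.0, 1660.0]),
    ("5M", high_salt, 3, [1588.0, 1620.0, 1653.0]),
):
    prepped = normalize_integral(correct_background(spec))
    processed[label] = prepped
    fit = fit_bands(prepped, ncomp, guesses)
    for center, sigma, area in fit.components:
        rows.append({"sample": label, "center_cm-1": center,
                     "sigma_cm-1": sigma, "area": area})
    print(f"{label}: centers", [f"{c:.1f}" for c in fit.centers],
          f"(residual rms {fit.residual_rms:.2e})")

diff = difference_spectrum(processed["5M"], processed["0M"])
np.savetxt(OUT / "difference_spectrum_5M_minus_0M.csv",
           np.column_stack([diff.wavenumbers, diff.absorbance]),
           delimiter=",", header="wavenumber_cm-1,delta_absorbance", comments="")
pd.DataFrame(rows).to_csv(OUT / "linear_band_fits.csv", index=False)

amide_shift = (
    [r for r in rows if r["sample"] == "0M"][-1]["center_cm-1"]
    - [r for r in rows if r["sample"] == "5M"][-1]["center_cm-1"]
)
print(f"recovered amide I redshift: {amide_shift:.2f} cm^-1 (generator: 7)")
print(f"wrote {OUT/'linear_band_fits.csv'}")
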