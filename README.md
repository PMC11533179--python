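# calpep

Analysis toolkit for deciphering Ca²⁺ binding to a zwitterionic dipeptide
(l-alanyl-l-alanine, "2Ala") from vibrational spectroscopy and molecular
trajectories. The dipeptide offers two competing Ca²⁺ sites — the C-terminal
carboxylate (asymmetric COO⁻ stretch, ≈1590 cm⁻¹) and the amide carbonyl
(amide I, ≈1660 cm⁻¹) — and the package implements the complete data-analysis
chain used to tell their binding motifs apart:

* **Linear IR**: linear background correction, normalization to the
  integrated absorbance, difference spectra and multi-Gaussian band
  decomposition (main carboxylate band, Ca²⁺-induced shoulder at 1620 cm⁻¹,
  amide I redshift).
* **2D-IR construction**: time-domain pump-pulse-pair data (t₁ = 0–2555 fs in
  35 fs steps, rotating frame at 1400 cm⁻¹) are Hamming-apodized, zero-padded
  to 128 points and Fourier transformed into excitation × detection spectra.
* **Center line slope (CLS)**: per-excitation-column bleach minima from
  Gaussian fits (10 % bleach mask), OLS slope as the CLS — 1 means perfectly
  correlated excitation/detection frequencies, 0 uncorrelated — and a
  monoexponential fit of CLS(T₂) giving the spectral-diffusion rate k_CLS.
* **Vibrational energy relaxation (VER)**: kinetic fits of the integrated
  bleach with an excited state decaying into a persistent heated ground
  state,

      V(T₂) = V_exc·exp(−T₂/τ_VER) + V_heat·(1 − exp(−T₂/τ_VER)),

  plus 5×5-pixel decay-time maps that localize species with different
  lifetimes.
* **Trajectory analytics**: minimum-image RDFs, per-frame categorization of
  Ca²⁺ occupancy at the carboxylate (0/1/2) and amide CO (0/1) sites,
  hydration numbers (water H within 2.4 Å of a CO oxygen) and binding-state
  resolved vibrational densities of states (VDOS) from CO bond velocities.

Because neither the instrument data nor the ab initio trajectories behind
the published values are deposited, the package ships first-class synthetic
generators (`calpep.synth_spectra`, `calpep.synth_traj`) with exactly known
ground truth, and validates every estimator by synthesis-and-recovery and
closed-form oracles.

## Worked example

```python
import numpy as np
from calpep import (BandParams, AcquisitionParams, make_2d_timedomain,
                    build_spectrum, cls_decay)

# carboxylate-like band: total width 18 cm^-1, CLS(0) = 0.5,
# spectral diffusion time 1 ps
band = BandParams(center=1590.0, sigma_inhom=12.73, sigma_hom=12.73,
                  tau_corr=1.0, tau_ver=0.46)
t2s = (0.0, 0.2, 0.4, 0.6, 0.8)
acq = AcquisitionParams(waiting_times=t2s, noise_rms=0.005, seed=1,
                        detection_axis=np.arange(1500.0, 1700.0, 2.0))
td = make_2d_timedomain([band], acq)
series = [build_spectrum(td, t) for t in t2s]
res = cls_decay(series, fit_window=1.0)
print(f"CLS(0) = {res.cls_zero:.3f}, k_CLS = {res.k_cls:.2f} 1/ps")
```

prints

```
CLS(0) = 0.468, k_CLS = 0.99 1/ps
```

CLS(0) sits slightly below the generator value 0.5 — apodization broadens
the excitation lineshape and uniformly shrinks the slope (see
`docs/methods.md`) — while the recovered decay rate matches the generator's
1/τ_corr = 1.0 ps⁻¹ within a few percent.

The numbered drivers under `analysis/` run the same chain as narrative
scripts (linear band fits → 2D construction → CLS → VER → trajectory
synthesis → trajectory analytics) and write tables under `results/`.
A configuration-driven end-to-end run is available from the shell:

```bash
calpep run --config configs/demo.yaml --out calpep_run
```

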