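# Methods

This note documents the models, estimators and numerical choices behind
`calpep`, and what the synthetic generators do and do not emulate.

## 2D-IR lineshape model

The generator (`calpep.synth_spectra`) represents each vibrational band at
waiting time T₂ as a bivariate Gaussian in the (excitation ω₁, detection ω₃)
plane with equal total widths σ = √(σ_inhom² + σ_hom²) on both axes and an
excitation–detection correlation

    ρ(T₂) = exp(−T₂/τ_corr) · σ_inhom²/(σ_inhom² + σ_hom²).

Four signed Gaussian terms build the response: a negative bleach at
(center, center), a positive excited-state absorption (ESA) shifted by the
anharmonicity Δ along detection (both carrying ρ(T₂) and decaying as
exp(−T₂/τ_VER)), and a heated-ground-state pair — same shapes, uncorrelated
(ρ = 0) — rising as V_heat·(1 − exp(−T₂/τ_VER)) and persisting. This is the
minimal model exhibiting the experimental phenomenology (diagonal
elongation, verticalization with T₂, signal decay into a persistent
thermal difference signal) while keeping closed forms: the analytic center
line slope is exactly ρ(T₂), and the integrated bleach follows the kinetic
model exactly. The heated-ground-state lineshape is a synthetic stand-in
(no published analytic form exists); it is flagged as such in the
generator metadata.

The excitation dimension is encoded as cosine amplitude modulation
relative to a rotating frame, as produced by pump-pulse pairs. For each
Gaussian term the conditional excitation distribution at fixed detection
frequency is Gaussian, so the cosine transform is analytic and generation
is exact (no numerical quadrature). Noise is additive white Gaussian in
the time domain, scaled to a fraction of the noise-free peak signal; the
experiments publish no noise model, so this is a pragmatic choice.

Defaults mirror the published acquisition: t₁ = 0–2555 fs in 35 fs steps
(Nyquist window ±476.5 cm⁻¹ around the 1400 cm⁻¹ rotating frame),
zero-padding to 128 points (excitation bin 7.45 cm⁻¹), Hamming
apodization. Band total widths of ≈18 cm⁻¹ (FWHM ≈ 42 cm⁻¹) are used in
fixtures, matching the displayed bandwidths of the carboxylate and amide I
bands.

## Spectrum construction

`build_spectrum` multiplies each t₁ trace by the *decaying half* of a
symmetric Hamming window (the data are one-sided; a full symmetric window
would suppress the t₁ = 0 point and grossly broaden the lineshape), halves
the t₁ = 0 sample (trapezoid weight of a one-sided cosine transform — with
full weight a flat spectral floor of ~2/N of the peak appears in every
excitation bin), zero-pads, FFTs, and keeps the real one-sided part so the
bleach stays negative. The window is normalized to unit mean to keep peak
amplitudes comparable across window choices. Since the cosine encoding
cannot distinguish frequencies above and below the rotating frame, only
the positive-offset side is reported; all bands of interest lie above
1400 cm⁻¹.

## Center line slope

For each excitation column whose T₂ = 0 bleach magnitude is at least 10 %
of the global T₂ = 0 bleach maximum (the two published phrasings of this
mask contradict each other; the "exceeding 10 %" reading is implemented,
the other is available via `mask_fraction`), the bleach minimum along
detection is located by a Gaussian fit to the contiguous negative lobe
around the column minimum, bounded by sign changes (the sign change to
the ESA naturally terminates the lobe). Ties for the deepest pixel break
toward the lower detection frequency. The CLS is the unweighted OLS slope
of these minima versus excitation frequency (bleach-depth weighting is
available by flag but the published analysis does not state any
weighting); CLS(0) is taken from the measured T₂ = 0 spectrum, never from
the decay fit. k_CLS comes from a monoexponential least-squares fit over
T₂ ≤ fit window (0.8 ps for the carboxylate, 1 ps for amide I in the
experimental protocol).

**Known bias.** Apodization convolves the excitation lineshape with the
window transform; for Gaussian bands the measured slope becomes
ρ/(1 + σ_win²/σ²) with σ_win ≈ 4.5 cm⁻¹ for the default acquisition. At
σ = 18 cm⁻¹ this is a ~6 % relative shrinkage — inherent to the
measurement, not corrected for. The shrink factor is identical for bands
of equal total width, so CLS *ratios* between regimes (the published
contrast between 0 M and 5 M CaCl₂ is ~3.5×) are unbiased; this is
verified against the closed-form oracle in the test suite. Estimator
fidelity proper (center-line extraction + OLS) is tested on exact
bivariate-Gaussian spectra, where it matches ρ to < 10⁻³.

## Relaxation kinetics and decay maps

The kinetic model is V(T₂) = V_exc·exp(−T₂/τ_VER) + V_heat·(1 −
exp(−T₂/τ_VER)): a single shared rate feeding a persistent heated ground
state (an independent heat-rise time is out of scope). Bleach integrals
are sign-gated (only negative pixels contribute), which excludes the ESA
without hand-drawn rectangles; rectangle bounds remain configurable.
Constant signals (the V_exc = V_heat limit) make τ unidentifiable and are
returned flagged `degenerate`, never as a silent number.

Decay maps integrate the sign-gated signal of 5×5-pixel blocks (grid
anchored at the spectrum corner; truncated edge blocks are kept and
flagged) and fit the same model per block with per-block V_heat (a
global-V_heat mode is available). Blocks below the 10 % T₂ = 0 bleach
mask, failed fits and degenerate fits are masked. When spectral diffusion
and relaxation time scales are comparable, block decay times mix both —
the same caveat the experimental analysis carries — so homogeneity tests
use statically inhomogeneous fixtures (τ_corr → ∞), for which every block
must and does recover the global lifetime.

## Linear-IR processing

Background correction subtracts the straight line through the mean
absorbance of two anchor windows (default: lowest/highest 20 cm⁻¹ of the
axis; the published anchors are unstated, so the choice is echoed into the
output metadata). Anchors overlapping spectral features are flagged with a
warning, not rejected. Normalization rescales to unit trapezoidal integral
over a window defaulting to the full axis. The order is fixed: background
first. Band fits are sums of Gaussians (the generator's profile; the
published profile is unstated) via Levenberg–Marquardt with area
parameters seeded from local peak heights; near-singular covariance
(condition number > 10⁸, e.g. duplicate components) flags the fit
degenerate.

## Toy trajectories

Generation is kinematic: every motion is prescribed, so ground truth is
exact — the artifact tests analysis code, not physics. The box defaults to
the simulated composition (60 waters, 6 CaCl₂, one solute, 13.3 Å cubic
box, frames every 8 fs). The solute carries the labelled sites
(carboxylate C/O₁/O₂, amide C/O/N/H). Binding states are assigned in
contiguous blocks realizing the requested fractions exactly (a shuffled
mode exists for robustness tests); bound Ca²⁺ sit at the 2.4 Å contact
distance along the site bond direction with 0.05 Å radial Gaussian
jitter; background particles get clipped per-frame jitter (σ = 0.3 Å)
with exclusion margins that keep them outside all binding and hydration
cutoffs. Hydration waters are dedicated molecules whose inner hydrogen
sits at 2.0 Å (inside the 2.4 Å criterion) when "present"; fractional
occupancies are realized by deterministic frame patterns, so recovered
means equal the configured table to within 1/n_frames. CO bonds oscillate
harmonically with binding-state-dependent frequencies (defaults: 1590 →
1610 → 1630 cm⁻¹ for 0/1/2 Ca²⁺ at the carboxylate, emulating the
blueshift ladder; amide 1660 → 1653 cm⁻¹ on contact) and phase continuity
across state changes. What the generator does **not** emulate: forces,
thermostats, realistic water structure beyond uniform placement,
anion–NH correlations, or exchange dynamics within a frame block —
passing tests therefore validate the estimators' bookkeeping and
resolution, not their behavior on rough ab initio data.

## Trajectory estimators

All distances use the minimum-image convention in a cubic box (no
triclinic support), validated against an all-images brute-force oracle.
RDFs normalize pair-distance histograms with exact shell volumes
4π/3·(r₊³ − r₋³) and the ideal-gas reference density, making the number
integral an exact bookkeeping identity. The Ca–O "bound" cutoff defaults
to 3.0 Å — beyond the 2.4 Å first-shell peak, before the second feature —
and is configurable (the published criterion is deferred to supporting
material not included here). Cutoffs are closed (≤): the hydration
criterion is printed both as "< 2.4 Å" and "≤ 2.4 Å" in the source
material; the difference is measure-zero.

The VDOS projects the relative velocity of a bonded pair on the
instantaneous bond axis (a full-vector mode is behind a flag) and
estimates its spectral density on the Blackman–Tukey route: biased
autocovariance to lag M (default half the segment length) with a Bartlett
lag window. The Bartlett choice is deliberate: its Fejér smoothing kernel
is non-negative, so the density cannot go negative, and the discrete
frequency integral equals the series variance exactly (Parseval), both of
which are tested. Binding-state-resolved VDOS are computed over the
contiguous frame blocks of each category; categories shorter than 64
frames are excluded as too short for a stable estimate (resolution
coarser than ~65 cm⁻¹ at 8 fs sampling).

## Validation protocol and problem sizes

Published values serve as generator ground truth: lifetimes
0.46/0.67/0.76/0.88 ps are re-fit from 50 noisy synthetic decays each
(T₂ = 0–4 ps, step 0.1 ps, 1 % noise, V_heat/V_exc = 0.3); the CLS(0)
contrast uses regimes at CLS(0) = 0.2 and 0.7 — the published value is the
*ratio* (~3.5×), the absolute levels are the package's choice of a
plausible pair — averaged over 20 seeds; the band decomposition recovers
1590/1620/1660 cm⁻¹ centers and a 7 cm⁻¹ shift; trajectory analytics run
on 1000–2000-frame toys. These sizes keep the full validation suite and
the recovery script in the seconds-to-minutes range on a single CPU while
leaving Monte-Carlo standard errors well inside the stated tolerances.

## Known limitations

* No optical-Bloch/response-function propagation, finite pulse durations,
  polarization dependence, phase cycling, or cross-peak synthesis; the
  pump-pulse-pair geometry yields absorptive spectra directly, which is
  what is implemented.
* Single-exponential spectral diffusion and relaxation only; no
  frequency-fluctuation correlation functions beyond the monoexponential,
  no rate-matrix energy transfer.
* CLS values (not ratios) carry the apodization shrinkage described
  above.
* The five binding categories assume at most two Ca²⁺ at the carboxylate
  and one at the amide CO; a Ca²⁺ within the cutoff of both carboxylate
  oxygens counts once (the generator never produces bidentate
  coordination, matching the simulations' finding).
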