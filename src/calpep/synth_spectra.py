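"""Synthetic linear-IR spectra and time-domain 2D-IR data with known ground truth.

The 2D lineshape model is a bivariate Gaussian per band: a negative bleach
centered at (excitation, detection) = (center, center) whose
excitation-detection correlation decays exponentially with waiting time,

    rho(T2) = exp(-T2 / tau_corr) * sigma_inhom^2 / (sigma_inhom^2 + sigma_hom^2),

plus a positive excited-state-absorption (ESA) replica shifted along the
detection axis by the anharmonicity.  With equal total widths on both axes
the analytic center-line slope is exactly rho(T2), which makes the whole CLS
pipeline testable against a closed form.  Signal amplitude follows
single-lifetime relaxation into a persistent heated ground state,

    V(T2) = V_exc * exp(-T2/tau_ver) + V_heat * (1 - exp(-T2/tau_ver)),

the heated contribution being an uncorrelated, waiting-time-independent
bleach/positive pair at the band center.  The excitation dimension is
encoded in the time domain as a cosine modulation relative to a rotating
frame, as produced by pump-pulse-pair amplitude modulation; the cosine
transform of each Gaussian term is analytic, so generation is exact and
fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from calpep.constants import C_CM_PER_FS, nyquist_wavenumber

__all__ = [
    "BandParams",
    "AcquisitionParams",
    "LinearSpectrum",
    "TimeDomain2D",
    "make_linear_spectrum",
    "make_2d_timedomain",
    "make_gaussian_spectrum2d",
]


@dataclass(frozen=True)
class BandParams:
    """Ground-truth parameters of one vibrational band.

    Parameters
    ----------
    center : float
        Band center in cm^-1 (e.g. ~1590 for the asymmetric carboxylate
        stretch, ~1660 for amide I).
    sigma_inhom : float
        Inhomogeneous (static-at-T2=0) width in cm^-1, >= 0.
    sigma_hom : float
        Homogeneous width in cm^-1, > 0.
    amplitude : float
        Dimensionless band amplitude, > 0.
    anharmonic_shift : float
        Red shift of the excited-state absorption along detection, cm^-1, > 0.
    tau_corr : float
        Frequency-correlation (spectral diffusion) decay time, ps, > 0.
    tau_ver : float
        Vibrational population lifetime, ps, > 0.
    heat_fraction : float
        V_heat / V_exc of the persistent heated-ground-state signal, >= 0.
    """

    center: float
    sigma_inhom: float
    sigma_hom: float
    amplitude: float = 1.0
    anharmonic_shift: float = 25.0
    tau_corr: float = 1.0
    tau_ver: float = 0.5
    heat_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_inhom < 0:
            raise ValueError(f"sigma_inhom must be >= 0, got {self.sigma_inhom}")
        if self.sigma_hom <= 0:
            raise ValueError(f"sigma_hom must be > 0, got {self.sigma_hom}")
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if self.anharmonic_shift <= 0:
            raise ValueError(
                f"anharmonic_shift must be > 0, got {self.anharmonic_shift}"
            )
        if self.tau_corr <= 0:
            raise ValueError(f"tau_corr must be > 0, got {self.tau_corr}")
        if self.tau_ver <= 0:
            raise ValueError(f"tau_ver must be > 0, got {self.tau_ver}")
        if self.heat_fraction < 0:
            raise ValueError(f"heat_fraction must be >= 0, got {self.heat_fraction}")

    @property
    def sigma_total(self) -> float:
        """Total Gaussian width sqrt(sigma_inhom^2 + sigma_hom^2)."""
        return float(np.hypot(self.sigma_inhom, self.sigma_hom))

    @property
    def cls0(self) -> float:
        """Analytic center-line slope at T2 = 0."""
        return self.sigma_inhom**2 / (self.sigma_inhom**2 + self.sigma_hom**2)

    def correlation(self, t2_ps: float) -> float:
        """Excitation-detection correlation rho(T2); the analytic CLS."""
        return self.cls0 * float(np.exp(-t2_ps / self.tau_corr))


@dataclass(frozen=True)
class AcquisitionParams:
    """Time-domain acquisition settings of the 2D-IR measurement."""

    t1_step: float = 35.0  # fs
    t1_max: float = 2555.0  # fs
    rotating_frame: float = 1400.0  # cm^-1
    n_zero_pad: int = 128
    detection_axis: np.ndarray = field(
        default_factory=lambda: np.arange(1520.0, 1740.0, 2.0)
    )
    waiting_times: tuple = (0.0,)  # ps
    noise_rms: float = 0.0  # fraction of the T2=0 peak signal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t1_step <= 0:
            raise ValueError("t1_step must be > 0")
        if self.t1_max < self.t1_step:
            raise ValueError("t1_max must be >= t1_step")
        det = np.asarray(self.detection_axis, dtype=float)
        if det.ndim != 1 or det.size < 2 or np.any(np.diff(det) <= 0):
            raise ValueError("detection_axis must be strictly increasing")
        object.__setattr__(self, "detection_axis", det)
        if self.n_zero_pad < self.n_t1:
            raise ValueError(
                f"n_zero_pad ({self.n_zero_pad}) must cover the "
                f"{self.n_t1} recorded t1 points"
            )
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")

    @property
    def t1_values(self) -> np.ndarray:
        return np.arange(0.0, self.t1_max + 0.5 * self.t1_step, self.t1_step)

    @property
    def n_t1(self) -> int:
        return int(self.t1_values.size)


@dataclass
class LinearSpectrum:
    """A linear IR spectrum: wavenumber axis, absorbance, provenance metadata."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.shape != self.absorbance.shape:
            raise ValueError("wavenumbers and absorbance must have equal length")
        d = np.diff(self.wavenumbers)
        if self.wavenumbers.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotonic")


@dataclass
class TimeDomain2D:
    """Raw pump-delay-resolved probe modulation, one matrix per waiting time.

    ``signal`` is indexed (waiting time, t1, detection wavenumber).
    """

    t1_values: np.ndarray
    detection_axis: np.ndarray
    waiting_times: np.ndarray
    signal: np.ndarray
    rotating_frame: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t1_values = np.asarray(self.t1_values, dtype=float)
        self.detection_axis = np.asarray(self.detection_axis, dtype=float)
        self.waiting_times = np.asarray(self.waiting_times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        expected = (
            self.waiting_times.size,
            self.t1_values.size,
            self.detection_axis.size,
        )
        if self.signal.shape != expected:
            raise ValueError(
                f"signal shape {self.signal.shape} does not match axes {expected}"
            )
        steps = np.diff(self.t1_values)
        if steps.size and not np.allclose(steps, steps[0]):
            raise ValueError("t1 grid must be uniform")

    @property
    def t1_step(self) -> float:
        return float(self.t1_values[1] - self.t1_values[0])


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def make_linear_spectrum(
    bands: Sequence[BandParams],
    axis: np.ndarray,
    baseline_slope: float = 0.0,
    baseline_offset: float = 0.0,
    noise_rms: float = 0.0,
    seed: int = 0,
) -> LinearSpectrum:
    """Sum-of-Gaussians linear spectrum plus linear baseline and white noise.

    Each band contributes ``amplitude * exp(-(nu-center)^2 / (2 sigma_total^2))``
    where ``sigma_total = sqrt(sigma_inhom^2 + sigma_hom^2)``.  Ground-truth
    parameters are recorded in the metadata.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2 or np.any(np.diff(axis) <= 0):
        raise ValueError("axis must be a strictly increasing 1-D grid")
    if noise_rms < 0:
        raise ValueError("noise_rms must be >= 0")
    for b in bands:
        if not (axis[0] <= b.center <= axis[-1]):
            raise ValueError(
                f"band center {b.center} cm^-1 lies outside the axis "
                f"[{axis[0]}, {axis[-1]}] cm^-1"
            )
    absorbance = baseline_offset + baseline_slope * axis
    for b in bands:
        absorbance = absorbance + b.amplitude * _gauss(axis, b.center, b.sigma_total)
    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_rms, axis.size)
    meta = {
        "generator": "make_linear_spectrum",
        "bands": [
            {
                "center": b.center,
                "sigma_total": b.sigma_total,
                "amplitude": b.amplitude,
            }
            for b in bands
        ],
        "baseline_slope": baseline_slope,
        "baseline_offset": baseline_offset,
        "noise_rms": noise_rms,
        "seed": seed,
    }
    return LinearSpectrum(axis, absorbance, meta)


def _band_terms(band: BandParams, t2_ps: float):
    """Gaussian terms (weight, detection center, rho) of one band at one T2.

    Bleach and ESA decay with tau_ver and carry the decaying correlation; the
    heated-ground-state pair rises as (1 - exp(-T2/tau_ver)), is uncorrelated
    and persists. Weights are signed: bleach negative, ESA positive.
    """
    e = float(np.exp(-t2_ps / band.tau_ver))
    h = band.heat_fraction * (1.0 - e)
    rho = band.correlation(t2_ps)
    a = band.amplitude
    terms = [
        (-a * e, band.center, rho),
        (+a * e, band.center - band.anharmonic_shift, rho),
    ]
    if h > 0:
        terms.append((-a * h, band.center, 0.0))
        terms.append((+a * h, band.center - band.anharmonic_shift, 0.0))
    return terms


def make_2d_timedomain(
    bands: Sequence[BandParams], acq: AcquisitionParams
) -> TimeDomain2D:
    """Generate time-domain 2D-IR data for the bivariate-Gaussian band model.

    For each Gaussian term with detection center ``c3``, excitation center
    ``c1`` and correlation ``rho`` (equal total widths ``s`` on both axes),
    the conditional excitation distribution at fixed detection ``w3`` is
    Gaussian with mean ``mu1 = c1 + rho (w3 - c3)`` and width
    ``s sqrt(1-rho^2)``; its cosine transform relative to the rotating frame
    is analytic::

        S(t1, w3) = w G(w3; c3, s) exp(-(a s1)^2/2) cos(a (mu1 - f0)),
        a = 2 pi c t1.

    Additive white Gaussian noise is scaled to ``noise_rms`` times the peak
    absolute noise-free signal at the first waiting time.
    """
    bands = list(bands)
    if not bands:
        raise ValueError("at least one band is required")
    nyq = nyquist_wavenumber(acq.t1_step)
    det = acq.detection_axis
    for b in bands:
        if abs(b.center - acq.rotating_frame) >= nyq:
            raise ValueError(
                f"band at {b.center} cm^-1 is outside the Nyquist window "
                f"{acq.rotating_frame} +/- {nyq:.1f} cm^-1 at t1_step="
                f"{acq.t1_step} fs"
            )
        if not (det[0] <= b.center <= det[-1]):
            raise ValueError(
                f"band at {b.center} cm^-1 is outside the detection window "
                f"[{det[0]}, {det[-1]}] cm^-1"
            )

    t1 = acq.t1_values
    t2s = np.asarray(acq.waiting_times, dtype=float)
    a_phase = 2.0 * np.pi * C_CM_PER_FS * t1  # rad per cm^-1, per t1 point

    signal = np.zeros((t2s.size, t1.size, det.size))
    for i, t2 in enumerate(t2s):
        for band in bands:
            s = band.sigma_total
            for w, c3, rho in _band_terms(band, t2):
                mu1 = band.center + rho * (det - c3)
                s1 = s * np.sqrt(1.0 - rho**2)
                det_profile = w * _gauss(det, c3, s)
                envelope = np.exp(-0.5 * (a_phase[:, None] * s1) ** 2)
                carrier = np.cos(a_phase[:, None] * (mu1 - acq.rotating_frame)[None, :])
                signal[i] += det_profile[None, :] * envelope * carrier

    if acq.noise_rms > 0:
        rng = np.random.default_rng(acq.seed)
        scale = acq.noise_rms * np.max(np.abs(signal[0]))
        signal = signal + rng.normal(0.0, scale, signal.shape)

    meta = {
        "generator": "make_2d_timedomain",
        "bands": [
            {
                "center": b.center,
                "sigma_inhom": b.sigma_inhom,
                "sigma_hom": b.sigma_hom,
                "amplitude": b.amplitude,
                "anharmonic_shift": b.anharmonic_shift,
                "tau_corr": b.tau_corr,
                "tau_ver": b.tau_ver,
                "heat_fraction": b.heat_fraction,
                "cls0": b.cls0,
            }
            for b in bands
        ],
        "noise_rms": acq.noise_rms,
        "seed": acq.seed,
        "n_zero_pad": acq.n_zero_pad,
        "heated_ground_state_shape": (
            "synthetic stand-in: uncorrelated, T2-independent bleach/positive "
            "pair at the band center"
        ),
    }
    return TimeDomain2D(t1, det, t2s, signal, acq.rotating_frame, meta)


def make_gaussian_spectrum2d(
    band: BandParams,
    excitation_axis: np.ndarray,
    detection_axis: np.ndarray,
    t2_ps: float = 0.0,
    include_esa: bool = True,
):
    """Exact bivariate-Gaussian 2D spectrum (no time-domain step).

    Oracle-side generator: the frequency-domain lineshape is written down
    directly, so the analytic center-line slope rho(T2) holds to machine
    precision.  Returns a :class:`calpep.spectra2d.Spectrum2D`.
    """
    from calpep.spectra2d import Spectrum2D

    w1 = np.asarray(excitation_axis, dtype=float)
    w3 = np.asarray(detection_axis, dtype=float)
    s = band.sigma_total
    signal = np.zeros((w1.size, w3.size))
    for w, c3, rho in _band_terms(band, t2_ps):
        if w > 0 and not include_esa:
            continue
        z1 = (w1[:, None] - band.center) / s
        z3 = (w3[None, :] - c3) / s
        q = (z1**2 - 2.0 * rho * z1 * z3 + z3**2) / (1.0 - rho**2)
        signal += w * np.exp(-0.5 * q)
    return Spectrum2D(w1, w3, float(t2_ps), signal)
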