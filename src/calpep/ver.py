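"""Vibrational-energy-relaxation (VER) kinetics and decay-time maps.

The kinetic model is a vibrationally excited state of peak integral V_exc
decaying with lifetime tau_VER into a persistent heated ground state of
peak integral V_heat:

    V(T2) = V_exc * exp(-T2 / tau_VER) + V_heat * (1 - exp(-T2 / tau_VER)).

Integrated bleach signals are fit with this model band-by-band; decay-time
maps repeat the fit on 5x5-pixel blocks of the 2D spectra, masking blocks
whose T2=0 bleach is below 10% of the global maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from calpep.spectra2d import Spectrum2D

__all__ = ["KineticFit", "DecayMap", "integrate_bleach", "fit_kinetics", "decay_map"]


@dataclass
class KineticFit:
    tau_ver: float
    v_exc: float
    v_heat: float
    residual_rms: float
    converged: bool
    degenerate: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and not self.degenerate and self.tau_ver <= 0:
            raise ValueError("converged fit must have tau_ver > 0")


@dataclass
class DecayMap:
    """Per-block decay times over the 2D spectral plane.

    ``tau`` is (n_blocks_excitation, n_blocks_detection); masked cells are
    NaN with ``mask`` False.
    """

    tau: np.ndarray
    mask: np.ndarray
    block: int
    excitation_edges: np.ndarray
    detection_edges: np.ndarray
    threshold: float
    n_fit_failures: int = 0
    edge_blocks_truncated: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.block < 1:
            raise ValueError("block size must be >= 1")
        if np.any(np.isfinite(self.tau[~self.mask])):
            raise ValueError("masked-out cells must carry no decay time")


def integrate_bleach(spec: Spectrum2D, region: Sequence[float] | None = None) -> float:
    """Integral of the negative (bleach) signal over a spectral rectangle.

    ``region`` is (excitation_lo, excitation_hi, detection_lo, detection_hi);
    by default the whole spectrum.  Positive ESA signal is excluded by sign
    gating.  Returns a negative number (or 0 for an all-positive region),
    in signal units times cm^-2.
    """
    w1, w3 = spec.excitation_axis, spec.detection_axis
    if region is None:
        region = (w1[0], w1[-1], w3[0], w3[-1])
    e_lo, e_hi, d_lo, d_hi = region
    m1 = (w1 >= e_lo) & (w1 <= e_hi)
    m3 = (w3 >= d_lo) & (w3 <= d_hi)
    if not (np.any(m1) and np.any(m3)):
        raise ValueError(f"region {region} does not overlap the spectrum")
    sub = spec.signal[np.ix_(m1, m3)]
    d1 = np.median(np.diff(w1)) if w1.size > 1 else 1.0
    d3 = np.median(np.diff(w3)) if w3.size > 1 else 1.0
    return float(np.sum(np.where(sub < 0, sub, 0.0)) * d1 * d3)


def _model(t2, v_exc, v_heat, tau):
    e = np.exp(-t2 / tau)
    return v_exc * e + v_heat * (1.0 - e)


def fit_kinetics(waiting_times: np.ndarray, integrals: np.ndarray) -> KineticFit:
    """Least-squares fit of the excited-state/heated-ground-state model.

    Accepts integrals of either sign (bleach integrals are negative); the
    fit runs on magnitudes.  A constant series (V_exc == V_heat limit) makes
    tau unidentifiable and is returned flagged degenerate, not as an error.
    """
    t2 = np.asarray(waiting_times, dtype=float)
    v = np.abs(np.asarray(integrals, dtype=float))
    if t2.size < 4:
        raise ValueError("need >= 4 waiting times")
    if t2.size != v.size:
        raise ValueError("waiting_times and integrals must have equal length")
    order = np.argsort(t2)
    t2, v = t2[order], v[order]
    span = t2[-1] - t2[0]
    if span <= 0:
        raise ValueError("waiting times must span a nonzero interval")

    scale = max(v.max(), 1e-30)
    if (v.max() - v.min()) < 1e-6 * scale:
        return KineticFit(
            tau_ver=np.nan,
            v_exc=float(v[0]),
            v_heat=float(v[0]),
            residual_rms=0.0,
            converged=True,
            degenerate=True,
            message="constant signal: tau unidentifiable (V_exc == V_heat)",
        )

    v0, vinf = v[0], v[-1]
    tau0 = span / 3.0
    mid = v0 + (vinf - v0) * (1 - np.e**-1)
    crossing = np.argmin(np.abs(v - mid))
    if 0 < crossing < t2.size and t2[crossing] > 0:
        tau0 = max(float(t2[crossing]), span / 50.0)
    p0 = [max(v0, 1e-12), max(vinf, 0.0), tau0]
    try:
        popt, pcov = curve_fit(
            _model,
            t2,
            v,
            p0=p0,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 100.0 * span]),
            maxfev=10000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"kinetic fit did not converge (initial guess {p0}): {err}"
        )
    resid = v - _model(t2, *popt)
    tau_err = np.sqrt(pcov[2, 2]) if np.all(np.isfinite(pcov)) else np.inf
    degenerate = not np.isfinite(tau_err) or tau_err > 10.0 * popt[2]
    return KineticFit(
        tau_ver=float(popt[2]),
        v_exc=float(popt[0]),
        v_heat=float(popt[1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=True,
        degenerate=degenerate,
    )


def decay_map(
    series: Sequence[Spectrum2D],
    block: int = 5,
    mask_fraction: float = 0.10,
) -> DecayMap:
    """Per-block decay times: integrate each block at every T2 and fit kinetics.

    Block integrals are sign-gated to the bleach (negative) signal, the same
    ESA exclusion used by :func:`integrate_bleach`, so a block covering the
    whole spectrum reproduces the global kinetic fit.  The block grid is
    anchored at the spectrum corner; edge blocks smaller than ``block``
    pixels are kept and flagged.  Blocks whose T2=0 bleach magnitude is at
    most ``mask_fraction`` of the global T2=0 maximum are masked, as are
    blocks whose fit fails or is degenerate.
    """
    if block < 1:
        raise ValueError("block size must be >= 1")
    series = sorted(series, key=lambda s: s.waiting_time)
    ref = series[0]
    for s in series[1:]:
        if not (
            np.allclose(s.excitation_axis, ref.excitation_axis)
            and np.allclose(s.detection_axis, ref.detection_axis)
        ):
            raise ValueError("all spectra in the series must share axes")
    t2s = np.array([s.waiting_time for s in series])
    n1, n3 = ref.signal.shape
    nb1 = int(np.ceil(n1 / block))
    nb3 = int(np.ceil(n3 / block))
    truncated = (n1 % block != 0) or (n3 % block != 0)

    bleach_ref = np.where(ref.signal < 0, -ref.signal, 0.0)
    global_max = bleach_ref.max()
    if global_max <= 0:
        raise ValueError("T2=0 spectrum contains no bleach")

    tau = np.full((nb1, nb3), np.nan)
    mask = np.zeros((nb1, nb3), dtype=bool)
    n_failures = 0
    stack = np.stack([s.signal for s in series])  # (T2, exc, det)
    for bi in range(nb1):
        sl1 = slice(bi * block, min((bi + 1) * block, n1))
        for bj in range(nb3):
            sl3 = slice(bj * block, min((bj + 1) * block, n3))
            if bleach_ref[sl1, sl3].max() <= mask_fraction * global_max:
                continue
            sub = stack[:, sl1, sl3]
            integrals = np.where(sub < 0, sub, 0.0).sum(axis=(1, 2))
            try:
                fit = fit_kinetics(t2s, integrals)
            except (RuntimeError, ValueError):
                n_failures += 1
                continue
            if fit.degenerate:
                n_failures += 1
                continue
            tau[bi, bj] = fit.tau_ver
            mask[bi, bj] = True
    if not mask.any():
        raise ValueError("every block is masked; no decay map can be built")

    e_edges = ref.excitation_axis[0] + np.arange(nb1 + 1) * block * np.median(
        np.diff(ref.excitation_axis)
    )
    d_edges = ref.detection_axis[0] + np.arange(nb3 + 1) * block * np.median(
        np.diff(ref.detection_axis)
    )
    return DecayMap(
        tau=tau,
        mask=mask,
        block=block,
        excitation_edges=e_edges,
        detection_edges=d_edges,
        threshold=mask_fraction,
        n_fit_failures=n_failures,
        edge_blocks_truncated=truncated,
    )
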