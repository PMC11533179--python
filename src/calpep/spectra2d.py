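"""Construction of 2D IR spectra from time-domain data.

Per detection wavenumber the recorded t1 trace is apodized with a Hamming
window (length = number of recorded points, normalized to unit mean),
zero-padded, discrete-Fourier-transformed, and the real one-sided part is
mapped onto an excitation axis offset from the rotating frame.  The cosine
encoding of the excitation frequency keeps the bleach negative after
transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from calpep.constants import C_CM_PER_FS, fft_bin_wavenumber
from calpep.synth_spectra import LinearSpectrum, TimeDomain2D

__all__ = ["Spectrum2D", "build_spectrum", "diagonal_cut"]


@dataclass
class Spectrum2D:
    """Excitation x detection 2D-IR spectrum at one waiting time.

    ``signal`` is indexed (excitation, detection); bleach is negative,
    excited-state absorption positive.
    """

    excitation_axis: np.ndarray
    detection_axis: np.ndarray
    waiting_time: float
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.excitation_axis = np.asarray(self.excitation_axis, dtype=float)
        self.detection_axis = np.asarray(self.detection_axis, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.excitation_axis) <= 0):
            raise ValueError("excitation axis must be strictly increasing")
        expected = (self.excitation_axis.size, self.detection_axis.size)
        if self.signal.shape != expected:
            raise ValueError(
                f"signal shape {self.signal.shape} does not match axes {expected}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite everywhere")


def build_spectrum(td: TimeDomain2D, waiting_time: float) -> Spectrum2D:
    """Fourier-construct the 2D spectrum at one waiting time.

    The excitation axis is ``rotating_frame + k / (n_zero_pad * t1_step * c)``
    for one-sided FFT bins k; its resolution is therefore
    ``1/(n_zero_pad * t1_step * c)`` (7.45 cm^-1 at 35 fs / 128 points).

    Raises
    ------
    KeyError
        If ``waiting_time`` is not present in the time-domain record.
    ValueError
        If fewer than 4 t1 points were recorded.
    """
    idx = np.flatnonzero(np.isclose(td.waiting_times, waiting_time))
    if idx.size == 0:
        raise KeyError(
            f"waiting time {waiting_time} ps not in {td.waiting_times.tolist()}"
        )
    n_rec = td.t1_values.size
    if n_rec < 4:
        raise ValueError(f"need at least 4 t1 points, got {n_rec}")
    n_pad = td.metadata.get("n_zero_pad", max(128, n_rec))
    if n_pad < n_rec:
        n_pad = n_rec

    # decaying half of the symmetric Hamming window: the t1 data are
    # one-sided, so apodization must be maximal at t1 = 0
    window = np.hamming(2 * n_rec - 1)[n_rec - 1 :]
    window = window / window.mean()  # unit mean: peak amplitudes comparable

    traces = td.signal[idx[0]].copy()  # (t1, detection)
    traces[0] *= 0.5  # trapezoid weight: one-sided data start at t1 = 0
    padded = np.zeros((n_pad, traces.shape[1]))
    padded[:n_rec] = traces * window[:, None]
    # real part of the one-sided DFT: cosine-transform convention, signs kept
    spec = np.real(np.fft.rfft(padded, axis=0)) * (2.0 / n_rec)

    dnu = fft_bin_wavenumber(n_pad, td.t1_step)
    excitation = td.rotating_frame + dnu * np.arange(spec.shape[0])
    meta = {
        "waiting_time": float(td.waiting_times[idx[0]]),
        "n_recorded": n_rec,
        "n_zero_pad": int(n_pad),
        "window": "hamming (unit mean)",
        "excitation_resolution": dnu,
        "rotating_frame_convention": (
            "cosine-encoded data; only the positive-offset side of the "
            "rotating frame is reported"
        ),
    }
    return Spectrum2D(
        excitation, td.detection_axis, float(td.waiting_times[idx[0]]), spec, meta
    )


def diagonal_cut(spec: Spectrum2D) -> LinearSpectrum:
    """Signal interpolated along the diagonal (excitation == detection).

    On single-band synthetic data the squared diagonal cut matches the
    squared linear spectrum shape.
    """
    lo = max(spec.excitation_axis[0], spec.detection_axis[0])
    hi = min(spec.excitation_axis[-1], spec.detection_axis[-1])
    if hi <= lo:
        raise ValueError(
            f"excitation [{spec.excitation_axis[0]}, {spec.excitation_axis[-1]}] and "
            f"detection [{spec.detection_axis[0]}, {spec.detection_axis[-1]}] axes "
            "do not overlap"
        )
    mask = (spec.detection_axis >= lo) & (spec.detection_axis <= hi)
    nus = spec.detection_axis[mask]
    values = np.empty(nus.size)
    for i, nu in enumerate(nus):
        col = np.interp(nu, spec.detection_axis, np.arange(spec.detection_axis.size))
        j0 = int(np.floor(col))
        j1 = min(j0 + 1, spec.detection_axis.size - 1)
        frac = col - j0
        row = np.interp(nu, spec.excitation_axis, np.arange(spec.excitation_axis.size))
        i0 = int(np.floor(row))
        i1 = min(i0 + 1, spec.excitation_axis.size - 1)
        rfrac = row - i0
        # bilinear interpolation at (nu, nu)
        values[i] = (
            (1 - rfrac) * ((1 - frac) * spec.signal[i0, j0] + frac * spec.signal[i0, j1])
            + rfrac * ((1 - frac) * spec.signal[i1, j0] + frac * spec.signal[i1, j1])
        )
    return LinearSpectrum(
        nus, values, {"kind": "diagonal_cut", "waiting_time": spec.waiting_time}
    )
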