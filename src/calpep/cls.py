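"""Center-line-slope (CLS) analysis of 2D-IR spectra.

For each excitation column whose T2=0 bleach is deep enough (>= 10% of the
global bleach maximum by default), the bleach minimum along the detection
axis is located by a Gaussian fit to the contiguous negative lobe.  The OLS
slope of these minima versus excitation frequency is the CLS: 1 means
perfectly correlated excitation/detection frequencies (full memory of the
initial frequency), 0 uncorrelated.  The decay of CLS(T2) is fit with a
monoexponential, rate k_CLS, over waiting times with sufficient signal
(800 fs for the carboxylate band, 1 ps for amide I in the experiments this
mirrors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from calpep.spectra2d import Spectrum2D

__all__ = ["CLSResult", "center_line", "cls_value", "cls_decay"]


@dataclass
class CLSResult:
    """CLS(T2) series with its monoexponential decay fit."""

    waiting_times: np.ndarray
    cls_values: np.ndarray
    cls_zero: float
    k_cls: float
    cls_amplitude: float
    fit_window: float
    centerlines: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.waiting_times = np.asarray(self.waiting_times, dtype=float)
        self.cls_values = np.asarray(self.cls_values, dtype=float)
        out_of_range = np.any(np.abs(self.cls_values) > 1.5)
        if out_of_range:
            raise ValueError("CLS values outside [-1.5, 1.5]; fit is unphysical")
        if np.any((self.cls_values < 0) | (self.cls_values > 1)):
            self.flags.append("cls_outside_unit_interval")
        if self.k_cls < 0:
            self.flags.append("negative_k_cls")


def _neg_gauss(x, amp, center, sigma):
    return -amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _fit_column_minimum(det: np.ndarray, col: np.ndarray) -> float | None:
    """Gaussian-fit minimum of the contiguous negative lobe around the deepest point.

    Returns the fitted center, or None if the fit fails/there is no negative
    lobe.  Ties for the deepest point break toward the lowest detection
    frequency.
    """
    if not np.any(col < 0):
        return None
    j = int(np.argmin(col))  # argmin takes the first (lowest-frequency) tie
    lo = j
    while lo > 0 and col[lo - 1] < 0:
        lo -= 1
    hi = j
    while hi < col.size - 1 and col[hi + 1] < 0:
        hi += 1
    if hi - lo + 1 < 4:
        return None
    x = det[lo : hi + 1]
    y = col[lo : hi + 1]
    depth = -col[j]
    width0 = max((x[-1] - x[0]) / 4.0, 1e-3)
    try:
        popt, _ = curve_fit(
            _neg_gauss,
            x,
            y,
            p0=[depth, det[j], width0],
            bounds=([0.0, x[0], 1e-4], [np.inf, x[-1], 10 * (x[-1] - x[0])]),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return None
    return float(popt[1])


def center_line(
    spec: Spectrum2D,
    mask_fraction: float = 0.10,
    ref_spec_t0: Spectrum2D | None = None,
    excitation_window: Sequence[float] | None = None,
) -> np.ndarray:
    """Per-excitation-column bleach minima (center-line points).

    Columns are kept where the reference (T2=0) bleach magnitude is at least
    ``mask_fraction`` of the global maximum bleach magnitude at T2=0; the
    minimum of each surviving column is located by a Gaussian fit to the
    contiguous negative lobe along detection.

    Returns an (n, 2) array of (excitation, detection-minimum) pairs.
    """
    ref = ref_spec_t0 if ref_spec_t0 is not None else spec
    bleach_ref = np.where(ref.signal < 0, -ref.signal, 0.0)
    w1 = spec.excitation_axis
    col_sel = np.ones(w1.size, dtype=bool)
    if excitation_window is not None:
        lo, hi = excitation_window
        col_sel &= (w1 >= lo) & (w1 <= hi)
        global_max = bleach_ref[col_sel].max() if np.any(col_sel) else 0.0
    else:
        global_max = bleach_ref.max()
    if global_max <= 0:
        raise ValueError("reference spectrum contains no bleach (negative signal)")

    points = []
    n_failed = 0
    for i in np.flatnonzero(col_sel):
        if bleach_ref[i].max() < mask_fraction * global_max:
            continue
        mu = _fit_column_minimum(spec.detection_axis, spec.signal[i])
        if mu is None:
            n_failed += 1
            continue
        points.append((w1[i], mu))
    if not points:
        raise ValueError(
            "no excitation column passed the bleach mask and Gaussian fit "
            f"({n_failed} fit failures)"
        )
    return np.asarray(points)


def cls_value(points: np.ndarray) -> float:
    """OLS slope of detection-minimum versus excitation frequency."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 3:
        raise ValueError("at least 3 center-line points are required")
    x, y = points[:, 0], points[:, 1]
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def cls_decay(
    series: Sequence[Spectrum2D],
    fit_window: float,
    mask_fraction: float = 0.10,
    excitation_window: Sequence[float] | None = None,
) -> CLSResult:
    """CLS(T2) for a waiting-time series plus monoexponential decay fit.

    CLS at T2=0 is taken from the measured T2=0 spectrum, not from the fit.
    A negative fitted rate is returned but flagged.
    """
    series = sorted(series, key=lambda s: s.waiting_time)
    t2s = np.array([s.waiting_time for s in series])
    ref = series[int(np.argmin(t2s))]
    in_window = t2s <= fit_window
    if in_window.sum() < 3:
        raise ValueError(
            f"need >= 3 waiting times within fit_window={fit_window} ps, "
            f"have {int(in_window.sum())}"
        )

    cls_vals = np.empty(t2s.size)
    centerlines = []
    for i, s in enumerate(series):
        pts = center_line(
            s,
            mask_fraction=mask_fraction,
            ref_spec_t0=ref,
            excitation_window=excitation_window,
        )
        cls_vals[i] = cls_value(pts)
        centerlines.append(pts)

    x = t2s[in_window]
    y = cls_vals[in_window]
    a0 = max(y[0], 1e-6)
    span = max(x[-1] - x[0], 1e-6)
    k0 = 1.0 / span if y[-1] >= y[0] or y[-1] <= 0 else np.log(y[0] / y[-1]) / span
    try:
        popt, _ = curve_fit(
            lambda t, a, k: a * np.exp(-k * t),
            x,
            y,
            p0=[a0, max(k0, 1e-3)],
            maxfev=5000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"monoexponential CLS fit did not converge: {err}")
    amp, k = float(popt[0]), float(popt[1])
    if k < 0:
        warnings.warn(
            f"fitted k_CLS is negative ({k:.3g} 1/ps); returned with flag",
            stacklevel=2,
        )
    return CLSResult(
        waiting_times=t2s,
        cls_values=cls_vals,
        cls_zero=float(cls_vals[int(np.argmin(t2s))]),
        k_cls=k,
        cls_amplitude=amp,
        fit_window=float(fit_window),
        centerlines=centerlines,
    )
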