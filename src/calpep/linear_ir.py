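"""Linear-IR preprocessing and multi-Gaussian band decomposition.

The processing order is fixed: linear background correction first, then
normalization to the integrated absorbance.  Band decomposition uses
sum-of-Gaussians nonlinear least squares (lmfit), matching the synthetic
generator's profile; the relevant phenomenology is a main carboxylate
band near 1590 cm^-1, a calcium-induced shoulder near 1620 cm^-1 and the
amide I band near 1660 cm^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lmfit.models import GaussianModel

from calpep.synth_spectra import LinearSpectrum

__all__ = [
    "BandFit",
    "correct_background",
    "normalize_integral",
    "fit_bands",
    "difference_spectrum",
]

#: condition-number threshold above which an lmfit covariance flags degeneracy
_DEGENERATE_CONDITION = 1e8


@dataclass
class BandFit:
    """Result of a sum-of-Gaussians decomposition.

    ``components`` holds (center cm^-1, width sigma cm^-1, area OD*cm^-1)
    sorted by center.  ``degenerate`` flags near-singular covariance
    (overlapping identical components).
    """

    components: list
    residual_rms: float
    converged: bool
    degenerate: bool = False
    covariance_condition: float = np.nan
    stderr: list = field(default_factory=list)

    @property
    def centers(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])


def correct_background(
    s: LinearSpectrum, anchor_windows: Sequence[Sequence[float]] | None = None
) -> LinearSpectrum:
    """Subtract the straight line through the mean absorbance of two anchors.

    ``anchor_windows`` is a pair of (lo, hi) wavenumber intervals; by default
    the lowest and highest 20 cm^-1 of the axis.  Overlapping a band with an
    anchor biases the baseline; that case is not rejected but flagged with a
    warning and ``metadata['background_anchor_warning']``.
    """
    nu = s.wavenumbers
    if anchor_windows is None:
        anchor_windows = [(nu[0], nu[0] + 20.0), (nu[-1] - 20.0, nu[-1])]
    (lo1, hi1), (lo2, hi2) = anchor_windows
    if lo1 < hi2 and lo2 < hi1:
        raise ValueError("anchor windows must not overlap each other")
    masks = []
    for lo, hi in anchor_windows:
        m = (nu >= lo) & (nu <= hi)
        if not np.any(m):
            raise ValueError(
                f"anchor window [{lo}, {hi}] cm^-1 contains no grid points"
            )
        masks.append(m)
    x1, y1 = nu[masks[0]].mean(), s.absorbance[masks[0]].mean()
    x2, y2 = nu[masks[1]].mean(), s.absorbance[masks[1]].mean()
    slope = (y2 - y1) / (x2 - x1)
    baseline = y1 + slope * (nu - x1)

    meta = dict(s.metadata)
    meta["background_anchors"] = [list(map(float, w)) for w in anchor_windows]
    # flag anchors that sit on substantial signal (possible bias)
    resid = s.absorbance - baseline
    span = np.ptp(resid) if resid.size else 0.0
    anchor_level = max(abs(resid[m]).mean() for m in masks)
    if span > 0 and anchor_level > 0.05 * span:
        warnings.warn(
            "background anchor windows overlap spectral features; baseline "
            "may be biased",
            stacklevel=2,
        )
        meta["background_anchor_warning"] = True
    return LinearSpectrum(nu, resid, meta)


def normalize_integral(
    s: LinearSpectrum, window: Sequence[float] | None = None
) -> LinearSpectrum:
    """Scale so the trapezoidal integral of absorbance over ``window`` is 1."""
    nu = s.wavenumbers
    if window is None:
        window = (nu[0], nu[-1])
    lo, hi = window
    m = (nu >= lo) & (nu <= hi)
    if m.sum() < 2:
        raise ValueError(f"normalization window [{lo}, {hi}] has <2 grid points")
    integral = np.trapezoid(s.absorbance[m], nu[m])
    if integral <= 0:
        raise ValueError(
            f"integral over [{lo}, {hi}] is {integral:.3g} <= 0; "
            "run background correction first"
        )
    meta = dict(s.metadata)
    meta["normalization_window"] = [float(lo), float(hi)]
    return LinearSpectrum(nu, s.absorbance / integral, meta)


def fit_bands(
    s: LinearSpectrum,
    n_components: int,
    init: Sequence[float],
    init_sigma: float = 15.0,
) -> BandFit:
    """Nonlinear least-squares sum-of-Gaussians fit.

    Parameters
    ----------
    n_components : int
        Number of Gaussian components (>= 1).
    init : sequence of float
        Center guesses, one per component, inside the axis range.
    init_sigma : float
        Initial width guess in cm^-1.

    Raises
    ------
    RuntimeError
        On non-convergence, carrying the last iterate in the message.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if len(init) != n_components:
        raise ValueError("one center guess per component is required")
    nu, y = s.wavenumbers, s.absorbance
    for c in init:
        if not (nu[0] <= c <= nu[-1]):
            raise ValueError(f"center guess {c} cm^-1 outside axis range")

    model = None
    params = None
    for i, c in enumerate(init):
        g = GaussianModel(prefix=f"g{i}_")
        # lmfit's 'amplitude' is the area; seed it from the local height
        height = max(float(np.interp(c, nu, y)), 1e-6 * max(y.max(), 1e-6))
        p = g.make_params(
            center=c, sigma=init_sigma,
            amplitude=height * init_sigma * np.sqrt(2 * np.pi),
        )
        p[f"g{i}_sigma"].min = 1e-3
        p[f"g{i}_sigma"].max = nu[-1] - nu[0]
        p[f"g{i}_amplitude"].min = 0.0
        p[f"g{i}_center"].min = nu[0]
        p[f"g{i}_center"].max = nu[-1]
        model = g if model is None else model + g
        params = p if params is None else params.update(p) or params
    result = model.fit(y, params, x=nu)
    if not result.success:
        raise RuntimeError(
            "band fit did not converge; last iterate: "
            + ", ".join(f"{k}={v.value:.4g}" for k, v in result.params.items())
        )

    comps = []
    stderr = []
    for i in range(n_components):
        center = result.params[f"g{i}_center"].value
        sigma = result.params[f"g{i}_sigma"].value
        area = result.params[f"g{i}_amplitude"].value  # lmfit amplitude == area
        comps.append((float(center), float(sigma), float(area)))
        stderr.append(
            tuple(
                result.params[f"g{i}_{p}"].stderr
                for p in ("center", "sigma", "amplitude")
            )
        )
    order = np.argsort([c[0] for c in comps])
    comps = [comps[i] for i in order]
    stderr = [stderr[i] for i in order]

    degenerate = False
    cond = np.nan
    if result.covar is not None:
        try:
            cond = float(np.linalg.cond(result.covar))
        except np.linalg.LinAlgError:
            cond = np.inf
        degenerate = not np.isfinite(cond) or cond > _DEGENERATE_CONDITION
    else:
        degenerate = n_components > 1
    residual_rms = float(np.sqrt(np.mean(result.residual**2)))
    return BandFit(
        components=comps,
        residual_rms=residual_rms,
        converged=bool(result.success),
        degenerate=degenerate,
        covariance_condition=cond,
        stderr=stderr,
    )


def difference_spectrum(
    a: LinearSpectrum, b: LinearSpectrum, interpolate: bool = False
) -> LinearSpectrum:
    """Pointwise a - b; grids must match unless ``interpolate`` is set.

    With ``interpolate``, b is linearly interpolated onto a's grid over their
    overlap; disjoint grids are rejected either way.
    """
    if a.wavenumbers.size == b.wavenumbers.size and np.allclose(
        a.wavenumbers, b.wavenumbers
    ):
        nu = a.wavenumbers
        diff = a.absorbance - b.absorbance
    elif interpolate:
        lo = max(a.wavenumbers[0], b.wavenumbers[0])
        hi = min(a.wavenumbers[-1], b.wavenumbers[-1])
        if hi <= lo:
            raise ValueError("spectra grids do not overlap")
        m = (a.wavenumbers >= lo) & (a.wavenumbers <= hi)
        nu = a.wavenumbers[m]
        diff = a.absorbance[m] - np.interp(nu, b.wavenumbers, b.absorbance)
    else:
        raise ValueError(
            "wavenumber grids differ; pass interpolate=True to resample b"
        )
    meta = {**b.metadata, **a.metadata, "kind": "difference_spectrum"}
    return LinearSpectrum(nu, diff, meta)
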