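"""Trajectory post-processing: RDFs, Ca2+ binding-state categorization,
hydration numbers, and binding-state-resolved VDOS from CO bond velocities.

All pair distances use the minimum-image convention in a cubic box.  The
vibrational density of states is estimated on the Blackman-Tukey route
(biased autocovariance, Bartlett lag window): the Bartlett window's Fejer
smoothing kernel is non-negative, so the density never goes negative and
its frequency integral equals the velocity-series variance (Parseval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from calpep.constants import C_CM_PER_FS
from calpep.synth_traj import STATE_LABELS, Trajectory

__all__ = [
    "BindingState",
    "RDFResult",
    "VDOS",
    "rdf",
    "categorize_frames",
    "hydration_numbers",
    "vdos",
    "categorized_vdos",
]


@dataclass(frozen=True)
class BindingState:
    """Ca2+ occupancy of the two dipeptide sites in one frame."""

    n_ca_at_coo: int
    n_ca_at_co: int

    def __post_init__(self) -> None:
        if self.n_ca_at_coo not in (0, 1, 2):
            raise ValueError("n_ca_at_coo must be 0, 1 or 2")
        if self.n_ca_at_co not in (0, 1):
            raise ValueError("n_ca_at_co must be 0 or 1")

    @property
    def label(self) -> str:
        return STATE_LABELS.get(
            (self.n_ca_at_coo, self.n_ca_at_co),
            f"{self.n_ca_at_coo}Ca@COO+{self.n_ca_at_co}Ca@CO",
        )


@dataclass
class RDFResult:
    r: np.ndarray  # bin centers, Angstrom
    g: np.ndarray
    dr: float
    sel_a: str
    sel_b: str
    n_frames: int
    mean_pair_count: float  # mean number of b partners within r_max per a atom
    rho_b: float  # reference number density of b, per Angstrom^3

    def first_peak(self) -> float:
        """Bin center of the first local maximum of g(r)."""
        return float(self.r[int(np.argmax(self.g))])


@dataclass
class VDOS:
    frequencies: np.ndarray  # cm^-1, up to Nyquist
    density: np.ndarray  # integrates (over cm^-1) to the series variance
    category: str
    n_frames: int
    resolution: float
    metadata: dict = field(default_factory=dict)

    def peak_frequency(self) -> float:
        return float(self.frequencies[int(np.argmax(self.density))])


def _min_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def pair_distances(
    pos_a: np.ndarray, pos_b: np.ndarray, L: float
) -> np.ndarray:
    """Minimum-image distances, shape (..., n_a, n_b)."""
    d = pos_a[..., :, None, :] - pos_b[..., None, :, :]
    d = _min_image(d, L)
    return np.sqrt((d**2).sum(axis=-1))


def rdf(
    traj: Trajectory,
    sel_a: str,
    sel_b: str,
    dr: float = 0.05,
    r_max: float | None = None,
) -> RDFResult:
    """Radial distribution function between two role selections.

    g(r) is the pair-distance histogram normalized by the ideal-gas
    expectation: exact shell volumes 4*pi/3 (r_out^3 - r_in^3) times the
    reference number density n_b/V, per a-atom and per frame.  Self pairs
    are excluded when the selections coincide.
    """
    L = traj.box_edge
    if r_max is None:
        r_max = L / 2.0
    if r_max > L / 2.0 + 1e-9:
        raise ValueError(
            f"r_max={r_max} exceeds half the box edge ({L / 2}); the "
            "minimum-image convention is only valid up to L/2"
        )
    ia = traj.atom_indices(sel_a)
    ib = traj.atom_indices(sel_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError(f"empty selection: {sel_a!r} ({ia.size}), {sel_b!r} ({ib.size})")

    edges = np.arange(0.0, r_max + dr * 0.5, dr)
    counts = np.zeros(edges.size - 1)
    same = sel_a == sel_b
    for f in range(traj.n_frames):
        dist = pair_distances(traj.positions[f, ia], traj.positions[f, ib], L)
        if same:
            np.fill_diagonal(dist, np.inf)
        counts += np.histogram(dist.ravel(), bins=edges)[0]

    n_b_ref = ib.size - 1 if same else ib.size
    rho_b = n_b_ref / L**3
    shell = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = traj.n_frames * ia.size * rho_b * shell
    g = counts / norm
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(
        r=centers,
        g=g,
        dr=dr,
        sel_a=sel_a,
        sel_b=sel_b,
        n_frames=traj.n_frames,
        mean_pair_count=float(counts.sum() / (traj.n_frames * ia.size)),
        rho_b=rho_b,
    )


def categorize_frames(
    traj: Trajectory, ca_cutoff: float = 3.0
) -> tuple[list, dict]:
    """Per-frame binding states and category fractions.

    A Ca2+ is bound to an oxygen when their minimum-image distance is
    <= ``ca_cutoff`` (closed boundary).  The carboxylate count is the number
    of distinct Ca2+ within the cutoff of either carboxylate oxygen (capped
    at 2); the amide count is 0 or 1.  Fractions are reported for the five
    categories (including absent ones, as 0.0).
    """
    if ca_cutoff <= 0:
        raise ValueError("ca_cutoff must be > 0")
    if ca_cutoff > traj.box_edge / 2.0:
        raise ValueError(
            f"ca_cutoff={ca_cutoff} exceeds half the box edge "
            f"({traj.box_edge / 2})"
        )
    ica = traj.atom_indices("Ca")
    icoo = np.concatenate(
        [traj.atom_indices("O_coo1"), traj.atom_indices("O_coo2")]
    )
    iam = traj.atom_indices("O_amide")
    L = traj.box_edge

    d_coo = pair_distances(traj.positions[:, ica], traj.positions[:, icoo], L)
    d_am = pair_distances(traj.positions[:, ica], traj.positions[:, iam], L)
    bound_coo = (d_coo <= ca_cutoff).any(axis=-1)  # (frames, n_ca)
    bound_am = (d_am <= ca_cutoff).any(axis=-1)

    states = []
    for f in range(traj.n_frames):
        n_coo = min(int(bound_coo[f].sum()), 2)
        n_co = min(int(bound_am[f].sum()), 1)
        states.append(BindingState(n_coo, n_co))

    fractions = {label: 0.0 for label in STATE_LABELS.values()}
    for s in states:
        fractions[s.label] = fractions.get(s.label, 0.0) + 1.0 / traj.n_frames
    return states, fractions


def hydration_numbers(
    traj: Trajectory, states: list, cutoff: float = 2.4
) -> pd.DataFrame:
    """Mean water-hydrogen counts per site, grouped by bound-Ca count.

    A water is counted when a water hydrogen sits within ``cutoff`` (closed
    boundary, <=) of the site oxygen.  Carboxylate rows average the two
    carboxylate oxygens.  Categories with zero frames are absent from the
    table, not reported as zero.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    ihw = traj.atom_indices("H_w")
    if ihw.size == 0:
        raise ValueError("no water hydrogens (role H_w) labelled")
    L = traj.box_edge
    n_coo = np.array([s.n_ca_at_coo for s in states])
    n_co = np.array([s.n_ca_at_co for s in states])

    def site_counts(role_indices: np.ndarray) -> np.ndarray:
        d = pair_distances(traj.positions[:, role_indices], traj.positions[:, ihw], L)
        return (d <= cutoff).sum(axis=-1).mean(axis=-1)  # mean over site oxygens

    counts_am = site_counts(traj.atom_indices("O_amide"))
    counts_coo = site_counts(
        np.concatenate([traj.atom_indices("O_coo1"), traj.atom_indices("O_coo2")])
    )

    rows = []
    for k in (0, 1):
        m = n_co == k
        if m.any():
            rows.append(
                (f"{k} Ca2+ at CO", float(counts_am[m].mean()), int(m.sum()))
            )
    for k in (0, 1, 2):
        m = n_coo == k
        if m.any():
            rows.append(
                (f"{k} Ca2+ at COO-", float(counts_coo[m].mean()), int(m.sum()))
            )
    return pd.DataFrame(
        rows, columns=["category", "mean_water_count", "n_frames"]
    ).set_index("category")


def _bond_velocity_series(
    traj: Trajectory, bond: tuple, frames: np.ndarray
) -> np.ndarray:
    ia = traj.atom_indices(bond[0])
    ib = traj.atom_indices(bond[1])
    if ia.size == 0 or ib.size == 0:
        raise ValueError(f"bond roles {bond} not present in the trajectory")
    a, b = ia[0], ib[0]
    rel = _min_image(
        traj.positions[frames, b] - traj.positions[frames, a], traj.box_edge
    )
    axis = rel / np.linalg.norm(rel, axis=-1, keepdims=True)
    vrel = traj.velocities[frames, b] - traj.velocities[frames, a]
    return np.einsum("ij,ij->i", vrel, axis)


def _blackman_tukey(series: np.ndarray, dt_fs: float, max_lag: int | None = None):
    """Non-negative spectral density; integral over cm^-1 equals the variance."""
    x = series - series.mean()
    n = x.size
    m = max_lag if max_lag is not None else max(n // 2, 2)
    m = min(m, n - 1)
    acov = np.array(
        [np.dot(x[: n - k], x[k:]) / n for k in range(m + 1)]
    )  # biased estimator
    w = 1.0 - np.arange(m + 1) / m  # Bartlett lag window (w[m] = 0)
    c = np.concatenate([w * acov, (w * acov)[1:-1][::-1]])  # symmetric, length 2m
    s_full = np.real(np.fft.fft(c)) * dt_fs  # per (1/fs)
    # one-sided fold so the discrete frequency integral equals acov[0]
    s = s_full[: m + 1].copy()
    s[1:-1] *= 2.0
    s = np.maximum(s, 0.0)
    freq_fs = np.arange(m + 1) / (2 * m * dt_fs)
    nu = freq_fs / C_CM_PER_FS
    density = s * C_CM_PER_FS  # per cm^-1
    return nu, density


def vdos(
    traj: Trajectory,
    bond: tuple = ("C_coo", "O_coo1"),
    frame_subset: np.ndarray | None = None,
    max_lag: int | None = None,
) -> VDOS:
    """VDOS of the bond-projected relative velocity of a labelled atom pair.

    The relative velocity of the bonded pair is projected on the
    instantaneous bond axis; the spectral density of this scalar series is
    estimated with a Bartlett-windowed autocovariance.  Non-contiguous
    frame subsets are segmented (with a warning) and the per-segment
    estimates averaged.
    """
    if frame_subset is None:
        frame_subset = np.arange(traj.n_frames)
    frames = np.asarray(frame_subset, dtype=int)
    if frames.size < 4:
        raise ValueError("frame subset must contain at least 4 samples")
    breaks = np.flatnonzero(np.diff(frames) != 1)
    segments = np.split(frames, breaks + 1)
    if len(segments) > 1:
        warnings.warn(
            f"frame subset is non-contiguous ({len(segments)} segments); "
            "returning a segmented estimate",
            stacklevel=2,
        )
    segments = [s for s in segments if s.size >= 4]
    if not segments:
        raise ValueError("no contiguous segment has >= 4 samples")
    m_common = max_lag if max_lag is not None else max(
        min(s.size for s in segments) // 2, 2
    )
    m_common = min(m_common, min(s.size for s in segments) - 1)

    nu = None
    acc = None
    weight = 0.0
    for seg in segments:
        series = _bond_velocity_series(traj, bond, seg)
        nu_s, dens = _blackman_tukey(series, traj.dt, max_lag=m_common)
        acc = dens * seg.size if acc is None else acc + dens * seg.size
        nu = nu_s
        weight += seg.size
    density = acc / weight
    return VDOS(
        frequencies=nu,
        density=density,
        category="all",
        n_frames=int(frames.size),
        resolution=float(nu[1] - nu[0]),
        metadata={"bond": list(bond), "segments": len(segments), "max_lag": m_common},
    )


def categorized_vdos(
    traj: Trajectory,
    states: list,
    bond: tuple = ("C_coo", "O_coo1"),
    min_segment: int = 64,
) -> dict:
    """VDOS per binding-state category, evaluated over contiguous frame blocks.

    Categories whose blocks are all shorter than ``min_segment`` frames are
    excluded (their frame counts are reported in the returned VDOS
    metadata of present categories is unaffected).  Categories are ordered
    canonically: no Ca, 1 Ca at COO-, 2 Ca at COO-, 1 Ca at CO, mixed.
    """
    labels = np.array([s.label for s in states])
    order = list(STATE_LABELS.values())
    out: dict = {}
    for label in order:
        frames = np.flatnonzero(labels == label)
        if frames.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(frames) != 1)
        segments = [s for s in np.split(frames, breaks + 1) if s.size >= min_segment]
        if not segments:
            continue
        usable = np.concatenate(segments)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = vdos(traj, bond=bond, frame_subset=usable)
        v.category = label
        out[label] = v
    return out
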