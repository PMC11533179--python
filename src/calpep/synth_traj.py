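"""Toy trajectories with prescribed Ca2+ binding-state schedules.

Generation is kinematic, not dynamic: every motion is prescribed so the
ground truth (binding-state fractions, hydration occupancies, CO oscillation
frequencies) is exact.  The solute mimics a zwitterionic dipeptide with two
carboxylate oxygens, one amide oxygen and an amide NH as competing Ca2+
sites, solvated by waters and CaCl2 in a cubic periodic box (defaults: 60
waters, 6 CaCl2, 13.3 Angstrom edge, frames every 8 fs).

Binding states are assigned in contiguous frame blocks realizing the
requested fractions exactly.  In bound frames a Ca2+ sits at the contact
distance from the site oxygen (radial Gaussian jitter); water hydrogens
occupy hydration sites following a per-state occupancy table (fractional
occupancies are realized by deterministic frame patterns, so recovered
means are exact up to 1/n_frames); CO bonds oscillate harmonically with a
binding-state-dependent frequency and phase continuity across state
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from calpep.constants import C_CM_PER_FS, nyquist_wavenumber

__all__ = ["STATE_LABELS", "TrajectoryConfig", "Trajectory", "make_trajectory"]

#: the five binding-state categories, keyed by (n Ca at COO-, n Ca at amide CO)
STATE_LABELS = {
    (0, 0): "none",
    (1, 0): "1Ca@COO",
    (2, 0): "2Ca@COO",
    (0, 1): "1Ca@CO",
    (1, 1): "1Ca@COO+1Ca@CO",
}
LABEL_TO_STATE = {v: k for k, v in STATE_LABELS.items()}

_SOLUTE = [
    # role, element
    ("C_coo", "C"),
    ("O_coo1", "O"),
    ("O_coo2", "O"),
    ("C_amide", "C"),
    ("O_amide", "O"),
    ("N_amide", "N"),
    ("H_amide", "H"),
]


def _default_co_frequencies() -> dict:
    # carboxylate C-O stretch blueshifts as Ca2+ ions coordinate the group
    return {
        "none": 1590.0,
        "1Ca@COO": 1610.0,
        "2Ca@COO": 1630.0,
        "1Ca@CO": 1590.0,
        "1Ca@COO+1Ca@CO": 1610.0,
    }


def _default_amide_frequencies() -> dict:
    # amide I redshifts slightly on direct Ca2+ contact
    return {0: 1660.0, 1: 1653.0}


def _default_hydration() -> dict:
    # water-H occupancy per site oxygen, keyed by site and bound-Ca count;
    # ordering (less water when Ca is bound) mirrors the AIMD hydration trend
    return {
        ("co", 0): 0.8,
        ("co", 1): 0.0,
        ("coo", 0): 1.5,
        ("coo", 1): 0.4,
        ("coo", 2): 0.1,
    }


@dataclass
class TrajectoryConfig:
    """Ground-truth parameters of a toy trajectory."""

    n_frames: int = 1000
    dt: float = 8.0  # fs between stored frames
    box_edge: float = 13.3  # Angstrom
    state_fractions: dict = field(default_factory=dict)  # label -> fraction
    ca_contact_distance: float = 2.4  # Angstrom, first-shell Ca-O distance
    ca_jitter: float = 0.05  # Angstrom, radial jitter of bound Ca
    water_contact_distance: float = 2.4  # Angstrom, water-H bonding criterion
    co_frequencies: dict = field(default_factory=_default_co_frequencies)
    amide_frequencies: dict = field(default_factory=_default_amide_frequencies)
    hydration_occupancy: dict = field(default_factory=_default_hydration)
    amplitude: float = 0.05  # Angstrom, CO bond oscillation amplitude
    n_ca: int = 6
    n_water: int = 60
    background_jitter: float = 0.3  # Angstrom, per-frame jitter (clipped)
    shuffle_states: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.dt <= 0:
            raise ValueError("n_frames must be >= 1 and dt > 0")
        total = sum(self.state_fractions.values())
        if any(f < 0 for f in self.state_fractions.values()) or total > 1 + 1e-9:
            raise ValueError("state fractions must be non-negative and sum <= 1")
        for label in self.state_fractions:
            if label not in LABEL_TO_STATE:
                raise ValueError(
                    f"unknown state label {label!r}; valid: {sorted(LABEL_TO_STATE)}"
                )
        nyq = nyquist_wavenumber(self.dt)
        freqs = list(self.co_frequencies.values()) + list(
            self.amide_frequencies.values()
        )
        for nu in freqs:
            if nu >= nyq:
                raise ValueError(
                    f"oscillator frequency {nu} cm^-1 exceeds the Nyquist limit "
                    f"{nyq:.0f} cm^-1 at dt={self.dt} fs"
                )


@dataclass
class Trajectory:
    """Frames of labelled positions and velocities in a cubic periodic box."""

    positions: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    velocities: np.ndarray  # (n_frames, n_atoms, 3), Angstrom/fs
    roles: list
    elements: list
    box_edge: float
    dt: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have the same shape")
        if self.positions.shape[1] != len(self.roles):
            raise ValueError("one role per atom is required")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities must be finite")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def atom_indices(self, role: str) -> np.ndarray:
        idx = np.flatnonzero([r == role for r in self.roles])
        return idx


def _schedule(cfg: TrajectoryConfig, rng: np.random.Generator) -> list:
    """Per-frame category labels in contiguous blocks (exact counts)."""
    labels = []
    remaining = cfg.n_frames
    for label, frac in cfg.state_fractions.items():
        n = int(round(frac * cfg.n_frames))
        n = min(n, remaining)
        labels.extend([label] * n)
        remaining -= n
    labels.extend(["none"] * remaining)
    if cfg.shuffle_states:
        order = rng.permutation(len(labels))
        labels = [labels[i] for i in order]
    return labels


def _place_background(
    cfg: TrajectoryConfig,
    rng: np.random.Generator,
    fixed: np.ndarray,
    site_oxygens: np.ndarray,
    n_points: int,
    site_margin: float,
    min_dist: float = 1.8,
    max_tries: int = 20000,
) -> np.ndarray:
    """Uniform random points avoiding existing atoms and site exclusion zones."""
    L = cfg.box_edge
    placed = []
    occupied = [fixed]
    tries = 0
    while len(placed) < n_points:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"box overcrowded: placed {len(placed)}/{n_points} background "
                f"points after {max_tries} attempts"
            )
        p = rng.uniform(0.0, L, 3)
        d_site = _min_image_dist(p[None, :], site_oxygens, L).min()
        if d_site < site_margin:
            continue
        all_occ = np.concatenate(occupied + ([np.array(placed)] if placed else []))
        if _min_image_dist(p[None, :], all_occ, L).min() < min_dist:
            continue
        placed.append(p)
    return np.asarray(placed).reshape(len(placed), 3)


def _min_image_dist(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d -= L * np.round(d / L)
    return np.sqrt((d**2).sum(axis=-1))


def make_trajectory(cfg: TrajectoryConfig) -> Trajectory:
    """Generate a toy trajectory realizing the configured binding schedule.

    Reproducible bit-for-bit for a fixed seed.  Ground truth (schedule,
    fractions, frequencies, occupancy table) is recorded in the metadata.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.box_edge
    center = np.full(3, L / 2.0)

    # --- solute geometry (static apart from the oscillating CO oxygens)
    u1 = np.array([1.0, 0.0, 0.0])
    u2 = np.array([-0.5, np.sqrt(3) / 2, 0.0])
    r_c_coo = center.copy()
    r_o1 = r_c_coo + 1.26 * u1
    r_o2 = r_c_coo + 1.26 * u2
    r_c_am = center + np.array([0.0, -3.2, 0.0])
    am_dir = np.array([0.0, -1.0, 0.0])
    r_o_am = r_c_am + 1.23 * am_dir
    r_n = r_c_am + 1.33 * np.array([0.94, 0.34, 0.0])
    r_h = r_n + 1.0 * np.array([0.94, 0.34, 0.0])
    solute_pos = np.stack([r_c_coo, r_o1, r_o2, r_c_am, r_o_am, r_n, r_h])
    site_oxygens = np.stack([r_o1, r_o2, r_o_am])

    schedule = _schedule(cfg, rng)
    states = [LABEL_TO_STATE[s] for s in schedule]
    n_coo = np.array([s[0] for s in states])
    n_co = np.array([s[1] for s in states])

    # --- hydration bookkeeping: slots per site, deterministic frame patterns
    sites = {
        "coo1": (1, u1, ("coo", n_coo)),
        "coo2": (2, u2, ("coo", n_coo)),
        "co": (4, am_dir, ("co", n_co)),
    }
    max_slots = {
        name: int(
            np.ceil(
                max(
                    cfg.hydration_occupancy.get((kind, k), 0.0)
                    for k in (0, 1, 2)
                )
            )
        )
        for name, (_, _, (kind, _)) in sites.items()
    }
    hyd_dirs = {
        "coo1": [np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])],
        "coo2": [np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])],
        "co": [np.array([0.0, -0.7, 0.714]), np.array([0.0, -0.7, -0.714])],
    }
    # present[site][slot] is a boolean per-frame mask
    present: dict = {}
    for name, (_idx, _dirv, (kind, counts)) in sites.items():
        present[name] = []
        for slot in range(max_slots[name]):
            mask = np.zeros(cfg.n_frames, dtype=bool)
            for k in (0, 1, 2):
                occ = cfg.hydration_occupancy.get((kind, k), 0.0)
                frames_k = np.flatnonzero(counts == k)
                if frames_k.size == 0:
                    continue
                if occ >= slot + 1:
                    mask[frames_k] = True
                elif occ > slot:
                    n_on = int(round((occ - slot) * frames_k.size))
                    mask[frames_k[:n_on]] = True
            present[name].append(mask)

    n_hyd_waters = sum(max_slots.values())
    n_bg_waters = cfg.n_water - n_hyd_waters
    if n_bg_waters < 0:
        raise ValueError("n_water too small for the hydration occupancy table")
    n_cl = 2 * cfg.n_ca

    # --- atom roster
    roles = [r for r, _ in _SOLUTE]
    elements = [e for _, e in _SOLUTE]
    ca_start = len(roles)
    roles += ["Ca"] * cfg.n_ca
    elements += ["Ca"] * cfg.n_ca
    cl_start = len(roles)
    roles += ["Cl"] * n_cl
    elements += ["Cl"] * n_cl
    w_start = len(roles)
    for _ in range(cfg.n_water):
        roles += ["O_w", "H_w", "H_w"]
        elements += ["O", "H", "H"]
    n_atoms = len(roles)

    # --- static background placement (waters, free ions)
    # water O exclusion: H atoms extend 0.96 A from O and the whole molecule
    # jitters by up to 0.8 A, so keep O beyond cutoff + 0.96 + 0.8 (+ slack)
    margin_water = cfg.water_contact_distance + 2.0
    margin_ca = 4.2
    bg_water_o = _place_background(
        cfg, rng, solute_pos, site_oxygens, n_bg_waters, margin_water
    )
    occupied = np.concatenate([solute_pos, bg_water_o]) if n_bg_waters else solute_pos
    bg_ca = _place_background(cfg, rng, occupied, site_oxygens, cfg.n_ca, margin_ca)
    occupied = np.concatenate([occupied, bg_ca])
    bg_cl = _place_background(cfg, rng, occupied, site_oxygens, n_cl, 2.5)

    positions = np.empty((cfg.n_frames, n_atoms, 3))
    velocities = np.zeros((cfg.n_frames, n_atoms, 3))

    # --- CO oscillators: phase-continuous harmonic bond motion
    co_freq = np.array([cfg.co_frequencies[schedule[f]] for f in range(cfg.n_frames)])
    am_freq = np.array(
        [cfg.amide_frequencies[int(n_co[f])] for f in range(cfg.n_frames)]
    )
    omega_co = 2.0 * np.pi * C_CM_PER_FS * co_freq  # rad/fs
    omega_am = 2.0 * np.pi * C_CM_PER_FS * am_freq
    phi_co = np.concatenate([[0.0], np.cumsum(omega_co[:-1] * cfg.dt)])
    phi_am = np.concatenate([[0.0], np.cumsum(omega_am[:-1] * cfg.dt)])

    solute_frames = np.broadcast_to(solute_pos, (cfg.n_frames, 7, 3)).copy()
    bond_len_co = 1.26 + cfg.amplitude * np.sin(phi_co)
    bond_len_am = 1.23 + cfg.amplitude * np.sin(phi_am)
    solute_frames[:, 1] = r_c_coo + bond_len_co[:, None] * u1
    solute_frames[:, 4] = r_c_am + bond_len_am[:, None] * am_dir
    positions[:, :7] = solute_frames
    velocities[:, 1] = (cfg.amplitude * omega_co * np.cos(phi_co))[:, None] * u1
    velocities[:, 4] = (cfg.amplitude * omega_am * np.cos(phi_am))[:, None] * am_dir

    # --- Ca ions: bound ones sit at the contact distance from their site
    ca_base = np.broadcast_to(bg_ca, (cfg.n_frames, cfg.n_ca, 3)).copy()
    jit = rng.normal(0.0, cfg.background_jitter, ca_base.shape)
    ca_pos = ca_base + np.clip(jit, -0.8, 0.8)
    radial = np.clip(
        rng.normal(0.0, cfg.ca_jitter, (cfg.n_frames, 3)), -4 * cfg.ca_jitter,
        4 * cfg.ca_jitter,
    )
    for f in range(cfg.n_frames):
        k_coo, k_co = states[f]
        slot = 0
        if k_coo >= 1:
            ca_pos[f, slot] = r_o1 + (cfg.ca_contact_distance + radial[f, 0]) * u1
            slot += 1
        if k_coo == 2:
            ca_pos[f, slot] = r_o2 + (cfg.ca_contact_distance + radial[f, 1]) * u2
            slot += 1
        if k_co == 1:
            ca_pos[f, slot] = (
                r_o_am + (cfg.ca_contact_distance + radial[f, 2]) * am_dir
            )
            slot += 1
    positions[:, ca_start : ca_start + cfg.n_ca] = ca_pos

    # --- Cl ions and background waters: static base + clipped jitter
    cl_base = np.broadcast_to(bg_cl, (cfg.n_frames, n_cl, 3)).copy()
    cl_pos = cl_base + np.clip(
        rng.normal(0.0, cfg.background_jitter, cl_base.shape), -0.8, 0.8
    )
    positions[:, cl_start : cl_start + n_cl] = cl_pos

    # hydration waters first, then background waters
    widx = w_start
    for name, (site_idx, _dirv, _key) in sites.items():
        site_o = solute_pos[site_idx]
        for slot in range(max_slots[name]):
            d = hyd_dirs[name][slot % len(hyd_dirs[name])]
            perp = np.cross(d, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(d, [0.0, 1.0, 0.0])
            perp = perp / np.linalg.norm(perp)
            mask = present[name][slot]
            # bound geometry: H1 at 2.0 A from the site oxygen, O behind it
            h1_in = site_o + 2.0 * d
            o_in = site_o + 2.96 * d
            h2_in = o_in + 0.96 * perp
            h1_out = site_o + 3.5 * d
            o_out = site_o + 4.46 * d
            h2_out = o_out + 0.96 * perp
            positions[:, widx] = np.where(mask[:, None], o_in, o_out)
            positions[:, widx + 1] = np.where(mask[:, None], h1_in, h1_out)
            positions[:, widx + 2] = np.where(mask[:, None], h2_in, h2_out)
            widx += 3
    for i in range(n_bg_waters):
        o = bg_water_o[i]
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        perp = np.cross(d, rng.normal(size=3))
        perp /= np.linalg.norm(perp)
        base = np.stack([o, o + 0.96 * d, o + 0.96 * (0.33 * d + 0.94 * perp)])
        jitter = np.clip(
            rng.normal(0.0, cfg.background_jitter, (cfg.n_frames, 1, 3)), -0.8, 0.8
        )
        positions[:, widx : widx + 3] = base[None, :, :] + jitter
        widx += 3

    positions = np.mod(positions, L)

    meta = {
        "generator": "make_trajectory",
        "schedule": schedule,
        "state_fractions": {
            label: schedule.count(label) / cfg.n_frames
            for label in set(schedule)
        },
        "co_frequencies": dict(cfg.co_frequencies),
        "amide_frequencies": dict(cfg.amide_frequencies),
        "hydration_occupancy": {
            f"{kind}_{k}": v for (kind, k), v in cfg.hydration_occupancy.items()
        },
        "ca_contact_distance": cfg.ca_contact_distance,
        "seed": cfg.seed,
        "dt": cfg.dt,
        "box_edge": L,
    }
    return Trajectory(
        positions, velocities, roles, elements, L, cfg.dt, metadata=meta
    )
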