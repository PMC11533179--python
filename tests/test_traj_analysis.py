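"""RDFs, binding-state categorization, hydration tables and VDOS estimators."""

import itertools

import numpy as np
import pytest

from calpep import (
    Trajectory,
    TrajectoryConfig,
    categorize_frames,
    categorized_vdos,
    hydration_numbers,
    make_trajectory,
    rdf,
    vdos,
)
from calpep.constants import C_CM_PER_FS
from calpep.traj_analysis import pair_distances


def _bare_trajectory(positions, roles, box=13.3, velocities=None, dt=8.0):
    positions = np.asarray(positions, dtype=float)
    if velocities is None:
        velocities = np.zeros_like(positions)
    elements = [r[0] for r in roles]
    return Trajectory(positions, velocities, roles, elements, box, dt)


def _brute_force_min_image(a, b, L):
    """All-images reference for minimum-image distances (<= 50 atoms)."""
    shifts = np.array(list(itertools.product((-1, 0, 1), repeat=3))) * L
    best = np.full((len(a), len(b)), np.inf)
    for s in shifts:
        d = np.linalg.norm(a[:, None, :] - (b[None, :, :] + s), axis=-1)
        best = np.minimum(best, d)
    return best


class TestMinimumImage:
    def test_matches_brute_force_all_images(self):
        rng = np.random.default_rng(0)
        L = 13.3
        a = rng.uniform(0, L, (20, 3))
        b = rng.uniform(0, L, (30, 3))
        np.testing.assert_allclose(
            pair_distances(a, b, L), _brute_force_min_image(a, b, L), atol=1e-10
        )


class TestRdf:
    def test_ideal_gas_rdf_is_unity(self):
        rng = np.random.default_rng(1)
        L = 13.3
        n_frames, n = 150, 40
        pos = rng.uniform(0, L, (n_frames, n, 3))
        traj = _bare_trajectory(pos, ["X"] * n, box=L)
        g = rdf(traj, "X", "X", dr=0.25)
        far = g.r > 2.0
        assert abs(g.g[far].mean() - 1.0) < 0.05

    def test_contact_shell_peak_at_first_shell_distance(self):
        cfg = TrajectoryConfig(
            n_frames=800, state_fractions={"1Ca@COO": 1.0}, seed=7
        )
        traj = make_trajectory(cfg)
        g = rdf(traj, "Ca", "O_coo1", dr=0.05)
        assert g.first_peak() == pytest.approx(2.4, abs=0.05)

    def test_single_fixed_pair_occupies_one_bin(self):
        pos = np.zeros((10, 2, 3))
        pos[:, 1, 0] = 3.12
        traj = _bare_trajectory(pos + 5.0, ["A", "B"])
        g = rdf(traj, "A", "B", dr=0.1)
        nonzero = np.flatnonzero(g.g)
        assert nonzero.size == 1
        assert g.r[nonzero[0]] == pytest.approx(3.15, abs=0.05)

    def test_number_integral_bookkeeping_is_exact(self):
        rng = np.random.default_rng(3)
        L = 10.0
        pos = rng.uniform(0, L, (50, 30, 3))
        traj = _bare_trajectory(pos, ["X"] * 30, box=L)
        g = rdf(traj, "X", "X", dr=0.2)
        shell = 4.0 * np.pi / 3.0 * (
            (g.r + g.dr / 2) ** 3 - (g.r - g.dr / 2) ** 3
        )
        integral = np.sum(g.g * g.rho_b * shell)
        assert integral == pytest.approx(g.mean_pair_count, rel=1e-9)

    def test_r_max_beyond_half_box_rejected(self):
        traj = _bare_trajectory(np.zeros((1, 2, 3)) + 5.0, ["A", "B"])
        with pytest.raises(ValueError, match="half the box"):
            rdf(traj, "A", "B", r_max=10.0)

    def test_empty_selection_rejected(self, scheduled_trajectory):
        with pytest.raises(ValueError, match="empty selection"):
            rdf(scheduled_trajectory, "Ca", "Xe")


class TestCategorization:
    def test_all_unbound(self):
        traj = make_trajectory(TrajectoryConfig(n_frames=40, seed=5))
        _, fracs = categorize_frames(traj)
        assert fracs["none"] == pytest.approx(1.0)
        assert all(v == 0.0 for k, v in fracs.items() if k != "none")

    def test_scheduled_fractions_recovered_exactly(self, scheduled_trajectory):
        _, fracs = categorize_frames(scheduled_trajectory)
        truth = scheduled_trajectory.metadata["state_fractions"]
        for label, want in truth.items():
            assert fracs[label] == pytest.approx(want, abs=1e-9)

    def test_cutoff_boundary_is_closed(self):
        # one Ca exactly at the cutoff, another epsilon beyond
        roles = ["O_coo1", "O_coo2", "O_amide", "Ca", "Ca"]
        pos = np.full((1, 5, 3), 6.0)
        pos[0, 1] += [0.0, 2.2, 0.0]
        pos[0, 2] += [0.0, -4.0, 0.0]
        pos[0, 3] = pos[0, 0] + [3.0, 0.0, 0.0]  # exactly at cutoff
        pos[0, 4] = pos[0, 0] + [-3.0 - 1e-9, 0.0, 0.0]
        traj = _bare_trajectory(pos, roles)
        states, _ = categorize_frames(traj, ca_cutoff=3.0)
        assert states[0].n_ca_at_coo == 1

    def test_cutoff_beyond_half_box_rejected(self, scheduled_trajectory):
        with pytest.raises(ValueError, match="half the box"):
            categorize_frames(scheduled_trajectory, ca_cutoff=7.0)


class TestHydration:
    def test_water_inside_and_outside_cutoff(self):
        roles = ["O_coo1", "O_coo2", "O_amide", "O_w", "H_w", "H_w"]
        for d, want in ((2.3, 1.0), (2.5, 0.0)):
            pos = np.full((4, 6, 3), 6.0)
            pos[:, 1] += [0.0, 2.2, 0.0]
            pos[:, 2] += [0.0, -4.0, 0.0]
            pos[:, 4] = pos[:, 2] + [d, 0.0, 0.0]  # water H near amide O
            pos[:, 3] = pos[:, 2] + [d + 0.96, 0.0, 0.0]
            pos[:, 5] = pos[:, 2] + [d + 1.2, 0.96, 0.0]
            traj = _bare_trajectory(pos, roles)
            states, _ = categorize_frames(traj)
            table = hydration_numbers(traj, states)
            assert table.loc["0 Ca2+ at CO", "mean_water_count"] == want

    def test_reference_occupancy_table_recovered_row_for_row(self):
        """Occupancies set to the AIMD hydration values are reproduced."""
        occupancy = {
            ("co", 0): 0.73, ("co", 1): 0.01,
            ("coo", 0): 1.64, ("coo", 1): 0.38, ("coo", 2): 0.10,
        }
        cfg = TrajectoryConfig(
            n_frames=1000,
            state_fractions={"1Ca@COO": 0.26, "2Ca@COO": 0.26,
                             "1Ca@CO": 0.02, "1Ca@COO+1Ca@CO": 0.13},
            hydration_occupancy=occupancy,
            seed=13,
        )
        traj = make_trajectory(cfg)
        states, _ = categorize_frames(traj)
        table = hydration_numbers(traj, states)
        assert table.loc["0 Ca2+ at CO", "mean_water_count"] == pytest.approx(
            0.73, abs=0.01
        )
        assert table.loc["1 Ca2+ at CO", "mean_water_count"] == pytest.approx(
            0.01, abs=0.01
        )
        assert table.loc["0 Ca2+ at COO-", "mean_water_count"] == pytest.approx(
            1.64, abs=0.01
        )
        assert table.loc["1 Ca2+ at COO-", "mean_water_count"] == pytest.approx(
            0.38, abs=0.01
        )

    def test_absent_category_not_reported(self):
        traj = make_trajectory(TrajectoryConfig(n_frames=30, seed=6))
        states, _ = categorize_frames(traj)
        table = hydration_numbers(traj, states)
        assert "1 Ca2+ at CO" not in table.index
        assert "0 Ca2+ at CO" in table.index


class TestVdos:
    def test_harmonic_oscillator_peak_within_one_bin(self):
        freqs = {k: 1660.0 for k in ("none", "1Ca@COO", "2Ca@COO",
                                     "1Ca@CO", "1Ca@COO+1Ca@CO")}
        traj = make_trajectory(
            TrajectoryConfig(n_frames=600, co_frequencies=freqs, seed=8)
        )
        v = vdos(traj, ("C_coo", "O_coo1"))
        assert abs(v.peak_frequency() - 1660.0) <= v.resolution

    def test_parseval_energy_bookkeeping(self):
        traj = make_trajectory(TrajectoryConfig(n_frames=400, seed=9))
        v = vdos(traj, ("C_coo", "O_coo1"))
        c = traj.atom_indices("C_coo")[0]
        o = traj.atom_indices("O_coo1")[0]
        rel = traj.positions[:, o] - traj.positions[:, c]
        rel -= traj.box_edge * np.round(rel / traj.box_edge)
        axis = rel / np.linalg.norm(rel, axis=1, keepdims=True)
        series = np.einsum(
            "ij,ij->i", traj.velocities[:, o] - traj.velocities[:, c], axis
        )
        series = series - series.mean()
        variance = np.mean(series**2)
        dnu = v.frequencies[1] - v.frequencies[0]
        assert np.sum(v.density) * dnu == pytest.approx(variance, rel=0.01)

    def test_white_noise_velocities_give_flat_density(self):
        rng = np.random.default_rng(10)
        n = 4000
        pos = np.zeros((n, 2, 3)) + 5.0
        pos[:, 1, 0] += 1.2
        vel = np.zeros((n, 2, 3))
        vel[:, 1, 0] = rng.normal(0, 1e-3, n)
        traj = _bare_trajectory(pos, ["C_coo", "O_coo1"], velocities=vel)
        # short lag window: heavy smoothing, so a white spectrum comes out flat
        v = vdos(traj, ("C_coo", "O_coo1"), max_lag=60)
        inner = v.density[2:-2]
        assert inner.std() / inner.mean() < 0.35

    def test_density_non_negative(self, scheduled_trajectory):
        v = vdos(scheduled_trajectory, ("C_coo", "O_coo1"))
        assert np.all(v.density >= 0.0)

    def test_non_contiguous_subset_warns(self, scheduled_trajectory):
        subset = np.concatenate([np.arange(0, 40), np.arange(60, 100)])
        with pytest.warns(UserWarning, match="non-contiguous"):
            vdos(scheduled_trajectory, ("C_coo", "O_coo1"), frame_subset=subset)

    def test_tiny_subset_rejected(self, scheduled_trajectory):
        with pytest.raises(ValueError, match="4 samples"):
            vdos(scheduled_trajectory, ("C_coo", "O_coo1"),
                 frame_subset=np.arange(3))


class TestCategorizedVdos:
    def test_single_category_matches_plain_vdos(self):
        traj = make_trajectory(TrajectoryConfig(n_frames=300, seed=12))
        states, _ = categorize_frames(traj)
        cvd = categorized_vdos(traj, states)
        assert set(cvd) == {"none"}
        plain = vdos(traj, ("C_coo", "O_coo1"))
        np.testing.assert_allclose(cvd["none"].density, plain.density)

    def test_blueshift_ladder_with_calcium_coordination(self):
        """Carboxylate VDOS peak moves up as 0 -> 1 -> 2 Ca2+ coordinate."""
        cfg = TrajectoryConfig(
            n_frames=900,
            state_fractions={"1Ca@COO": 0.3, "2Ca@COO": 0.3},
            seed=14,
        )
        traj = make_trajectory(cfg)
        states, _ = categorize_frames(traj)
        cvd = categorized_vdos(traj, states)
        peaks = [cvd[k].peak_frequency() for k in ("none", "1Ca@COO", "2Ca@COO")]
        assert peaks[0] < peaks[1] < peaks[2]
        res = cvd["none"].resolution
        want = [cfg.co_frequencies[k] for k in ("none", "1Ca@COO", "2Ca@COO")]
        for got, ref in zip(peaks, want):
            assert abs(got - ref) <= res

    def test_configured_intercategory_offset_recovered(self):
        freqs = {
            "none": 1590.0, "1Ca@COO": 1615.0, "2Ca@COO": 1640.0,
            "1Ca@CO": 1590.0, "1Ca@COO+1Ca@CO": 1615.0,
        }
        cfg = TrajectoryConfig(
            n_frames=1000,
            state_fractions={"1Ca@COO": 0.5},
            co_frequencies=freqs,
            seed=15,
        )
        traj = make_trajectory(cfg)
        states, _ = categorize_frames(traj)
        cvd = categorized_vdos(traj, states)
        offset = cvd["1Ca@COO"].peak_frequency() - cvd["none"].peak_frequency()
        assert abs(offset - 25.0) <= cvd["none"].resolution

    def test_absent_category_excluded(self, scheduled_trajectory):
        states, _ = categorize_frames(scheduled_trajectory)
        cvd = categorized_vdos(scheduled_trajectory, states)
        assert "2Ca@COO" in cvd
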