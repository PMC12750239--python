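"""Density profiles, thickness, and the Poisson electrostatic potential."""

import numpy as np
import pytest

from bilayerkit import (
    NoBilayerError,
    SyntheticSpec,
    ZProfile,
    bilayer_thickness,
    electrostatic_potential,
    generate,
    nonlamellar_variant,
    potential_difference,
    z_profile,
)
from bilayerkit.profiles import EPSILON_0, E_CHARGE, _peaks_from_profile

from .conftest import make_point_trajectory


class TestZProfile:
    def test_single_atom_single_slab(self):
        traj = make_point_trajectory([[3.0, 3.0, 5.0]], (6.1, 6.1, 24.1))
        prof = z_profile(traj, None, bin_width=0.1)
        nz = np.flatnonzero(prof.values)
        assert len(nz) == 1
        assert np.isclose(prof.values[nz[0]], 1.0 / (6.1 * 6.1 * 0.1))
        # midplane-centered: the only atom defines the midplane
        assert abs(prof.bin_centers[nz[0]]) < 0.1

    def test_opposite_charges_cancel_in_slab(self):
        traj = make_point_trajectory(
            [[1.0, 1.0, 5.0], [2.0, 2.0, 5.0]],
            (6.1, 6.1, 24.1),
            charges=[1.0, -1.0],
            lipid_ids=[0, 0],
        )
        prof = z_profile(traj, None, bin_width=0.1, quantity="charge")
        assert np.allclose(prof.values, 0.0)

    def test_uniform_atoms_flat_within_poisson_errors(self):
        rng = np.random.default_rng(5)
        n, box = 10_000, (5.0, 5.0, 10.0)
        pos = rng.uniform([0, 0, 0], box, size=(n, 3))
        traj = make_point_trajectory(pos, box)
        prof = z_profile(traj, None, bin_width=0.1)
        slab_vol = 5.0 * 5.0 * 0.1
        expected_count = n / 100
        sigma = np.sqrt(expected_count) / slab_vol
        assert np.all(np.abs(prof.values - n / 250.0) < 5 * sigma)

    def test_density_integral_counts_atoms(self):
        rng = np.random.default_rng(6)
        pos = rng.uniform([0, 0, 0], [5, 5, 10], size=(500, 3))
        traj = make_point_trajectory(pos, (5.0, 5.0, 10.0))
        prof = z_profile(traj, None, bin_width=0.1)
        total = prof.values.sum() * 5.0 * 5.0 * 0.1
        assert abs(total - 500) < 1e-9

    def test_empty_selection_warns_and_zero(self):
        traj = make_point_trajectory([[1.0, 1.0, 5.0]], (5.0, 5.0, 10.0))
        with pytest.warns(UserWarning, match="empty selection"):
            prof = z_profile(traj, lambda a: a.name == "NONE", 0.1)
        assert np.allclose(prof.values, 0.0)

    def test_partial_last_bin_dropped_with_warning(self):
        traj = make_point_trajectory([[1.0, 1.0, 5.0]], (5.0, 5.0, 10.03))
        with pytest.warns(UserWarning, match="partial bin"):
            prof = z_profile(traj, None, 0.1)
        assert len(prof.values) == 100


class TestThickness:
    def test_delta_layers_peak_separation(self):
        z = np.concatenate([np.full(50, 3.0), np.full(50, 7.0)])
        pos = np.column_stack([np.random.default_rng(0).uniform(0, 5, (100, 2)), z])
        traj = make_point_trajectory(pos, (5.0, 5.0, 10.0))
        res = bilayer_thickness(traj, None, bin_width=0.05, smooth_window=1)
        assert np.isclose(res.thickness, 4.0)
        assert res.method == "peak_to_peak"

    @pytest.mark.parametrize("d", [5.0, 6.3, 7.2])
    def test_recovers_generator_head_separation(self, d):
        spec = SyntheticSpec(head_separation=d, n_frames=30, seed=11)
        traj, truth = generate(spec)
        res = bilayer_thickness(traj, lambda a: a.role == "head")
        assert abs(res.thickness - truth.thickness) <= 0.05 + 1e-9

    def test_all_heads_in_one_slab_errors(self):
        pos = np.column_stack(
            [np.random.default_rng(1).uniform(0, 5, (50, 2)), np.full(50, 5.0)]
        )
        traj = make_point_trajectory(pos, (5.0, 5.0, 10.0))
        with pytest.raises(NoBilayerError):
            bilayer_thickness(traj, None)

    def test_nonlamellar_scatter_raises_no_bilayer_peaks(self):
        traj = nonlamellar_variant(SyntheticSpec(n_frames=1, seed=3))
        with pytest.raises(NoBilayerError, match="no bilayer peaks"):
            bilayer_thickness(traj, lambda a: a.role == "head")

    def test_nonlamellar_head_density_not_bimodal(self):
        traj = nonlamellar_variant(SyntheticSpec(n_frames=1, seed=3))
        prof = z_profile(traj, lambda a: a.role == "head", 0.05)
        with pytest.raises(NoBilayerError):
            _peaks_from_profile(prof, 5)


def capacitor_profile(dz=0.01, sep=2.0, sigma=0.05, w_bins=5, length=6.0):
    """Two opposite uniform charge slabs: the parallel-plate oracle."""
    n = int(round(length / dz))
    edges = np.linspace(0.0, length, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rho = np.zeros(n)
    i1 = int(np.argmin(np.abs(centers - (length - sep) / 2)))
    i2 = int(np.argmin(np.abs(centers - (length + sep) / 2)))
    h = w_bins // 2
    w = w_bins * dz
    rho[i1 - h : i1 + h + 1] = sigma / w
    rho[i2 - h : i2 + h + 1] = -sigma / w
    actual_sep = centers[i2] - centers[i1]
    expected = sigma * (E_CHARGE / 1e-18) * actual_sep * 1e-9 / EPSILON_0
    return ZProfile(edges, rho, "charge"), expected


class TestPotential:
    def test_zero_charge_zero_potential(self):
        prof = ZProfile(np.linspace(0, 6, 301), np.zeros(300), "charge")
        pot = electrostatic_potential(prof)
        assert np.allclose(pot.profile.values, 0.0)

    def test_parallel_plate_closed_form(self):
        prof, expected = capacitor_profile(dz=0.01)
        pot = electrostatic_potential(prof)
        dv = potential_difference(pot, "max_minus_min")
        assert dv == pytest.approx(expected, rel=1e-6)
        # sigma = 0.05 e/nm^2 over a 2 nm gap: sigma*d/eps0 = 1.810 V
        assert dv == pytest.approx(1.810, rel=0.01)
        assert pot.profile.values[0] == 0.0

    def test_linearity_in_charge(self):
        prof, _ = capacitor_profile()
        double = ZProfile(prof.bin_edges, 2 * prof.values, "charge")
        v1 = electrostatic_potential(prof).profile.values
        v2 = electrostatic_potential(double).profile.values
        assert np.allclose(v2, 2 * v1)

    def test_requires_charge_profile(self):
        prof = ZProfile(np.linspace(0, 6, 301), np.zeros(300), "number")
        with pytest.raises(ValueError, match="charge"):
            electrostatic_potential(prof)

    def test_flat_profile_zero_difference(self):
        prof = ZProfile(np.linspace(0, 6, 301), np.zeros(300), "charge")
        pot = electrostatic_potential(prof)
        assert potential_difference(pot, "center_vs_bulk") == 0.0
        assert potential_difference(pot, "max_minus_min") == 0.0


class TestNeutralSystemPotential:
    def test_flat_bulk_and_zero_origin(self, default_system):
        traj, truth = default_system
        charge = z_profile(traj, None, 0.05, "charge")
        # overall neutrality of the binned charge
        box = traj.mean_box()
        total = charge.values.sum() * box.lx * box.ly * charge.bin_width
        assert abs(total) < 1e-9
        pot = electrostatic_potential(charge)
        v, z = pot.profile.values, pot.profile.bin_centers
        assert v[0] == 0.0
        for mask in (z < -5.0, z > 5.0):
            assert np.ptp(v[mask]) < 1e-6

    def test_recovers_dipole_layer_plateau(self, default_system):
        traj, truth = default_system
        charge = z_profile(traj, None, 0.05, "charge")
        pot = electrostatic_potential(charge)
        dv = potential_difference(pot, "center_vs_bulk")
        assert dv == pytest.approx(truth.delta_v, rel=0.01)

    def test_conventions_agree_for_symmetric_dipole(self, default_system):
        traj, truth = default_system
        pot = electrostatic_potential(z_profile(traj, None, 0.05, "charge"))
        a = potential_difference(pot, "center_vs_bulk")
        b = potential_difference(pot, "max_minus_min")
        assert a == pytest.approx(b, rel=0.02)

    def test_invariant_to_zero_charge_solvent(self, default_system):
        from bilayerkit.model import SOLVENT, Atom, Topology, Trajectory

        traj, _ = default_system
        pot1 = electrostatic_potential(z_profile(traj, None, 0.05, "charge"))
        # append zero-charge water filler atoms in the bulk region
        rng = np.random.default_rng(9)
        n_w = 500
        box = traj.boxes[0]
        water = rng.uniform([0, 0, 0], box, size=(n_w, 3))
        atoms = list(traj.topology.atoms) + [
            Atom(traj.n_atoms + i, "W", SOLVENT, "SOL") for i in range(n_w)
        ]
        coords = np.concatenate(
            [traj.coordinates, np.tile(water, (traj.n_frames, 1, 1))], axis=1
        )
        solvated = Trajectory(Topology(atoms), coords, traj.times, traj.boxes)
        pot2 = electrostatic_potential(z_profile(solvated, None, 0.05, "charge"))
        assert np.allclose(pot1.profile.values, pot2.profile.values)
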