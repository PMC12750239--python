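"""Intramolecular distances, RDFs against brute-force oracles, end-to-end."""

import numpy as np
import pytest

from bilayerkit import (
    end_to_end_length,
    first_peak_distance,
    first_shell_mean_distance,
    intramolecular_distances,
    rdf,
)
from bilayerkit.distances import RDFResult, SelectorError, resolve_pair
from bilayerkit.model import Atom, Box, Frame, Topology, Trajectory

from .conftest import brute_force_min_image, make_point_trajectory


def pair_trajectory(offset, box=(6.0, 6.0, 6.0), base=(1.0, 1.0, 1.0), n_frames=1):
    """One lipid of two named atoms separated by ``offset``."""
    atoms = [
        Atom(0, "N1", 0, "LIP", role="head"),
        Atom(1, "N2", 0, "LIP", role="other"),
    ]
    pos = np.zeros((n_frames, 2, 3))
    pos[:, 0] = base
    pos[:, 1] = np.mod(np.add(base, offset), box)
    return Trajectory(
        Topology(atoms), pos, np.arange(n_frames, dtype=float) * 50, np.tile(box, (n_frames, 1))
    )


class TestIntramolecular:
    def test_rigid_pair_exact(self):
        traj = pair_trajectory([0.66, 0.0, 0.0])
        res = intramolecular_distances(traj, {"N1_N2": ("N1", "N2")}, n_blocks=1)
        mean, _ = res["N1_N2"]
        assert mean == pytest.approx(0.66, abs=1e-12)

    def test_pair_across_periodic_boundary(self):
        # wrapped coordinates put the partner 5.9 nm away; true distance 0.2
        traj = pair_trajectory([-0.2, 0.0, 0.0], base=(0.1, 1.0, 1.0))
        res = intramolecular_distances(traj, {"p": ("N1", "N2")}, n_blocks=1)
        assert res["p"][0] == pytest.approx(0.2, abs=1e-12)

    def test_jittered_pair_mean_within_sampling_error(self):
        rng = np.random.default_rng(3)
        sigma, n_frames, d0 = 0.02, 400, 0.66
        atoms = [
            Atom(0, "N1", 0, "LIP", role="head"),
            Atom(1, "N2", 0, "LIP", role="other"),
        ]
        pos = np.zeros((n_frames, 2, 3))
        pos[:, 0] = [1.0, 1.0, 1.0]
        pos[:, 1] = [1.0 + d0, 1.0, 1.0]
        pos[:, 1, 0] += rng.normal(0, sigma, n_frames)
        traj = Trajectory(
            Topology(atoms),
            pos,
            np.arange(n_frames) * 50.0,
            np.tile([6.0, 6.0, 6.0], (n_frames, 1)),
        )
        res = intramolecular_distances(traj, {"p": ("N1", "N2")})
        mean, stderr = res["p"]
        assert abs(mean - d0) < 3 * sigma / np.sqrt(n_frames) + sigma**2 / d0
        assert stderr < 3 * sigma / np.sqrt(n_frames)

    def test_ambiguous_selector_names_lipid(self):
        atoms = [
            Atom(0, "C", 0, "LIP", role="other"),
            Atom(1, "C", 0, "LIP", role="other"),
            Atom(2, "N", 0, "LIP", role="head"),
        ]
        top = Topology(atoms)
        with pytest.raises(SelectorError, match="lipid 0.*'C'"):
            resolve_pair(top, 0, "C", "N")

    def test_identical_selector_resolves_two_atoms(self):
        atoms = [
            Atom(0, "C", 0, "LIP", role="sn1", chain_index=1, labels=("terminal",)),
            Atom(1, "C", 0, "LIP", role="sn2", chain_index=1, labels=("terminal",)),
        ]
        top = Topology(atoms)
        assert resolve_pair(top, 0, "label:terminal", "label:terminal") == (0, 1)


class TestRDF:
    def test_two_atoms_single_bin(self):
        pos = np.array([[[1.0, 1.0, 1.0], [1.4, 1.0, 1.0]]])
        traj = make_point_trajectory(pos, (6.0, 6.0, 6.0))
        res = rdf(
            traj,
            lambda a: True,
            lambda a: True,
            r_max=1.0,
            dr=0.01,
        )
        nz = np.flatnonzero(res.counts)
        assert len(nz) == 1
        assert res.r[nz[0]] == pytest.approx(0.4, abs=res.dr)

    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(10)
        box = (5.0, 5.0, 5.0)
        pos = rng.uniform(0, 5, size=(1000, 3))
        traj = make_point_trajectory(pos, box)
        res = rdf(traj, lambda a: True, lambda a: True, r_max=2.0, dr=0.05)
        far = res.r > 0.5
        assert np.all(np.abs(res.g[far] - 1.0) < 0.1)

    def test_matches_27_image_brute_force(self):
        rng = np.random.default_rng(11)
        box = np.array([3.0, 3.0, 3.0])
        n = 20
        pos = rng.uniform(0, 3, size=(n, 3))
        traj = make_point_trajectory(pos, tuple(box))
        dr, r_max = 0.05, 1.4
        res = rdf(traj, lambda a: True, lambda a: True, r_max=r_max, dr=dr)
        # brute force: every ordered pair, nearest of 27 images
        edges = np.arange(0, r_max + dr / 2, dr)
        dists = [
            brute_force_min_image(pos[i], pos[j], box)
            for i in range(n)
            for j in range(n)
            if i != j
        ]
        expected, _ = np.histogram(dists, bins=edges)
        assert np.array_equal(res.counts, expected)

    def test_counting_identity(self):
        rng = np.random.default_rng(13)
        pos = rng.uniform(0, 5, size=(200, 3))
        traj = make_point_trajectory(pos, (5.0, 5.0, 5.0))
        res = rdf(traj, lambda a: True, lambda a: True, r_max=2.0, dr=0.02)
        # integral of g * rho_b * shell equals mean partners per atom
        shell = 4 * np.pi * res.r**2 * res.dr
        integral = np.sum(res.g * res.rho_b * shell)
        assert integral == pytest.approx(res.partners_within(2.0), rel=1e-9)

    def test_same_lipid_pairs_excluded(self):
        atoms = [
            Atom(0, "A", 0, "LIP", role="other"),
            Atom(1, "B", 0, "LIP", role="other"),
        ]
        pos = np.array([[[1.0, 1.0, 1.0], [1.4, 1.0, 1.0]]])
        traj = Trajectory(Topology(atoms), pos, [0.0], [[6.0, 6.0, 6.0]])
        res = rdf(traj, lambda a: True, lambda a: True, r_max=1.0, dr=0.01)
        assert res.counts.sum() == 0

    def test_r_max_bounded_by_half_box(self):
        traj = make_point_trajectory(np.ones((1, 2, 3)), (4.0, 4.0, 4.0))
        with pytest.raises(ValueError, match="half"):
            rdf(traj, lambda a: True, lambda a: True, r_max=2.5, dr=0.01)


class TestFirstPeak:
    def test_lattice_first_shell(self):
        # simple cubic lattice, spacing 0.41 nm: first peak at 0.41
        a = 0.41
        n = 8
        grid = np.array(
            [(i * a, j * a, k * a) for i in range(n) for j in range(n) for k in range(n)]
        )
        traj = make_point_trajectory(grid + a / 2, (n * a, n * a, n * a))
        res = rdf(traj, lambda x: True, lambda x: True, r_max=1.0, dr=0.01)
        peak = first_peak_distance(res, smooth_window=1)
        assert peak == pytest.approx(0.41, abs=0.011)

    def test_monotone_decreasing_is_structureless(self):
        r = np.arange(0.005, 1.0, 0.01)
        g = 1.0 / (1.0 + r)  # decreasing, never a local max above 1
        res = RDFResult(
            r=r, g=g, mode="3d", dr=0.01, counts=np.ones_like(r), n_frames=1,
            n_a=10, rho_b=1.0,
        )
        with pytest.raises(ValueError, match="structureless"):
            first_peak_distance(res, smooth_window=1)

    def test_plateau_tie_breaks_to_lower_bin(self):
        r = np.arange(0.005, 1.0, 0.01)
        g = np.zeros_like(r)
        g[40:43] = 2.0  # flat-topped peak spanning three bins
        res = RDFResult(
            r=r, g=g, mode="3d", dr=0.01, counts=g, n_frames=1, n_a=10, rho_b=1.0
        )
        assert first_peak_distance(res, smooth_window=1) == pytest.approx(r[40])

    def test_first_shell_mean_near_peak(self):
        a = 0.41
        n = 8
        grid = np.array(
            [(i * a, j * a, k * a) for i in range(n) for j in range(n) for k in range(n)]
        )
        traj = make_point_trajectory(grid + a / 2, (n * a, n * a, n * a))
        res = rdf(traj, lambda x: True, lambda x: True, r_max=1.0, dr=0.01)
        assert first_shell_mean_distance(res) == pytest.approx(0.41, abs=0.02)


class TestStructuralClaim:
    def test_intermolecular_first_shell_shorter_than_intramolecular(
        self, default_system
    ):
        traj, truth = default_system
        heads = rdf(
            traj,
            lambda a: a.role == "head",
            lambda a: a.role == "head",
            r_max=1.5,
            dr=0.01,
        )
        inter = first_peak_distance(heads)
        intra = intramolecular_distances(
            traj, {"tt": ("label:terminal", "label:terminal")}
        )["tt"][0]
        assert inter < intra
        assert inter == pytest.approx(truth.neighbor_distance, abs=0.05)
        assert intra == pytest.approx(truth.intramolecular["terminal_terminal"], abs=1e-6)


class TestEndToEnd:
    def _chain(self, n=10, b=0.15):
        atoms = [
            Atom(k - 1, f"C{k}", 0, "LIP", role="sn1", chain_index=k)
            for k in range(1, n + 1)
        ]
        coords = np.zeros((n, 3))
        coords[:, 2] = np.arange(n) * b
        top = Topology(atoms)
        frame = Frame(0.0, coords + 1.0, Box(6.0, 6.0, 6.0))
        return top, frame

    def test_linear_chain_arithmetic(self):
        top, frame = self._chain()
        assert end_to_end_length(top, frame, 0, "C1", "C10") == pytest.approx(1.35)

    def test_same_atom_zero(self):
        top, frame = self._chain()
        assert end_to_end_length(top, frame, 0, "C1", "sn1:1") == 0.0

    def test_doubled_length_approximates_straight_bilayer_thickness(self):
        # a bilayer of straight chains is about twice one extended lipid
        from bilayerkit import SyntheticSpec, bilayer_thickness, generate

        m, b = 10, 0.15
        extension = m * b  # head-to-terminal distance of a straight chain
        spec = SyntheticSpec(
            n_per_leaflet=16,
            chain_beads=m,
            bond_length=b,
            tilt_model={"kind": "fixed", "theta": 0.0},
            head_separation=2 * extension,
            positional_jitter=0.0,
            lateral_D=0.0,
            n_frames=2,
            seed=2,
        )
        traj, _ = generate(spec)
        res = bilayer_thickness(traj, lambda a: a.role == "head")
        assert res.thickness == pytest.approx(2 * extension, abs=0.05)
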