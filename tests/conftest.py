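"""Shared fixtures: small synthetic bilayers and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from bilayerkit import SyntheticSpec, generate, species_map, write_fixture
from bilayerkit.model import Atom, Topology, Trajectory


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    """Default study conditions, shortened to 60 frames for test speed."""
    return SyntheticSpec(n_frames=60, seed=7)


@pytest.fixture(scope="session")
def default_system(default_spec):
    from bilayerkit import assign_leaflets

    traj, truth = generate(default_spec)
    traj.topology = assign_leaflets(traj)
    return traj, truth


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_spec):
    traj, _ = generate(default_spec)
    out = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(traj, out, species_map(default_spec))
    return paths, traj


def brute_force_min_image(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Minimum distance over the 27 neighbor images (independent oracle)."""
    best = np.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in (-1, 0, 1):
                shift = np.array([ix, iy, iz]) * box
                d = np.linalg.norm(b + shift - a)
                best = min(best, d)
    return best


def make_point_trajectory(
    positions: np.ndarray,
    box: tuple[float, float, float],
    charges=None,
    times=None,
    lipid_ids=None,
) -> Trajectory:
    """Trajectory of free point atoms (one per lipid unless grouped)."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[None]
    n = positions.shape[1]
    charges = np.zeros(n) if charges is None else np.asarray(charges, float)
    lids = list(range(n)) if lipid_ids is None else list(lipid_ids)
    atoms = [
        Atom(i, f"X{i}", lids[i], "PT", role="head", charge=float(charges[i]))
        for i in range(n)
    ]
    if times is None:
        times = np.arange(positions.shape[0], dtype=float)
    boxes = np.tile(box, (positions.shape[0], 1))
    return Trajectory(Topology(atoms), positions, np.asarray(times, float), boxes)
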