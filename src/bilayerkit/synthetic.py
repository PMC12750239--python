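"""Synthetic bilayer trajectories with exactly known ground truth.

The generator emulates the statistical structure of an equilibrated
two-leaflet lipid bilayer — headgroup layers at +-d/2, tilted acyl-chain
beads, a z-layered charge distribution, and lateral Brownian motion —
while keeping every observable analytic:

* lipids sit on a jittered square lattice, one per site and leaflet;
* each lipid is **laterally rigid**: its internal geometry is built once
  and the whole molecule then performs a 2-D Gaussian random walk with
  per-component step variance 2 D dt, so the lateral MSD is exactly
  4 D tau in expectation and the true unwrapped tracks are stored;
* both tails are bead chains descending toward the midplane; segment j
  makes a prescribed tilt phi(j) with the normal, all segments of a tail
  sharing one azimuth, so the carbon-(n-1) to carbon-(n+1) chord of
  carbon n makes the exact tilt (phi(n) + phi(n+1))/2 and its order
  parameter is closed-form;
* each lipid carries a +q bead on the inner side of its head and a -q
  bead on the outer side (a dipole bilayer, net charge zero), so the
  transmembrane potential is the parallel-plate closed form
  sigma * 2 delta / eps0 with sigma = n q / (lx ly).

The default parameters mirror a typical ionizable-lipid bilayer system:
75 lipids per leaflet in a 6.1 x 6.1 x 24.1 nm box, head separation
6.3 nm, lateral D of 0.1e-7 cm^2/s, and a tilt schedule rising from 10
to 50 degrees so the S_CD profile decays along the chain.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.integrate import cumulative_trapezoid

from .model import Atom, Topology, Trajectory
from .profiles import EPSILON_0, E_CHARGE

SPECIES_NAME = "SYNL"

#: cm^2/s -> nm^2/ps
_CM2_PER_S_TO_NM2_PER_PS = 100.0


@dataclass
class SyntheticSpec:
    """Generator parameters; every observable is analytic in these."""

    n_per_leaflet: int = 75
    box: tuple[float, float, float] = (6.1, 6.1, 24.1)  # nm
    head_separation: float = 6.3  # nm, bilayer thickness d
    chain_beads: int = 14  # carbons m per tail
    bond_length: float = 0.15  # nm
    tilt_model: dict = field(
        default_factory=lambda: {"kind": "linear", "start": 10.0, "end": 50.0}
    )  # degrees
    lateral_D: float = 0.1e-7  # cm^2/s
    positional_jitter: float = 0.1  # nm, head z jitter sigma
    lattice_jitter: float = 0.03  # nm, xy jitter of lattice sites
    charge_q: float = 0.046  # e, dipole bead charge
    charge_sep: float = 0.15  # nm, half-separation of the head dipole
    n_frames: int = 200
    dt: float = 50.0  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        lx, ly, lz = self.box
        if not self.head_separation < lz - 2.0:
            raise ValueError("head separation must leave a >2 nm water slab (d < lz - 2)")
        if self.chain_beads < 3:
            raise ValueError("chains need at least 3 beads")
        if self.n_per_leaflet < 1 or self.n_frames < 1:
            raise ValueError("counts must be positive")

    # -- analytic geometry -------------------------------------------------

    @property
    def lattice_side(self) -> int:
        return int(math.ceil(math.sqrt(self.n_per_leaflet)))

    @property
    def lattice_spacing(self) -> tuple[float, float]:
        return self.box[0] / self.lattice_side, self.box[1] / self.lattice_side

    def segment_tilts(self) -> np.ndarray:
        """Tilt (radians) of segment j = 1..m from the membrane normal."""
        m = self.chain_beads
        tm = self.tilt_model
        if tm["kind"] == "fixed":
            deg = np.full(m, float(tm["theta"]))
        elif tm["kind"] == "linear":
            deg = np.linspace(float(tm["start"]), float(tm["end"]), m)
        else:
            raise ValueError(f"unknown tilt model {tm['kind']!r}")
        return np.deg2rad(deg)

    def chord_tilts(self) -> np.ndarray:
        """Exact tilt of the C(n-1)->C(n+1) chord, carbons n = 2..m-1."""
        phi = self.segment_tilts()
        return 0.5 * (phi[1:-1] + phi[2:])

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SyntheticSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "box" in data:
            data["box"] = tuple(data["box"])
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = asdict(self)
        data["box"] = list(data["box"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Exact values every observable must recover from the trajectory."""

    thickness: float  # nm
    packing_density: float  # nm^-2
    area_per_lipid: float  # nm^2
    carbon_index: np.ndarray  # 2..m-1
    s_cd: np.ndarray  # per carbon, both chains identical
    diffusion: float  # cm^2/s
    intramolecular: dict[str, float]  # nm, by pair name
    neighbor_distance: float  # nm, nearest lattice spacing
    delta_v: float  # V, closed-form dipole-layer plateau
    rho_z: np.ndarray  # analytic charge density grid, e nm^-3
    rho_grid: np.ndarray  # z (centered, nm) for rho_z
    v_z: np.ndarray  # double-integrated potential on rho_grid, V
    tracks: np.ndarray  # true unwrapped COM xy, (n_frames, n_lipids, 2)
    leaflets: list[str]  # per lipid


def species_map(spec: SyntheticSpec) -> dict:
    """Species map resolving every role/charge/label of the fixture."""
    m = spec.chain_beads
    mid = (m + 1) // 2
    atoms: dict[str, dict] = {
        "HD": {"role": "head", "charge": 0.0},
        "QP": {"role": "other", "charge": float(spec.charge_q)},
        "QM": {"role": "other", "charge": -float(spec.charge_q)},
    }
    for chain, prefix in (("sn1", "A"), ("sn2", "B")):
        for k in range(1, m + 1):
            labels = []
            if k == m:
                labels.append("terminal")
            if k == mid:
                labels.append("unsaturated")
            entry = {"role": chain, "index": k, "charge": 0.0}
            if labels:
                entry["labels"] = labels
            atoms[f"{prefix}{k}"] = entry
    return {"species": {SPECIES_NAME: {"atoms": atoms}}, "solvent": ["SOL"]}


def _build_topology(spec: SyntheticSpec) -> Topology:
    smap = species_map(spec)
    entries = smap["species"][SPECIES_NAME]["atoms"]
    names = list(entries)
    atoms: list[Atom] = []
    aid = 0
    for lid in range(2 * spec.n_per_leaflet):
        for name in names:
            e = entries[name]
            atoms.append(
                Atom(
                    atom_id=aid,
                    name=name,
                    lipid_id=lid,
                    species=SPECIES_NAME,
                    role=e["role"],
                    chain_index=e.get("index"),
                    charge=e["charge"],
                    labels=tuple(e.get("labels", ())),
                )
            )
            aid += 1
    return Topology(atoms)


def _lipid_template(spec: SyntheticSpec, psi: float, sign: float) -> np.ndarray:
    """Coordinates of one lipid relative to its head bead.

    ``sign`` is +1 for the upper leaflet (chains descend in -z).
    Order: HD, QP, QM, A1..Am, B1..Bm.
    """
    m = spec.chain_beads
    b = spec.bond_length
    phi = spec.segment_tilts()
    out = np.zeros((3 + 2 * m, 3))
    out[1] = (0.0, 0.0, -sign * spec.charge_sep)  # QP, inner side
    out[2] = (0.0, 0.0, +sign * spec.charge_sep)  # QM, outer side
    for t, azim in enumerate((psi, psi + np.pi)):
        seg = b * np.column_stack(
            [
                np.sin(phi) * np.cos(azim) * np.ones_like(phi),
                np.sin(phi) * np.sin(azim) * np.ones_like(phi),
                -sign * np.cos(phi),
            ]
        )
        out[3 + t * m : 3 + (t + 1) * m] = np.cumsum(seg, axis=0)
    return out


def _analytic_charge_profile(spec: SyntheticSpec, grid: np.ndarray) -> np.ndarray:
    """Ensemble charge density (e nm^-3) on a midplane-centered grid."""
    lx, ly, _ = spec.box
    sigma_s = spec.n_per_leaflet * spec.charge_q / (lx * ly)  # e nm^-2
    s = spec.positional_jitter
    d2, dq = spec.head_separation / 2.0, spec.charge_sep

    def gauss(z, mu):
        if s == 0:
            out = np.zeros_like(z)
            out[np.argmin(np.abs(z - mu))] = 1.0 / (grid[1] - grid[0])
            return out
        return np.exp(-((z - mu) ** 2) / (2 * s * s)) / (s * np.sqrt(2 * np.pi))

    rho = sigma_s * (
        gauss(grid, d2 - dq)
        - gauss(grid, d2 + dq)
        + gauss(grid, -(d2 - dq))
        - gauss(grid, -(d2 + dq))
    )
    return rho


def generate(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Build the trajectory and its exact ground truth. Deterministic in seed."""
    lx, ly, lz = spec.box
    n = spec.n_per_leaflet
    side = spec.lattice_side
    sx, sy = spec.lattice_spacing
    if min(sx, sy) < 0.3:
        raise ValueError(
            f"lattice cannot host {n} lipids per leaflet in a {lx} x {ly} nm box"
        )
    rng = np.random.default_rng(spec.seed)

    sites = np.array(
        [((i + 0.5) * sx, (j + 0.5) * sy) for i in range(side) for j in range(side)]
    )[:n]
    n_lipids = 2 * n
    m = spec.chain_beads
    apl = 3 + 2 * m  # atoms per lipid

    base = np.empty((n_lipids, apl, 3))
    leaflets: list[str] = []
    lid = 0
    for sign, leaf in ((+1.0, "upper"), (-1.0, "lower")):
        xy = sites + rng.normal(0.0, spec.lattice_jitter, size=sites.shape)
        z_head = sign * spec.head_separation / 2.0 + rng.normal(
            0.0, spec.positional_jitter, size=n
        )
        psi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        for i in range(n):
            head = np.array([xy[i, 0], xy[i, 1], lz / 2.0 + z_head[i]])
            base[lid] = head + _lipid_template(spec, psi[i], sign)
            leaflets.append(leaf)
            lid += 1

    # lateral Brownian motion, rigid per lipid
    d_nm = spec.lateral_D * _CM2_PER_S_TO_NM2_PER_PS  # nm^2/ps
    step_std = math.sqrt(2.0 * d_nm * spec.dt)
    steps = rng.normal(0.0, step_std, size=(spec.n_frames - 1, n_lipids, 2))
    offsets = np.zeros((spec.n_frames, n_lipids, 2))
    if spec.n_frames > 1:
        offsets[1:] = np.cumsum(steps, axis=0)

    coords = np.empty((spec.n_frames, n_lipids * apl, 3))
    flat_base = base.reshape(n_lipids * apl, 3)
    for f in range(spec.n_frames):
        frame = flat_base.copy()
        frame[:, :2] += np.repeat(offsets[f], apl, axis=0)
        coords[f] = np.mod(frame, (lx, ly, lz))

    topology = _build_topology(spec)
    times = np.arange(spec.n_frames) * spec.dt
    boxes = np.tile((lx, ly, lz), (spec.n_frames, 1))
    leaflet_map = {i: leaflets[i] for i in range(n_lipids)}
    traj = Trajectory(topology.with_leaflets(leaflet_map), coords, times, boxes)

    # ---- ground truth ----------------------------------------------------
    tilts = spec.chord_tilts()
    s_cd = 0.5 * (3.0 * np.cos(tilts) ** 2 - 1.0)

    template = _lipid_template(spec, 0.0, +1.0)
    iA = 3 + np.arange(m)
    iB = 3 + m + np.arange(m)
    mid = (m + 1) // 2
    intra = {
        "charge_pair": float(np.linalg.norm(template[1] - template[2])),
        "terminal_terminal": float(np.linalg.norm(template[iA[-1]] - template[iB[-1]])),
        "unsaturated_unsaturated": float(
            np.linalg.norm(template[iA[mid - 1]] - template[iB[mid - 1]])
        ),
        "head_terminal_sn1": float(np.linalg.norm(template[iA[-1]] - template[0])),
    }

    sigma_s = n * spec.charge_q / (lx * ly)  # e nm^-2
    delta_v = (
        sigma_s * (E_CHARGE / 1.0e-18) * (2.0 * spec.charge_sep * 1.0e-9) / EPSILON_0
    )

    grid = np.arange(-lz / 2.0 + 0.005, lz / 2.0, 0.01)
    rho = _analytic_charge_profile(spec, grid)
    first = cumulative_trapezoid(rho, grid, initial=0.0)
    second = cumulative_trapezoid(first, grid, initial=0.0)
    v_z = -(E_CHARGE * 1.0e9 / EPSILON_0) * second

    base_com = base.mean(axis=1)[:, :2]
    tracks = base_com[None, :, :] + offsets

    truth = GroundTruth(
        thickness=spec.head_separation,
        packing_density=n / (lx * ly),
        area_per_lipid=(lx * ly) / n,
        carbon_index=np.arange(2, m),
        s_cd=s_cd,
        diffusion=spec.lateral_D,
        intramolecular=intra,
        neighbor_distance=min(sx, sy),
        delta_v=delta_v,
        rho_z=rho,
        rho_grid=grid,
        v_z=v_z,
        tracks=tracks,
        leaflets=leaflets,
    )
    return traj, truth


def nonlamellar_variant(spec: SyntheticSpec) -> Trajectory:
    """Scattered-head control: no two-layer structure along z.

    Heads are placed uniformly in z over the bilayer region (rather than
    at +-d/2) with random chain descent direction — the signature of a
    collapsed / non-lamellar aggregate.  Thickness estimation on this
    trajectory must fail with its "no bilayer peaks" error.
    """
    lx, ly, lz = spec.box
    n = spec.n_per_leaflet
    side = spec.lattice_side
    sx, sy = spec.lattice_spacing
    rng = np.random.default_rng(spec.seed + 1)
    sites = np.array(
        [((i + 0.5) * sx, (j + 0.5) * sy) for i in range(side) for j in range(side)]
    )[:n]
    m = spec.chain_beads
    apl = 3 + 2 * m
    n_lipids = 2 * n
    span = spec.head_separation / 2.0 + 1.0
    base = np.empty((n_lipids, apl, 3))
    lid = 0
    for _ in range(2):
        xy = sites + rng.normal(0.0, spec.lattice_jitter, size=sites.shape)
        z_head = rng.uniform(-span, span, size=n)
        psi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        signs = rng.choice([-1.0, 1.0], size=n)
        for i in range(n):
            head = np.array([xy[i, 0], xy[i, 1], lz / 2.0 + z_head[i]])
            base[lid] = head + _lipid_template(spec, psi[i], signs[i])
            lid += 1
    coords = np.mod(base.reshape(1, n_lipids * apl, 3), (lx, ly, lz))
    topology = _build_topology(spec)
    return Trajectory(
        topology, coords, np.array([0.0]), np.array([[lx, ly, lz]])
    )


def write_fixture(
    traj: Trajectory, out_dir: str | os.PathLike, smap: dict
) -> dict[str, str]:
    """Emit GRO structure + multi-frame trajectory + species map.

    The files are readable by the structure/trajectory readers with no
    further configuration; returns the paths written.
    """
    from .io import save_species_map, write_gro, write_structure_gro

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "structure": os.path.join(out_dir, "structure.gro"),
        "trajectory": os.path.join(out_dir, "trajectory.gro"),
        "species_map": os.path.join(out_dir, "species_map.yaml"),
    }
    write_structure_gro(traj.topology, traj.frame(0), paths["structure"])
    write_gro(traj, paths["trajectory"])
    save_species_map(smap, paths["species_map"])
    return paths
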