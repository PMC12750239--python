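"""Data model for bilayer trajectories.

A :class:`Trajectory` couples a :class:`Topology` (atoms with lipid
membership, chain roles and partial charges) with time-ordered coordinate
frames in an orthorhombic periodic box.  The membrane normal is fixed to
the z-axis throughout the package; boxes are orthorhombic by contract.

Units follow the GROMACS convention: lengths in nm, times in ps, partial
charges in elementary-charge units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

ROLES = ("head", "sn1", "sn2", "other")
LEAFLETS = ("upper", "lower", "unassigned")

#: lipid_id used for atoms that belong to no lipid (solvent, filler)
SOLVENT = -1


class TopologyError(ValueError):
    """Raised when a topology violates its structural invariants."""


@dataclass(frozen=True)
class Atom:
    """One atom (or coarse bead) with its lipid membership and role.

    ``role`` is one of ``head`` / ``sn1`` / ``sn2`` / ``other``; for the two
    acyl chains ``chain_index`` gives the 1-based carbon position along the
    tail.  ``labels`` carries free-form structural tags (``terminal``,
    ``unsaturated``, ...) used by the distance selectors.
    """

    atom_id: int
    name: str
    lipid_id: int
    species: str
    role: str = "other"
    chain_index: int | None = None
    charge: float = 0.0
    mass: float = 1.0
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TopologyError(
                f"atom {self.name!r}: unknown role {self.role!r} (expected one of {ROLES})"
            )
        if self.role in ("sn1", "sn2") and self.chain_index is None:
            raise TopologyError(
                f"atom {self.name!r}: chain role {self.role!r} requires a carbon index"
            )


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box, edge lengths in nm."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if not (self.lx > 0 and self.ly > 0 and self.lz > 0):
            raise ValueError(f"box lengths must be positive, got {self}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz])

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz

    @property
    def area(self) -> float:
        """Lateral (xy) cross-section, nm^2."""
        return self.lx * self.ly


@dataclass
class Frame:
    """A single coordinate frame: per-atom (x, y, z) in nm plus the box."""

    time: float
    coordinates: np.ndarray
    box: Box

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


class Topology:
    """Ordered atom list plus per-lipid bookkeeping.

    Parameters
    ----------
    atoms:
        Atoms in file order.  Atoms sharing a non-negative ``lipid_id``
        form one lipid molecule; ``lipid_id == SOLVENT`` marks solvent.
    leaflets:
        Optional mapping lipid_id -> ``upper`` / ``lower`` / ``unassigned``.
    """

    def __init__(self, atoms: list[Atom], leaflets: dict[int, str] | None = None):
        self.atoms = list(atoms)
        grouped: dict[int, list[int]] = {}
        for i, a in enumerate(self.atoms):
            if a.lipid_id != SOLVENT:
                grouped.setdefault(a.lipid_id, []).append(i)
        self._lipid_atoms: dict[int, np.ndarray] = {
            lid: np.array(idx) for lid, idx in sorted(grouped.items())
        }
        self.lipid_ids = list(self._lipid_atoms)
        self._validate()
        self.leaflets: dict[int, str] = {lid: "unassigned" for lid in self.lipid_ids}
        if leaflets:
            for lid, leaf in leaflets.items():
                if leaf not in LEAFLETS:
                    raise TopologyError(f"unknown leaflet label {leaf!r}")
                self.leaflets[lid] = leaf

    # -- invariants -------------------------------------------------------

    def _validate(self) -> None:
        for lid, idx in self._lipid_atoms.items():
            members = [self.atoms[i] for i in idx]
            net = sum(a.charge for a in members)
            if abs(net) > 1e-6:
                raise TopologyError(
                    f"lipid {lid} carries net charge {net:.3e} e; lipids must be neutral"
                )
            for chain in ("sn1", "sn2"):
                cidx = [a.chain_index for a in members if a.role == chain]
                if cidx and cidx != list(range(1, len(cidx) + 1)):
                    raise TopologyError(
                        f"lipid {lid}: {chain} carbon indices {cidx} are not "
                        "contiguous 1..m in atom order"
                    )

    # -- queries ----------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_lipids(self) -> int:
        return len(self.lipid_ids)

    def atom_indices_of_lipid(self, lipid_id: int) -> np.ndarray:
        return self._lipid_atoms[lipid_id]

    def lipid_atom_indices(self) -> np.ndarray:
        """Indices of all atoms belonging to any lipid (solvent excluded)."""
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.lipid_id != SOLVENT], dtype=int
        )

    def chain_indices(self, lipid_id: int, chain: str) -> np.ndarray:
        """Atom indices of one acyl chain, ordered by carbon position."""
        members = [
            (a.chain_index, i)
            for i, a in zip(self._lipid_atoms[lipid_id], self.atoms_of(lipid_id))
            if a.role == chain
        ]
        return np.array([i for _, i in sorted(members)], dtype=int)

    def atoms_of(self, lipid_id: int) -> list[Atom]:
        return [self.atoms[i] for i in self._lipid_atoms[lipid_id]]

    def select(self, predicate) -> np.ndarray:
        """Atom indices for which ``predicate(atom)`` is true."""
        return np.array(
            [i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int
        )

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def with_leaflets(self, leaflets: dict[int, str]) -> "Topology":
        return Topology(self.atoms, leaflets)

    def leaflet_lipids(self, leaflet: str) -> list[int]:
        return [lid for lid in self.lipid_ids if self.leaflets[lid] == leaflet]


class Trajectory:
    """Time-ordered frames over one topology, with an analysis window.

    Coordinates are stored as one ``(n_frames, n_atoms, 3)`` array, wrapped
    into the primary box.  ``analysis_window = (t_start, t_end)`` in ps
    restricts which frames the observables average over (the customary
    "equilibrated tail" of a production run); it defaults to the full range.
    """

    def __init__(
        self,
        topology: Topology,
        coordinates: np.ndarray,
        times: np.ndarray,
        boxes: np.ndarray,
        analysis_window: tuple[float, float] | None = None,
    ):
        self.topology = topology
        self.coordinates = np.asarray(coordinates, dtype=float)
        self.times = np.asarray(times, dtype=float)
        self.boxes = np.asarray(boxes, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} does not match "
                f"topology atom count {topology.n_atoms}"
            )
        if self.boxes.shape != (self.n_frames, 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if len(self.times) != self.n_frames:
            raise ValueError("times length must match frame count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if analysis_window is None:
            analysis_window = (float(self.times[0]), float(self.times[-1]))
        self.set_analysis_window(*analysis_window)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def set_analysis_window(self, t_start: float, t_end: float) -> None:
        if t_start > t_end:
            raise ValueError("analysis window start exceeds end")
        if t_start < self.times[0] or t_end > self.times[-1]:
            raise ValueError(
                f"analysis window ({t_start}, {t_end}) outside trajectory time "
                f"range ({self.times[0]}, {self.times[-1]})"
            )
        self.analysis_window = (float(t_start), float(t_end))

    def window_indices(self) -> np.ndarray:
        t0, t1 = self.analysis_window
        return np.flatnonzero((self.times >= t0) & (self.times <= t1))

    def frame(self, i: int) -> Frame:
        return Frame(
            time=float(self.times[i]),
            coordinates=self.coordinates[i],
            box=Box(*self.boxes[i]),
        )

    def mean_box(self) -> Box:
        """Box averaged over the analysis window (grid reference)."""
        idx = self.window_indices()
        return Box(*self.boxes[idx].mean(axis=0))

    def iter_window(self):
        for i in self.window_indices():
            yield i, self.frame(i)


def assign_leaflets(traj: Trajectory) -> Topology:
    """Assign each lipid to the upper or lower leaflet.

    The bilayer midplane is taken as the mean z of all lipid atoms in the
    first analysis frame; a lipid goes to the upper leaflet if the mean z
    of its head atoms lies above the midplane, else to the lower one.
    Lipids without any head atom stay ``unassigned`` with a warning.
    """
    top = traj.topology
    i0 = int(traj.window_indices()[0])
    z = traj.coordinates[i0, :, 2]
    lipid_idx = top.lipid_atom_indices()
    if len(lipid_idx) == 0:
        raise TopologyError("no lipid atoms in topology")
    midplane = float(z[lipid_idx].mean())
    leaflets: dict[int, str] = {}
    for lid in top.lipid_ids:
        head_idx = [
            i for i in top.atom_indices_of_lipid(lid) if top.atoms[i].role == "head"
        ]
        if not head_idx:
            warnings.warn(f"lipid {lid} has no head atom; leaflet unassigned")
            leaflets[lid] = "unassigned"
            continue
        leaflets[lid] = "upper" if z[head_idx].mean() > midplane else "lower"
    counts = {leaf: sum(1 for v in leaflets.values() if v == leaf) for leaf in LEAFLETS}
    if counts["upper"] == 0 or counts["lower"] == 0:
        warnings.warn(
            "all lipid heads fall on one side of the midplane; "
            "this does not look like a bilayer"
        )
    return top.with_leaflets(leaflets)
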