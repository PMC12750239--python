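"""Structure/trajectory readers and writers (GRO, PDB) plus the species map.

File parsing is delegated to :mod:`mdtraj`, which natively works in the
package's units (nm, ps) and reads multi-frame GRO files — the canonical
plain-text fixture format here.  PDB input (Angstrom on disk) comes back
already converted to nm.

Because bespoke lipid force fields rarely ship with published
trajectories, chemical identity is supplied out-of-band: a *species map*
(YAML) keyed by residue and atom name assigns every atom its role
(head / sn1[k] / sn2[k] / other), partial charge, optional mass and
structural labels such as ``terminal`` or ``unsaturated``.
"""

from __future__ import annotations

import os
from typing import Sequence

import mdtraj as md
import numpy as np
import yaml

from .model import SOLVENT, Atom, Box, Frame, Topology, Trajectory


class SpeciesMapError(KeyError):
    """An atom or residue has no entry in the species map."""


# ---------------------------------------------------------------------------
# species map

def load_species_map(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        smap = yaml.safe_load(fh)
    validate_species_map(smap)
    return smap


def save_species_map(smap: dict, path: str | os.PathLike) -> None:
    validate_species_map(smap)
    with open(path, "w") as fh:
        yaml.safe_dump(smap, fh, sort_keys=False)


def validate_species_map(smap: dict) -> None:
    if not isinstance(smap, dict) or "species" not in smap:
        raise SpeciesMapError("species map must contain a top-level 'species' mapping")
    for res, entry in smap["species"].items():
        if "atoms" not in entry:
            raise SpeciesMapError(f"species {res!r}: missing 'atoms' mapping")
        for name, spec in entry["atoms"].items():
            role = spec.get("role", "other")
            if role in ("sn1", "sn2") and "index" not in spec:
                raise SpeciesMapError(
                    f"species {res!r} atom {name!r}: chain role {role!r} needs 'index'"
                )


def _atom_from_map(
    atom_id: int, name: str, resname: str, lipid_id: int, smap: dict
) -> Atom:
    try:
        spec = smap["species"][resname]["atoms"][name]
    except KeyError:
        raise SpeciesMapError(
            f"species map has no entry for atom {name!r} in residue {resname!r}"
        ) from None
    return Atom(
        atom_id=atom_id,
        name=name,
        lipid_id=lipid_id,
        species=resname,
        role=spec.get("role", "other"),
        chain_index=spec.get("index"),
        charge=float(spec.get("charge", 0.0)),
        mass=float(spec.get("mass", 1.0)),
        labels=tuple(spec.get("labels", ())),
    )


def topology_from_mdtraj(md_top: md.Topology, smap: dict) -> Topology:
    """Map an mdtraj topology to a role/charge-annotated :class:`Topology`."""
    solvent_names = set(smap.get("solvent", ["SOL", "HOH", "WAT", "W"]))
    atoms: list[Atom] = []
    lipid_counter = 0
    for res in md_top.residues:
        if res.name in solvent_names:
            for a in res.atoms:
                atoms.append(
                    Atom(a.index, a.name, SOLVENT, res.name, role="other", charge=0.0)
                )
            continue
        if res.name not in smap["species"]:
            raise SpeciesMapError(
                f"residue {res.name!r} is neither a mapped species nor solvent"
            )
        lid = lipid_counter
        lipid_counter += 1
        for a in res.atoms:
            atoms.append(_atom_from_map(a.index, a.name, res.name, lid, smap))
    atoms.sort(key=lambda a: a.atom_id)
    return Topology(atoms)


# ---------------------------------------------------------------------------
# reading

def read_structure(path: str | os.PathLike, species_map: dict | str | os.PathLike):
    """Read a single-conformation GRO/PDB file.

    Returns ``(Topology, Frame)`` with coordinates in nm (PDB input is
    converted from Angstrom).  Atom order is preserved.
    """
    smap = species_map if isinstance(species_map, dict) else load_species_map(species_map)
    t = md.load(str(path))
    if t.unitcell_lengths is None:
        raise ValueError(f"{path}: no periodic box found (missing box/CRYST1 record)")
    top = topology_from_mdtraj(t.topology, smap)
    frame = Frame(
        time=float(t.time[0]),
        coordinates=t.xyz[0].astype(float),
        box=Box(*t.unitcell_lengths[0]),
    )
    return top, frame


def load_trajectory(
    topology: Topology,
    frame_source: str | os.PathLike | Sequence[str | os.PathLike],
    analysis_window: tuple[float, float] | None = None,
) -> Trajectory:
    """Load time-ordered frames (multi-frame GRO, or any mdtraj format).

    Several files are concatenated in the order given.  The analysis
    window defaults to the full time range; pass e.g. the final 100 ns of
    a production run to restrict averaging.
    """
    paths = (
        [frame_source]
        if isinstance(frame_source, (str, os.PathLike))
        else list(frame_source)
    )
    xyz, times, boxes = [], [], []
    for p in paths:
        t = md.load(str(p))
        if t.unitcell_lengths is None:
            raise ValueError(f"{p}: no periodic box found")
        if t.n_atoms != topology.n_atoms:
            raise ValueError(
                f"{p}: frame atom count {t.n_atoms} does not match topology "
                f"atom count {topology.n_atoms}"
            )
        xyz.append(t.xyz.astype(float))
        times.append(t.time.astype(float))
        boxes.append(t.unitcell_lengths.astype(float))
    times_all = np.concatenate(times)
    if np.any(np.diff(times_all) <= 0):
        raise ValueError("frame times are not strictly increasing (duplicate or unordered time stamps)")
    return Trajectory(
        topology,
        np.concatenate(xyz),
        times_all,
        np.concatenate(boxes),
        analysis_window=analysis_window,
    )


# ---------------------------------------------------------------------------
# writing

def _mdtraj_topology(topology: Topology) -> md.Topology:
    from mdtraj.core import element

    md_top = md.Topology()
    chain = md_top.add_chain()
    current = None
    res = None
    for a in topology.atoms:
        key = (a.lipid_id, a.species)
        if key != current:
            resname = a.species if a.lipid_id != SOLVENT else a.species
            res = md_top.add_residue(resname, chain)
            current = key
        # element is irrelevant downstream (masses come from the species map)
        md_top.add_atom(a.name, element.carbon, res)
    return md_top


def write_gro(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write all frames as a multi-frame GRO file (plain text, nm)."""
    t = md.Trajectory(
        traj.coordinates.astype(np.float32),
        _mdtraj_topology(traj.topology),
        time=traj.times,
        unitcell_lengths=traj.boxes.astype(np.float32),
        unitcell_angles=np.full((traj.n_frames, 3), 90.0, dtype=np.float32),
    )
    t.save_gro(str(path))


def write_structure_gro(topology: Topology, frame: Frame, path: str | os.PathLike) -> None:
    """Write a single conformation as GRO."""
    t = md.Trajectory(
        frame.coordinates[None].astype(np.float32),
        _mdtraj_topology(topology),
        time=np.array([frame.time]),
        unitcell_lengths=np.array([frame.box.lengths], dtype=np.float32),
        unitcell_angles=np.array([[90.0, 90.0, 90.0]], dtype=np.float32),
    )
    t.save_gro(str(path))
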