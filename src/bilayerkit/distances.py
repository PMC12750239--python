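"""Intra- and intermolecular chain distances.

Intramolecular distances are minimum-image separations between two named
atoms of the same lipid, averaged over lipids and frames (minimum image
even within a molecule, since wrapped tails can straddle the box).
Intermolecular chain distances follow the standard membrane reading:
compute the radial distribution function g(r) between chain atoms of
*different* lipids and take the position of its first peak as the
nearest-neighbor (first-shell) distance.

Atom selectors
--------------
Pairs are declared with small string selectors, resolved per lipid:

- ``"C9"`` or ``"name:C9"``   — atom name
- ``"role:head"``             — role label
- ``"sn1:5"`` / ``"sn2:5"``   — chain and 1-based carbon position
- ``"label:terminal"``        — structural label from the species map

A selector must resolve to exactly one atom per lipid; as the one
convenient exception, a pair whose two selectors are identical (e.g.
terminal carbon to terminal carbon across the two tails) may resolve to
exactly two atoms, which then form the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import min_image_displacement, pairwise_min_image_distances
from .model import Atom, Frame, Topology, Trajectory
from .profiles import smooth_profile


class SelectorError(ValueError):
    """A pair selector did not resolve to the expected atom count."""


def _selector_predicate(selector: str):
    if ":" not in selector:
        return lambda a: a.name == selector
    kind, _, arg = selector.partition(":")
    if kind == "name":
        return lambda a: a.name == arg
    if kind == "role":
        return lambda a: a.role == arg
    if kind == "label":
        return lambda a: arg in a.labels
    if kind in ("sn1", "sn2"):
        k = int(arg)
        return lambda a: a.role == kind and a.chain_index == k
    raise SelectorError(f"unknown selector kind {kind!r} in {selector!r}")


def resolve_pair(
    topology: Topology, lipid_id: int, sel_a: str, sel_b: str
) -> tuple[int, int]:
    """Resolve a selector pair to two atom indices within one lipid."""
    idx = topology.atom_indices_of_lipid(lipid_id)
    atoms = [topology.atoms[i] for i in idx]
    match_a = [i for i, a in zip(idx, atoms) if _selector_predicate(sel_a)(a)]
    if sel_a == sel_b:
        if len(match_a) != 2:
            raise SelectorError(
                f"lipid {lipid_id}: selector {sel_a!r} used for both pair members "
                f"must match exactly 2 atoms, matched {len(match_a)}"
            )
        return match_a[0], match_a[1]
    match_b = [i for i, a in zip(idx, atoms) if _selector_predicate(sel_b)(a)]
    for sel, match in ((sel_a, match_a), (sel_b, match_b)):
        if len(match) != 1:
            raise SelectorError(
                f"lipid {lipid_id}: selector {sel!r} matched {len(match)} atoms, "
                "expected exactly 1"
            )
    return match_a[0], match_b[0]


def intramolecular_distances(
    traj: Trajectory,
    pairs: dict[str, tuple[str, str]],
    species: str | None = None,
    n_blocks: int = 5,
) -> dict[str, tuple[float, float]]:
    """Mean minimum-image distance per named pair: {name: (mean, stderr)}.

    Per frame the pair distance is averaged over lipids; the stderr is a
    block estimate over the per-frame means.
    """
    from .dynamics import block_error

    top = traj.topology
    lids = [
        lid
        for lid in top.lipid_ids
        if species is None or top.atoms_of(lid)[0].species == species
    ]
    if not lids:
        raise ValueError("no lipids selected")
    frames = traj.window_indices()
    out: dict[str, tuple[float, float]] = {}
    for name, (sel_a, sel_b) in pairs.items():
        ia = np.array([resolve_pair(top, lid, sel_a, sel_b) for lid in lids])
        per_frame = np.empty(len(frames))
        for row, fi in enumerate(frames):
            pos = traj.coordinates[fi]
            d = min_image_displacement(pos[ia[:, 0]], pos[ia[:, 1]], traj.boxes[fi])
            per_frame[row] = np.sqrt(np.sum(d * d, axis=-1)).mean()
        nb = min(n_blocks, len(frames))
        if nb >= 2:
            mean, err = block_error(per_frame, nb)
        else:
            mean, err = float(per_frame.mean()), float("nan")
        out[name] = (mean, err)
    return out


# ---------------------------------------------------------------------------
# RDF

@dataclass
class RDFResult:
    r: np.ndarray  # bin centers, nm
    g: np.ndarray
    mode: str  # "3d" or "lateral"
    dr: float
    counts: np.ndarray  # raw pair counts per bin (all frames)
    n_frames: int
    n_a: int
    rho_b: float  # nm^-3 (3d) or nm^-2 (lateral)

    def partners_within(self, r_max: float) -> float:
        """Mean number of b-partners per a-atom within ``r_max`` (counting
        identity of the normalization)."""
        mask = self.r <= r_max
        return float(self.counts[mask].sum() / (self.n_frames * self.n_a))

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.r, self.g]),
            delimiter="\t",
            header="r_nm\tg",
            comments="",
        )


def rdf(
    traj: Trajectory,
    sel_a,
    sel_b,
    r_max: float,
    dr: float = 0.002,
    mode: str = "3d",
    exclude_same_lipid: bool = True,
) -> RDFResult:
    """Radial distribution function between two selections.

    Pairs are counted under the minimum image; pairs within the same
    lipid are excluded by default (the intermolecular definition).  In
    ``3d`` mode shells are normalized by 4 pi r^2 dr and the volume
    density of the b-selection; in ``lateral`` mode distances are xy-only
    and shells by 2 pi r dr and the areal density.
    """
    if mode not in ("3d", "lateral"):
        raise ValueError(f"unknown RDF mode {mode!r}")
    top = traj.topology
    idx_a = top.select(sel_a) if callable(sel_a) else np.asarray(sel_a, dtype=int)
    idx_b = top.select(sel_b) if callable(sel_b) else np.asarray(sel_b, dtype=int)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("RDF selections must be non-empty")
    box = traj.mean_box()
    if mode == "3d" and r_max > min(box.lx, box.ly, box.lz) / 2.0 + 1e-9:
        raise ValueError("r_max exceeds half the smallest box edge")
    if mode == "lateral" and r_max > min(box.lx, box.ly) / 2.0 + 1e-9:
        raise ValueError("r_max exceeds half the smallest lateral box edge")

    lipid_of = np.array([a.lipid_id for a in top.atoms])
    same_lipid = lipid_of[idx_a][:, None] == lipid_of[idx_b][None, :]
    # solvent atoms (lipid_id == -1) are never "same molecule" as each other
    both_solvent = (lipid_of[idx_a][:, None] < 0) & (lipid_of[idx_b][None, :] < 0)
    exclude = same_lipid & ~both_solvent if exclude_same_lipid else np.zeros_like(same_lipid)
    self_pair = idx_a[:, None] == idx_b[None, :]
    exclude = exclude | self_pair

    n_bins = int(np.round(r_max / dr))
    edges = np.linspace(0.0, n_bins * dr, n_bins + 1)
    counts = np.zeros(n_bins)
    frames = traj.window_indices()
    for fi in frames:
        pos = traj.coordinates[fi]
        L = traj.boxes[fi].copy()
        if mode == "lateral":
            pa, pb, Ld = pos[idx_a][:, :2], pos[idx_b][:, :2], L[:2]
        else:
            pa, pb, Ld = pos[idx_a], pos[idx_b], L
        dmat = pairwise_min_image_distances(pa, pb, Ld)
        dmat = dmat[~exclude]
        hist, _ = np.histogram(dmat, bins=edges)
        counts += hist

    r = 0.5 * (edges[:-1] + edges[1:])
    if mode == "3d":
        rho_b = len(idx_b) / box.volume
        shell = 4.0 * np.pi * r**2 * dr
    else:
        rho_b = len(idx_b) / box.area
        shell = 2.0 * np.pi * r * dr
    g = counts / (len(frames) * len(idx_a) * rho_b * shell)
    return RDFResult(
        r=r,
        g=g,
        mode=mode,
        dr=dr,
        counts=counts,
        n_frames=len(frames),
        n_a=len(idx_a),
        rho_b=rho_b,
    )


def first_peak_distance(rdf_result: RDFResult, smooth_window: int = 5) -> float:
    """Position of the first local maximum of the smoothed g(r).

    This is the nearest-neighbor shell distance, the usual reading of an
    "average intermolecular chain distance" from an RDF.  The peak must
    rise above 1; a plateau tie-breaks to its lower-r bin.  A g(r) with
    no such maximum raises (structureless RDF).
    """
    g = smooth_profile(rdf_result.g, smooth_window)
    for i in range(1, len(g) - 1):
        if g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] > 1.0:
            return float(rdf_result.r[i])
    raise ValueError("structureless RDF: no first peak above g = 1")


def first_shell_mean_distance(rdf_result: RDFResult, smooth_window: int = 5) -> float:
    """Alternative estimator: g-weighted mean r over the first shell.

    The first shell extends from the first peak to the following minimum
    of the smoothed g(r); the mean is weighted by the raw pair counts.
    """
    g = smooth_profile(rdf_result.g, smooth_window)
    i_peak = None
    for i in range(1, len(g) - 1):
        if g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] > 1.0:
            i_peak = i
            break
    if i_peak is None:
        raise ValueError("structureless RDF: no first peak above g = 1")
    i_min = i_peak
    while i_min + 1 < len(g) and g[i_min + 1] <= g[i_min]:
        i_min += 1
    lo = 0
    weights = rdf_result.counts[lo : i_min + 1]
    if weights.sum() == 0:
        raise ValueError("empty first shell")
    return float(np.average(rdf_result.r[lo : i_min + 1], weights=weights))


def end_to_end_length(
    topology: Topology, frame: Frame, lipid_id: int, sel_a: str, sel_b: str
) -> float:
    """Straight-line distance between two selected atoms of one lipid (nm).

    Meant for a single extended conformation (e.g. an energy-minimized
    lipid); doubled, it is comparable to the thickness of a bilayer built
    from straight chains.
    """
    ia, ib = resolve_pair(topology, lipid_id, sel_a, sel_b)
    d = frame.coordinates[ib] - frame.coordinates[ia]
    return float(np.sqrt(np.dot(d, d)))
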