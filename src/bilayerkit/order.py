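"""Deuterium order parameter S_CD along the acyl chains.

For carbon n the orientation is that of the chord from carbon n-1 to
carbon n+1 (minimum image), and

    S_CD(n) = 1/2 < 3 cos^2(theta) - 1 >,

theta being the angle between the chord and the membrane normal (z).
The average runs over lipids within a frame first, then over frames;
uncertainties come from block statistics over the per-frame means, which
respects the strong within-frame correlation between lipids.

S is reported exactly as defined above — no sign flip or absolute value.
S = 1 means chords aligned with the normal, -0.5 in-plane, 0 isotropic.
Terminal carbons (k = 1 and k = m) have no chord and are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import min_image_displacement
from .model import Trajectory


@dataclass
class OrderProfile:
    chain: str
    carbon_index: np.ndarray  # 1-based interior positions, 2..m-1
    s_cd: np.ndarray
    uncertainty: np.ndarray

    def __post_init__(self) -> None:
        self.carbon_index = np.asarray(self.carbon_index, dtype=int)
        self.s_cd = np.asarray(self.s_cd, dtype=float)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        if np.any(self.s_cd < -0.5 - 1e-9) or np.any(self.s_cd > 1.0 + 1e-9):
            raise ValueError("S_CD values must lie in [-0.5, 1.0]")

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.carbon_index, self.s_cd, self.uncertainty]),
            delimiter="\t",
            header=f"carbon_index\ts_cd_{self.chain}\tstderr",
            comments="",
            fmt=("%d", "%.6f", "%.6f"),
        )


def scd_profile(
    traj: Trajectory,
    chain: str = "sn1",
    species: str | None = None,
    n_blocks: int = 5,
) -> OrderProfile:
    """Per-carbon S_CD profile for one acyl chain (``sn1`` or ``sn2``).

    ``species`` restricts the average to lipids of that species; all
    analyzed lipids must carry chains of equal length with at least three
    carbons.
    """
    from .dynamics import block_error

    if chain not in ("sn1", "sn2"):
        raise ValueError(f"chain must be 'sn1' or 'sn2', got {chain!r}")
    top = traj.topology
    lipid_chains = []
    for lid in top.lipid_ids:
        if species is not None and top.atoms_of(lid)[0].species != species:
            continue
        idx = top.chain_indices(lid, chain)
        if len(idx) > 0:
            lipid_chains.append(idx)
    if not lipid_chains:
        raise ValueError(f"no lipids with a {chain} chain in the selection")
    lengths = {len(c) for c in lipid_chains}
    if len(lengths) > 1:
        raise ValueError(
            f"{chain} chains have unequal lengths {sorted(lengths)}; "
            "restrict to one species"
        )
    m = lengths.pop()
    if m < 3:
        raise ValueError(f"{chain} chain has {m} carbons; at least 3 are required")

    chains = np.array(lipid_chains)  # (n_lipids, m)
    frames = traj.window_indices()
    interior = np.arange(2, m)  # 1-based carbons 2..m-1
    per_frame = np.empty((len(frames), len(interior)))
    for row, fi in enumerate(frames):
        pos = traj.coordinates[fi]
        box = traj.boxes[fi]
        prev = pos[chains[:, :-2]]  # carbon n-1
        nxt = pos[chains[:, 2:]]  # carbon n+1
        vec = min_image_displacement(prev, nxt, box)
        norm2 = np.sum(vec * vec, axis=-1)
        cos2 = vec[..., 2] ** 2 / norm2
        s = 0.5 * (3.0 * cos2 - 1.0)
        per_frame[row] = s.mean(axis=0)  # mean over lipids

    nb = min(n_blocks, len(frames))
    means = np.empty(len(interior))
    errs = np.empty(len(interior))
    for j in range(len(interior)):
        if nb >= 2:
            means[j], errs[j] = block_error(per_frame[:, j], nb)
        else:
            means[j], errs[j] = per_frame[:, j].mean(), float("nan")
    return OrderProfile(chain=chain, carbon_index=interior, s_cd=means, uncertainty=errs)
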