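"""z-binned density profiles, headgroup-peak bilayer thickness, and the
transmembrane electrostatic potential.

The membrane normal is z.  Profiles are accumulated in *midplane-centered*
coordinates: for every frame the mean z of all lipid atoms defines the
bilayer midplane, coordinates are shifted so the midplane sits at z = 0,
and the histogram grid is fixed on the analysis-window mean box.  This
cancels slow drift of the bilayer along the normal, which would otherwise
smear the headgroup peaks over a long production run.

The electrostatic potential follows the one-dimensional Poisson equation:
the laterally averaged charge density rho(z) (partial charges per slab
over slab volume) is integrated twice from the start of the profile,

    V(z) = -(1/eps0) * int_0^z dz' int_0^z' rho(z'') dz'',

with V = 0 at the profile origin.  Input charge densities are in
e nm^-3; the output is in volts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks  # noqa: F401  (re-export convenience)

from .model import Trajectory

#: vacuum permittivity, F/m
EPSILON_0 = 8.8541878128e-12
#: elementary charge, C
E_CHARGE = 1.602176634e-19
#: volts per (e nm^-3 integrated twice over nm): e * 1e9 / eps0
_POISSON_PREFACTOR = E_CHARGE * 1.0e9 / EPSILON_0

QUANTITIES = ("number", "charge", "potential")


class NoBilayerError(ValueError):
    """Head density has no two-peak (lamellar) structure."""


@dataclass
class ZProfile:
    """A binned quantity along the membrane normal.

    ``values`` has one entry per bin; units are nm^-3 (number density),
    e nm^-3 (charge density) or V (potential).
    """

    bin_edges: np.ndarray
    values: np.ndarray
    quantity: str
    frames_averaged: int = 1

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown profile quantity {self.quantity!r}")
        if len(self.values) != len(self.bin_edges) - 1:
            raise ValueError("values length must be len(bin_edges) - 1")
        if self.quantity == "number" and np.any(self.values < -1e-12):
            raise ValueError("number densities must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def to_tsv(self, path) -> None:
        header = f"z_center_nm\t{self.quantity}"
        np.savetxt(
            path,
            np.column_stack([self.bin_centers, self.values]),
            delimiter="\t",
            header=header,
            comments="",
        )


@dataclass
class ThicknessResult:
    thickness: float
    peak_lower: float
    peak_upper: float
    uncertainty: float
    method: str = "peak_to_peak"

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError("thickness must be positive")


@dataclass
class PotentialResult:
    profile: ZProfile
    delta_v: float
    convention: str
    epsilon0: float = EPSILON_0


# ---------------------------------------------------------------------------

def _midplane(traj: Trajectory, frame_index: int, lipid_idx: np.ndarray) -> float:
    return float(traj.coordinates[frame_index, lipid_idx, 2].mean())


def _resolve_selection(traj: Trajectory, selection) -> np.ndarray:
    if selection is None:
        return np.arange(traj.n_atoms)
    if callable(selection):
        return traj.topology.select(selection)
    return np.asarray(selection, dtype=int)


def z_profile(
    traj: Trajectory,
    selection=None,
    bin_width: float = 0.05,
    quantity: str = "number",
) -> ZProfile:
    """Mean density profile of the selected atoms along z.

    ``selection`` is an atom predicate (``lambda atom: ...``), an index
    array, or ``None`` for all atoms.  ``quantity`` is ``number`` (counts
    per slab volume) or ``charge`` (summed partial charges per slab
    volume).  Profiles are midplane-centered (see module docstring); the
    grid spans the mean box z-length, and if ``bin_width`` does not divide
    it the last partial bin is dropped with a warning.
    """
    if quantity not in ("number", "charge"):
        raise ValueError(f"z_profile computes 'number' or 'charge', not {quantity!r}")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    frames = traj.window_indices()
    if len(frames) == 0:
        raise ValueError("no frames in the analysis window")
    idx = _resolve_selection(traj, selection)
    if len(idx) == 0:
        warnings.warn("empty selection: returning an all-zero profile")
    lz = traj.mean_box().lz
    n_bins = int(np.floor(lz / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("bin_width exceeds the box z-length")
    span = n_bins * bin_width
    if lz - span > 1e-9 * lz:
        warnings.warn(
            f"bin_width {bin_width} does not divide box z-length {lz:.4f}; "
            "dropping the last partial bin"
        )
    edges = np.linspace(-span / 2.0, span / 2.0, n_bins + 1)
    lipid_idx = traj.topology.lipid_atom_indices()
    if len(lipid_idx) == 0:
        raise ValueError("topology has no lipid atoms to define the midplane")
    charges = traj.topology.charges()[idx] if quantity == "charge" else None

    acc = np.zeros(n_bins)
    for fi in frames:
        lz_f = traj.boxes[fi, 2]
        zc = traj.coordinates[fi, idx, 2] - _midplane(traj, fi, lipid_idx)
        zc = (zc + lz_f / 2.0) % lz_f - lz_f / 2.0  # wrap to [-lz/2, lz/2)
        if quantity == "number":
            hist, _ = np.histogram(zc, bins=edges)
        else:
            hist, _ = np.histogram(zc, bins=edges, weights=charges)
        acc += hist
    box = traj.mean_box()
    slab_volume = box.lx * box.ly * bin_width
    values = acc / (len(frames) * slab_volume)
    return ZProfile(edges, values, quantity, frames_averaged=len(frames))


def smooth_profile(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with reflected edges; window forced odd."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    w = window if window % 2 == 1 else window + 1
    half = w // 2
    padded = np.pad(np.asarray(values, dtype=float), half, mode="reflect")
    kernel = np.ones(w) / w
    return np.convolve(padded, kernel, mode="valid")


def _peaks_from_profile(profile: ZProfile, smooth_window: int):
    """Locate the two headgroup peaks of a (centered) head-density profile.

    Returns (z_lower, z_upper).  Raises :class:`NoBilayerError` when the
    profile lacks the characteristic two-peak lamellar shape — either one
    side carries no density, or the trough between the side maxima is not
    clearly below them (unimodal / structureless density).
    """
    z = profile.bin_centers
    g = smooth_profile(profile.values, smooth_window)
    lower_mask = z < 0
    upper_mask = z > 0
    if not lower_mask.any() or not upper_mask.any():
        raise NoBilayerError("no bilayer peaks: profile does not straddle the midplane")
    if g[lower_mask].max() <= 0 or g[upper_mask].max() <= 0:
        raise NoBilayerError("no bilayer peaks: head density missing on one side")
    i_lo = np.flatnonzero(lower_mask)[np.argmax(g[lower_mask])]
    i_hi = np.flatnonzero(upper_mask)[np.argmax(g[upper_mask])]
    # Lamellar order means the region between the head layers is depleted.
    # Compare the mean density over the central half of the peak-to-peak
    # span with the smaller peak: a flat/scattered (non-lamellar) profile
    # keeps the center at the same level as its noise "peaks".
    q = (i_hi - i_lo) // 4
    central = g[i_lo + q : i_hi - q + 1]
    if len(central) and central.mean() > 0.35 * min(g[i_lo], g[i_hi]):
        raise NoBilayerError(
            "no bilayer peaks: head density is not bimodal across the midplane"
        )
    return float(z[i_lo]), float(z[i_hi])


def bilayer_thickness(
    traj: Trajectory,
    head_selection,
    bin_width: float = 0.05,
    smooth_window: int = 5,
    n_blocks: int = 5,
) -> ThicknessResult:
    """Peak-to-peak headgroup distance: the bilayer thickness.

    The head-atom number-density profile is smoothed with a centered
    moving average and the maximum on each side of the midplane located;
    their separation is the thickness.  The uncertainty is a block
    estimate: the analysis window is split into ``n_blocks`` contiguous
    frame blocks, the thickness recomputed per block, and the standard
    error of the block values reported.
    """
    from .dynamics import block_error

    profile = z_profile(traj, head_selection, bin_width, "number")
    z_lo, z_hi = _peaks_from_profile(profile, smooth_window)
    thickness = z_hi - z_lo

    frames = traj.window_indices()
    block_values = []
    if n_blocks >= 2 and len(frames) >= n_blocks:
        for chunk in np.array_split(frames, n_blocks):
            sub = Trajectory(
                traj.topology,
                traj.coordinates[chunk],
                traj.times[chunk],
                traj.boxes[chunk],
            )
            try:
                p = z_profile(sub, head_selection, bin_width, "number")
                lo, hi = _peaks_from_profile(p, smooth_window)
                block_values.append(hi - lo)
            except NoBilayerError:
                continue
    if len(block_values) >= 2:
        _, stderr = block_error(np.array(block_values), n_blocks=len(block_values))
    else:
        stderr = float("nan")
    return ThicknessResult(
        thickness=thickness, peak_lower=z_lo, peak_upper=z_hi, uncertainty=stderr
    )


# ---------------------------------------------------------------------------

def electrostatic_potential(
    charge_profile: ZProfile, convention: str = "center_vs_bulk"
) -> PotentialResult:
    """Solve the 1-D Poisson equation on a charge-density profile.

    Two successive cumulative trapezoidal integrations over the bin
    centers give V(z) in volts, with V fixed to zero at the profile
    origin (the first bin center, playing the role of the box start).
    """
    if charge_profile.quantity != "charge":
        raise ValueError(
            f"electrostatic_potential needs a charge profile, got {charge_profile.quantity!r}"
        )
    z = charge_profile.bin_centers
    rho = charge_profile.values
    first = cumulative_trapezoid(rho, z, initial=0.0)
    second = cumulative_trapezoid(first, z, initial=0.0)
    v = -_POISSON_PREFACTOR * second
    profile = ZProfile(
        charge_profile.bin_edges, v, "potential", charge_profile.frames_averaged
    )
    result = PotentialResult(profile=profile, delta_v=0.0, convention=convention)
    result.delta_v = potential_difference(result, convention)
    return result


def potential_difference(
    pot: PotentialResult, convention: str = "center_vs_bulk", bulk_width: float = 1.0
) -> float:
    """Potential difference across the bilayer, as a magnitude (V).

    ``center_vs_bulk``: V at the profile center minus the mean V over the
    outermost ``bulk_width`` nm of each end (the bulk-water plateaus),
    averaged over both ends.  ``max_minus_min``: the profile's full range.
    """
    z = pot.profile.bin_centers
    v = pot.profile.values
    if convention == "max_minus_min":
        return float(np.max(v) - np.min(v))
    if convention != "center_vs_bulk":
        raise ValueError(f"unknown potential-difference convention {convention!r}")
    z_mid = 0.5 * (z[0] + z[-1])
    i_mid = int(np.argmin(np.abs(z - z_mid)))
    left = v[z <= z[0] + bulk_width]
    right = v[z >= z[-1] - bulk_width]
    bulk = 0.5 * (left.mean() + right.mean())
    return float(abs(v[i_mid] - bulk))
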