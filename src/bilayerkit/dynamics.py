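"""Packing density, lateral diffusion via the Einstein relation, and the
shared block-averaging error estimator.

Area per lipid (APL) is the lateral box area over the per-leaflet lipid
count; packing density is its reciprocal.  The lateral diffusion
coefficient comes from the 2-D Einstein relation, MSD(tau) = 4 D tau,
fitted over an intermediate lag window of the lipid center-of-mass MSD
computed with sliding time origins.  Uncertainties throughout the
package use block averaging: the series is cut into contiguous blocks
and the spread of block means gives the standard error, which is robust
to the time correlation that makes naive per-frame errors meaningless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import min_image_displacement
from .model import Trajectory

#: nm^2/ps -> cm^2/s
_NM2_PER_PS_TO_CM2_PER_S = 1.0e-2


def block_error(series, n_blocks: int = 5) -> tuple[float, float]:
    """Mean and block-averaged standard error of a correlated series.

    The series is split into ``n_blocks`` contiguous blocks;
    ``stderr = std(block means) / sqrt(n_blocks)``.  Independent
    replicate runs can be fed as additional blocks.
    """
    x = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("n_blocks must be at least 2")
    if len(x) < n_blocks:
        raise ValueError(f"series of length {len(x)} cannot fill {n_blocks} blocks")
    block_means = np.array([b.mean() for b in np.array_split(x, n_blocks)])
    return float(block_means.mean()), float(np.std(block_means) / np.sqrt(n_blocks))


# ---------------------------------------------------------------------------
# packing

@dataclass
class PackingResult:
    area_per_lipid: float  # nm^2, mean over analysis frames
    apl_series: np.ndarray
    packing_density: float  # nm^-2
    uncertainty: float  # stderr of the packing density
    n_leaflet: int


def packing_density(
    traj: Trajectory, n_leaflet: int, n_blocks: int = 5
) -> PackingResult:
    """Packing density 1/APL with APL = <lx*ly> / n_leaflet."""
    if n_leaflet <= 0:
        raise ValueError("n_leaflet must be positive")
    frames = traj.window_indices()
    areas = traj.boxes[frames, 0] * traj.boxes[frames, 1]
    if np.any(areas <= 0):
        raise ValueError("box has zero lateral area")
    apl = areas / n_leaflet
    mean_apl = float(apl.mean())
    density_series = n_leaflet / areas
    if len(frames) >= n_blocks >= 2:
        _, stderr = block_error(density_series, n_blocks)
    else:
        stderr = float("nan")
    return PackingResult(
        area_per_lipid=mean_apl,
        apl_series=apl,
        packing_density=1.0 / mean_apl,
        uncertainty=stderr,
        n_leaflet=n_leaflet,
    )


# ---------------------------------------------------------------------------
# unwrapping and MSD

@dataclass
class LateralTracks:
    """Continuous per-lipid xy center-of-mass tracks over the window."""

    times: np.ndarray  # ps, (n_frames,)
    positions: np.ndarray  # nm, (n_frames, n_lipids, 2), unwrapped
    lipid_ids: list[int]
    leaflets: list[str]


@dataclass
class MSDResult:
    lag_times: np.ndarray  # ps
    msd: np.ndarray  # nm^2
    n_origins: np.ndarray


@dataclass
class DiffusionResult:
    d: float  # cm^2/s
    fit_window: tuple[float, float]  # ps
    r_squared: float
    uncertainty: float  # cm^2/s, from the fit slope

    @property
    def d_1e7(self) -> float:
        """D in units of 1e-7 cm^2/s, the customary reporting scale."""
        return self.d * 1.0e7


def _lipid_com(traj: Trajectory, frame_index: int, lipid_atom_idx, masses) -> np.ndarray:
    """Minimum-image-aware center of mass of one lipid in one frame."""
    pos = traj.coordinates[frame_index, lipid_atom_idx]
    box = traj.boxes[frame_index]
    ref = pos[0]
    rel = min_image_displacement(ref, pos, box)
    w = masses[lipid_atom_idx]
    return ref + (rel * w[:, None]).sum(axis=0) / w.sum()


def unwrap_lateral(traj: Trajectory, lipid_ids=None) -> LateralTracks:
    """Continuous xy tracks of lipid centers of mass.

    Frame-to-frame displacements are minimum-image corrected and
    accumulated, removing the periodic wrap.  A displacement reaching
    half a box edge between consecutive frames is unresolvable and
    raises (frame spacing too coarse).
    """
    top = traj.topology
    lids = list(lipid_ids) if lipid_ids is not None else list(top.lipid_ids)
    if not lids:
        raise ValueError("no lipids to track")
    frames = traj.window_indices()
    if len(frames) < 1:
        raise ValueError("no frames in the analysis window")
    masses = top.masses()
    atom_idx = [top.atom_indices_of_lipid(lid) for lid in lids]
    com = np.empty((len(frames), len(lids), 2))
    for row, fi in enumerate(frames):
        for j, idx in enumerate(atom_idx):
            com[row, j] = _lipid_com(traj, fi, idx, masses)[:2]
    tracks = np.empty_like(com)
    tracks[0] = com[0]
    for row in range(1, len(frames)):
        box_xy = traj.boxes[frames[row], :2]
        step = min_image_displacement(com[row - 1], com[row], box_xy)
        if np.any(np.abs(step) >= box_xy / 2.0):
            raise ValueError(
                "frame spacing too coarse: lateral displacement reaches half a box edge"
            )
        tracks[row] = tracks[row - 1] + step
    return LateralTracks(
        times=traj.times[frames].copy(),
        positions=tracks,
        lipid_ids=lids,
        leaflets=[top.leaflets[lid] for lid in lids],
    )


def lateral_msd(
    tracks: LateralTracks,
    max_lag: float | None = None,
    origin_stride: int = 1,
    remove_drift: bool = True,
) -> MSDResult:
    """Lateral MSD over lipids and sliding time origins.

    ``max_lag`` (ps) defaults to half the track duration.  With
    ``remove_drift`` the per-leaflet center of mass is subtracted per
    frame before differencing, removing collective drift that would
    otherwise inflate the apparent diffusion.
    """
    t = tracks.times
    if len(t) < 2:
        raise ValueError("at least two frames are required for an MSD")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("MSD requires uniformly spaced frames")
    dt = float(dt[0])
    duration = t[-1] - t[0]
    if max_lag is None:
        max_lag = duration / 2.0
    if max_lag >= duration + 1e-9:
        raise ValueError("max_lag must be smaller than the track duration")
    pos = tracks.positions
    if remove_drift:
        pos = pos.copy()
        groups: dict[str, list[int]] = {}
        for j, leaf in enumerate(tracks.leaflets):
            groups.setdefault(leaf, []).append(j)
        for members in groups.values():
            n = len(members)
            if n < 2:
                continue  # cannot separate drift from motion for a lone lipid
            pos[:, members] -= pos[:, members].mean(axis=1, keepdims=True)
            # removing the group COM shrinks each displacement variance by
            # (1 - 1/n); rescale to keep the MSD unbiased
            pos[:, members] *= np.sqrt(n / (n - 1.0))
    n_frames = pos.shape[0]
    max_k = min(int(np.floor(max_lag / dt + 1e-9)), n_frames - 1)
    lags = np.arange(max_k + 1)
    msd = np.zeros(len(lags))
    n_origins = np.zeros(len(lags), dtype=int)
    n_origins[0] = n_frames
    for k in lags[1:]:
        origins = np.arange(0, n_frames - k, origin_stride)
        disp = pos[origins + k] - pos[origins]
        msd[k] = np.mean(np.sum(disp * disp, axis=-1))
        n_origins[k] = len(origins)
    return MSDResult(lag_times=lags * dt, msd=msd, n_origins=n_origins)


def diffusion_coefficient(
    msd: MSDResult, fit_window: tuple[float, float] = (0.1, 0.5)
) -> DiffusionResult:
    """Lateral D from the Einstein relation: slope of MSD(tau) / 4.

    ``fit_window`` is a fraction pair of the maximum lag; the default
    10-50 % skips the short-time regime and the noisy long-lag tail.
    """
    f_lo, f_hi = fit_window
    if not (0 <= f_lo < f_hi <= 1):
        raise ValueError("fit_window must be an increasing fraction pair within [0, 1]")
    tau_max = msd.lag_times[-1]
    t_lo, t_hi = f_lo * tau_max, f_hi * tau_max
    mask = (msd.lag_times >= t_lo) & (msd.lag_times <= t_hi) & (msd.lag_times > 0)
    if mask.sum() < 2:
        raise ValueError("fit window contains fewer than two lag points")
    x = msd.lag_times[mask]
    y = msd.msd[mask]
    A = np.column_stack([x, np.ones_like(x)])
    coef, residuals, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = coef
    fit = A @ coef
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = len(x) - 2
    if dof > 0 and ss_tot > 0:
        sigma2 = ss_res / dof
        slope_var = sigma2 / float(np.sum((x - x.mean()) ** 2))
        slope_err = float(np.sqrt(slope_var))
    else:
        slope_err = 0.0
    d = slope / 4.0 * _NM2_PER_PS_TO_CM2_PER_S
    if d < 0:
        warnings.warn("negative MSD slope; reporting D = 0 (no detectable diffusion)")
        d = 0.0
    return DiffusionResult(
        d=float(d),
        fit_window=(float(t_lo), float(t_hi)),
        r_squared=r2,
        uncertainty=float(slope_err / 4.0 * _NM2_PER_PS_TO_CM2_PER_S),
    )
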