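"""Configuration-driven end-to-end analysis of one bilayer trajectory.

``run`` executes the enabled observables in dependency order (profiles
before thickness and potential, unwrapping before the MSD) and collects
everything into an :class:`ObservableReport` — thickness (nm), lateral
diffusion (10^-7 cm^2/s), packing density (nm^-2) and transmembrane
potential difference (V), each with an uncertainty, plus the attached
S_CD, intramolecular-distance and RDF-peak tables.  A stage failure is
recorded under the stage name and the remaining independent stages still
run.  Every default the user did not set explicitly is logged, since
bin widths, fit windows and potential conventions are exactly the knobs
that published tables rarely state.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import distances as dist
from . import dynamics as dyn
from . import io as bio
from . import order as ordr
from . import profiles as prof
from .model import Trajectory, assign_leaflets

OBSERVABLES = (
    "density",
    "thickness",
    "packing",
    "diffusion",
    "order",
    "potential",
    "distances",
    "rdf",
)

logger = logging.getLogger("bilayerkit")


@dataclass
class RunConfig:
    structure: str
    trajectory: str | list[str]
    species_map: str
    name: str = "system"
    analysis_window: tuple[float, float] | None = None
    observables: list[str] = field(default_factory=lambda: list(OBSERVABLES))
    bin_width: float = 0.05
    smooth_window: int = 5
    n_blocks: int = 5
    head_selection: str = "role:head"
    fit_window: tuple[float, float] = (0.1, 0.5)
    max_lag: float | None = None
    origin_stride: int = 1
    potential_convention: str = "center_vs_bulk"
    n_leaflet: int | None = None
    intra_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    rdf_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    rdf_r_max: float = 1.5
    rdf_dr: float = 0.002
    rdf_mode: str = "3d"
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.observables) - set(OBSERVABLES)
        if unknown:
            raise ValueError(f"unknown observables {sorted(unknown)}")
        paths = [self.structure, self.species_map]
        trajs = self.trajectory if isinstance(self.trajectory, list) else [self.trajectory]
        for p in paths + list(trajs):
            if not os.path.exists(p):
                raise FileNotFoundError(f"configured input does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("analysis_window", "fit_window"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        for key in ("intra_pairs", "rdf_pairs"):
            if data.get(key):
                data[key] = {k: tuple(v) for k, v in data[key].items()}
        return cls(**data)


@dataclass
class ObservableReport:
    """Machine-readable analogue of a bilayer-properties table row."""

    system: str
    observables: dict = field(default_factory=dict)
    s_cd: dict = field(default_factory=dict)
    intramolecular_nm: dict = field(default_factory=dict)
    rdf_first_peak_nm: dict = field(default_factory=dict)
    conventions: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, float) and not np.isfinite(obj):
                return None  # JSON has no NaN
            return obj

        return clean(dataclasses.asdict(self))

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ObservableReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def _selection(selector: str):
    return dist._selector_predicate(selector)


def run(config: RunConfig) -> ObservableReport:
    config.validate()
    out_dir = config.output_dir
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        handler = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    report = ObservableReport(system=config.name)
    report.conventions = {
        "bin_width_nm": config.bin_width,
        "smooth_window_bins": config.smooth_window,
        "n_blocks": config.n_blocks,
        "fit_window_fractions": list(config.fit_window),
        "potential_convention": config.potential_convention,
        "head_selection": config.head_selection,
        "rdf_mode": config.rdf_mode,
        "rdf_dr_nm": config.rdf_dr,
        "thickness_method": "peak_to_peak",
        "diffusion_estimator": "einstein_2d_msd_slope_over_4",
    }
    for key, val in report.conventions.items():
        logger.info("convention %s = %r", key, val)

    try:
        smap = bio.load_species_map(config.species_map)
        topology, _ = bio.read_structure(config.structure, smap)
        traj = bio.load_trajectory(
            topology, config.trajectory, analysis_window=config.analysis_window
        )
        traj.topology = assign_leaflets(traj)
    except Exception as exc:  # input loading failure voids all stages
        report.errors["load"] = f"{type(exc).__name__}: {exc}"
        return report

    head_pred = _selection(config.head_selection)
    upper = traj.topology.leaflet_lipids("upper")
    lower = traj.topology.leaflet_lipids("lower")
    n_leaflet = config.n_leaflet or max(len(upper), len(lower))
    logger.info(
        "leaflets: %d upper / %d lower; n_leaflet=%d", len(upper), len(lower), n_leaflet
    )

    def stage(name):
        def deco(fn):
            if name in config.observables:
                try:
                    fn()
                except Exception as exc:
                    report.errors[name] = f"{type(exc).__name__}: {exc}"
                    logger.error("stage %s failed: %s", name, exc)
            return fn

        return deco

    @stage("density")
    def _density():
        heads = prof.z_profile(traj, head_pred, config.bin_width, "number")
        tails = prof.z_profile(
            traj, lambda a: a.role in ("sn1", "sn2"), config.bin_width, "number"
        )
        if out_dir:
            heads.to_tsv(os.path.join(out_dir, "density_heads.tsv"))
            tails.to_tsv(os.path.join(out_dir, "density_tails.tsv"))

    @stage("thickness")
    def _thickness():
        res = prof.bilayer_thickness(
            traj, head_pred, config.bin_width, config.smooth_window, config.n_blocks
        )
        report.observables["thickness_nm"] = {
            "value": res.thickness,
            "stderr": res.uncertainty,
            "method": res.method,
        }

    @stage("packing")
    def _packing():
        res = dyn.packing_density(traj, n_leaflet, config.n_blocks)
        report.observables["packing_per_nm2"] = {
            "value": res.packing_density,
            "stderr": res.uncertainty,
        }
        report.observables["area_per_lipid_nm2"] = {
            "value": res.area_per_lipid,
            "stderr": float("nan"),
        }

    @stage("potential")
    def _potential():
        charge = prof.z_profile(traj, None, config.bin_width, "charge")
        pot = prof.electrostatic_potential(charge, config.potential_convention)
        frames = traj.window_indices()
        block_dv = []
        if len(frames) >= config.n_blocks >= 2:
            for chunk in np.array_split(frames, config.n_blocks):
                sub = Trajectory(
                    traj.topology,
                    traj.coordinates[chunk],
                    traj.times[chunk],
                    traj.boxes[chunk],
                )
                cp = prof.z_profile(sub, None, config.bin_width, "charge")
                block_dv.append(
                    prof.potential_difference(
                        prof.electrostatic_potential(cp), config.potential_convention
                    )
                )
        stderr = (
            dyn.block_error(np.array(block_dv), len(block_dv))[1]
            if len(block_dv) >= 2
            else float("nan")
        )
        report.observables["potential_difference_v"] = {
            "value": pot.delta_v,
            "stderr": stderr,
            "convention": pot.convention,
        }
        if out_dir:
            pot.profile.to_tsv(os.path.join(out_dir, "potential.tsv"))
            charge.to_tsv(os.path.join(out_dir, "charge_density.tsv"))

    @stage("diffusion")
    def _diffusion():
        tracks = dyn.unwrap_lateral(traj)
        msd = dyn.lateral_msd(
            tracks, max_lag=config.max_lag, origin_stride=config.origin_stride
        )
        res = dyn.diffusion_coefficient(msd, config.fit_window)
        report.observables["diffusion_1e7_cm2_per_s"] = {
            "value": res.d_1e7,
            "stderr": res.uncertainty * 1.0e7,
            "fit_window_ps": list(res.fit_window),
            "r_squared": res.r_squared,
        }
        if out_dir:
            np.savetxt(
                os.path.join(out_dir, "msd.tsv"),
                np.column_stack([msd.lag_times, msd.msd]),
                delimiter="\t",
                header="lag_ps\tmsd_nm2",
                comments="",
            )

    @stage("order")
    def _order():
        for chain in ("sn1", "sn2"):
            p = ordr.scd_profile(traj, chain, n_blocks=config.n_blocks)
            report.s_cd[chain] = [
                [int(k), float(s), float(e)]
                for k, s, e in zip(p.carbon_index, p.s_cd, p.uncertainty)
            ]
            if out_dir:
                p.to_tsv(os.path.join(out_dir, f"s_cd_{chain}.tsv"))

    @stage("distances")
    def _distances():
        if config.intra_pairs:
            res = dist.intramolecular_distances(
                traj, config.intra_pairs, n_blocks=config.n_blocks
            )
            report.intramolecular_nm = {
                name: [float(m), float(e)] for name, (m, e) in res.items()
            }

    @stage("rdf")
    def _rdf():
        for name, (sa, sb) in config.rdf_pairs.items():
            r = dist.rdf(
                traj,
                _selection(sa),
                _selection(sb),
                r_max=config.rdf_r_max,
                dr=config.rdf_dr,
                mode=config.rdf_mode,
            )
            report.rdf_first_peak_nm[name] = dist.first_peak_distance(
                r, config.smooth_window
            )
            if out_dir:
                r.to_tsv(os.path.join(out_dir, f"rdf_{name}.tsv"))

    if out_dir:
        report.save(os.path.join(out_dir, "report.json"))
    return report


def compare_systems(reports: list[ObservableReport]) -> dict:
    """Uncertainty-aware per-observable ordering across systems.

    For every scalar observable present in the reports the systems are
    ranked by value (descending) and each adjacent difference flagged
    significant when it exceeds the combined standard error.
    """
    if len(reports) < 2:
        raise ValueError("at least two reports are required to compare systems")
    keys = set()
    for r in reports:
        keys |= set(r.observables)
    out: dict = {}
    for key in sorted(keys):
        have = [r for r in reports if key in r.observables]
        if len(have) < len(reports):
            warnings.warn(f"observable {key!r} missing from some reports; comparing the rest")
        if len(have) < 2:
            continue
        entries = sorted(
            (
                (r.system, r.observables[key]["value"], r.observables[key].get("stderr"))
                for r in have
            ),
            key=lambda t: t[1],
            reverse=True,
        )
        flags = {}
        for (na, va, ea), (nb, vb, eb) in zip(entries, entries[1:]):
            ea = 0.0 if ea is None or not np.isfinite(ea) else ea
            eb = 0.0 if eb is None or not np.isfinite(eb) else eb
            combined = float(np.hypot(ea, eb))
            flags[f"{na}>{nb}"] = bool(abs(va - vb) > combined)
        out[key] = {
            "ranking": [n for n, _, _ in entries],
            "values": {n: v for n, v, _ in entries},
            "significant": flags,
        }
    return out
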