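"""End-to-end orchestration: simulate → spread → mobility → Ea → free volume.

A run sweeps a water-activity grid and a T - Tg grid with several seeds
(replicate runs — the in-silico analogue of triplicate measurements),
then writes:

* per-run extended-XYZ trajectories and spread-series CSVs,
* ``mobility.csv``    — one row per (a_w, T - Tg, seed),
* ``table1.csv``      — replicate-aggregated mobility table
  (composition, slope k, R², D = |k|/6) per (a_w, T - Tg),
* ``ea.csv``          — Arrhenius activation energies per a_w and seed,
  both from the spread-RMSD route and from per-species from-origin MSD,
  with replicate summaries,
* ``freevol.csv``     — probe-based free volume at selected times,
* ``manifest.json``   — the full config, seeds, package version and a
  config hash; re-running from the manifest reproduces every output
  byte for byte.

Every CSV carries the config hash in a leading comment line, so outputs
from different configurations cannot be mixed silently.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _sstats

from . import __version__
from .cell import DynamicsParams, build_cell, simulate
from .datamodel import LACTOSE, WATER
from .errors import DomainError
from .freevolume import DEFAULT_GRID_SPACING, DEFAULT_PROBE_RADIUS, \
    DEFAULT_RADII, free_volume_frame
from .kinetics import arrhenius_fit, fit_linear_window, mobility_coefficient
from .spread import AnalysisParams, msd_from_origin, total_rmsd
from .trajio import write_table, write_trajectory

log = logging.getLogger("amorphmob")

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Flat, YAML-serialisable configuration of one pipeline run."""

    a_w_grid: list[float] = field(default_factory=lambda: [0.11])
    t_minus_tg_grid: list[float] = field(default_factory=lambda: [0., 10., 20., 30.])
    n_total: int = 100
    seeds: list[int] = field(default_factory=lambda: [1, 2, 3])
    t_min: float = 0.0
    t_max: float = 20.0
    r: float = 9.08
    unwrap: bool = False
    density: float = 0.5
    # dynamics knobs (None -> DynamicsParams defaults)
    dynamics: dict = field(default_factory=dict)
    # free volume
    probe_radius: float = DEFAULT_PROBE_RADIUS
    grid_spacing: float = DEFAULT_GRID_SPACING
    radii: dict = field(default_factory=lambda: dict(DEFAULT_RADII))
    freevol_times: list[float] = field(default_factory=lambda: [0., 20., 100.])
    compute_free_volume: bool = True
    write_trajectories: bool = True

    def __post_init__(self):
        if not self.a_w_grid or not self.t_minus_tg_grid:
            raise DomainError("a_w and T - Tg grids must be non-empty")
        if len(self.seeds) < 1:
            raise DomainError("at least one seed is required")

    def dynamics_params(self) -> DynamicsParams:
        return DynamicsParams(**self.dynamics)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("schema_version", None)
        return cls.from_dict(data)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical JSON form of a config."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class ReplicateSummary:
    """Descriptive statistics of replicate runs.

    sd uses the n - 1 denominator (sd = 0 by convention for n = 1); the
    95% half-width uses the t distribution, and is NaN for n = 1 where a
    CI is undefined.
    """

    mean: float
    sd: float
    n: int
    ci95_half_width: float


def summarize_replicates(values) -> ReplicateSummary:
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 1:
        raise DomainError("summarize_replicates needs at least one value")
    mean = float(vals.mean())
    if vals.size == 1:
        return ReplicateSummary(mean=mean, sd=0.0, n=1,
                                ci95_half_width=float("nan"))
    sd = float(vals.std(ddof=1))
    tcrit = float(_sstats.t.ppf(0.975, vals.size - 1))
    return ReplicateSummary(mean=mean, sd=sd, n=int(vals.size),
                            ci95_half_width=tcrit * sd / np.sqrt(vals.size))


def _run_seed(base_seed: int, i_aw: int, i_t: int) -> np.random.SeedSequence:
    """Independent, reproducible stream per (seed, a_w, T) combination."""
    return np.random.SeedSequence([int(base_seed), i_aw, i_t])


def run_pipeline(config: RunConfig, outdir, force: bool = False) -> dict:
    """Execute the full sweep; returns a dict of output paths.

    Refuses to write into a directory that already holds a manifest
    unless ``force`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        raise DomainError(
            f"{manifest_path} exists; pass force=True to overwrite")
    chash = config_hash(config)
    dyn = config.dynamics_params()
    params = AnalysisParams(r=config.r, unwrap=config.unwrap)

    mobility_rows, freevol_rows, ea_rows = [], [], []
    for i_aw, a_w in enumerate(config.a_w_grid):
        t0 = _time.perf_counter()
        cell = build_cell(a_w, n_total=config.n_total, density=config.density)
        if cell.T_g is None:
            raise DomainError(f"no Tg known for a_w = {a_w}")
        ratio = f"{cell.n_lactose}:{cell.n_water}"
        # D(T) per seed for Arrhenius, keyed by route/species
        d_of_t: dict[tuple, list] = {}
        for i_t, dT in enumerate(config.t_minus_tg_grid):
            T = cell.T_g + dT
            for seed in config.seeds:
                traj = simulate(cell, dyn, T, _run_seed(seed, i_aw, i_t))
                tag = f"aw{a_w}_dT{dT:g}_seed{seed}"
                if config.write_trajectories:
                    write_trajectory(traj, outdir / f"traj_{tag}.xyz")
                series = total_rmsd(traj, params)
                fit = fit_linear_window(series, config.t_min, config.t_max)
                if fit.r_squared < 0.5:
                    log.warning("low R^2 (%.3f) for %s", fit.r_squared, tag)
                mob = mobility_coefficient(fit)
                d_msd = {}
                for sp in (WATER, LACTOSE):
                    msd = msd_from_origin(traj, species=sp, unwrap=True)
                    mfit = fit_linear_window(msd, config.t_min, config.t_max)
                    d_msd[sp] = abs(mfit.k) / 6.0
                write_table(pd.DataFrame({
                    "time_ps": series.times, "rmsd_total_A": series.values}),
                    outdir / f"rmsd_{tag}.csv", config_hash=chash)
                mobility_rows.append({
                    "a_w": a_w, "ratio": ratio, "T_minus_Tg_K": dT, "T_K": T,
                    "seed": seed, "k": fit.k, "b": fit.b,
                    "r_squared": fit.r_squared, "D_A_per_ps": mob.D,
                    "D_msd_water_A2_per_ps": d_msd[WATER],
                    "D_msd_lactose_A2_per_ps": d_msd[LACTOSE]})
                d_of_t.setdefault(("rmsd", "total", seed), []).append((T, mob.D))
                for sp in (WATER, LACTOSE):
                    d_of_t.setdefault(("msd", sp, seed), []).append(
                        (T, d_msd[sp]))
                if config.compute_free_volume:
                    times = list(traj.times)
                    for want in config.freevol_times:
                        idx = int(np.argmin(np.abs(np.array(times) - want)))
                        fv = free_volume_frame(
                            traj.frames[idx], radii=config.radii,
                            probe_radius=config.probe_radius,
                            grid_spacing=config.grid_spacing)
                        freevol_rows.append({
                            "a_w": a_w, "box_side_A": cell.box_side,
                            "density_g_cm3": cell.density,
                            "T_K": T, "T_minus_Tg_K": dT, "seed": seed,
                            "time_ps": fv.time, "total_A3": fv.total_volume,
                            "free_A3": fv.free_volume,
                            "percentage": fv.percentage})
        # Arrhenius per seed and route (needs >= 2 temperatures)
        if len(config.t_minus_tg_grid) >= 2:
            for (route, sp, seed), pts in sorted(d_of_t.items()):
                try:
                    arr = arrhenius_fit(pts)
                except DomainError as exc:
                    log.warning("Arrhenius fit skipped (%s/%s/%s): %s",
                                route, sp, seed, exc)
                    continue
                ea_rows.append({"a_w": a_w, "ratio": ratio, "route": route,
                                "species": sp, "seed": seed,
                                "Ea_kJ_per_mol": arr.Ea, "D0": arr.D0,
                                "r_squared": arr.r_squared})
        log.info("a_w=%s done in %.1f s", a_w, _time.perf_counter() - t0)

    mobility = pd.DataFrame(mobility_rows)
    write_table(mobility, outdir / "mobility.csv", config_hash=chash)

    # replicate-aggregated Table-1-style view
    agg_rows = []
    for (a_w, ratio, dT, T), grp in mobility.groupby(
            ["a_w", "ratio", "T_minus_Tg_K", "T_K"], sort=True):
        row = {"a_w": a_w, "ratio": ratio, "T_minus_Tg_K": dT, "T_K": T}
        for col, name in (("k", "k"), ("r_squared", "r_squared"),
                          ("D_A_per_ps", "D_A_per_ps")):
            s = summarize_replicates(grp[col])
            row[f"{name}_mean"] = s.mean
            row[f"{name}_sd"] = s.sd
            row[f"{name}_ci95"] = s.ci95_half_width
        row["n"] = len(grp)
        agg_rows.append(row)
    write_table(pd.DataFrame(agg_rows), outdir / "table1.csv",
                config_hash=chash)

    outputs = {"mobility": outdir / "mobility.csv",
               "table1": outdir / "table1.csv",
               "manifest": manifest_path}
    if ea_rows:
        ea = pd.DataFrame(ea_rows)
        write_table(ea, outdir / "ea.csv", config_hash=chash)
        ea_agg = []
        for (a_w, ratio, route, sp), grp in ea.groupby(
                ["a_w", "ratio", "route", "species"], sort=True):
            s = summarize_replicates(grp["Ea_kJ_per_mol"])
            ea_agg.append({"a_w": a_w, "ratio": ratio, "route": route,
                           "species": sp, "Ea_mean_kJ_per_mol": s.mean,
                           "Ea_sd": s.sd, "Ea_ci95": s.ci95_half_width,
                           "n": s.n})
        write_table(pd.DataFrame(ea_agg), outdir / "ea_summary.csv",
                    config_hash=chash)
        outputs["ea"] = outdir / "ea.csv"
        outputs["ea_summary"] = outdir / "ea_summary.csv"
    if freevol_rows:
        write_table(pd.DataFrame(freevol_rows), outdir / "freevol.csv",
                    config_hash=chash)
        outputs["freevol"] = outdir / "freevol.csv"

    manifest = {"schema_version": SCHEMA_VERSION,
                "package_version": __version__,
                "config_hash": chash,
                "config": config.to_dict()}
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outputs


def run_from_manifest(manifest_path, outdir, force: bool = False) -> dict:
    """Reproduce a run from its manifest (numeric outputs are identical)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = RunConfig.from_dict(manifest["config"])
    if config_hash(config) != manifest["config_hash"]:
        raise DomainError("manifest config hash mismatch — file edited?")
    return run_pipeline(config, outdir, force=force)


def check_same_config(paths) -> str:
    """Assert all CSVs carry the same config hash; returns it."""
    from .trajio import read_table
    hashes = {}
    for p in paths:
        _, h = read_table(p)
        hashes[str(p)] = h
    uniq = set(hashes.values())
    if len(uniq) != 1 or None in uniq:
        raise DomainError(f"outputs mix configurations: {hashes}")
    return uniq.pop()
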