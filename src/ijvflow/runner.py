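"""Case orchestration: time loops, snapshots, metrics, mesh studies, I/O.

Two presets are provided:

* ``study``: 400 x 30 lumen cells (0.5 mm), 6 s of simulated time with the
  k-omega closure enabled — the study configuration;
* ``desk``: 200 x 16 lumen cells, 3 s, laminar — a reduced configuration on
  which the qualitative flow-disturbance phenomena (jet, separation,
  asymmetry, leaflet distortion) already emerge and which runs in minutes
  on one CPU.

All computation is deterministic given the configuration; the config seed
feeds only the optional inlet-perturbation experiment (a fixed, smooth,
sub-percent distortion of the plug inlet used to trigger jet instability
reproducibly instead of waiting for round-off-seeded symmetry breaking).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .coupling import CouplingConfig, coupled_step
from .fluid import FlowState, ProjectionSolver, reynolds_number, FluidProperties, InletWaveform
from .geometry import (CaseConfig, SimControls, ValveSpec, VesselGeometry,
                       build_valve, standard_cases, wall_mask)
from .grid import Grid
from .metrics import (asymmetry_index, leaflet_asymmetry, max_velocity_vs_x,
                      post_throat_dip, reverse_flow_area, centerline_offset)
from .solid import LeafletState
from .turbulence import (KOmegaCoefficients, TurbulenceState, advance_k_omega,
                         _center_gradients, eddy_viscosity, inlet_k_omega)
from .vtkio import write_polylines, write_structured_points

__all__ = [
    "PRESETS",
    "preset_controls",
    "RunResult",
    "inlet_perturbation_profile",
    "run_case",
    "mesh_independence",
    "compare_cases",
    "poiseuille_case",
]

log = logging.getLogger("ijvflow")

PRESETS = {
    "study": SimControls(nx=400, ny=30, end_time=6.0, turbulence=True,
                         snapshot_times=(0.25, 1.5, 3.0)),
    "desk": SimControls(nx=200, ny=16, end_time=3.0, turbulence=False,
                        snapshot_times=(0.25, 1.5, 3.0)),
}


#: valve discretization matched to the desk grid (node spacing about one cell)
DESK_VALVE = ValveSpec(n_nodes=12)


def desk_cases(seed: int = 1, inlet_perturbation: float = 0.005,
               **overrides) -> list[CaseConfig]:
    """The four standard cases on the desk preset, with the leaflet node
    spacing matched to the coarse grid and the seeded inlet perturbation
    enabled so the jet instability of the severe-stenosis cases is
    triggered reproducibly."""
    ctrl = preset_controls("desk", seed=seed,
                           inlet_perturbation=inlet_perturbation, **overrides)
    return standard_cases(controls=ctrl, valve=DESK_VALVE)


def preset_controls(name: str, **overrides) -> SimControls:
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(base, **overrides) if overrides else base


@dataclass
class RunResult:
    """Outcome of one case run: snapshots, metric tables, provenance."""

    label: str
    config: CaseConfig
    grid: Grid
    mask: np.ndarray
    snapshots: list[dict]                 # {"t", "state", "leaflets"}
    series: pd.DataFrame                  # sampled time series of metrics
    metrics: pd.DataFrame                 # tidy (case, time, metric, value)
    config_hash: str
    seed: int
    files: dict = field(default_factory=dict)

    @property
    def lumen(self) -> np.ndarray:
        return ~self.mask

    def snapshot_at(self, t: float) -> dict:
        err = [abs(s["t"] - t) for s in self.snapshots]
        i = int(np.argmin(err))
        if err[i] > 1e-6:
            raise KeyError(f"no snapshot at t = {t}")
        return self.snapshots[i]

    def time_averaged(self, column: str, t0: float, t1: float) -> float:
        sel = (self.series["t"] >= t0) & (self.series["t"] <= t1)
        return float(self.series.loc[sel, column].mean())

    def roi(self) -> tuple[float, float]:
        """Downstream-of-stenosis region of interest: throat exit to valve anchor."""
        g = self.config.geometry
        return (g.stenosis_center + g.stenosis_length / 2,
                self.config.valve.anchor_x if self.config.valve else g.L)


def inlet_perturbation_profile(grid: Grid, amplitude: float, seed: int
                               ) -> np.ndarray:
    """Fixed smooth multiplicative inlet distortion 1 + amplitude * g(y).

    g is a sum of three low-order transverse sine modes with seeded random
    amplitudes and phases, normalized to max |g| = 1; it is generically
    asymmetric about the midline and deterministic given the seed.
    """
    if amplitude == 0.0:
        return np.ones(grid.ny)
    rng = np.random.default_rng(seed)
    y = grid.y_centers()
    g = np.zeros(grid.ny)
    for n in range(1, 4):
        a = rng.uniform(0.5, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        g += a * np.sin(n * np.pi * y / grid.D + phase)
    g /= np.abs(g).max()
    return 1.0 + amplitude * g


def _metric_row(state: FlowState, grid: Grid, lumen: np.ndarray,
                leaflets: list[LeafletState] | None,
                roi: tuple[float, float]) -> dict:
    rep = reverse_flow_area(state, grid, lumen, x_range=roi)
    # upstream-of-valve restriction: separates stenosis-driven disturbance
    # (fills the whole course in severe cases) from the valve wake common
    # to every case
    upstream = lumen & (grid.x_centers() <= roi[1])[None, :]
    row = {
        "t": state.t,
        "asymmetry_index": asymmetry_index(state, lumen),
        "asymmetry_upstream": asymmetry_index(state, upstream),
        "reverse_area": rep.area,
        "n_recirculation_regions": rep.n_regions,
        "max_speed": float(state.max_speed()),
    }
    if leaflets:
        row["leaflet_asymmetry"] = leaflet_asymmetry(leaflets[1], leaflets[0])
        row["tip_disp_lower"] = float(np.linalg.norm(leaflets[0].tip_displacement()))
        row["tip_disp_upper"] = float(np.linalg.norm(leaflets[1].tip_displacement()))
    return row


def run_case(config: CaseConfig, outdir: str | None = None,
             with_valve: bool = True) -> RunResult:
    """Run one case to its end time, collecting snapshots and metrics.

    Deterministic given the configuration (the only randomness is the
    seeded, fixed inlet-perturbation profile).  Snapshots are taken at the
    configured times that fit inside the end time, plus the final state.
    """
    ctrl = config.controls
    grid = config.grid()
    mask = wall_mask(config.geometry, grid)
    lumen = ~mask
    profile = inlet_perturbation_profile(grid, ctrl.inlet_perturbation, ctrl.seed)
    solver = ProjectionSolver(grid, mask, config.fluid, inlet=config.inlet,
                              inlet_profile=profile,
                              advect=not ctrl.stokes_mode, dt_max=ctrl.dt_max)
    state = solver.initialize_state()
    leaflets: list[LeafletState] | None = None
    if with_valve and config.valve is not None:
        lower, upper = build_valve(config.geometry.D, config.valve)
        leaflets = [lower, upper]
    cpl = CouplingConfig(thickness=config.valve.leaflet_thickness,
                         damping=ctrl.damping) if leaflets else None

    turb: TurbulenceState | None = None
    coeffs = KOmegaCoefficients()
    mu_t = None
    if ctrl.turbulence:
        k_in, om_in = inlet_k_omega(solver.inlet_speed_ms(0.0),
                                    ctrl.turbulence_intensity,
                                    ctrl.turbulence_length_scale)
        turb = TurbulenceState(np.where(lumen, k_in, 0.0),
                               np.full(mask.shape, max(om_in, coeffs.omega_min)))
        mu_t = eddy_viscosity(config.fluid.rho, turb.k, turb.omega)

    re0 = reynolds_number(config.fluid, solver.inlet_speed_ms(0.0),
                          config.geometry.D)
    log.info("case %s: grid %dx%d, Re(inlet, t=0) = %.0f, hash %s",
             config.label, grid.nx, grid.ny_lumen, re0, config.config_hash())

    snap_times = sorted(t for t in ctrl.snapshot_times if t <= ctrl.end_time)
    events = sorted(set(snap_times) | {ctrl.end_time}
                    | set(np.arange(ctrl.metric_sample_dt, ctrl.end_time,
                                    ctrl.metric_sample_dt).round(9)))
    roi = (config.geometry.stenosis_center + config.geometry.stenosis_length / 2,
           config.valve.anchor_x if config.valve else config.geometry.L)

    snapshots: list[dict] = []
    rows: list[dict] = []
    rows.append(_metric_row(state, grid, lumen, leaflets, roi))
    n_steps = 0
    for target in events:
        while state.t < target - 1e-12:
            dt = min(solver.courant_dt(state, ctrl.cfl, mu_t),
                     target - state.t)
            if leaflets:
                state, leaflets, diag = coupled_step(
                    solver, state, leaflets, dt, config.material, cpl,
                    mu_t=mu_t)
            else:
                state = solver.advance(state, dt, mu_t=mu_t)
            if turb is not None:
                uc = 0.5 * (state.u[:, :-1] + state.u[:, 1:])
                vc = 0.5 * (state.v[:-1, :] + state.v[1:, :])
                dudx, dudy = _center_gradients(uc, grid.dx, grid.dy, lumen)
                dvdx, dvdy = _center_gradients(vc, grid.dx, grid.dy, lumen)
                k_in, om_in = inlet_k_omega(solver.inlet_speed_ms(state.t),
                                            ctrl.turbulence_intensity,
                                            ctrl.turbulence_length_scale)
                turb = advance_k_omega(turb, uc, vc, (dudx, dudy, dvdx, dvdy),
                                       dt, grid.dx, grid.dy, lumen,
                                       config.fluid.rho, config.fluid.mu,
                                       coeffs, inlet_bc=(k_in, om_in),
                                       wall_bc=True)
                mu_t = eddy_viscosity(config.fluid.rho, turb.k, turb.omega)
                state.k, state.omega = turb.k, turb.omega
            n_steps += 1
            if n_steps % 100 == 0:
                div = float(np.abs(solver.divergence(state)).max())
                log.info("case %s t=%.3f s dt=%.2e max|u|=%.3f div=%.2e%s",
                         config.label, state.t, dt, state.max_speed(), div,
                         f" clips={turb.clip_events}" if turb else "")
        rows.append(_metric_row(state, grid, lumen, leaflets, roi))
        if any(abs(state.t - ts) < 1e-9 for ts in snap_times) or \
                abs(state.t - ctrl.end_time) < 1e-9:
            snapshots.append({"t": state.t, "state": state.copy(),
                              "leaflets": [l.copy() for l in leaflets] if leaflets else None})

    series = pd.DataFrame(rows).drop_duplicates(subset="t").reset_index(drop=True)
    metrics = _tidy_metrics(config.label, series, snapshots, grid, lumen, roi,
                            config)
    result = RunResult(config.label, config, grid, mask, snapshots, series,
                       metrics, config.config_hash(), ctrl.seed)
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _tidy_metrics(label: str, series: pd.DataFrame, snapshots: list[dict],
                  grid: Grid, lumen: np.ndarray, roi: tuple[float, float],
                  config: CaseConfig) -> pd.DataFrame:
    rows = []
    throat_x = config.geometry.stenosis_center
    for snap in snapshots:
        state = snap["state"]
        prof = max_velocity_vs_x(state, grid, lumen)
        rep = reverse_flow_area(state, grid, lumen, x_range=roi)
        vals = {
            "max_velocity": float(prof.speed.max()),
            "throat_peak": prof.peak_in(throat_x - 0.005, throat_x + 0.005),
            "reverse_area": rep.area,
            "asymmetry_index": asymmetry_index(state, lumen),
            "asymmetry_upstream": asymmetry_index(
                state, lumen & (grid.x_centers() <= roi[1])[None, :]),
            "post_throat_dip": post_throat_dip(prof, throat_x, roi),
            "centerline_offset": centerline_offset(
                state, grid, lumen, 0.5 * (roi[0] + roi[1])),
        }
        if snap["leaflets"]:
            vals["leaflet_asymmetry"] = leaflet_asymmetry(
                snap["leaflets"][1], snap["leaflets"][0])
        for m, v in vals.items():
            rows.append({"case": label, "time": snap["t"], "metric": m,
                         "value": v})
    return pd.DataFrame(rows, columns=["case", "time", "metric", "value"])


def _write_outputs(result: RunResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    files = {}
    from .metrics import cell_center_velocity
    for snap in result.snapshots:
        tag = f"{result.label}_t{snap['t']:.2f}".replace(".", "p")
        state = snap["state"]
        uc, vc = cell_center_velocity(state)
        scalars = {"p": state.p, "speed": np.hypot(uc, vc)}
        if state.k is not None:
            scalars["k"] = state.k
            scalars["omega"] = state.omega
        path = os.path.join(outdir, f"fields_{tag}.vtk")
        write_structured_points(path, result.grid, scalars=scalars,
                                vectors={"velocity": (uc, vc)})
        files[f"fields_{tag}"] = path
        if snap["leaflets"]:
            lp = os.path.join(outdir, f"leaflets_{tag}.vtk")
            write_polylines(lp, [l.x for l in snap["leaflets"]])
            files[f"leaflets_{tag}"] = lp
    mpath = os.path.join(outdir, f"metrics_{result.label}.csv")
    result.metrics.to_csv(mpath, index=False, float_format="%.10g")
    files["metrics"] = mpath
    spath = os.path.join(outdir, f"series_{result.label}.csv")
    result.series.to_csv(spath, index=False, float_format="%.10g")
    files["series"] = spath
    if result.snapshots and result.snapshots[-1]["leaflets"]:
        rows = []
        for snap in result.snapshots:
            for li, leaf in enumerate(snap["leaflets"]):
                for ni, (x, y) in enumerate(leaf.x):
                    rows.append((snap["t"], li, ni, x, y))
        tpath = os.path.join(outdir, f"leaflet_traj_{result.label}.csv")
        pd.DataFrame(rows, columns=["time", "leaflet", "node", "x", "y"]
                     ).to_csv(tpath, index=False, float_format="%.10g")
        files["leaflet_traj"] = tpath
    manifest = {
        "case": result.label,
        "config_hash": result.config_hash,
        "seed": result.seed,
        "version": __version__,
        "files": files,
    }
    mjson = os.path.join(outdir, f"manifest_{result.label}.json")
    with open(mjson, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    files["manifest"] = mjson
    result.files = files


# ----------------------------------------------------------------------
# mesh-independence study
# ----------------------------------------------------------------------

def mesh_independence(config: CaseConfig, ladder: list[tuple[int, int]],
                      with_valve: bool = True) -> pd.DataFrame:
    """Grid-independence table: run the case on successively refined grids
    and record the maximum velocity in the domain at the end time.

    Flags the first resolution whose maximum velocity changes by < 1 % from
    the next finer one.  Non-monotone behaviour is reported as-is.
    """
    if len(ladder) < 3:
        raise ValueError("need at least 3 resolutions for a mesh study")
    rows = []
    for nx, ny in ladder:
        cfg = replace(config, controls=replace(config.controls, nx=nx, ny=ny))
        res = run_case(cfg, with_valve=with_valve)
        final = res.snapshots[-1]["state"]
        prof = max_velocity_vs_x(final, res.grid, res.lumen)
        rows.append({"nx": nx, "ny": ny, "cells": nx * ny,
                     "max_velocity": float(prof.speed.max())})
    df = pd.DataFrame(rows).sort_values("cells").reset_index(drop=True)
    change = np.full(len(df), np.nan)
    for i in range(len(df) - 1):
        change[i] = abs(df.loc[i + 1, "max_velocity"] - df.loc[i, "max_velocity"]) \
            / abs(df.loc[i + 1, "max_velocity"])
    df["rel_change_to_finer"] = change
    df["converged"] = df["rel_change_to_finer"] < 0.01
    return df


# ----------------------------------------------------------------------
# case comparison
# ----------------------------------------------------------------------

def compare_cases(results: list[RunResult], time: float = 3.0) -> dict:
    """Aligned max-velocity profiles and metric ordering across cases.

    Returns a dict with the per-case profile, throat peak, reverse-flow
    area, dip depth and time-averaged asymmetry, plus the peak ordering.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 case results to compare")
    L0 = results[0].config.geometry.L
    if any(abs(r.config.geometry.L - L0) > 1e-12 for r in results):
        raise ValueError("mismatched geometry lengths")
    report: dict = {"time": time, "cases": {}}
    for r in results:
        snap = r.snapshot_at(time)
        prof = max_velocity_vs_x(snap["state"], r.grid, r.lumen)
        geom = r.config.geometry
        roi = r.roi()
        rep = reverse_flow_area(snap["state"], r.grid, r.lumen, x_range=roi)
        t1 = min(time, r.config.controls.end_time)
        entry = {
            "profile_x": prof.x,
            "profile": prof.speed,
            "throat_peak": prof.peak_in(geom.stenosis_center - 0.005,
                                        geom.stenosis_center + 0.005),
            "reverse_area": rep.area,
            "post_throat_dip": post_throat_dip(prof, geom.stenosis_center, roi),
            "asymmetry_avg": r.time_averaged("asymmetry_index",
                                             max(t1 - 1.0, 0.0), t1),
            "asymmetry_upstream_avg": r.time_averaged(
                "asymmetry_upstream", max(t1 - 1.0, 0.0), t1),
        }
        if "leaflet_asymmetry" in r.series:
            entry["leaflet_asymmetry_avg"] = r.time_averaged(
                "leaflet_asymmetry", max(t1 - 1.0, 0.0), t1)
        report["cases"][r.label] = entry
    peaks = {lab: c["throat_peak"] for lab, c in report["cases"].items()}
    report["peak_ordering"] = sorted(peaks, key=peaks.get)
    return report


def comparison_table(report: dict) -> pd.DataFrame:
    rows = []
    for lab, c in report["cases"].items():
        rows.append({"case": lab, "throat_peak": c["throat_peak"],
                     "reverse_area": c["reverse_area"],
                     "post_throat_dip": c["post_throat_dip"],
                     "asymmetry_avg": c["asymmetry_avg"],
                     "asymmetry_upstream_avg": c["asymmetry_upstream_avg"],
                     "leaflet_asymmetry_avg": c.get("leaflet_asymmetry_avg")})
    return pd.DataFrame(rows).sort_values("case").reset_index(drop=True)


# ----------------------------------------------------------------------
# analytic validation configuration
# ----------------------------------------------------------------------

def poiseuille_case(nx: int = 64, ny: int = 32, Re: float = 8.0,
                    U: float = 0.16, end_time: float = 1.2) -> CaseConfig:
    """Straight short channel with a steady plug inlet at mean speed U and
    viscosity scaled so Re = rho U D / mu equals ``Re``.

    At this Reynolds number the flow is fully developed well before the
    outlet, so the exit profile approaches plane Poiseuille flow with
    maximum 1.5 U at the centerline — a closed-form check of the solver.
    """
    D = 0.015
    geom = VesselGeometry(L=2 * D, D=D, stenosis_fraction=0.0)
    props = FluidProperties(rho=1055.0, mu=1055.0 * U * D / Re)
    inlet = InletWaveform(amplitude=0.0, offset=U * 100.0)
    ctrl = SimControls(nx=nx, ny=ny, end_time=end_time,
                       snapshot_times=(), dt_max=5e-3,
                       metric_sample_dt=0.2)
    return CaseConfig(label="poiseuille", geometry=geom, valve=None,
                      fluid=props, inlet=inlet, controls=ctrl)
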