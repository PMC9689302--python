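"""Parametric vessel geometry, stenosis cases and valve layout.

This module is the synthetic case generator.  It builds the idealized 2D
internal-jugular-vein channel (length L = 200 mm, width D = 15 mm), a
nozzle-like stenosis near the inlet that occludes a fraction ``f`` of the
width (open throat gap d1 = (1 - f) * D), and a symmetric two-leaflet valve
downstream whose leaflet tips are separated by a gap d2.  The four standard
cases are

=====  ==========  ==================
label  f           throat gap d1 (mm)
=====  ==========  ==================
A      0.00        15.0   (no stenosis)
B      0.30        10.5
C      0.60        6.0
D      0.75        3.75
=====  ==========  ==================

Coordinates: x runs axially from the inlet (0) to the outlet (L); y from the
lower wall (0) to the upper wall (D).  SI units internally; the config/CLI
surface additionally accepts cm/s for velocities.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

from .grid import Grid
from .fluid import FluidProperties, InletWaveform
from .solid import HyperelasticMaterial, LeafletState

__all__ = [
    "VesselGeometry",
    "ValveSpec",
    "SimControls",
    "CaseConfig",
    "build_vessel",
    "standard_cases",
    "wall_mask",
    "lumen_is_connected",
    "build_valve",
    "load_case",
    "save_case",
]

STANDARD_FRACTIONS = {"A": 0.0, "B": 0.30, "C": 0.60, "D": 0.75}


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class VesselGeometry:
    """Straight channel with an optional bilateral (or one-sided) stenosis.

    Parameters are in meters.  ``stenosis_fraction`` is the occluded
    fraction of the width, so the open gap at the throat is
    ``d1 = (1 - f) * D``.
    """

    L: float = 0.200
    D: float = 0.015
    stenosis_fraction: float = 0.0
    stenosis_center: float = 0.020
    stenosis_length: float = 0.005
    stenosis_profile: str = "step"  # "step" | "cosine"
    one_sided: bool = False

    def __post_init__(self) -> None:
        if self.L <= 0 or self.D <= 0:
            raise ValueError("L and D must be positive")
        if not 0.0 <= self.stenosis_fraction < 1.0:
            raise ValueError("stenosis fraction must satisfy 0 <= f < 1 "
                             "(f >= 1 fully occludes the lumen)")
        if self.stenosis_profile not in ("step", "cosine"):
            raise ValueError(f"unknown stenosis profile {self.stenosis_profile!r}")
        if self.stenosis_fraction > 0:
            xs, ls = self.stenosis_center, self.stenosis_length
            if not (xs - ls / 2 > 0 and xs + ls / 2 < self.L):
                raise ValueError("stenosis must lie strictly inside the vessel")

    @property
    def throat_gap(self) -> float:
        """Open width d1 at the throat: (1 - f) * D."""
        return (1.0 - self.stenosis_fraction) * self.D

    def occlusion_depth(self, x: np.ndarray) -> np.ndarray:
        """Total occluded width as a function of axial position."""
        x = np.asarray(x, dtype=float)
        f, xs, ls = self.stenosis_fraction, self.stenosis_center, self.stenosis_length
        depth = np.zeros_like(x)
        if f == 0:
            return depth
        inside = np.abs(x - xs) <= ls / 2
        if self.stenosis_profile == "step":
            depth[inside] = f * self.D
        else:  # cosine bump, peak f*D at xs, zero at the ends
            depth[inside] = f * self.D * 0.5 * (
                1.0 + np.cos(2.0 * np.pi * (x[inside] - xs) / ls))
        return depth


@dataclass(frozen=True)
class ValveSpec:
    """Two-leaflet valve: straight leaflets anchored on opposite walls.

    The lower leaflet runs from (anchor_x, 0) toward the centerline; the
    upper one is its mirror image about y = D/2.  Tip separation is d2.
    """

    anchor_x: float = 0.110
    leaflet_length: float = 0.010
    leaflet_thickness: float = 0.001
    tip_gap: float = 0.003
    n_nodes: int = 32

    def __post_init__(self) -> None:
        if self.tip_gap <= 0:
            raise ValueError("tip gap d2 must be positive")
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes per leaflet")
        if self.leaflet_length <= 0 or self.leaflet_thickness <= 0:
            raise ValueError("leaflet dimensions must be positive")


@dataclass(frozen=True)
class SimControls:
    """Numerical controls for one case run."""

    nx: int = 400
    ny: int = 30                      # lumen cells across D
    cfl: float = 0.5
    dt_max: float = 2.0e-3
    end_time: float = 6.0
    snapshot_times: tuple[float, ...] = (0.25, 1.5, 3.0)
    turbulence: bool = False
    stokes_mode: bool = False
    turbulence_intensity: float = 0.05
    turbulence_length_scale: float = 0.07 * 0.015
    inlet_perturbation: float = 0.0   # fractional amplitude of inlet distortion
    seed: int = 0                     # seeds the inlet perturbation only
    metric_sample_dt: float = 0.05    # cadence of the metric time series
    damping: float = 0.0              # leaflet Rayleigh damping coefficient


@dataclass(frozen=True)
class CaseConfig:
    label: str
    geometry: VesselGeometry
    valve: ValveSpec | None = ValveSpec()
    fluid: FluidProperties = FluidProperties()
    material: HyperelasticMaterial = HyperelasticMaterial()
    inlet: InletWaveform = InletWaveform()
    controls: SimControls = SimControls()

    def grid(self) -> Grid:
        return Grid(self.geometry.L, self.geometry.D,
                    self.controls.nx, self.controls.ny)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
# constructors
# ----------------------------------------------------------------------

def build_vessel(L: float = 0.200, D: float = 0.015, f: float = 0.0,
                 xs: float = 0.020, ls: float = 0.005,
                 profile: str = "step", *, one_sided: bool = False,
                 valve: ValveSpec | None = None) -> VesselGeometry:
    """Build the parametric vessel; validates the stenosis placement.

    When a ``valve`` is given, a stenosis overlapping the valve anchor
    region is rejected.
    """
    geom = VesselGeometry(L=L, D=D, stenosis_fraction=f, stenosis_center=xs,
                          stenosis_length=ls, stenosis_profile=profile,
                          one_sided=one_sided)
    if valve is not None and f > 0:
        if xs + ls / 2 >= valve.anchor_x - valve.leaflet_length:
            raise ValueError("stenosis overlaps the valve anchor region")
    return geom


def standard_cases(*, controls: SimControls | None = None,
                   valve: ValveSpec | None = None,
                   profile: str = "step") -> list[CaseConfig]:
    """The four standard stenosis cases A-D with identical everything else."""
    controls = controls or SimControls()
    valve = valve or ValveSpec()
    cases = []
    for label, f in STANDARD_FRACTIONS.items():
        geom = build_vessel(f=f, profile=profile, valve=valve)
        cases.append(CaseConfig(label=label, geometry=geom, valve=valve,
                                controls=controls))
    return cases


# ----------------------------------------------------------------------
# rasterization
# ----------------------------------------------------------------------

def wall_mask(geometry: VesselGeometry, grid: Grid) -> np.ndarray:
    """Boolean cell mask, True at solid (wall / stenosis) cells.

    A cell is solid when its center lies inside the wall or inside the
    stenosis occlusion.  Raises if the throat is resolved by fewer than
    4 open cells.
    """
    if not (grid.L == geometry.L and abs(grid.D - geometry.D) < 1e-12):
        raise ValueError("grid does not cover the vessel domain")
    xc = grid.x_centers()
    yc = grid.y_centers()
    mask = np.zeros((grid.ny, grid.nx), dtype=bool)
    mask[yc < 0.0, :] = True
    mask[yc > geometry.D, :] = True

    depth = geometry.occlusion_depth(xc)
    if geometry.one_sided:
        lower = depth
        upper = np.zeros_like(depth)
    else:
        lower = depth / 2
        upper = depth / 2
    yg = yc[:, None]
    mask |= (yg >= 0) & (yg < lower[None, :])
    mask |= (yg <= geometry.D) & (yg > geometry.D - upper[None, :])

    if geometry.stenosis_fraction > 0:
        throat = grid.column_of_x(geometry.stenosis_center)
        n_open = int((~mask[:, throat]).sum())
        if n_open < 4:
            raise ValueError(
                f"grid too coarse: only {n_open} open cells across the throat "
                f"(d1 = {geometry.throat_gap * 1e3:.2f} mm, dy = {grid.dy * 1e3:.2f} mm)")
    return mask


def lumen_is_connected(mask: np.ndarray) -> bool:
    """True when the open (fluid) region is a single 4-connected component."""
    from scipy import ndimage
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    _, n = ndimage.label(~mask, structure=structure)
    return n == 1


# ----------------------------------------------------------------------
# valve
# ----------------------------------------------------------------------

def build_valve(D: float, spec: ValveSpec) -> tuple[LeafletState, LeafletState]:
    """Initial (lower, upper) leaflet states, mirror-symmetric about y = D/2.

    Each leaflet is a straight fiber from its wall anchor to a tip at
    lateral position D/2 -+ d2/2; the two tips are separated by exactly d2.
    The first two nodes are anchored (clamped root, U_solid = 0).
    """
    if spec.tip_gap >= D:
        raise ValueError("tip gap d2 must be smaller than the vessel width D")
    rise = D / 2 - spec.tip_gap / 2          # lateral extent of one leaflet
    if spec.leaflet_length <= rise:
        raise ValueError("leaflet too short to span from wall to tip gap")
    run = float(np.sqrt(spec.leaflet_length ** 2 - rise ** 2))

    s = np.linspace(0.0, 1.0, spec.n_nodes)
    lower_xy = np.column_stack([spec.anchor_x + run * s, rise * s])
    upper_xy = lower_xy.copy()
    upper_xy[:, 1] = D - upper_xy[:, 1]

    anchored = np.zeros(spec.n_nodes, dtype=bool)
    anchored[:2] = True
    lower = LeafletState.from_reference(lower_xy, anchored)
    upper = LeafletState.from_reference(upper_xy, anchored)
    return lower, upper


# ----------------------------------------------------------------------
# declarative case files (YAML)
# ----------------------------------------------------------------------

def save_case(config: CaseConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def load_case(path: str) -> CaseConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["geometry"] = VesselGeometry(**raw["geometry"])
    raw["valve"] = ValveSpec(**raw["valve"]) if raw["valve"] is not None else None
    raw["fluid"] = FluidProperties(**raw["fluid"])
    raw["material"] = HyperelasticMaterial(**raw["material"])
    raw["inlet"] = InletWaveform(**raw["inlet"])
    ctrl = raw["controls"]
    ctrl["snapshot_times"] = tuple(ctrl["snapshot_times"])
    raw["controls"] = SimControls(**ctrl)
    return CaseConfig(**raw)
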