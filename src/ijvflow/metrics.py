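"""Quantification of the flow-disturbance phenomena.

Operationalizes the qualitative findings of the stenosed-vein study:

* the per-cross-section maximum-velocity profile along the vessel,
* reverse-flow (flow-separation) area downstream of the stenosis
  (axial velocity below ``-eps_rev``, with eps_rev = 1e-3 * U_max),
* a mirror-based field asymmetry index in [0, 1],
* lateral offset of the cross-section velocity maximum (jet asymmetry),
* the leaflet-tip distortion asymmetry between upper and lower leaflet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fluid import FlowState
from .grid import Grid
from .solid import LeafletState

__all__ = [
    "MaxVelocityProfile",
    "SeparationReport",
    "AsymmetryReport",
    "cell_center_velocity",
    "max_velocity_vs_x",
    "reverse_flow_area",
    "asymmetry_index",
    "centerline_offset",
    "leaflet_asymmetry",
    "post_throat_dip",
]

REVERSE_FLOW_EPS = 1e-3  # threshold as a fraction of the domain max speed


@dataclass(frozen=True)
class MaxVelocityProfile:
    x: np.ndarray          # axial positions (m), cell centers
    speed: np.ndarray      # per-column maximum speed over the lumen (m/s)
    t: float

    def peak_in(self, x_lo: float, x_hi: float) -> float:
        sel = (self.x >= x_lo) & (self.x <= x_hi)
        return float(self.speed[sel].max())


@dataclass(frozen=True)
class SeparationReport:
    area: float                         # total reverse-flow area (m^2)
    n_regions: int
    boxes: tuple = ()                   # (x_lo, x_hi, y_lo, y_hi) per region
    mean_reverse_speed: tuple = ()      # mean |u| per region (m/s)


@dataclass(frozen=True)
class AsymmetryReport:
    index: float                    # in [0, 1]
    centerline_offset: float        # m, at the profile-peak column
    leaflet_tip_difference: float   # m


def cell_center_velocity(state: FlowState) -> tuple[np.ndarray, np.ndarray]:
    """(u, v) averaged to cell centers."""
    uc = 0.5 * (state.u[:, :-1] + state.u[:, 1:])
    vc = 0.5 * (state.v[:-1, :] + state.v[1:, :])
    return uc, vc


def max_velocity_vs_x(state: FlowState, grid: Grid,
                      lumen: np.ndarray) -> MaxVelocityProfile:
    """Per-column maximum of the speed over lumen cells."""
    uc, vc = cell_center_velocity(state)
    speed = np.hypot(uc, vc)
    speed = np.where(lumen, speed, 0.0)
    return MaxVelocityProfile(grid.x_centers(), speed.max(axis=0), state.t)


def reverse_flow_area(state: FlowState, grid: Grid, lumen: np.ndarray,
                      x_range: tuple[float, float] | None = None,
                      eps_frac: float = REVERSE_FLOW_EPS) -> SeparationReport:
    """Area where the axial velocity is below -eps_rev, with connected
    recirculation regions labeled; restricted to ``x_range`` when given."""
    uc, _ = cell_center_velocity(state)
    u_max = max(float(np.abs(uc[lumen]).max()), 1e-30)
    eps = eps_frac * u_max
    rev = lumen & (uc < -eps)
    if x_range is not None:
        xc = grid.x_centers()
        col = (xc >= x_range[0]) & (xc <= x_range[1])
        rev &= col[None, :]
    labels, n = ndimage.label(rev)
    area = float(rev.sum()) * grid.cell_area()
    boxes, means = [], []
    xc, yc = grid.x_centers(), grid.y_centers()
    for r in range(1, n + 1):
        jj, ii = np.nonzero(labels == r)
        boxes.append((float(xc[ii].min()), float(xc[ii].max()),
                      float(yc[jj].min()), float(yc[jj].max())))
        means.append(float(np.abs(uc[jj, ii]).mean()))
    return SeparationReport(area, n, tuple(boxes), tuple(means))


def asymmetry_index(state: FlowState, lumen: np.ndarray) -> float:
    """Mirror asymmetry of the velocity field about the midline y = D/2:

        index = sum |q - M(q)| / sum (|q| + |M(q)|)

    over lumen cells and both components (the transverse component changes
    sign under mirroring).  0 for a symmetric field, 1 for a purely
    antisymmetric one, invariant under uniform rescaling; defined as 0 for
    the zero field.
    """
    uc, vc = cell_center_velocity(state)
    m = lumen & lumen[::-1, :]
    u_m = uc[::-1, :]
    v_m = -vc[::-1, :]
    num = np.abs(uc - u_m)[m].sum() + np.abs(vc - v_m)[m].sum()
    den = (np.abs(uc) + np.abs(u_m))[m].sum() + (np.abs(vc) + np.abs(v_m))[m].sum()
    if den == 0.0:
        return 0.0
    return float(num / den)


def centerline_offset(state: FlowState, grid: Grid, lumen: np.ndarray,
                      x: float) -> float:
    """Lateral position of the cross-section speed maximum minus D/2, with
    parabolic sub-cell refinement of the peak."""
    uc, vc = cell_center_velocity(state)
    speed = np.where(lumen, np.hypot(uc, vc), -np.inf)
    i = grid.column_of_x(x)
    col = speed[:, i]
    j = int(np.argmax(col))
    yc = grid.y_centers()
    y_peak = yc[j]
    if 0 < j < len(col) - 1 and np.isfinite(col[j - 1]) and np.isfinite(col[j + 1]):
        denom = col[j - 1] - 2 * col[j] + col[j + 1]
        if denom < 0:
            y_peak += 0.5 * grid.dy * (col[j - 1] - col[j + 1]) / denom
    return float(y_peak - grid.D / 2)


def leaflet_asymmetry(upper: LeafletState, lower: LeafletState) -> float:
    """| |d_tip,upper| - |d_tip,lower| | (m), the leaflet distortion
    asymmetry; zero for mirror-symmetric deformations."""
    if upper.n_nodes != lower.n_nodes:
        raise ValueError("leaflets have mismatched discretizations")
    du = np.linalg.norm(upper.tip_displacement())
    dl = np.linalg.norm(lower.tip_displacement())
    return float(abs(du - dl))


def post_throat_dip(profile: MaxVelocityProfile, throat_x: float,
                    roi: tuple[float, float]) -> float:
    """Relative depth of the velocity dip just downstream of the throat:
    (throat peak - profile minimum over the downstream region) / throat peak.
    Near zero when the profile recovers monotonically (mild stenosis)."""
    sel_throat = np.abs(profile.x - throat_x) <= (profile.x[1] - profile.x[0]) * 2
    peak = float(profile.speed[sel_throat].max()) if sel_throat.any() else float(profile.speed.max())
    sel = (profile.x >= roi[0]) & (profile.x <= roi[1])
    if not sel.any() or peak <= 0:
        return 0.0
    dip = (peak - float(profile.speed[sel].min())) / peak
    return max(dip, 0.0)
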