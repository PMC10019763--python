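"""Defect-frame registration and ensemble averaging.

Every +1/2 observation is resampled onto a common grid centered on the core
and rotated so the comet tail lies along +x.  Director patches travel as the
2-theta tensor components (never raw angles: the nematic pi-ambiguity makes
angle means ill-defined); velocity vectors are rotated into the defect frame.
Averaging many registered observations produces the mean orientation/flow
maps around a defect, the axial velocity profile, and the contractile vs
extensile diagnosis from the direction of the core flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .fields import DefectObservation, DirectorField, VelocityField, wrap_nematic


@dataclass
class DefectFramePatch:
    """One observation resampled into the defect frame (core at origin,
    tail along +x).  ``x``/``y`` are defect-frame node coordinates in um."""

    x: np.ndarray
    y: np.ndarray
    cos2: np.ndarray
    sin2: np.ndarray
    dir_mask: np.ndarray
    vx: Optional[np.ndarray] = None
    vy: Optional[np.ndarray] = None
    vel_mask: Optional[np.ndarray] = None

    @property
    def theta(self) -> np.ndarray:
        return wrap_nematic(0.5 * np.arctan2(self.sin2, self.cos2))


@dataclass
class AveragedDefectFrame:
    """Ensemble mean fields in the defect frame with per-node counts."""

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    dir_order: np.ndarray  # norm of the mean 2-theta tensor, in [0, 1]
    n_dir: np.ndarray
    vx: Optional[np.ndarray]
    vy: Optional[np.ndarray]
    n_vel: Optional[np.ndarray]


def register_observation(
    director: DirectorField,
    velocity: Optional[VelocityField],
    obs: DefectObservation,
    half_size_um: float = 150.0,
    grid_step_um: Optional[float] = None,
) -> DefectFramePatch:
    """Resample one +1/2 observation into the canonical defect frame.

    The output grid spans [-half_size, half_size] um in both axes.  A
    defect-frame point (X, Y) maps to the lab position
    ``core + R(psi) @ (X, Y)`` with psi the measured tail direction; director
    angles are shifted by -psi after resampling, velocities rotated by -psi.
    Out-of-field nodes are masked.
    """
    if obs.charge != 0.5:
        raise ValueError("defect-frame registration is defined for +1/2 observations")
    if grid_step_um is None:
        grid_step_um = director.pixel_size
    coords = np.arange(-half_size_um, half_size_um + grid_step_um / 2, grid_step_um)
    X, Y = np.meshgrid(coords, coords)
    psi = obs.axis_angle
    ca, sa = np.cos(psi), np.sin(psi)
    lab_x = obs.position[0] + ca * X - sa * Y
    lab_y = obs.position[1] + sa * X + ca * Y

    # director sampling (pixel indices of the director grid)
    px = (lab_x - director.origin[0]) / director.pixel_size
    py = (lab_y - director.origin[1]) / director.pixel_size
    h, w = director.shape
    dir_mask = (px >= 0) & (px <= w - 1) & (py >= 0) & (py <= h - 1)
    c2, s2 = director.tensor_components()
    cs = ndimage.map_coordinates(c2, [py, px], order=1, mode="nearest")
    ss = ndimage.map_coordinates(s2, [py, px], order=1, mode="nearest")
    # rotate the nematic tensor into the defect frame: theta -> theta - psi
    rot = np.exp(-2j * psi) * (cs + 1j * ss)
    cs, ss = rot.real, rot.imag

    vx = vy = vel_mask = None
    if velocity is not None:
        gx = (lab_x - velocity.x[0]) / velocity.grid_spacing
        gy = (lab_y - velocity.y[0]) / velocity.grid_spacing
        vel_mask = (
            (gx >= 0) & (gx <= velocity.x.size - 1)
            & (gy >= 0) & (gy <= velocity.y.size - 1)
        )
        lab_vx = ndimage.map_coordinates(velocity.vx, [gy, gx], order=1, mode="nearest")
        lab_vy = ndimage.map_coordinates(velocity.vy, [gy, gx], order=1, mode="nearest")
        vmask = ndimage.map_coordinates(
            velocity.valid.astype(float), [gy, gx], order=1, mode="constant", cval=0.0
        )
        vel_mask &= vmask > 0.99
        # rotate vectors by -psi
        vx = ca * lab_vx + sa * lab_vy
        vy = -sa * lab_vx + ca * lab_vy
    return DefectFramePatch(
        x=coords, y=coords, cos2=cs, sin2=ss, dir_mask=dir_mask,
        vx=vx, vy=vy, vel_mask=vel_mask,
    )


def average_frames(
    patches: Sequence[DefectFramePatch],
    min_count: int = 1,
) -> AveragedDefectFrame:
    """Average registered patches node-by-node.

    Directors are averaged through the mean 2-theta tensor (half-angle of the
    resultant); velocities per component over unmasked nodes.  Nodes observed
    fewer than ``min_count`` times are masked (NaN).
    """
    if not patches:
        raise ValueError("no patches to average")
    shape = patches[0].cos2.shape
    sum_c = np.zeros(shape)
    sum_s = np.zeros(shape)
    n_dir = np.zeros(shape)
    sum_vx = np.zeros(shape)
    sum_vy = np.zeros(shape)
    n_vel = np.zeros(shape)
    has_vel = False
    for p in patches:
        if p.cos2.shape != shape:
            raise ValueError("patches must share one grid")
        m = p.dir_mask
        sum_c[m] += p.cos2[m]
        sum_s[m] += p.sin2[m]
        n_dir += m
        if p.vx is not None:
            has_vel = True
            vm = p.vel_mask
            sum_vx[vm] += p.vx[vm]
            sum_vy[vm] += p.vy[vm]
            n_vel += vm
    with np.errstate(invalid="ignore", divide="ignore"):
        mc = np.where(n_dir >= min_count, sum_c / n_dir, np.nan)
        ms = np.where(n_dir >= min_count, sum_s / n_dir, np.nan)
    theta = wrap_nematic(0.5 * np.arctan2(ms, mc))
    theta[~np.isfinite(mc)] = np.nan
    order = np.hypot(mc, ms)
    vx = vy = None
    if has_vel:
        with np.errstate(invalid="ignore", divide="ignore"):
            vx = np.where(n_vel >= min_count, sum_vx / n_vel, np.nan)
            vy = np.where(n_vel >= min_count, sum_vy / n_vel, np.nan)
    return AveragedDefectFrame(
        x=patches[0].x, y=patches[0].y, theta=theta, dir_order=order,
        n_dir=n_dir, vx=vx, vy=vy, n_vel=n_vel if has_vel else None,
    )


def axial_profile(
    frame: AveragedDefectFrame,
    band_halfwidth_um: float = 30.0,
    n_bins: int = 21,
) -> dict[str, np.ndarray]:
    """Axial velocity profile v_x(x) in a band |y| <= band_halfwidth.

    Returns bin centers (x, um), the mean axial velocity, the SEM across the
    contributing nodes and the node count per bin.  x < 0 is the head side,
    x > 0 the tail side, x = 0 the core.
    """
    if band_halfwidth_um <= 0:
        raise ValueError("band_halfwidth_um must be positive")
    if frame.vx is None:
        raise ValueError("averaged frame carries no velocity")
    X, Y = np.meshgrid(frame.x, frame.y)
    band = (np.abs(Y) <= band_halfwidth_um) & np.isfinite(frame.vx)
    edges = np.linspace(frame.x[0], frame.x[-1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    xb = X[band]
    vb = frame.vx[band]
    idx = np.clip(np.digitize(xb, edges) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        vals = vb[idx == b]
        count[b] = vals.size
        if vals.size:
            mean[b] = vals.mean()
            sem[b] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
    return {"x_um": centers, "v_axial_umh": mean, "sem": sem, "n": count}


def contractility_sign(
    frame: AveragedDefectFrame,
    core_radius_um: float = 30.0,
    noise_floor_umh: float = 0.5,
) -> dict[str, object]:
    """Diagnose the active-stress sign from the mean core flow.

    In a contractile system the +1/2 core flow points toward the tail (+x in
    the defect frame); extensile systems drive it toward the head.  Also
    reports the antisymmetry of the vorticity about the defect axis
    (counter-rotating vortex pair) as a correlation score in [-1, 1].
    """
    if frame.vx is None:
        raise ValueError("averaged frame carries no velocity")
    X, Y = np.meshgrid(frame.x, frame.y)
    core = (np.hypot(X, Y) <= core_radius_um) & np.isfinite(frame.vx)
    if not core.any():
        return {"sign": "indeterminate", "core_axial_umh": np.nan, "vorticity_antisymmetry": np.nan}
    u_core = float(frame.vx[core].mean())
    if u_core > noise_floor_umh:
        sign = "contractile"
    elif u_core < -noise_floor_umh:
        sign = "extensile"
    else:
        sign = "indeterminate"
    # vorticity antisymmetry about y = 0: omega(x, -y) ~ -omega(x, y)
    step = float(frame.x[1] - frame.x[0])
    vx = np.nan_to_num(frame.vx)
    vy = np.nan_to_num(frame.vy)
    omega = np.gradient(vy, step, axis=1) - np.gradient(vx, step, axis=0)
    flipped = omega[::-1, :]
    num = -np.nansum(omega * flipped)
    den = np.nansum(omega**2)
    antisym = float(num / den) if den > 0 else np.nan
    return {"sign": sign, "core_axial_umh": u_core, "vorticity_antisymmetry": antisym}


# ---------------------------------------------------------------------------
# cell density


def density_map(
    points_um: np.ndarray,
    fov_um: tuple[float, float],
    window_um: float = 100.0,
    grid_step_um: Optional[float] = None,
) -> dict[str, np.ndarray]:
    """Sliding-window point density map in cells/mm^2.

    Points are binned onto a fine grid and counted in a square window of side
    ``window_um`` centered on each node.
    """
    if window_um <= 0:
        raise ValueError("window_um must be positive")
    if grid_step_um is None:
        grid_step_um = window_um / 4.0
    w_um, h_um = fov_um
    nx = max(1, int(round(w_um / grid_step_um)))
    ny = max(1, int(round(h_um / grid_step_um)))
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    counts, _, _ = np.histogram2d(
        pts[:, 1], pts[:, 0], bins=[ny, nx], range=[[0, h_um], [0, w_um]]
    )
    win = max(1, int(round(window_um / grid_step_um)))
    summed = ndimage.uniform_filter(counts, size=win, mode="constant") * win**2
    area_mm2 = (win * grid_step_um / 1000.0) ** 2
    x = (np.arange(nx) + 0.5) * grid_step_um
    y = (np.arange(ny) + 0.5) * grid_step_um
    return {"x_um": x, "y_um": y, "density_mm2": summed / area_mm2}


def head_density_profile(
    points_um: np.ndarray,
    defect: DefectObservation,
    half_size_um: float = 150.0,
    band_halfwidth_um: float = 50.0,
    n_bins: int = 11,
) -> dict[str, np.ndarray]:
    """Point density vs defect-frame x (head: x < 0; tail: x > 0), cells/mm^2."""
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    psi = defect.axis_angle
    ca, sa = np.cos(psi), np.sin(psi)
    rel = pts - np.asarray(defect.position)
    xf = ca * rel[:, 0] + sa * rel[:, 1]
    yf = -sa * rel[:, 0] + ca * rel[:, 1]
    keep = np.abs(yf) <= band_halfwidth_um
    edges = np.linspace(-half_size_um, half_size_um, n_bins + 1)
    counts, _ = np.histogram(xf[keep], bins=edges)
    bin_area_mm2 = (np.diff(edges) / 1000.0) * (2.0 * band_halfwidth_um / 1000.0)
    return {
        "x_um": 0.5 * (edges[:-1] + edges[1:]),
        "density_mm2": counts / bin_area_mm2,
        "n": counts,
    }
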