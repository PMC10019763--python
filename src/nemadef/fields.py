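"""Core field containers shared by all pipeline stages.

Conventions
-----------
* Arrays are indexed ``[row, col]`` = ``[y, x]``; the origin ``(0, 0)`` is the
  top-left pixel center, ``x`` points right, ``y`` points *down* (raster/TIFF
  storage order).  All angles are measured from the +x axis toward +y, i.e.
  clockwise on screen.
* Director angles ``theta`` are nematic: defined modulo pi and stored in
  ``[0, pi)``.  Angle differences are always reduced into ``(-pi/2, pi/2]``.
* Physical positions are micrometres, velocities micrometres per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_nematic(theta: np.ndarray | float) -> np.ndarray | float:
    """Reduce nematic angles into [0, pi)."""
    return np.mod(theta, np.pi)


def nematic_difference(a: np.ndarray | float, b: np.ndarray | float):
    """Signed nematic angle difference a - b reduced into (-pi/2, pi/2]."""
    d = np.mod(np.asarray(a) - np.asarray(b), np.pi)
    d = np.where(d > np.pi / 2, d - np.pi, d)
    return d


@dataclass
class DirectorField:
    """Nematic orientation field on a regular grid.

    Parameters
    ----------
    theta : (H, W) array
        Director angle in radians, reduced into [0, pi).
    coherency : (H, W) array
        Local anisotropy in [0, 1]; 0 flags unreliable angles.
    pixel_size : float
        Grid spacing in micrometres per node (image pixel size for per-pixel
        fields; ``pixel_size * block`` after coarse graining).
    origin : (float, float)
        Physical (x, y) position in micrometres of node (0, 0).
    """

    theta: np.ndarray
    coherency: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.theta = wrap_nematic(np.asarray(self.theta, dtype=float))
        self.coherency = np.asarray(self.coherency, dtype=float)
        if self.theta.shape != self.coherency.shape:
            raise ValueError("theta and coherency must share a grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta.shape

    def tensor_components(self) -> tuple[np.ndarray, np.ndarray]:
        """(cos 2theta, sin 2theta) — the headless representation used for
        every averaging/interpolation step (raw angle means are ill-defined)."""
        return np.cos(2.0 * self.theta), np.sin(2.0 * self.theta)

    def to_um(self, xy_px: np.ndarray) -> np.ndarray:
        """Node coordinates (x, y) in px -> physical micrometres."""
        xy_px = np.asarray(xy_px, dtype=float)
        return xy_px * self.pixel_size + np.asarray(self.origin)

    def to_px(self, xy_um: np.ndarray) -> np.ndarray:
        xy_um = np.asarray(xy_um, dtype=float)
        return (xy_um - np.asarray(self.origin)) / self.pixel_size


@dataclass
class VelocityField:
    """PIV velocity field on a coarse grid.

    ``x`` and ``y`` are 1-D node coordinates in micrometres; ``vx``/``vy`` are
    velocities in micrometres/hour with shape ``(len(y), len(x))``; ``valid``
    masks nodes where the correlation produced a usable vector.
    """

    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    valid: np.ndarray
    frame_interval: float

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        shape = (self.y.size, self.x.size)
        for arr in (self.vx, self.vy, self.valid):
            if arr.shape != shape:
                raise ValueError("velocity arrays must be (len(y), len(x))")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    @property
    def grid_spacing(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else float("nan")


@dataclass
class OrderField:
    """Windowed nematic order parameter q in [0, 1] (minima flag defect cores)."""

    q: np.ndarray
    window_um: float
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def window_px(self) -> int:
        w = int(round(self.window_um / self.pixel_size))
        return w if w % 2 == 1 else w + 1


@dataclass
class DefectObservation:
    """A single detected topological defect.

    ``axis_angle`` is the tail direction for +1/2 (comet) defects and the
    canonical threefold symmetry axis, reduced into [0, 2*pi/3), for -1/2.
    """

    position: tuple[float, float]  # (x, y) micrometres
    charge: float
    axis_angle: float
    frame: int = 0
    q_at_core: float = float("nan")

    def __post_init__(self):
        if self.charge not in (-1.0, -0.5, 0.5, 1.0):
            raise ValueError(f"charge must be a non-zero multiple of 1/2, got {self.charge}")
        self.axis_angle = float(np.mod(self.axis_angle, TWO_PI))


@dataclass
class DefectTrack:
    """Time linkage of one defect across frames."""

    observations: list[DefectObservation] = field(default_factory=list)
    motility_class: str = "unclassified"

    def __post_init__(self):
        frames = [o.frame for o in self.observations]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("frames must be strictly increasing")
        charges = {o.charge for o in self.observations}
        if len(charges) > 1:
            raise ValueError("a track links observations of one charge")

    @property
    def charge(self) -> float:
        return self.observations[0].charge

    @property
    def frames(self) -> np.ndarray:
        return np.array([o.frame for o in self.observations])

    @property
    def positions(self) -> np.ndarray:
        return np.array([o.position for o in self.observations])

    def __len__(self) -> int:
        return len(self.observations)


@dataclass
class FocalAdhesion:
    """A segmented focal adhesion with the morphometrics used downstream."""

    centroid: tuple[float, float]  # (x, y) micrometres
    area: float  # um^2
    perimeter: float  # um
    circularity: float  # 4*pi*area/perimeter^2
    orientation: float  # major-axis angle, nematic, [0, pi)
    label: int = 0
    region: str = "other"  # head / tail / other

    def __post_init__(self):
        self.orientation = float(wrap_nematic(self.orientation))
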