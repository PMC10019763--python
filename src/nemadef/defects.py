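"""Topological defect detection, charge and orientation measurement.

Defects are located as minima of the windowed nematic order parameter

    q(window) = sqrt(<cos 2 theta>^2 + <sin 2 theta>^2),

which equals 1 for perfect local alignment and drops toward 0 at defect
cores where every orientation is present.  The charge of each candidate is
the winding number: the total director rotation accumulated along a closed
loop around the core divided by 2*pi, with successive nematic differences
each reduced into (-pi/2, pi/2] so that half-integer charges are resolved.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .fields import (
    DefectObservation,
    DirectorField,
    OrderField,
    nematic_difference,
    wrap_nematic,
)

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi

#: default order-parameter window, micrometres
DEFAULT_WINDOW_UM = 27.8
#: loop radii (px) polled when measuring the winding number
LOOP_RADII_PX = (5, 8, 11)
#: |k_raw - snap| tolerance for accepting a half-integer charge
SNAP_TOL = 0.1


def local_order_parameter(director: DirectorField, window_um: float = DEFAULT_WINDOW_UM) -> OrderField:
    """Sliding-window nematic order parameter q in [0, 1].

    The window is the physical size ``window_um`` converted to an odd pixel
    count.  q is the norm of the window mean of (cos 2 theta, sin 2 theta).
    """
    wpx = int(round(window_um / director.pixel_size))
    if wpx % 2 == 0:
        wpx += 1
    if wpx < 4:
        raise ValueError("window smaller than 4 px after conversion")
    if wpx > min(director.shape):
        raise ValueError("window larger than the field")
    c2, s2 = director.tensor_components()
    mc = ndimage.uniform_filter(c2, size=wpx, mode="reflect")
    ms = ndimage.uniform_filter(s2, size=wpx, mode="reflect")
    q = np.hypot(mc, ms)
    return OrderField(
        q=np.clip(q, 0.0, 1.0),
        window_um=window_um,
        pixel_size=director.pixel_size,
        origin=director.origin,
    )


def _sample_theta(director: DirectorField, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Bilinear director sampling through the 2-theta tensor components
    (interpolating theta itself across its pi jumps would be wrong)."""
    c2, s2 = director.tensor_components()
    c = ndimage.map_coordinates(c2, [py, px], order=1, mode="nearest")
    s = ndimage.map_coordinates(s2, [py, px], order=1, mode="nearest")
    return 0.5 * np.arctan2(s, c)


def winding_number(
    director: DirectorField,
    center: tuple[float, float],
    radius: float,
    n_samples: int = 72,
    snap_tol: float = SNAP_TOL,
) -> float:
    """Winding number of the director along a circular loop.

    Parameters
    ----------
    center : (x, y) in *pixels* of the director grid.
    radius : loop radius in pixels, >= 3; the loop must stay inside the field.
    n_samples : loop sampling density (>= 16).

    Returns
    -------
    The accumulated angle / 2*pi, snapped to the nearest multiple of 1/2 when
    within ``snap_tol``; otherwise the raw (non-half-integer) value, which
    callers should treat as invalid.
    """
    if radius < 3:
        raise ValueError("radius must be >= 3 px")
    n_samples = max(16, int(n_samples))
    cx, cy = center
    h, w = director.shape
    if (cx - radius < 0) or (cx + radius > w - 1) or (cy - radius < 0) or (cy + radius > h - 1):
        raise ValueError("loop exits the field")
    phi = np.linspace(0.0, TWO_PI, n_samples, endpoint=False)
    px = cx + radius * np.cos(phi)
    py = cy + radius * np.sin(phi)
    theta = _sample_theta(director, px, py)
    closed = np.append(theta, theta[0])
    steps = nematic_difference(closed[1:], closed[:-1])
    k_raw = float(np.sum(steps) / TWO_PI)
    k_snap = round(2.0 * k_raw) / 2.0
    return k_snap if abs(k_raw - k_snap) <= snap_tol else k_raw


def defect_axis(
    director: DirectorField,
    core: tuple[float, float],
    charge: float,
    radius: float = 8.0,
    n_samples: int = 72,
) -> float:
    """Orientation of a +-1/2 defect from the director on a loop around it.

    The director along a loop around an isolated charge-k defect follows
    ``theta(phi) = k*phi + c``; the offset ``c`` is estimated (mod pi) as half
    the argument of the circular mean of ``exp(2i*(theta - k*phi))``, which is
    insensitive to the pi-ambiguity of the director.  For k = +1/2 the tail
    lies along ``2c`` (unique in [0, 2*pi)); for k = -1/2 the three symmetry
    axes are ``2c/3 + n*2*pi/3`` and the canonical representative in
    [0, 2*pi/3) is returned.
    """
    if charge not in (0.5, -0.5):
        raise ValueError("axis undefined for |charge| != 1/2")
    cx, cy = core
    n_samples = max(16, int(n_samples))
    phi = np.linspace(0.0, TWO_PI, n_samples, endpoint=False)
    px = cx + radius * np.cos(phi)
    py = cy + radius * np.sin(phi)
    theta = _sample_theta(director, px, py)
    resid = 2.0 * (theta - charge * phi)
    c = 0.5 * np.angle(np.mean(np.exp(1j * resid)))  # offset mod pi
    if charge == 0.5:
        return float(np.mod(2.0 * c, TWO_PI))
    return float(np.mod(2.0 * c / 3.0, TWO_PI / 3.0))


def _subpixel_minimum(q: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Quadratic (parabolic) refinement of a grid minimum, one axis at a time."""

    def refine(m1: float, c0: float, p1: float) -> float:
        denom = m1 - 2.0 * c0 + p1
        if denom <= 0:
            return 0.0
        delta = 0.5 * (m1 - p1) / denom
        return float(np.clip(delta, -0.5, 0.5))

    h, w = q.shape
    dx = refine(q[iy, ix - 1], q[iy, ix], q[iy, ix + 1]) if 0 < ix < w - 1 else 0.0
    dy = refine(q[iy - 1, ix], q[iy, ix], q[iy + 1, ix]) if 0 < iy < h - 1 else 0.0
    return ix + dx, iy + dy


def detect_defects(
    order: OrderField,
    director: DirectorField,
    q_threshold: float = 0.5,
    min_separation_um: Optional[float] = None,
    frame: int = 0,
    loop_radii: Sequence[float] = LOOP_RADII_PX,
) -> list[DefectObservation]:
    """Detect topological defects as sub-pixel-localized minima of q.

    Candidate minima below ``q_threshold`` are non-maximum-suppressed at
    ``min_separation_um`` (default: the order-parameter window), localized by
    a quadratic fit, then charged by polling the winding number on loops of
    several radii (majority vote); candidates whose winding does not snap to
    a non-zero half-integer are dropped and logged.
    """
    if not 0.0 < q_threshold < 1.0:
        raise ValueError("q_threshold must be in (0, 1)")
    if min_separation_um is None:
        min_separation_um = order.window_um
    q = order.q
    h, w = q.shape
    px_size = order.pixel_size
    margin = max(loop_radii) + 1
    is_min = (q == ndimage.minimum_filter(q, size=3, mode="reflect")) & (q < q_threshold)
    iy, ix = np.nonzero(is_min)
    inside = (ix >= margin) & (ix < w - margin) & (iy >= margin) & (iy < h - margin)
    iy, ix = iy[inside], ix[inside]
    cand = sorted(zip(q[iy, ix], iy, ix), key=lambda t: t[0])

    accepted: list[DefectObservation] = []
    accepted_px: list[tuple[float, float]] = []
    min_sep_px = min_separation_um / px_size
    for (qv, cy, cx) in cand:
        if any(np.hypot(cx - ax, cy - ay) < min_sep_px for (ax, ay) in accepted_px):
            logger.warning(
                "suppressed candidate at (%.1f, %.1f) px within min_separation", cx, cy
            )
            continue
        sx, sy = _subpixel_minimum(q, cy, cx)
        votes = []
        for r in loop_radii:
            try:
                votes.append(winding_number(director, (sx, sy), r))
            except ValueError:
                continue
        snapped = [k for k in votes if k != 0 and (2 * k) == round(2 * k)]
        if not snapped:
            logger.info(
                "dropped candidate at (%.1f, %.1f) px: winding %s not half-integer",
                sx, sy, votes,
            )
            continue
        values, counts = np.unique(snapped, return_counts=True)
        k = float(values[np.argmax(counts)])
        axis = defect_axis(director, (sx, sy), k) if abs(k) == 0.5 else 0.0
        pos_um = director.to_um(np.array([sx, sy]))
        accepted.append(
            DefectObservation(
                position=(float(pos_um[0]), float(pos_um[1])),
                charge=k,
                axis_angle=axis,
                frame=frame,
                q_at_core=float(qv),
            )
        )
        accepted_px.append((sx, sy))
    return accepted


def boundary_winding(director: DirectorField, margin_px: int = 2) -> float:
    """Winding number along the rectangular boundary of the field (total
    enclosed charge); used for charge-conservation checks."""
    h, w = director.shape
    m = margin_px
    top = [(x, m) for x in range(m, w - m)]
    right = [(w - 1 - m, y) for y in range(m, h - m)]
    bottom = [(x, h - 1 - m) for x in range(w - 1 - m, m - 1, -1)]
    left = [(m, y) for y in range(h - 1 - m, m - 1, -1)]
    pts = np.array(top + right + bottom + left, dtype=float)
    theta = _sample_theta(director, pts[:, 0], pts[:, 1])
    closed = np.append(theta, theta[0])
    steps = nematic_difference(closed[1:], closed[:-1])
    k = float(np.sum(steps) / TWO_PI)
    return round(2.0 * k) / 2.0
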