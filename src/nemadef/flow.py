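"""Velocity fields by window cross-correlation PIV.

Single-pass PIV: the image pair is tiled into square interrogation windows
(default 16 px, 50% overlap); each window of the first frame is matched by
normalized cross-correlation against a search region of the second frame
(padding half a window on every side), the integer peak is refined by a
three-point Gaussian fit per axis, and displacements are converted to
micrometres/hour with the pixel calibration and frame interval.  Spurious
vectors are flagged by the normalized median test against the 3x3
neighborhood and optionally replaced by the neighborhood median.  Valid for
displacements small compared to the window (|d| < window/3).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
from skimage.feature import match_template

from .fields import VelocityField

logger = logging.getLogger(__name__)


def _gauss3(cm: float, c0: float, cp: float) -> float:
    """Three-point Gaussian peak interpolation; 0 if not applicable.

    A peak at the theoretical NCC maximum (perfect match, e.g. a pure integer
    shift) has zero width: the surface carries no subpixel information and no
    refinement is applied.
    """
    if cm <= 0 or c0 <= 0 or cp <= 0:
        return 0.0
    if c0 >= 1.0 - 1e-9:  # perfect match
        return 0.0
    lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
    denom = lm - 2.0 * l0 + lp
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (lm - lp) / denom, -0.5, 0.5))


def _window_displacement(
    a: np.ndarray,
    b: np.ndarray,
    y0: int,
    x0: int,
    window: int,
    margin: int,
) -> tuple[float, float, bool]:
    """Displacement of the ``window`` x ``window`` patch of ``a`` at (y0, x0),
    located by NCC inside the margin-padded search region of ``b``; returns
    valid=False for textureless windows."""
    template = a[y0 : y0 + window, x0 : x0 + window]
    if template.std() < 1e-12:
        return 0.0, 0.0, False
    ys0, ys1 = max(0, y0 - margin), min(b.shape[0], y0 + window + margin)
    xs0, xs1 = max(0, x0 - margin), min(b.shape[1], x0 + window + margin)
    search = b[ys0:ys1, xs0:xs1]
    if search.std() < 1e-12:
        return 0.0, 0.0, False
    corr = match_template(search, template)
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    # a peak on the border of the search range cannot be trusted (the true
    # peak may lie outside); typical at image boundaries
    on_border = (
        corr.shape[0] > 1 and (iy == 0 or iy == corr.shape[0] - 1)
    ) or (
        corr.shape[1] > 1 and (ix == 0 or ix == corr.shape[1] - 1)
    )
    dx = dy = 0.0
    if 0 < ix < corr.shape[1] - 1:
        dx = _gauss3(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
    if 0 < iy < corr.shape[0] - 1:
        dy = _gauss3(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    return (xs0 + ix - x0) + dx, (ys0 + iy - y0) + dy, not on_border


def _normalized_median_mask(
    dx: np.ndarray, dy: np.ndarray, valid: np.ndarray,
    threshold: float = 2.0, eps: float = 0.1,
) -> np.ndarray:
    """Universal outlier detection (normalized median test) on the vector grid."""
    h, w = dx.shape
    bad = np.zeros((h, w), dtype=bool)
    for j in range(h):
        for i in range(w):
            if not valid[j, i]:
                continue
            rmax = 0.0
            for comp in (dx, dy):
                neigh = []
                for dj in (-1, 0, 1):
                    for di in (-1, 0, 1):
                        if di == 0 and dj == 0:
                            continue
                        jj, ii = j + dj, i + di
                        if 0 <= jj < h and 0 <= ii < w and valid[jj, ii]:
                            neigh.append(comp[jj, ii])
                if len(neigh) < 3:
                    continue
                neigh = np.asarray(neigh)
                med = np.median(neigh)
                rm = np.median(np.abs(neigh - med))
                rmax = max(rmax, abs(comp[j, i] - med) / (rm + eps))
            if rmax > threshold:
                bad[j, i] = True
    return bad


def piv_pair(
    image_a: np.ndarray,
    image_b: np.ndarray,
    window: int = 16,
    overlap: float = 0.5,
    frame_interval: float = 0.25,
    pixel_size: float = 1.856,
    outlier_threshold: float = 2.0,
    replace_outliers: bool = True,
) -> VelocityField:
    """PIV velocity field between two frames.

    Parameters
    ----------
    window : interrogation window size, px.
    overlap : window overlap fraction in [0, 1); grid step = window*(1-overlap).
    frame_interval : hours between the frames.
    pixel_size : micrometres per pixel.
    outlier_threshold : normalized-median-test threshold (<=0 disables).
    replace_outliers : replace flagged vectors with the neighborhood median
        (they stay marked invalid).
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    step = max(1, int(round(window * (1.0 - overlap))))
    h, w = a.shape
    ys = np.arange(0, h - window + 1, step)
    xs = np.arange(0, w - window + 1, step)
    if len(ys) < 2 or len(xs) < 2:
        raise ValueError("images must fit at least 2 windows per side")

    dx = np.zeros((len(ys), len(xs)))
    dy = np.zeros_like(dx)
    valid = np.zeros(dx.shape, dtype=bool)
    margin = window // 2
    for j, y0 in enumerate(ys):
        for i, x0 in enumerate(xs):
            dx[j, i], dy[j, i], valid[j, i] = _window_displacement(
                a, b, y0, x0, window, margin
            )
    if not valid.all():
        logger.info("piv_pair: %d textureless windows masked", int((~valid).sum()))

    if outlier_threshold > 0:
        bad = _normalized_median_mask(dx, dy, valid, threshold=outlier_threshold)
        if bad.any():
            logger.info("piv_pair: %d outlier vectors flagged", int(bad.sum()))
        if replace_outliers:
            for j, i in zip(*np.nonzero(bad)):
                neigh_x, neigh_y = [], []
                for dj in (-1, 0, 1):
                    for di in (-1, 0, 1):
                        jj, ii = j + dj, i + di
                        if (dj or di) and 0 <= jj < dx.shape[0] and 0 <= ii < dx.shape[1] \
                                and valid[jj, ii] and not bad[jj, ii]:
                            neigh_x.append(dx[jj, ii])
                            neigh_y.append(dy[jj, ii])
                if neigh_x:
                    dx[j, i] = np.median(neigh_x)
                    dy[j, i] = np.median(neigh_y)
        valid &= ~bad

    scale = pixel_size / frame_interval
    centers_x = (xs + (window - 1) / 2.0) * pixel_size
    centers_y = (ys + (window - 1) / 2.0) * pixel_size
    return VelocityField(
        x=centers_x, y=centers_y,
        vx=dx * scale, vy=dy * scale,
        valid=valid, frame_interval=frame_interval,
    )


def piv_movie(stack: np.ndarray | Sequence[np.ndarray], **params) -> list[VelocityField]:
    """PIV on every consecutive frame pair of a stack."""
    frames = [np.asarray(f, dtype=float) for f in stack]
    if len(frames) < 2:
        raise ValueError("stack must contain at least 2 frames")
    fields = []
    for t in range(len(frames) - 1):
        vf = piv_pair(frames[t], frames[t + 1], **params)
        frac = 1.0 - vf.valid.mean()
        logger.info("piv_movie: pair %d-%d, masked fraction %.3f", t, t + 1, frac)
        fields.append(vf)
    return fields
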