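"""Director-field estimation by the local gradient structure tensor.

The texture orientation at each pixel is taken from the structure tensor
``J = G_w * (grad I grad I^T)`` (Gaussian-derivative gradients, Gaussian window
smoothing): the director is the eigenvector of the *smallest* eigenvalue —
the direction along which intensity varies least, i.e. the ridge direction,
perpendicular to the mean gradient.  Coherency ``(l1 - l2)/(l1 + l2)``
quantifies how anisotropic the local texture is and flags unreliable angles.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .fields import DirectorField, wrap_nematic


def structure_tensor_director(
    image: np.ndarray,
    gradient_sigma: float = 2.0,
    window_sigma: float = 8.0,
    pixel_size: float = 1.0,
) -> DirectorField:
    """Estimate the per-pixel nematic director of a textured image.

    Parameters
    ----------
    image : 2-D array, at least 16 x 16 px, finite values.
    gradient_sigma : scale (px) of the Gaussian-derivative gradient filters.
    window_sigma : scale (px) of the Gaussian tensor-smoothing window.
    pixel_size : micrometres per pixel, propagated to the output field.

    Returns
    -------
    DirectorField with ``theta`` in [0, pi) and ``coherency`` in [0, 1]
    (0 where the local tensor trace vanishes, e.g. constant images).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 16:
        raise ValueError("image must be 2-D and at least 16 x 16 px")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if gradient_sigma <= 0 or window_sigma <= 0:
        raise ValueError("sigmas must be positive")

    # axis 0 is y (rows, pointing down), axis 1 is x
    gx = ndimage.gaussian_filter(image, gradient_sigma, order=(0, 1))
    gy = ndimage.gaussian_filter(image, gradient_sigma, order=(1, 0))
    jxx = ndimage.gaussian_filter(gx * gx, window_sigma)
    jxy = ndimage.gaussian_filter(gx * gy, window_sigma)
    jyy = ndimage.gaussian_filter(gy * gy, window_sigma)

    trace = jxx + jyy
    # eigenvector of the largest eigenvalue (dominant gradient direction)
    alpha = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    theta = wrap_nematic(alpha + np.pi / 2.0)  # texture direction: perpendicular
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.where(
            trace > 0, np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2) / trace, 0.0
        )
    return DirectorField(theta=theta, coherency=np.clip(coherency, 0.0, 1.0),
                         pixel_size=pixel_size)


def coarse_grain_director(field: DirectorField, block: int) -> DirectorField:
    """Nematic block average onto a coarser grid (e.g. to match a PIV grid).

    Angles are averaged through the order-tensor components weighted by
    coherency: ``v = <coh * exp(2i theta)>``, ``theta_block = arg(v)/2``.  The
    output coherency is ``|v| / <coh>`` so that antagonistic blocks (e.g. half
    at 0, half at pi/2) come out with coherency ~ 0 — the angle there is
    meaningless and flagged.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    h, w = field.shape
    nh, nw = h // block, w // block
    if nh < 1 or nw < 1:
        raise ValueError("block larger than the field")
    c2, s2 = field.tensor_components()
    coh = field.coherency

    def block_mean(a: np.ndarray) -> np.ndarray:
        return a[: nh * block, : nw * block].reshape(nh, block, nw, block).mean(axis=(1, 3))

    wc2 = block_mean(coh * c2)
    ws2 = block_mean(coh * s2)
    wsum = block_mean(coh)
    theta = wrap_nematic(0.5 * np.arctan2(ws2, wc2))
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.where(wsum > 0, np.hypot(wc2, ws2) / wsum, 0.0)
    x0 = field.origin[0] + (block - 1) / 2.0 * field.pixel_size
    y0 = field.origin[1] + (block - 1) / 2.0 * field.pixel_size
    return DirectorField(
        theta=theta,
        coherency=np.clip(coherency, 0.0, 1.0),
        pixel_size=field.pixel_size * block,
        origin=(x0, y0),
    )
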