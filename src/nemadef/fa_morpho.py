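"""Focal-adhesion segmentation and morphometrics.

Paxillin-like images are histogram-equalized and thresholded at one shared
level per comparison set (Otsu on the pooled equalized histogram), then
labeled with 8-connectivity.  Each adhesion is quantified by area,
Crofton-estimated perimeter, circularity ``4*pi*area/perimeter^2`` and
major-axis orientation; only adhesions with area strictly between 1 and
7 um^2 are retained.  Head/tail assignment and the between-region
comparison (rank test, orientation histograms) mirror the defect-frame
convention: head at x < 0, tail at x > 0.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats
from skimage import exposure, filters, measure

from .fields import DefectObservation, FocalAdhesion, wrap_nematic

#: area filter bounds, um^2 (open interval: boundary values excluded)
AREA_BOUNDS_UM2 = (1.0, 7.0)
#: discretization headroom on circularity for small digital discs
CIRCULARITY_EPS = 0.1


def segment_fas(
    images: np.ndarray | Sequence[np.ndarray],
    equalize: bool = True,
    threshold: Optional[float] = None,
) -> list[np.ndarray]:
    """Segment focal adhesions in one or more images of a comparison set.

    All images are (optionally) histogram-equalized, then thresholded at one
    absolute level shared across the whole set, and labeled (8-connectivity).

    The shared level defaults to Otsu on the pooled *raw* intensities,
    translated into the equalized domain as the corresponding pooled
    quantile.  (Equalization itself flattens the histogram, so running Otsu
    after it would always land mid-range and flood sparse images with
    background; the raw pooled histogram keeps the foreground/background
    bimodality Otsu needs.)

    Returns one label image per input image.
    """
    if isinstance(images, np.ndarray) and images.ndim == 2:
        images = [images]
    raws = [np.asarray(img, dtype=float) for img in images]
    pooled = np.concatenate([img.ravel() for img in raws])
    if pooled.max() == pooled.min():
        return [np.zeros(img.shape, dtype=int) for img in raws]
    prepped = [exposure.equalize_hist(img) if equalize else img for img in raws]
    if threshold is None:
        t_raw = filters.threshold_otsu(pooled)
        bg, fg = pooled[pooled <= t_raw], pooled[pooled > t_raw]
        # Otsu always returns a split; demand genuinely bimodal intensities,
        # otherwise a blob-free (noise-only) image would segment into specks
        if fg.size == 0 or (fg.mean() - bg.mean()) < 2.0 * (bg.std() + fg.std()):
            return [np.zeros(img.shape, dtype=int) for img in raws]
        if equalize:
            # equalized values approximate intensity quantiles
            threshold = float(np.mean(pooled <= t_raw))
        else:
            threshold = float(t_raw)
    return [measure.label(img > threshold, connectivity=2) for img in prepped]


def fa_metrics(
    label_image: np.ndarray,
    pixel_size: float,
    area_bounds_um2: tuple[float, float] = AREA_BOUNDS_UM2,
) -> list[FocalAdhesion]:
    """Morphometrics for each labeled adhesion, area-filtered.

    Area is the pixel count times ``pixel_size**2``; the perimeter uses the
    Crofton formula (4 directions), which is far less biased than counting
    boundary pixels and keeps disc circularity near 1; circularity is
    ``4*pi*area/perimeter^2`` (may exceed 1 by up to ~``CIRCULARITY_EPS`` for
    small digital discs); orientation is the major axis from the second
    central moments, reported nematically in [0, pi) in image coordinates
    (x right, y down).  Adhesions with area outside the *open* interval
    ``area_bounds_um2`` are discarded.
    """
    lo, hi = area_bounds_um2
    out: list[FocalAdhesion] = []
    for rp in measure.regionprops(np.asarray(label_image)):
        area = rp.area * pixel_size**2
        if not (lo < area < hi):
            continue
        perimeter = rp.perimeter_crofton * pixel_size
        if perimeter <= 0:
            continue
        circ = 4.0 * np.pi * area / perimeter**2
        # regionprops orientation: angle from the row (y) axis, CCW in (row, col);
        # convert to angle from +x toward +y (down)
        orient = wrap_nematic(np.pi / 2.0 - rp.orientation)
        cy, cx = rp.centroid
        out.append(
            FocalAdhesion(
                centroid=(cx * pixel_size, cy * pixel_size),
                area=float(area),
                perimeter=float(perimeter),
                circularity=float(circ),
                orientation=float(orient),
                label=rp.label,
            )
        )
    return out


def split_by_region(
    fas: Sequence[FocalAdhesion],
    defect: DefectObservation,
    radius_limit_um: float = 150.0,
) -> list[FocalAdhesion]:
    """Label each adhesion head/tail/other relative to a +1/2 defect.

    The plane is split by the line through the core perpendicular to the
    defect axis: defect-frame x < 0 is the head half, x > 0 the tail half;
    adhesions beyond ``radius_limit_um`` from the core are 'other'.
    """
    psi = defect.axis_angle
    ca, sa = np.cos(psi), np.sin(psi)
    for fa in fas:
        dx = fa.centroid[0] - defect.position[0]
        dy = fa.centroid[1] - defect.position[1]
        if np.hypot(dx, dy) > radius_limit_um:
            fa.region = "other"
            continue
        xf = ca * dx + sa * dy
        fa.region = "head" if xf < 0 else "tail"
    return list(fas)


def orientation_histogram(
    fas: Sequence[FocalAdhesion],
    defect_axis: float = 0.0,
    n_bins: int = 18,
) -> dict[str, np.ndarray]:
    """Nematic orientation histogram relative to the defect axis.

    Angles are reduced into [-90, 90) degrees with the defect axis at 0.
    """
    rel = [
        np.degrees(np.mod(fa.orientation - defect_axis + np.pi / 2, np.pi) - np.pi / 2)
        for fa in fas
    ]
    counts, edges = np.histogram(rel, bins=n_bins, range=(-90.0, 90.0))
    return {"counts": counts, "edges_deg": edges}


def compare_regions(
    head: Sequence[FocalAdhesion],
    tail: Sequence[FocalAdhesion],
    defect_axis: float = 0.0,
) -> dict[str, object]:
    """Head-vs-tail morphometric comparison.

    Means and SDs of area and circularity per region, a two-sided
    Mann-Whitney U p-value on circularity (rank-based: circularity is bounded
    and not Gaussian), and nematic orientation histograms relative to the
    defect axis.
    """
    def stats_of(fas, attr):
        vals = np.array([getattr(f, attr) for f in fas])
        return {
            "mean": float(vals.mean()) if vals.size else np.nan,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            "n": int(vals.size),
        }

    head_circ = np.array([f.circularity for f in head])
    tail_circ = np.array([f.circularity for f in tail])
    if head_circ.size and tail_circ.size:
        p = float(stats.mannwhitneyu(head_circ, tail_circ, alternative="two-sided").pvalue)
    else:
        p = np.nan
    return {
        "head_area": stats_of(head, "area"),
        "tail_area": stats_of(tail, "area"),
        "head_circularity": stats_of(head, "circularity"),
        "tail_circularity": stats_of(tail, "circularity"),
        "p_circularity": p,
        "head_orientation_hist": orientation_histogram(head, defect_axis),
        "tail_orientation_hist": orientation_histogram(tail, defect_axis),
    }
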