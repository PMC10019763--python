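"""End-to-end pipeline: TIFF stack in, defect/track/profile tables out.

Stages run in order orientation -> PIV -> defect detection -> tracking ->
defect-frame averaging; every table is written as CSV with a fixed float
format alongside a JSON snapshot of the configuration, so a rerun with the
same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import AnalysisConfig
from .defect_frame import average_frames, axial_profile, contractility_sign, register_observation
from .defects import detect_defects, local_order_parameter
from .fields import DefectObservation
from .flow import piv_movie
from .orientation import structure_tensor_director
from .synthetic import (
    SyntheticScene,
    advect_texture_movie,
    make_defect_flow,
    make_fa_image,
    make_nuclei_points,
    make_scene,
    random_scene,
    write_scene,
)
from .tracking import link_tracks, tracks_table

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6f"
CSV_HEADER = "# coordinates in um, raster convention (origin top-left, y down); frames 0-based\n"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(CSV_HEADER)
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a single- or multi-page TIFF as a (T, H, W) float stack."""
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 — report the offending file
        raise IOError(f"could not read TIFF {path!s}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path!s}: expected a 2-D image or 3-D stack, got shape {arr.shape}")
    return arr


def run_pipeline(
    config: AnalysisConfig,
    stack: np.ndarray | str | Path,
    outdir: str | Path,
) -> Path:
    """Run every analysis stage on an image stack and write the output tables.

    Returns the output directory containing: ``directors.npz`` (per-frame
    theta/coherency), ``defects.csv``, ``tracks.csv``, ``piv_###.csv``,
    ``axial_profile.csv``, ``averaged_frame.npz``, ``config.json``.
    """
    if isinstance(stack, (str, Path)):
        stack = read_stack(stack)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    snapshot = {"config": asdict(config), "version": __version__}
    (outdir / "config.json").write_text(json.dumps(snapshot, indent=2, sort_keys=True))

    # orientation
    directors = [
        structure_tensor_director(
            frame,
            gradient_sigma=config.gradient_sigma_px,
            window_sigma=config.window_sigma_px,
            pixel_size=config.pixel_size,
        )
        for frame in stack
    ]
    np.savez_compressed(
        outdir / "directors.npz",
        theta=np.stack([d.theta for d in directors]),
        coherency=np.stack([d.coherency for d in directors]),
        pixel_size=config.pixel_size,
    )
    coh = pd.DataFrame({
        "frame": np.arange(len(directors)),
        "mean_coherency": [d.coherency.mean() for d in directors],
    })
    _write_csv(coh, outdir / "coherency.csv")

    # PIV
    velocities = None
    if len(stack) >= 2:
        velocities = piv_movie(
            stack,
            window=config.piv_window_px,
            overlap=config.piv_overlap,
            frame_interval=config.frame_interval,
            pixel_size=config.pixel_size,
        )
        for t, vf in enumerate(velocities):
            X, Y = np.meshgrid(vf.x / config.pixel_size, vf.y / config.pixel_size)
            df = pd.DataFrame({
                "x_px": X.ravel(), "y_px": Y.ravel(),
                "vx_umh": vf.vx.ravel(), "vy_umh": vf.vy.ravel(),
                "valid": vf.valid.ravel().astype(int),
            })
            _write_csv(df, outdir / f"piv_{t:03d}.csv")

    # defects per frame
    per_frame: list[list[DefectObservation]] = []
    rows = []
    for t, director in enumerate(directors):
        order = local_order_parameter(director, config.order_window_um)
        obs = detect_defects(
            order, director,
            q_threshold=config.q_threshold,
            min_separation_um=config.min_separation_um,
            frame=t,
        )
        per_frame.append(obs)
        logger.info("frame %d: %d defects", t, len(obs))
        for o in obs:
            rows.append({
                "frame": t, "x_um": o.position[0], "y_um": o.position[1],
                "charge": o.charge, "axis_rad": o.axis_angle, "q_core": o.q_at_core,
            })
    defect_df = pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "charge", "axis_rad", "q_core"])
    _write_csv(defect_df, outdir / "defects.csv")

    # tracking
    tracks = link_tracks(per_frame, max_disp_per_frame=config.max_disp_per_frame_um)
    ttable = tracks_table(
        tracks, config.frame_interval,
        stationary_threshold=config.stationary_threshold_umh,
        smoothing_window=config.speed_smoothing_frames,
    )
    _write_csv(ttable, outdir / "tracks.csv")

    # defect-frame averaging over all +1/2 observations
    patches = []
    for t, obs_list in enumerate(per_frame):
        vel = velocities[min(t, len(velocities) - 1)] if velocities else None
        for o in obs_list:
            if o.charge == 0.5:
                patches.append(
                    register_observation(
                        directors[t], vel, o,
                        half_size_um=config.patch_half_size_um,
                        grid_step_um=config.pixel_size * 4,
                    )
                )
    if patches:
        avg = average_frames(patches)
        np.savez_compressed(
            outdir / "averaged_frame.npz",
            x=avg.x, y=avg.y, theta=avg.theta, dir_order=avg.dir_order,
            n_dir=avg.n_dir,
            vx=avg.vx if avg.vx is not None else np.array([]),
            vy=avg.vy if avg.vy is not None else np.array([]),
        )
        if avg.vx is not None:
            prof = axial_profile(avg, band_halfwidth_um=config.band_halfwidth_um)
            _write_csv(pd.DataFrame(prof), outdir / "axial_profile.csv")
            sign = contractility_sign(avg)
            (outdir / "contractility.json").write_text(json.dumps(
                {k: (v if isinstance(v, str) else float(v)) for k, v in sign.items()},
                indent=2, sort_keys=True,
            ))
    return outdir


def make_synthetic_suite(seed: int, outdir: str | Path) -> Path:
    """Write the canonical synthetic fixture set.

    Scenes: a +1/2 comet, a -1/2 trefoil, a +-1/2 pair, a stationary-defect
    flow movie (texture advected only at the head), a focal-adhesion panel
    and a nuclei point set with a head hotspot.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    px = 1.856
    shape = (192, 192)
    cx = (shape[1] - 1) * px / 2
    cy = (shape[0] - 1) * px / 2

    comet = make_scene([((cx, cy), 0.5, 0.0)], shape=shape, pixel_size=px, seed=seed)
    write_scene(comet, outdir, "comet")
    trefoil = make_scene([((cx, cy), -0.5, 0.0)], shape=shape, pixel_size=px, seed=seed + 1)
    write_scene(trefoil, outdir, "trefoil")
    pair = random_scene(2, shape=(256, 256), pixel_size=px, seed=seed + 2, render=True)
    write_scene(pair, outdir, "pair")

    flow = make_defect_flow(
        "stationary_asymmetric", axis_angle=0.0, v0=20.0, decay_length=60.0,
        shape=(25, 25), grid_spacing=shape[1] * px / 25, frame_interval=0.25,
    )
    movie = advect_texture_movie(comet.texture, flow, n_frames=5, pixel_size=px)
    tifffile.imwrite(outdir / "stationary_movie.tif", movie.astype(np.float32), photometric="minisblack")

    rng = np.random.default_rng(seed + 3)
    blobs = []
    for _ in range(12):
        center = tuple(rng.uniform(5, 45, size=2))
        blobs.append((center, rng.uniform(1.5, 6.0), rng.uniform(1.0, 4.0), rng.uniform(0, np.pi)))
    fa_img = make_fa_image(blobs, shape=(256, 256), pixel_size=0.2, seed=seed + 3)
    tifffile.imwrite(outdir / "fa_panel.tif", fa_img.astype(np.float32))

    pts = make_nuclei_points(
        1000.0, area=(500.0, 500.0),
        hotspot=((150.0, 250.0), 60.0, 2.0), seed=seed + 4,
    )
    pd.DataFrame(pts, columns=["x_um", "y_um"]).to_csv(
        outdir / "nuclei.csv", index=False, float_format=FLOAT_FMT
    )
    return outdir
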