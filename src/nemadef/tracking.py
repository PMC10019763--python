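"""Defect trajectory linking, speeds, density and motility classification.

Linking is greedy mutual-nearest-neighbor between consecutive frames,
restricted to equal charge and a maximum displacement; defect counts per
field of view are small, so global assignment buys nothing.  A missed frame
terminates a track (no gap closing).  Tracks whose mean speed stays below
the stationary threshold (default 10 um/h) are classified stationary;
defects moving at ~20 um/h and above are motile.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fields import DefectObservation, DefectTrack

#: stationary/motile speed threshold, um/h
STATIONARY_THRESHOLD_UMH = 10.0


def link_tracks(
    per_frame_observations: Sequence[Sequence[DefectObservation]],
    max_disp_per_frame: float,
) -> list[DefectTrack]:
    """Link per-frame observations into tracks.

    Mutual nearest neighbors of equal charge within ``max_disp_per_frame``
    (micrometres) are linked; everything else starts a new track.
    """
    open_tracks: list[list[DefectObservation]] = []
    closed: list[list[DefectObservation]] = []
    prev_obs: list[DefectObservation] = []
    prev_track_of: list[int] = []

    for frame_obs in per_frame_observations:
        frame_obs = list(frame_obs)
        links: dict[int, int] = {}  # index in frame_obs -> open-track index
        if prev_obs and frame_obs:
            cost = np.full((len(prev_obs), len(frame_obs)), np.inf)
            for i, p in enumerate(prev_obs):
                for j, c in enumerate(frame_obs):
                    if p.charge != c.charge:
                        continue
                    d = np.hypot(p.position[0] - c.position[0], p.position[1] - c.position[1])
                    if d <= max_disp_per_frame:
                        cost[i, j] = d
            for i in range(len(prev_obs)):
                if not np.isfinite(cost[i]).any():
                    continue
                j = int(np.argmin(cost[i]))
                if int(np.argmin(cost[:, j])) == i and np.isfinite(cost[i, j]):
                    links[j] = prev_track_of[i]

        new_prev_obs: list[DefectObservation] = []
        new_prev_track: list[int] = []
        linked_tracks = set(links.values())
        # terminate unextended tracks
        for ti, track in enumerate(open_tracks):
            if track is not None and ti not in linked_tracks:
                closed.append(track)
                open_tracks[ti] = None
        for j, obs in enumerate(frame_obs):
            if j in links:
                ti = links[j]
                open_tracks[ti].append(obs)
            else:
                open_tracks.append([obs])
                ti = len(open_tracks) - 1
            new_prev_obs.append(obs)
            new_prev_track.append(ti)
        prev_obs, prev_track_of = new_prev_obs, new_prev_track

    closed.extend(t for t in open_tracks if t is not None)
    closed.sort(key=lambda t: (t[0].frame, t[0].position))
    return [DefectTrack(observations=obs) for obs in closed]


def track_speed(
    track: DefectTrack,
    frame_interval: float,
    smoothing_window: int = 1,
) -> float:
    """Mean speed (um/h) of a track: mean of |dr|/dt over consecutive pairs,
    after optional box smoothing of the positions."""
    if len(track) < 2:
        raise ValueError("speed needs at least 2 observations")
    pos = track.positions.astype(float)
    if smoothing_window > 1:
        k = min(smoothing_window, len(pos))
        kernel = np.ones(k) / k
        pad = k // 2
        padded = np.pad(pos, ((pad, pad), (0, 0)), mode="edge")
        pos = np.column_stack([
            np.convolve(padded[:, 0], kernel, mode="valid"),
            np.convolve(padded[:, 1], kernel, mode="valid"),
        ])[: len(track)]
    dt = np.diff(track.frames) * frame_interval
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return float(np.mean(steps / dt))


def classify_motility(
    track: DefectTrack,
    frame_interval: float,
    stationary_threshold: float = STATIONARY_THRESHOLD_UMH,
    min_duration_h: float = 2.0,
    smoothing_window: int = 1,
) -> str:
    """'stationary' if mean speed < threshold, 'motile' otherwise;
    'unclassified' for tracks observed for less than ``min_duration_h``."""
    if len(track) < 2:
        return "unclassified"
    duration = (track.frames[-1] - track.frames[0]) * frame_interval
    if duration < min_duration_h:
        return "unclassified"
    speed = track_speed(track, frame_interval, smoothing_window=smoothing_window)
    return "stationary" if speed < stationary_threshold else "motile"


def defect_density_timeseries(
    per_frame_observations: Sequence[Sequence[DefectObservation]],
    fov_area_mm2: float,
    charge_filter: Optional[float] = None,
) -> np.ndarray:
    """Defect surface density (defects/mm^2) per frame, optionally for one
    charge only (e.g. +1/2)."""
    if fov_area_mm2 <= 0:
        raise ValueError("fov_area_mm2 must be positive")
    counts = [
        sum(1 for o in obs if charge_filter is None or o.charge == charge_filter)
        for obs in per_frame_observations
    ]
    return np.asarray(counts, dtype=float) / fov_area_mm2


def tracks_table(
    tracks: Sequence[DefectTrack],
    frame_interval: float,
    stationary_threshold: float = STATIONARY_THRESHOLD_UMH,
    smoothing_window: int = 1,
) -> pd.DataFrame:
    """Long-format table: track_id, frame, x_um, y_um, charge, speed_umh, class."""
    rows = []
    for tid, track in enumerate(tracks):
        cls = classify_motility(
            track, frame_interval,
            stationary_threshold=stationary_threshold,
            smoothing_window=smoothing_window,
        )
        speed = (
            track_speed(track, frame_interval, smoothing_window=smoothing_window)
            if len(track) >= 2 else np.nan
        )
        for o in track.observations:
            rows.append({
                "track_id": tid, "frame": o.frame,
                "x_um": o.position[0], "y_um": o.position[1],
                "charge": o.charge, "speed_umh": speed, "class": cls,
            })
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "x_um", "y_um", "charge", "speed_umh", "class"]
    )
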