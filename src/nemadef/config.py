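"""Pipeline configuration: physical calibrations and stage parameters.

Defaults follow the analysis this package implements: order-parameter window
27.8 um, PIV windows of 16 px with 50% overlap at 1.856 um/px, stationary
threshold 10 um/h, focal-adhesion area filter (1, 7) um^2.  The pixel size
and frame interval are calibrations of the acquisition and are never
guessed: loading a config without them is a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields as dc_fields
from pathlib import Path


@dataclass
class AnalysisConfig:
    pixel_size: float  # um/px — required, never inferred
    frame_interval: float  # h — required, never inferred
    order_window_um: float = 27.8
    piv_window_px: int = 16
    piv_overlap: float = 0.5
    q_threshold: float = 0.5
    min_separation_um: float = 27.8
    stationary_threshold_umh: float = 10.0
    min_track_duration_h: float = 2.0
    speed_smoothing_frames: int = 5
    max_disp_per_frame_um: float = 30.0
    gradient_sigma_px: float = 2.0
    window_sigma_px: float = 8.0
    patch_half_size_um: float = 150.0
    band_halfwidth_um: float = 30.0
    fa_area_min_um2: float = 1.0
    fa_area_max_um2: float = 7.0
    seed: int = 0

    def __post_init__(self):
        positive = [
            "pixel_size", "frame_interval", "order_window_um", "piv_window_px",
            "min_separation_um", "stationary_threshold_umh", "max_disp_per_frame_um",
            "gradient_sigma_px", "window_sigma_px", "patch_half_size_um",
            "band_halfwidth_um", "fa_area_min_um2", "fa_area_max_um2",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.piv_overlap < 1.0:
            raise ValueError("piv_overlap must be in [0, 1)")
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must be in (0, 1)")

    def to_file(self, path: str | Path) -> None:
        """Write as a flat key = value text file (lossless round-trip)."""
        lines = [f"{k} = {v!r}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        known = {f.name: f.type for f in dc_fields(cls)}
        kwargs = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in known:
                raise KeyError(f"unknown config key: {key}")
            kwargs[key] = eval(value.strip(), {"__builtins__": {}})  # literals only
        missing = {"pixel_size", "frame_interval"} - kwargs.keys()
        if missing:
            raise ValueError(f"missing required calibration(s): {sorted(missing)}")
        return cls(**kwargs)
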