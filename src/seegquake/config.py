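"""Run configuration: every tunable of the pipeline with its default.

Geometry defaults match the depth electrodes the method was built around
(8-16 contacts per shaft, 2 mm contact diameter, 3.5 mm center-to-center
pitch); the signal-path defaults are the canonical high-gamma / ripple
settings (60-140 Hz and 80-250 Hz bands, 50 Hz mains notch with Q = 30,
5th-order Butterworth, 500 ms energy smoothing, 250 ms energy-coefficient
window, 20 ms event merge gap, 50 ms minimum event duration).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple


@dataclass
class RunConfig:
    # --- electrode localization ---
    threshold_rule: str = "bright"
    direction_subdivisions: int = 3       # icosphere refinement level (~321 signed dirs)
    distance_bin_voxels: float = 1.0      # Hough anchor-plane bin width
    inlier_radius_voxels: float = 2.0     # point-to-line distance to claim inliers
    min_votes: Optional[int] = None       # None -> max(10, 25% of first peak)
    n_electrodes: Optional[int] = None    # None -> vote-based stopping
    gmm_seed: int = 0
    pitch_mm: float = 3.5
    contact_diameter_mm: float = 2.0
    cube_mm: float = 2.0
    max_contacts: int = 16
    com_tol_voxels: float = 0.05
    com_max_iter: int = 10

    # --- ictal (EI) ---
    ictal_band: Tuple[float, float] = (60.0, 140.0)
    notch_hz: float = 50.0
    notch_q: float = 30.0
    butter_order: int = 5
    smooth_window_ms: float = 500.0
    ec_window_ms: float = 250.0
    k_sigma: float = 10.0

    # --- interictal (HI) ---
    interictal_band: Tuple[float, float] = (80.0, 250.0)
    envelope_smooth_ms: float = 10.0
    merge_gap_ms: float = 20.0
    min_duration_ms: float = 50.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("ictal_band", "interictal_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def echo_header(self) -> str:
        """One-line '#'-prefixed config echo placed atop tabular outputs."""
        return "# " + json.dumps(self.to_dict(), sort_keys=True)
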