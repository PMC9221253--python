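"""Motion-energy scoring: stabilized flow → image-derived task score.

The per-pixel flow speed is converted from px/frame to degree/s with a
small-angle pixel-to-degree factor at the principal point, averaged over
pixels per frame (the motion-energy temporal profile) and over frames per
video.  The video-level mean is the image-derived task score: a continuous
motion-quantity measure in degree/s, not a movement count — correspondence
with the administrator's counts is established statistically downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optic_flow import FlowField

__all__ = [
    "MotionProfile",
    "TaskScore",
    "speed_field",
    "motion_profile",
    "image_derived_score",
]

MASK_POLICIES = ("valid", "all_pixels")


@dataclass
class MotionProfile:
    """Per-frame mean speed trace (degree/s) with matching frame times."""

    mean_speed_deg_s: np.ndarray
    frame_times_s: np.ndarray
    valid_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.mean_speed_deg_s = np.asarray(self.mean_speed_deg_s, dtype=np.float64)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=np.float64)
        self.valid_fraction = np.asarray(self.valid_fraction, dtype=np.float64)
        n = len(self.mean_speed_deg_s)
        if len(self.frame_times_s) != n or len(self.valid_fraction) != n:
            raise ValueError("profile arrays must have matching lengths")
        if n and (
            not np.all(np.isfinite(self.mean_speed_deg_s))
            or self.mean_speed_deg_s.min() < 0
        ):
            raise ValueError("speeds must be finite and non-negative")


@dataclass
class TaskScore:
    """One subject × task score pair.

    ``image_derived`` is the mean motion speed in degree/s; ``conventional``
    is the administrator's movement count when available.
    """

    subject_id: str
    task_id: int
    image_derived: float
    conventional: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= int(self.task_id) <= 5:
            raise ValueError("task_id must be in 1..5")
        if self.image_derived < 0:
            raise ValueError("image-derived score must be non-negative")
        if self.conventional is not None and self.conventional < 0:
            raise ValueError("conventional count must be non-negative")


def speed_field(flow: FlowField, f: float, frame_rate: float) -> np.ndarray:
    """Per-pixel speed in degree/s.

    speed = ‖(vx, vy)‖ px/frame × frame_rate × (180/π)/f, the small-angle
    pixel-to-degree conversion at the principal point.
    """
    if not f > 0:
        raise ValueError("focal length must be positive")
    if not frame_rate > 0:
        raise ValueError("frame rate must be positive")
    return flow.speed * frame_rate * (180.0 / np.pi) / f


def motion_profile(
    flows: list[FlowField],
    f: float,
    frame_rate: float,
    mask_policy: str = "all_pixels",
) -> MotionProfile:
    """Average speed over pixels, per frame.

    ``mask_policy='all_pixels'`` (default) counts invalid pixels as zero
    speed and averages over the full frame, so the frame value is a true
    motion-energy density that stays well defined when the validity mask
    is sparse; ``'valid'`` averages over valid pixels only.  Frames with
    no valid pixel get speed 0 and valid_fraction 0.
    """
    if not flows:
        raise ValueError("empty flow list")
    if mask_policy not in MASK_POLICIES:
        raise ValueError(f"mask_policy must be one of {MASK_POLICIES}")
    means = np.zeros(len(flows))
    fracs = np.zeros(len(flows))
    times = np.zeros(len(flows))
    for i, flow in enumerate(flows):
        deg = speed_field(flow, f, frame_rate)
        n_valid = int(flow.valid.sum())
        fracs[i] = n_valid / flow.valid.size
        times[i] = flow.frame_index / frame_rate
        if n_valid == 0:
            means[i] = 0.0
        elif mask_policy == "valid":
            means[i] = deg[flow.valid].mean()
        else:
            means[i] = np.where(flow.valid, deg, 0.0).mean()
    return MotionProfile(means, times, fracs)


def image_derived_score(profile: MotionProfile) -> float:
    """The video-level score: mean of the per-frame mean speeds (degree/s)."""
    if len(profile.mean_speed_deg_s) == 0:
        raise ValueError("empty motion profile")
    return float(profile.mean_speed_deg_s.mean())
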