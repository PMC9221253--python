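"""Flat key-value run configuration (YAML or JSON) for the CLI.

Every key has a module default; unknown keys are rejected so typos fail
loudly.  The effective configuration is hashed and echoed into each run's
metadata sidecar so any output can be traced to the exact settings.
"""

from __future__ import annotations

import hashlib
import json

from . import ego_motion, optic_flow, video_io
from .pipeline import PipelineConfig

__all__ = ["DEFAULTS", "load_config", "build_pipeline_config", "config_hash"]

DEFAULTS: dict = {
    "target_h": video_io.DEFAULT_TARGET_H,
    "target_w": video_io.DEFAULT_TARGET_W,
    "target_frames": video_io.DEFAULT_TARGET_FRAMES,
    "target_duration_s": video_io.DEFAULT_TARGET_DURATION_S,
    "percentile_clip_low": 1.0,
    "percentile_clip_high": 99.0,
    "focal_length_px": None,  # None -> image width
    "normalize": True,
    "n_orientations": 8,
    "wavelength_px": 8.0,
    "sigma_px": 4.0,
    "temporal_window": 5,
    "amplitude_frac": 0.05,
    "residual_max_rad": 0.5,
    "grad_min_rad_px": 0.05,
    "v_max_px": 10.0,
    "cond_max": 1e3,
    "boundary": "wrap",
    "bmatrix_dialect": "printed",
    "smooth_window": 5,
    "stabilize": True,
    "robust_rotation": True,
    "mask_policy": "all_pixels",
    "target_sensitivity": 0.70,
    "n_boot": 2000,
    "seed": 0,
}


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults ← config file ← CLI overrides; validate keys."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml

                loaded = yaml.safe_load(fh) or {}
            else:
                loaded = json.load(fh)
        unknown = set(loaded) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    for k, v in (overrides or {}).items():
        if v is not None:
            if k not in DEFAULTS:
                raise ValueError(f"unknown config key: {k}")
            cfg[k] = v
    return cfg


def build_pipeline_config(cfg: dict) -> PipelineConfig:
    """Validate a flat config dict into a :class:`PipelineConfig`."""
    return PipelineConfig(
        normalize=bool(cfg["normalize"]),
        target_h=int(cfg["target_h"]),
        target_w=int(cfg["target_w"]),
        target_frames=int(cfg["target_frames"]),
        target_duration_s=float(cfg["target_duration_s"]),
        percentile_clip=(float(cfg["percentile_clip_low"]), float(cfg["percentile_clip_high"])),
        bank=optic_flow.FilterBank(
            int(cfg["n_orientations"]),
            float(cfg["wavelength_px"]),
            float(cfg["sigma_px"]),
            int(cfg["temporal_window"]),
        ),
        flow=optic_flow.FlowConfig(
            amplitude_frac=float(cfg["amplitude_frac"]),
            residual_max_rad=float(cfg["residual_max_rad"]),
            grad_min_rad_px=float(cfg["grad_min_rad_px"]),
            v_max_px=float(cfg["v_max_px"]),
            cond_max=float(cfg["cond_max"]),
            boundary=str(cfg["boundary"]),
        ),
        ego=ego_motion.EgoMotionConfig(
            bmatrix_dialect=str(cfg["bmatrix_dialect"]),
            smooth_window=int(cfg["smooth_window"]),
        ),
        stabilize=bool(cfg["stabilize"]),
        robust_rotation=bool(cfg["robust_rotation"]),
        mask_policy=str(cfg["mask_policy"]),
    )


def config_hash(cfg: dict) -> str:
    """Stable short hash of the effective configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
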