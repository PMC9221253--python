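"""Synthetic fixtures with known ground truth.

Every stage of the pipeline gets an oracle with no external download:

* band-limited random textures translating at a known sub-pixel velocity
  (flow accuracy),
* pure camera-rotation sequences obeying v(x) = B(x)ω (ego-motion
  recovery and stabilization),
* oscillating hand-task videos — a "clench" blob whose radius breathes at
  a known cycle frequency, or two "finger–thumb" blobs with an oscillating
  gap — with optional sensor noise and camera jitter (scoring),
* paired conventional/image-derived score tables with a calibrated output
  Pearson correlation and Table-2-like marginals (validation).

All generators are bit-reproducible given their seed.  Default geometry
matches the normalization targets (240×320 px, 30 fps, 10 s); callers may
pass smaller grids for fast tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndi

from .ego_motion import CameraRotation, rotational_flow
from .optic_flow import FlowField
from .video_io import FrameSequence

__all__ = [
    "SimSpec",
    "TASK_MARGINALS",
    "gen_texture",
    "gen_translating_sequence",
    "gen_camera_rotation_sequence",
    "gen_task_video",
    "gen_paired_scores",
]

#: (conventional mean, conventional SD, image-derived mean, image-derived SD)
#: per task, mimicking the observed score distributions of the five tasks.
TASK_MARGINALS = {
    1: (23.48, 7.54, 0.17, 0.11),
    2: (23.15, 7.69, 0.18, 0.11),
    3: (17.50, 6.31, 0.14, 0.08),
    4: (9.67, 2.86, 0.10, 0.05),
    5: (9.13, 2.96, 0.10, 0.05),
}

SIM_KINDS = ("translate", "rotate_camera", "clench", "finger_thumb", "paired_scores")


@dataclass
class SimSpec:
    """Declarative description of a synthetic fixture (CLI / config use)."""

    kind: str
    seed: int
    h: int = 240
    w: int = 320
    t: int = 300
    frame_rate: float = 30.0
    f: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SIM_KINDS:
            raise ValueError(f"kind must be one of {SIM_KINDS}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        freq = self.params.get("frequency_hz")
        if freq is not None and freq > self.frame_rate / 4.0:
            raise ValueError(
                f"frequency {freq} Hz exceeds frame_rate/4 = {self.frame_rate / 4.0}"
            )
        if self.kind == "paired_scores":
            if self.params.get("n", 46) < 4:
                raise ValueError("paired_scores needs n >= 4")
            if abs(self.params.get("rho", 0.72)) > 1:
                raise ValueError("|rho| must be <= 1")


def gen_texture(
    seed: int, h: int = 240, w: int = 320, correlation_length_px: float = 3.0
) -> np.ndarray:
    """Band-limited pseudo-random luminance pattern in [0, 1].

    Gaussian white noise smoothed with a periodic Gaussian kernel, then
    min-max scaled; the correlation length sets the dominant spatial scale
    so the default flow filter bank sees plenty of in-band structure.
    """
    if h < 16 or w < 16:
        raise ValueError("texture must be at least 16x16")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((h, w))
    tex = _ndi.gaussian_filter(noise, correlation_length_px, mode="wrap")
    tex -= tex.min()
    rng_range = tex.max()
    return tex / rng_range if rng_range > 0 else tex


def _fourier_shift(img: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Exact sub-pixel periodic shift via the Fourier shift theorem."""
    spec = np.fft.fft2(img)
    shifted = _ndi.fourier_shift(spec, (dy, dx))
    return np.real(np.fft.ifft2(shifted))


def gen_translating_sequence(
    seed: int,
    velocity: tuple[float, float] = (1.0, 0.0),
    h: int = 240,
    w: int = 320,
    t: int = 300,
    frame_rate: float = 30.0,
    f: float | None = None,
    correlation_length_px: float = 3.0,
    allow_fast: bool = False,
) -> tuple[FrameSequence, FlowField]:
    """Texture translating globally at a known (vx, vy) px/frame.

    Frame k is the base texture shifted by k·v with periodic boundary, so
    the ground-truth flow is the constant velocity everywhere.
    """
    vx, vy = velocity
    if np.hypot(vx, vy) > 2.0 and not allow_fast:
        raise ValueError(
            "speeds above 2 px/frame exceed the single-scale filter bank range"
        )
    tex = gen_texture(seed, h, w, correlation_length_px)
    frames = np.stack([_fourier_shift(tex, k * vy, k * vx) for k in range(t)])
    frames = np.clip(frames, 0.0, 1.0)
    seq = FrameSequence(
        frames,
        frame_rate,
        f,
        meta={"kind": "translate", "velocity": (vx, vy), "seed": seed},
    )
    truth = FlowField(
        vx=np.full((h, w), vx),
        vy=np.full((h, w), vy),
        valid=np.ones((h, w), dtype=bool),
    )
    return seq, truth


def gen_camera_rotation_sequence(
    seed: int,
    omega: tuple[float, float, float],
    h: int = 240,
    w: int = 320,
    t: int = 300,
    frame_rate: float = 30.0,
    f: float | None = None,
    dialect: str = "printed",
    correlation_length_px: float = 3.0,
) -> tuple[FrameSequence, CameraRotation]:
    """Pure camera-rotation sequence obeying v(x) = B(x)ω.

    Each frame is warped from its predecessor by the displacement field
    B(x)ω (cubic resampling, periodic boundary), so the inter-frame flow
    equals the model field; the constant true rotation is returned.
    """
    f_eff = float(f if f is not None else w)
    rot = CameraRotation(tuple(omega), f_eff)
    cam = rotational_flow(rot, (h, w), dialect=dialect)
    vmax = float(cam.speed.max())
    if vmax > 2.0:
        raise ValueError(
            f"rotation implies max displacement {vmax:.2f} px/frame > 2; reduce omega"
        )
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([yy - cam.vy, xx - cam.vx])
    frames = np.empty((t, h, w))
    frames[0] = gen_texture(seed, h, w, correlation_length_px)
    for k in range(1, t):
        frames[k] = _ndi.map_coordinates(
            frames[k - 1], coords, order=3, mode="grid-wrap"
        )
    frames = np.clip(frames, 0.0, 1.0)
    seq = FrameSequence(
        frames,
        frame_rate,
        f_eff,
        meta={"kind": "rotate_camera", "omega": tuple(omega), "dialect": dialect, "seed": seed},
    )
    return seq, rot


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def gen_task_video(
    seed: int,
    kind: str = "clench",
    frequency_hz: float = 1.0,
    amplitude_px: float = 4.0,
    noise_sd: float = 0.01,
    jitter_sd: float = 0.0,
    h: int = 240,
    w: int = 320,
    t: int = 300,
    frame_rate: float = 30.0,
    f: float | None = None,
    dialect: str = "printed",
) -> tuple[FrameSequence, dict]:
    """Oscillating hand-task video over a textured background.

    ``clench``: a textured blob at the image centre whose radius breathes
    sinusoidally with the given amplitude, so the whole blob expands and
    contracts radially (speed scales with frequency × amplitude).
    ``finger_thumb``: two textured blobs whose vertical gap oscillates
    (rigid translation).  Optional additive Gaussian sensor noise and a
    per-frame camera-jitter rotation (ω components i.i.d. N(0, jitter_sd)
    rad/frame applied through the B(x)ω displacement field).

    Returns the sequence and a truth dict with the cycle frequency and the
    cycle count frequency × duration.
    """
    if kind not in ("clench", "finger_thumb"):
        raise ValueError("kind must be 'clench' or 'finger_thumb'")
    if frequency_hz < 0:
        raise ValueError("frequency must be non-negative")
    if frequency_hz > frame_rate / 4.0:
        raise ValueError("frequency exceeds frame_rate/4 (temporal sampling adequacy)")
    rng = np.random.default_rng(seed)
    f_eff = float(f if f is not None else w)
    bg = 0.25 + 0.5 * gen_texture(seed, h, w)
    blob_tex = gen_texture(seed + 1, h, w)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r0 = min(h, w) / 4.0
    edge = 2.0

    if kind == "clench" and r0 + amplitude_px + edge > min(h, w) / 2.0:
        raise ValueError("blob oscillation exceeds frame bounds")
    gap0 = r0  # finger_thumb: rest gap between blob centres
    r_ft = r0 / 2.0
    if kind == "finger_thumb" and gap0 / 2.0 + amplitude_px / 2.0 + r_ft + edge > h / 2.0:
        raise ValueError("blob oscillation exceeds frame bounds")

    jitter = (
        rng.normal(0.0, jitter_sd, size=(t, 3)) if jitter_sd > 0 else np.zeros((t, 3))
    )
    frames = np.empty((t, h, w))
    for k in range(t):
        phase = 2.0 * np.pi * frequency_hz * k / frame_rate
        if kind == "clench":
            r = r0 + amplitude_px * np.sin(phase)
            s = r / r0
            # blob texture rescaled about the centre: radial motion field
            sample = np.stack([(yy - cy) / s + cy, (xx - cx) / s + cx])
            blob = _ndi.map_coordinates(blob_tex, sample, order=1, mode="nearest")
            dist = np.hypot(yy - cy, xx - cx)
            alpha = _smoothstep((r - dist) / edge)
            frame = bg * (1.0 - alpha) + blob * alpha
        else:
            offset = (gap0 + amplitude_px * np.sin(phase)) / 2.0
            frame = bg.copy()
            for sgn in (-1.0, 1.0):
                by = cy + sgn * offset
                sample = np.stack([yy - (by - cy), xx])
                blob = _ndi.map_coordinates(blob_tex, sample, order=1, mode="nearest")
                dist = np.hypot(yy - by, xx - cx)
                alpha = _smoothstep((r_ft - dist) / edge)
                frame = frame * (1.0 - alpha) + blob * alpha
        if jitter_sd > 0:
            cam = rotational_flow(CameraRotation(tuple(jitter[k]), f_eff), (h, w), dialect)
            frame = _ndi.map_coordinates(
                frame, np.stack([yy - cam.vy, xx - cam.vx]), order=1, mode="grid-wrap"
            )
        frames[k] = frame
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, 1.0)
    duration = t / frame_rate
    seq = FrameSequence(
        frames,
        frame_rate,
        f_eff,
        meta={
            "kind": kind,
            "frequency_hz": frequency_hz,
            "amplitude_px": amplitude_px,
            "noise_sd": noise_sd,
            "jitter_sd": jitter_sd,
            "seed": seed,
        },
    )
    truth = {
        "cycle_frequency_hz": frequency_hz,
        "cycles": frequency_hz * duration,
        "duration_s": duration,
    }
    return seq, truth


def _sample_paired(
    rng: np.random.Generator,
    n: int,
    latent_rho: float,
    marginals: tuple[float, float, float, float],
) -> tuple[np.ndarray, np.ndarray]:
    m1, s1, m2, s2 = marginals
    z = rng.standard_normal((n, 2))
    z2 = latent_rho * z[:, 0] + np.sqrt(max(0.0, 1.0 - latent_rho**2)) * z[:, 1]
    conv = np.maximum(np.round(m1 + s1 * z[:, 0]), 0.0)
    img = np.maximum(m2 + s2 * z2, 0.0)
    return conv, img


from functools import lru_cache


@lru_cache(maxsize=64)
def _calibrate_latent_rho(
    rho: float,
    marginals: tuple[float, float, float, float],
    n_cal: int = 100_000,
    iters: int = 25,
) -> float:
    """Monotone bisection on the latent correlation so the sampled OUTPUT
    (post rounding/clipping) Pearson correlation matches the target.

    Calibration uses its own fixed generator so the mapping is a
    deterministic function of (rho, marginals), independent of the user's
    sampling seed.
    """
    if rho == 0.0:
        return 0.0
    sign = np.sign(rho)
    target = abs(rho)
    lo, hi = 0.0, 0.999999

    def achieved(lat: float) -> float:
        rng = np.random.default_rng(20220608)
        conv, img = _sample_paired(rng, n_cal, lat, marginals)
        return float(np.corrcoef(conv, img)[0, 1])

    if achieved(hi) < target:  # rounding/clipping caps what is reachable
        return float(sign * hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if achieved(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(sign * 0.5 * (lo + hi))


def gen_paired_scores(
    n: int = 46,
    rho: float = 0.72,
    marginals: tuple[float, float, float, float] | None = None,
    seed: int = 0,
    task_id: int = 1,
):
    """Paired conventional/image-derived scores with target Pearson r.

    A bivariate Gaussian copula whose latent correlation is calibrated so
    that the OUTPUT correlation — after the conventional marginal is
    rounded to a count and clipped at 0 and the image-derived marginal is
    clipped at 0 — matches ``rho`` in expectation.  Marginals default to
    the task's Table-2-like (mean, SD) pairs.

    Returns a DataFrame with columns subject_id, task_id, conventional,
    image_derived; the calibrated latent correlation is stored in
    ``df.attrs['latent_rho']``.
    """
    import pandas as pd

    if n < 4:
        raise ValueError("need n >= 4")
    if abs(rho) >= 1.0:
        raise ValueError("|rho| must be < 1")
    if marginals is None:
        marginals = TASK_MARGINALS[task_id]
    latent = _calibrate_latent_rho(float(rho), tuple(float(m) for m in marginals))
    rng = np.random.default_rng(seed)
    conv, img = _sample_paired(rng, n, latent, marginals)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "task_id": task_id,
            "conventional": conv.astype(int),
            "image_derived": img,
        }
    )
    df.attrs["latent_rho"] = latent
    df.attrs["target_rho"] = rho
    return df
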