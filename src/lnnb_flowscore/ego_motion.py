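"""Camera ego-rotation estimation and flow-domain stabilization.

Hand-held recording adds a rotational camera component to the observed
flow.  For an instantaneous camera rotation ω = (ωx, ωy, ωz) and focal
length f, the induced image velocity is linear in ω:

    v(x) = B(x) ω ,

with B evaluated at principal-point-centred pixel coordinates (x rightward,
y downward).  Two dialects of B are supported:

``printed`` (default)::

    B = [[ x*y/f,  (-f - x**2)/f,  y ],
         [ (f + y**2)/f,  -x*y/f, -x ]]

``classical`` — the standard rotational-flow Jacobian, which differs in the
two pure-tilt entries (f² instead of f); the dialects coincide at f = 1::

    B = [[ x*y/f,  -(f**2 + x**2)/f,  y ],
         [ (f**2 + y**2)/f,  -x*y/f, -x ]]

ω is estimated per frame by (optionally robust) linear least squares over
the valid flow pixels, smoothed along time so only the unstable jitter is
attributed to the camera, and subtracted from the observed flow; the
residual is the subject-motion signal passed to scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .optic_flow import FlowField

__all__ = [
    "CameraRotation",
    "RotationEstimate",
    "EgoMotionConfig",
    "projection_matrix",
    "rotational_flow",
    "estimate_rotation",
    "smooth_rotation_track",
    "stabilize_flow",
]

DIALECTS = ("printed", "classical")


@dataclass(frozen=True)
class CameraRotation:
    """Instantaneous camera rotation ω (rad/frame) with focal length f (px)."""

    omega: tuple[float, float, float]
    f: float

    def __post_init__(self) -> None:
        if not self.f > 0:
            raise ValueError("focal length must be positive")
        if not np.all(np.isfinite(self.omega)):
            raise ValueError("rotation components must be finite")
        object.__setattr__(self, "omega", tuple(float(w) for w in self.omega))


@dataclass
class RotationEstimate:
    """A fitted :class:`CameraRotation` plus fit diagnostics."""

    rotation: CameraRotation
    residual_rms: float
    n_valid: int
    downweighted_fraction: float


@dataclass
class EgoMotionConfig:
    bmatrix_dialect: str = "printed"
    irls_iterations: int = 5
    tukey_c: float = 4.685
    smooth_window: int = 5

    def __post_init__(self) -> None:
        if self.bmatrix_dialect not in DIALECTS:
            raise ValueError(f"bmatrix_dialect must be one of {DIALECTS}")


def projection_matrix(
    x: float, y: float, f: float, dialect: str = "printed"
) -> np.ndarray:
    """The 2×3 matrix B(x) mapping ω to image velocity at (x, y).

    Coordinates are relative to the principal point (image centre).
    """
    if not f > 0:
        raise ValueError("focal length must be positive")
    if dialect == "printed":
        return np.array(
            [
                [x * y / f, (-f - x**2) / f, y],
                [(f + y**2) / f, -x * y / f, -x],
            ]
        )
    if dialect == "classical":
        return np.array(
            [
                [x * y / f, -(f**2 + x**2) / f, y],
                [(f**2 + y**2) / f, -x * y / f, -x],
            ]
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def _centered_grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal-point-centred pixel coordinates (x rightward, y downward)."""
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    return x - (w - 1) / 2.0, y - (h - 1) / 2.0


def _b_columns(x, y, f, dialect):
    """The three columns of B evaluated on arrays of coordinates."""
    ff = f if dialect == "printed" else f * f
    bx = np.stack([x * y / f, (-ff - x**2) / f, y], axis=-1)
    by = np.stack([(ff + y**2) / f, -x * y / f, -x], axis=-1)
    return bx, by


def rotational_flow(
    rot: CameraRotation,
    grid: tuple[int, int],
    dialect: str = "printed",
    frame_index: int = 0,
) -> FlowField:
    """Evaluate v(x) = B(x)ω at every pixel of an H×W grid (mask all-true)."""
    h, w = grid
    x, y = _centered_grid(h, w)
    bx, by = _b_columns(x, y, rot.f, dialect)
    omega = np.asarray(rot.omega)
    return FlowField(
        vx=bx @ omega,
        vy=by @ omega,
        valid=np.ones((h, w), dtype=bool),
        frame_index=frame_index,
    )


def estimate_rotation(
    flow: FlowField,
    f: float,
    robust: bool = True,
    config: EgoMotionConfig | None = None,
) -> RotationEstimate:
    """Least-squares fit of ω from one flow field.

    Minimizes Σ‖v_obs(x) − B(x)ω‖² over valid pixels; with ``robust`` a
    Tukey-biweight IRLS (scale 1.4826·MAD of the per-pixel residual norms)
    downweights independently moving regions such as the hand, so the
    camera term is estimated from the static background.
    """
    config = config or EgoMotionConfig()
    h, w = flow.valid.shape
    ys, xs = np.nonzero(flow.valid)
    if len(xs) < 3:
        raise ValueError("need at least 3 valid pixels to fit a 3-parameter rotation")
    xg, yg = _centered_grid(h, w)
    x = xg[ys, xs]
    y = yg[ys, xs]
    bx, by = _b_columns(x, y, f, config.bmatrix_dialect)
    a = np.concatenate([bx, by], axis=0)  # (2N, 3)
    b = np.concatenate([flow.vx[ys, xs], flow.vy[ys, xs]])

    if np.linalg.matrix_rank(a) < 3:
        raise ValueError("degenerate pixel configuration: rotation not identifiable")

    n = len(xs)
    weights = np.ones(n)
    omega = np.linalg.lstsq(a, b, rcond=None)[0]
    if robust:
        for _ in range(config.irls_iterations):
            res = (a @ omega - b).reshape(2, n)
            rnorm = np.hypot(res[0], res[1])
            mad = np.median(np.abs(rnorm - np.median(rnorm)))
            scale = 1.4826 * mad
            if scale < 1e-12:
                # residual scale collapsed (fit already tight on the
                # inliers); keep the converged weights for diagnostics
                weights = np.where(rnorm <= 10 * (scale + 1e-15), weights, 0.0)
                break
            u = rnorm / (config.tukey_c * scale)
            weights = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
            if weights.sum() < 3:  # keep the fit identifiable
                break
            wfull = np.sqrt(np.concatenate([weights, weights]))
            omega = np.linalg.lstsq(a * wfull[:, None], b * wfull, rcond=None)[0]

    res = (a @ omega - b).reshape(2, n)
    rnorm = np.hypot(res[0], res[1])
    return RotationEstimate(
        rotation=CameraRotation(tuple(omega), f),
        residual_rms=float(np.sqrt(np.mean(rnorm**2))),
        n_valid=n,
        downweighted_fraction=float(np.mean(weights < 0.5)),
    )


def smooth_rotation_track(
    rotations: list[CameraRotation], window: int = 5
) -> list[CameraRotation]:
    """Temporally regularize per-frame ω by a moving median.

    Only the unstable (jitter) component should be attributed to the
    camera; a median over ``window`` frames passes slow drift and removes
    single-frame spikes.  Tracks shorter than the window are handled with
    nearest-edge padding; a length-1 track is returned unchanged.
    """
    if not rotations:
        raise ValueError("empty rotation track")
    if len(rotations) == 1:
        return list(rotations)
    from scipy.ndimage import median_filter

    arr = np.array([r.omega for r in rotations])  # (T, 3)
    smoothed = np.stack(
        [median_filter(arr[:, j], size=window, mode="nearest") for j in range(3)],
        axis=1,
    )
    return [
        CameraRotation(tuple(smoothed[i]), rotations[i].f)
        for i in range(len(rotations))
    ]


def stabilize_flow(
    flow: FlowField, rot: CameraRotation, dialect: str = "printed"
) -> FlowField:
    """Subtract the camera-rotation field: residual = v_obs − B(x)ω.

    The residual, on the original validity mask, is the subject-motion
    signal passed to scoring.
    """
    h, w = flow.valid.shape
    cam = rotational_flow(rot, (h, w), dialect=dialect)
    if cam.vx.shape != flow.vx.shape:
        raise ValueError("flow and rotation grid dimensions differ")
    return FlowField(
        vx=flow.vx - cam.vx,
        vy=flow.vy - cam.vy,
        valid=flow.valid.copy(),
        frame_index=flow.frame_index,
    )
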