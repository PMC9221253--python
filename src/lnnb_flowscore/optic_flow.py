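"""Dense phase-based optic flow.

The motion signal is read from the *phase* of oriented quadrature (Gabor)
filter responses rather than from raw brightness: contours of constant
phase track the moving image structure and are far less sensitive to
illumination and contrast changes.  For each orientation k with unit normal
n̂_k, the temporal drift of phase gives a component (normal) velocity

    v_n = -φ_t / ‖∇φ‖        along  ∇φ / ‖∇φ‖ ,

and the full velocity at a pixel solves the over-determined system
min_v Σ_k w_k (n̂_k·v − v_{n,k})² over the reliable orientation channels.

Reliability of a channel at a pixel requires (a) response amplitude above a
fraction of the frame maximum, (b) a small residual of the linear temporal
phase fit (phase-linearity test), and (c) a usable spatial phase gradient.
The temporal derivative is a least-squares slope over a short window of
frames, which is what makes test (b) possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilterBank",
    "FlowConfig",
    "PhaseVolume",
    "ComponentVelocity",
    "FlowField",
    "build_filter_bank",
    "compute_phase",
    "component_velocity",
    "combine_components",
    "compute_flow",
    "export_flow",
    "import_flow",
]


@dataclass(frozen=True)
class FilterBank:
    """Oriented Gabor quadrature filter bank.

    ``n_orientations`` evenly spaced angles in [0, π); each filter is an
    even/odd (cosine/sine) pair with spatial wavelength ``wavelength_px``
    and Gaussian envelope ``sigma_px``.  ``temporal_window`` frames are used
    for each temporal phase-derivative fit.
    """

    n_orientations: int = 8
    wavelength_px: float = 8.0
    sigma_px: float = 4.0
    temporal_window: int = 5

    def __post_init__(self) -> None:
        if self.n_orientations < 3:
            raise ValueError(
                "need at least 3 orientations (2 independent constraints plus redundancy)"
            )
        if self.wavelength_px <= 2:
            raise ValueError("wavelength must exceed 2 px (Nyquist)")
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")
        if self.temporal_window < 3 or self.temporal_window % 2 == 0:
            raise ValueError("temporal_window must be an odd integer >= 3")

    @property
    def orientations(self) -> np.ndarray:
        """Filter orientations in radians, evenly spaced in [0, π)."""
        return np.arange(self.n_orientations) * (np.pi / self.n_orientations)

    def kernel(self, theta: float) -> np.ndarray:
        """Complex Gabor kernel (even + i·odd) at orientation ``theta``.

        The even part has its residual DC removed so blank regions give
        (numerically) zero response.
        """
        half = int(np.ceil(3.0 * self.sigma_px))
        y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
        env = np.exp(-(x**2 + y**2) / (2.0 * self.sigma_px**2))
        k = 2.0 * np.pi / self.wavelength_px
        carrier = np.exp(1j * k * (x * np.cos(theta) + y * np.sin(theta)))
        g = env * carrier
        even = g.real - env * (g.real.sum() / env.sum())
        kernel = (even + 1j * g.imag) / env.sum()
        return kernel


def build_filter_bank(
    n_orientations: int = 8,
    wavelength_px: float = 8.0,
    sigma_px: float = 4.0,
    temporal_window: int = 5,
) -> FilterBank:
    """Construct and validate a :class:`FilterBank`."""
    return FilterBank(n_orientations, wavelength_px, sigma_px, temporal_window)


@dataclass
class FlowConfig:
    """Reliability thresholds and numerical guards for flow estimation.

    amplitude_frac
        Channel amplitude must exceed this fraction of the frame's maximum
        amplitude for that orientation.
    residual_max_rad
        Maximum RMS residual (radians) of the linear temporal phase fit.
    grad_min_rad_px
        Minimum spatial phase-gradient magnitude (rad/px).
    slope_tsig
        Detection test on the temporal phase slope: the fitted slope must
        exceed ``slope_tsig`` standard errors (derived from the fit
        residuals) before a channel is trusted, so sensor noise on a
        static scene does not masquerade as slow motion.  An exactly
        static, noise-free channel (slope 0, zero residual) passes.
    min_valid_neighbors, coherence_abs_px, coherence_rel
        Spatial-coherence validity filter applied to the combined field:
        a valid pixel must have at least ``min_valid_neighbors`` valid
        3×3 neighbours and deviate from their median velocity by at most
        max(coherence_abs_px, coherence_rel·‖median‖) px/frame.  True
        motion is locally smooth; noise vectors that survive the
        per-channel tests are isolated and incoherent, so this is the
        outlier-rejection pass familiar from particle-image velocimetry.
    v_max_px
        Speed cap in px/frame; full velocities are clipped to this norm.
    cond_max
        Maximum condition number of the 2×2 normal matrix before a pixel is
        declared aperture-limited (invalid).
    boundary
        'wrap' filters with circular boundary (matches the periodic
        synthetic fixtures and avoids border roll-off); 'fill' zero-pads.
    """

    amplitude_frac: float = 0.05
    residual_max_rad: float = 0.5
    grad_min_rad_px: float = 0.05
    slope_tsig: float = 4.0
    v_max_px: float = 10.0
    cond_max: float = 1e3
    boundary: str = "wrap"
    min_valid_neighbors: int = 4
    coherence_abs_px: float = 0.25
    coherence_rel: float = 0.5


@dataclass
class PhaseVolume:
    """Amplitude/phase of one orientation channel over a frame range."""

    orientation: float
    amplitude: np.ndarray  # (T, H, W), >= 0
    phase: np.ndarray  # (T, H, W), in (-pi, pi]


@dataclass
class ComponentVelocity:
    """Normal velocities of one orientation channel on the interior frames.

    Frames carrying a full temporal window are ``frame_offset ..
    frame_offset + vn.shape[0] - 1`` of the source sequence.
    """

    orientation: float
    vn: np.ndarray  # (Ti, H, W) signed normal speed, px/frame
    nx: np.ndarray  # unit constraint normal, x component (array or scalar)
    ny: np.ndarray  # unit constraint normal, y component (array or scalar)
    weight: np.ndarray  # (Ti, H, W) channel amplitude
    reliable: np.ndarray  # (Ti, H, W) bool
    frame_offset: int


@dataclass
class FlowField:
    """Per-pixel 2-D velocity for one frame pair, with a validity mask."""

    vx: np.ndarray
    vy: np.ndarray
    valid: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=np.float64)
        self.vy = np.asarray(self.vy, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.vx.shape == self.vy.shape == self.valid.shape):
            raise ValueError("vx, vy and valid must share a shape")
        if self.valid.any() and not np.all(
            np.isfinite(self.vx[self.valid]) & np.isfinite(self.vy[self.valid])
        ):
            raise ValueError("non-finite velocities on valid pixels")

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)


def _filter_frames(frames: np.ndarray, kernel: np.ndarray, boundary: str) -> np.ndarray:
    """Convolve every frame with a complex kernel; returns complex64 (T,H,W)."""
    t, h, w = frames.shape
    if boundary == "wrap":
        kh, kw = kernel.shape
        pad = np.zeros((h, w), dtype=np.complex128)
        pad[:kh, :kw] = kernel
        # centre the kernel at the origin for circular convolution
        pad = np.roll(pad, (-(kh // 2), -(kw // 2)), axis=(0, 1))
        kf = np.fft.fft2(pad)
        out = np.empty((t, h, w), dtype=np.complex64)
        for i in range(t):
            out[i] = np.fft.ifft2(np.fft.fft2(frames[i]) * kf)
        return out
    from scipy.signal import fftconvolve

    out = np.empty((t, h, w), dtype=np.complex64)
    for i in range(t):
        out[i] = fftconvolve(frames[i], kernel, mode="same")
    return out


def _phase_for_orientation(frames, bank: FilterBank, theta: float, boundary: str):
    resp = _filter_frames(frames, bank.kernel(theta), boundary)
    return PhaseVolume(
        orientation=theta,
        amplitude=np.abs(resp).astype(np.float32),
        phase=np.angle(resp).astype(np.float32),
    )


def compute_phase(seq, bank: FilterBank, config: FlowConfig | None = None):
    """Amplitude/phase volumes for every orientation of the bank.

    ``seq`` may be a FrameSequence or a raw (T, H, W) array.
    """
    config = config or FlowConfig()
    frames = np.asarray(getattr(seq, "frames", seq), dtype=np.float64)
    if frames.shape[0] < bank.temporal_window:
        raise ValueError(
            f"sequence of {frames.shape[0]} frames is shorter than the "
            f"temporal window ({bank.temporal_window})"
        )
    return [
        _phase_for_orientation(frames, bank, theta, config.boundary)
        for theta in bank.orientations
    ]


def _wrap(d: np.ndarray) -> np.ndarray:
    """Wrap phase differences into (-pi, pi]."""
    return d - 2.0 * np.pi * np.round(d / (2.0 * np.pi))


def component_velocity(
    pv: PhaseVolume, temporal_window: int = 5, config: FlowConfig | None = None
) -> ComponentVelocity:
    """Normal velocity and reliability mask for one orientation channel.

    The temporal phase derivative φ_t is the least-squares slope of the
    unwrapped phase over a centred window of ``temporal_window`` frames
    (unwrapping accumulates pairwise wrapped differences, never a global
    unwrap); the spatial gradient averages the two one-pixel wrapped
    differences.  A pixel is reliable when the channel amplitude, the
    temporal-fit residual and the gradient magnitude all pass their
    thresholds and the implied speed is below the cap.
    """
    config = config or FlowConfig()
    if temporal_window < 3 or temporal_window % 2 == 0:
        raise ValueError("temporal_window must be an odd integer >= 3")
    phi = np.asarray(pv.phase, dtype=np.float64)
    rho = np.asarray(pv.amplitude, dtype=np.float64)
    t, h, w = phi.shape
    if t < temporal_window:
        raise ValueError("phase volume shorter than temporal window")
    hw = temporal_window // 2

    # Cumulative unwrapped phase along time: C[t] - C[s] is the unwrapped
    # phase change from frame s to t provided each step stays within pi.
    d = _wrap(np.diff(phi, axis=0))
    c = np.concatenate([np.zeros((1, h, w)), np.cumsum(d, axis=0)], axis=0)

    ti = t - 2 * hw  # number of interior (full-window) frames
    offs = np.arange(-hw, hw + 1)
    m2 = float((offs**2).sum())
    # slope and residual of the linear fit, windows stacked via slicing
    sum_m_c = np.zeros((ti, h, w))
    sum_c = np.zeros((ti, h, w))
    for m in offs:
        sum_m_c += m * c[hw + m : hw + m + ti]
        sum_c += c[hw + m : hw + m + ti]
    slope = sum_m_c / m2
    mean_c = sum_c / temporal_window
    res_sq = np.zeros((ti, h, w))
    for m in offs:
        r = c[hw + m : hw + m + ti] - mean_c - slope * m
        res_sq += r * r
    rms = np.sqrt(res_sq / temporal_window)
    # standard error of the fitted slope (residual df = window - 2)
    slope_se = np.sqrt(res_sq / max(temporal_window - 2, 1)) / np.sqrt(m2)

    phi_i = phi[hw : hw + ti]
    # spatial gradient: mean of forward/backward one-pixel wrapped diffs
    gx = np.zeros_like(phi_i)
    gy = np.zeros_like(phi_i)
    gx[:, :, 1:-1] = 0.5 * (
        _wrap(phi_i[:, :, 2:] - phi_i[:, :, 1:-1])
        + _wrap(phi_i[:, :, 1:-1] - phi_i[:, :, :-2])
    )
    gy[:, 1:-1, :] = 0.5 * (
        _wrap(phi_i[:, 2:, :] - phi_i[:, 1:-1, :])
        + _wrap(phi_i[:, 1:-1, :] - phi_i[:, :-2, :])
    )
    grad = np.hypot(gx, gy)

    rho_i = rho[hw : hw + ti]
    amp_max = rho_i.reshape(ti, -1).max(axis=1).reshape(ti, 1, 1)
    ok_grad = grad >= config.grad_min_rad_px
    with np.errstate(divide="ignore", invalid="ignore"):
        vn_raw = np.where(ok_grad, -slope / np.where(ok_grad, grad, 1.0), 0.0)
    reliable = (
        (rho_i >= config.amplitude_frac * np.maximum(amp_max, 1e-30))
        & (rms <= config.residual_max_rad)
        & (np.abs(slope) + 1e-9 >= config.slope_tsig * slope_se)
        & ok_grad
        & (np.abs(vn_raw) <= config.v_max_px)
    )
    reliable[:, 0, :] = reliable[:, -1, :] = False
    reliable[:, :, 0] = reliable[:, :, -1] = False

    # Constraint normal is the per-pixel phase-gradient direction (the
    # exact phase-constancy equation ∇φ·v + φ_t = 0), not the nominal
    # filter orientation; the two agree where the channel is well tuned.
    safe = np.where(ok_grad, grad, 1.0)
    nx = np.where(ok_grad, gx / safe, np.cos(pv.orientation))
    ny = np.where(ok_grad, gy / safe, np.sin(pv.orientation))

    return ComponentVelocity(
        orientation=pv.orientation,
        vn=vn_raw,
        nx=nx,
        ny=ny,
        weight=rho_i,
        reliable=reliable,
        frame_offset=hw,
    )


def combine_components(
    components: list[ComponentVelocity], config: FlowConfig | None = None
) -> list[FlowField]:
    """Solve the weighted phase-constancy system for the full velocity.

    At each pixel, min_v Σ_k w_k (n̂_k·v − v_{n,k})² over reliable channels;
    pixels with fewer than 2 reliable channels or an ill-conditioned 2×2
    normal matrix (aperture problem) are invalid.  Valid speeds are clipped
    to ``v_max_px``.
    """
    config = config or FlowConfig()
    if not components:
        raise ValueError("no components to combine")
    ti, h, w = components[0].vn.shape
    sxx = np.zeros((ti, h, w))
    sxy = np.zeros((ti, h, w))
    syy = np.zeros((ti, h, w))
    bx = np.zeros((ti, h, w))
    by = np.zeros((ti, h, w))
    count = np.zeros((ti, h, w), dtype=np.int32)
    for comp in components:
        wgt = np.where(comp.reliable, comp.weight, 0.0)
        sxx += wgt * comp.nx * comp.nx
        sxy += wgt * comp.nx * comp.ny
        syy += wgt * comp.ny * comp.ny
        bx += wgt * comp.nx * comp.vn
        by += wgt * comp.ny * comp.vn
        count += comp.reliable

    det = sxx * syy - sxy * sxy
    tr = sxx + syy
    disc = np.sqrt(np.maximum(tr * tr - 4.0 * det, 0.0))
    lam_min = 0.5 * (tr - disc)
    lam_max = 0.5 * (tr + disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(lam_min > 0, lam_max / np.where(lam_min > 0, lam_min, 1.0), np.inf)
    valid = (count >= 2) & (lam_min > 1e-12) & (cond <= config.cond_max)

    safe_det = np.where(valid, det, 1.0)
    vx = np.where(valid, (syy * bx - sxy * by) / safe_det, 0.0)
    vy = np.where(valid, (sxx * by - sxy * bx) / safe_det, 0.0)
    speed = np.hypot(vx, vy)
    over = speed > config.v_max_px
    scale = np.where(over, config.v_max_px / np.where(over, speed, 1.0), 1.0)
    vx *= scale
    vy *= scale

    off = components[0].frame_offset
    fields = []
    for i in range(ti):
        v = _coherence_filter(vx[i], vy[i], valid[i], config)
        fields.append(FlowField(vx[i], vy[i], v, frame_index=off + i))
    return fields


def _coherence_filter(
    vx: np.ndarray, vy: np.ndarray, valid: np.ndarray, config: FlowConfig
) -> np.ndarray:
    """Spatial-coherence validity pass (neighbourhood support + median test)."""
    if config.min_valid_neighbors <= 0:
        return valid
    h, w = valid.shape
    shifts = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    nvx = np.full((8, h, w), np.nan)
    nvy = np.full((8, h, w), np.nan)
    for s, (dy, dx) in enumerate(shifts):
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        yd = slice(max(-dy, 0), h + min(-dy, 0))
        xd = slice(max(-dx, 0), w + min(-dx, 0))
        sub_valid = valid[ys, xs]
        nvx[s][yd, xd] = np.where(sub_valid, vx[ys, xs], np.nan)
        nvy[s][yd, xd] = np.where(sub_valid, vy[ys, xs], np.nan)
    n_nb = np.sum(~np.isnan(nvx), axis=0)
    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        med_x = np.nanmedian(nvx, axis=0)
        med_y = np.nanmedian(nvy, axis=0)
    med_x = np.nan_to_num(med_x)
    med_y = np.nan_to_num(med_y)
    dev = np.hypot(vx - med_x, vy - med_y)
    tol = np.maximum(config.coherence_abs_px, config.coherence_rel * np.hypot(med_x, med_y))
    return valid & (n_nb >= config.min_valid_neighbors) & (dev <= tol)


def compute_flow(
    seq, bank: FilterBank | None = None, config: FlowConfig | None = None
) -> list[FlowField]:
    """Dense flow for every interior frame of a sequence.

    Composition of :func:`compute_phase` → :func:`component_velocity` →
    :func:`combine_components`, processing one orientation at a time to
    bound memory.  Returns one :class:`FlowField` per frame that carries a
    full temporal window; ``frame_index`` refers to the source sequence.
    """
    bank = bank or FilterBank()
    config = config or FlowConfig()
    frames = np.asarray(getattr(seq, "frames", seq), dtype=np.float64)
    if frames.shape[0] < bank.temporal_window:
        raise ValueError(
            f"sequence of {frames.shape[0]} frames is shorter than the "
            f"temporal window ({bank.temporal_window})"
        )
    components = []
    for theta in bank.orientations:
        pv = _phase_for_orientation(frames, bank, theta, config.boundary)
        components.append(component_velocity(pv, bank.temporal_window, config))
        del pv
    return combine_components(components, config)


def export_flow(flows: list[FlowField], path: str) -> None:
    """Write flow fields as a multi-page float32 TIFF.

    Each frame contributes three pages: vx, vy and the validity mask
    (1.0/0.0); frame indices go into the page descriptions.
    """
    import tifffile

    pages = []
    for fl in flows:
        pages.extend(
            [
                fl.vx.astype(np.float32),
                fl.vy.astype(np.float32),
                fl.valid.astype(np.float32),
            ]
        )
    tifffile.imwrite(
        path,
        np.stack(pages),
        metadata={"frame_indices": [fl.frame_index for fl in flows]},
    )


def import_flow(path: str) -> list[FlowField]:
    """Read flow fields written by :func:`export_flow`."""
    import json as _json

    import tifffile

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    idx = meta.get("frame_indices")
    if data.ndim != 3 or data.shape[0] % 3:
        raise ValueError(f"{path!r} is not a vx/vy/mask page triplet stack")
    n = data.shape[0] // 3
    if isinstance(idx, str):
        idx = _json.loads(idx)
    if idx is None:
        idx = list(range(n))
    return [
        FlowField(data[3 * i], data[3 * i + 1], data[3 * i + 2] > 0.5, int(idx[i]))
        for i in range(n)
    ]
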