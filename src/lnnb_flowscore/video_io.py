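"""Reading, writing and normalization of hand-movement video.

Everything downstream (flow, stabilization, scoring) consumes the canonical
:class:`FrameSequence`: a T×H×W grid of grayscale intensities in [0, 1] with
a frame rate and a camera focal length in pixel units.  Recordings arrive
either as container video (MP4/AVI, decoded through whatever imageio plugin
is installed) or as numbered PNG/TIFF image sequences.

Normalization resamples every recording onto a common spatial grid, frame
count and duration, so that scores from different subjects and devices are
comparable, and rescales intensities robustly to [0, 1].
"""

from __future__ import annotations

import glob as _glob
import os
import re
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as _sktransform
from skimage.util import img_as_float

__all__ = [
    "FrameSequence",
    "VideoReadError",
    "read_video",
    "normalize_sequence",
    "write_frames",
]

#: Default normalization targets: 240x320 px, 30 fps, 10 s (T = 300).
DEFAULT_TARGET_H = 240
DEFAULT_TARGET_W = 320
DEFAULT_TARGET_FRAMES = 300
DEFAULT_TARGET_DURATION_S = 10.0
DEFAULT_PERCENTILE_CLIP = (1.0, 99.0)

# ITU-R BT.709 luminance weights (matches skimage.color.rgb2gray).
_LUMA = np.array([0.2125, 0.7154, 0.0721])


class VideoReadError(RuntimeError):
    """Raised when a video file or image sequence cannot be decoded."""


@dataclass
class FrameSequence:
    """A normalized grayscale video clip.

    Parameters
    ----------
    frames
        Array of shape (T, H, W) with finite intensities in [0, 1].
    frame_rate
        Frames per second.
    focal_length_px
        Camera focal length in pixel units (``f`` of the ego-motion model).
        When ``None`` it defaults to the image width, i.e. roughly a 53
        degree horizontal field of view.
    meta
        Free-form subject/task labels and provenance.
    """

    frames: np.ndarray
    frame_rate: float
    focal_length_px: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W); got shape {self.frames.shape}")
        t, h, w = self.frames.shape
        if t < 2:
            raise ValueError(f"need at least 2 frames, got {t}")
        if h < 16 or w < 16:
            raise ValueError(f"frames must be at least 16x16, got {h}x{w}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite intensities")
        if self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.focal_length_px is None:
            self.focal_length_px = float(w)
        if not self.focal_length_px > 0:
            raise ValueError("focal_length_px must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration_s(self) -> float:
        """Clip duration in seconds (T / frame_rate)."""
        return self.frames.shape[0] / self.frame_rate


def _to_gray01(frame: np.ndarray) -> np.ndarray:
    """Convert a decoded frame to float64 grayscale in [0, 1]."""
    frame = img_as_float(frame)
    if frame.ndim == 3:
        if frame.shape[-1] == 4:  # drop alpha
            frame = frame[..., :3]
        if frame.shape[-1] == 3:
            frame = frame @ _LUMA
        elif frame.shape[-1] == 1:
            frame = frame[..., 0]
        else:
            raise VideoReadError(f"cannot interpret frame with shape {frame.shape}")
    return np.clip(frame, 0.0, 1.0)


_NUM_RE = re.compile(r"(\d+)")


def _natural_key(path: str) -> list:
    name = os.path.basename(path)
    return [int(p) if p.isdigit() else p for p in _NUM_RE.split(name)]


def _list_sequence_files(path: str) -> list[str]:
    if os.path.isdir(path):
        exts = (".png", ".tif", ".tiff")
        files = [
            os.path.join(path, f)
            for f in os.listdir(path)
            if f.lower().endswith(exts)
        ]
    else:  # glob pattern
        files = _glob.glob(path)
    return sorted(files, key=_natural_key)


def read_video(
    path: str,
    focal_length_px: float | None = None,
    frame_rate: float | None = None,
    meta: dict | None = None,
) -> FrameSequence:
    """Read a container video or numbered image sequence.

    Parameters
    ----------
    path
        An MP4/AVI file, a directory of numbered PNG/TIFF frames, or a glob
        pattern matching such frames.
    focal_length_px
        Camera focal length in pixels; defaults to the image width.
    frame_rate
        Required for image sequences (there is no container metadata to
        take it from); for container video it overrides the metadata value.

    Raises
    ------
    VideoReadError
        Missing file, zero decodable frames, inconsistent frame sizes, or
        unknown frame rate for an image sequence.
    """
    meta = dict(meta or {})
    is_sequence = os.path.isdir(path) or any(c in path for c in "*?[")
    if not is_sequence and not os.path.exists(path):
        raise VideoReadError(f"no such file: {path}")

    if is_sequence:
        files = _list_sequence_files(path)
        if not files:
            raise VideoReadError(f"zero decodable frames under {path!r}")
        if frame_rate is None:
            raise VideoReadError(
                "frame_rate must be supplied for image sequences (no container metadata)"
            )
        import imageio.v3 as iio

        frames = []
        for fp in files:
            try:
                frames.append(_to_gray01(iio.imread(fp)))
            except (OSError, ValueError) as exc:
                raise VideoReadError(f"cannot decode frame {fp}: {exc}") from exc
        meta.setdefault("source", path)
    else:
        import imageio.v2 as iio2

        try:
            reader = iio2.get_reader(path)
        except Exception as exc:  # no plugin for this container
            raise VideoReadError(
                f"cannot open {path!r}: no installed imageio plugin decodes it ({exc})"
            ) from exc
        with reader:
            if frame_rate is None:
                frame_rate = reader.get_meta_data().get("fps")
            if frame_rate is None:
                raise VideoReadError(f"container {path!r} reports no frame rate")
            frames = [_to_gray01(np.asarray(f)) for f in reader]
        if not frames:
            raise VideoReadError(f"zero decodable frames in {path!r}")
        meta.setdefault("source", path)

    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise VideoReadError(f"frames of inconsistent size: {sorted(shapes)}")
    if len(frames) < 2:
        raise VideoReadError("need at least 2 decodable frames")
    return FrameSequence(
        np.stack(frames), float(frame_rate), focal_length_px, meta=meta
    )


def _rescale_intensity(
    frames: np.ndarray, percentile_clip: tuple[float, float]
) -> np.ndarray:
    """Clip at robust percentiles then min-max to [0, 1].

    Constant input has zero percentile range and is returned unchanged
    (already within [0, 1]); robust clipping makes the rescale insensitive
    to specular highlights.
    """
    lo, hi = np.percentile(frames, percentile_clip)
    if hi - lo < 1e-12:
        return np.clip(frames, 0.0, 1.0)
    out = (np.clip(frames, lo, hi) - lo) / (hi - lo)
    return out


def normalize_sequence(
    seq: FrameSequence,
    target_h: int = DEFAULT_TARGET_H,
    target_w: int = DEFAULT_TARGET_W,
    target_frames: int = DEFAULT_TARGET_FRAMES,
    target_duration_s: float = DEFAULT_TARGET_DURATION_S,
    percentile_clip: tuple[float, float] = DEFAULT_PERCENTILE_CLIP,
) -> FrameSequence:
    """Resample a sequence onto the pre-defined grid, frame count and duration.

    Spatial resampling is bilinear (anti-aliased when downsampling);
    temporal resampling interpolates linearly between neighbouring frames at
    ``target_frames`` instants uniformly spanning the original duration.
    Output ``frame_rate = target_frames / target_duration_s`` and the focal
    length is scaled by the width ratio so angular units are preserved.
    """
    if min(target_h, target_w, target_frames) <= 0 or target_duration_s <= 0:
        raise ValueError("normalization targets must be positive")
    t_src, h_src, w_src = seq.shape
    if t_src < 2:
        raise ValueError("sequence shorter than 2 frames")

    # Temporal resample: target sample j sits at source index j * T_src / T_tgt
    # so an already-matching sequence maps onto itself exactly.
    idx = np.arange(target_frames) * (t_src / target_frames)
    idx = np.clip(idx, 0.0, t_src - 1)
    i0 = np.floor(idx).astype(int)
    i1 = np.minimum(i0 + 1, t_src - 1)
    a = (idx - i0)[:, None, None]
    frames = (1.0 - a) * seq.frames[i0] + a * seq.frames[i1]

    if (h_src, w_src) != (target_h, target_w):
        down = target_h < h_src or target_w < w_src
        frames = np.stack(
            [
                _sktransform.resize(
                    f,
                    (target_h, target_w),
                    order=1,
                    mode="reflect",
                    anti_aliasing=down,
                    preserve_range=True,
                )
                for f in frames
            ]
        )

    frames = _rescale_intensity(frames, percentile_clip)
    meta = dict(seq.meta)
    meta.update(
        normalized=True,
        percentile_clip=tuple(percentile_clip),
        source_shape=(t_src, h_src, w_src),
        source_frame_rate=seq.frame_rate,
    )
    return FrameSequence(
        frames,
        frame_rate=target_frames / target_duration_s,
        focal_length_px=seq.focal_length_px * (target_w / w_src),
        meta=meta,
    )


def write_frames(seq: FrameSequence, out_dir: str, prefix: str = "frame") -> list[str]:
    """Dump the sequence as a 16-bit PNG sequence (lossless, for debugging)."""
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, frame in enumerate(seq.frames):
        p = os.path.join(out_dir, f"{prefix}_{i:05d}.png")
        iio.imwrite(p, np.round(frame * 65535).astype(np.uint16))
        paths.append(p)
    return paths
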