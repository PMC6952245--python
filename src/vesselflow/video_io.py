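"""Video and mask I/O with explicit frame-rate and channel metadata.

Conventions used throughout the package:

* Pixel coordinates are ``(row, col)``, 0-based, row 0 at the top.
* Frames are stored as float arrays in ``[0, 1]``; 8-bit input maps
  255 -> 1.0 exactly, so the normalization is a bijection on the 8-bit
  lattice and a write/read round trip through the lossless frame-stack
  format is bit-exact at 8-bit quantization.
* Channel order is fixed to (red, green, blue) after ingestion; the green
  channel -- the one carrying the plethysmographic signal -- is index 1.

The canonical lossless format is a directory of ``frame_%05d.png`` files
plus a ``clip.json`` metadata file holding the frame rate.  Compressed
containers (AVI/MP4) are accepted on input when an imageio video backend
is available, but tests and synthetic data use frame stacks only.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio

#: Fixed channel convention after ingestion.
CHANNEL_ORDER = ("red", "green", "blue")
#: Index of the green channel.
GREEN = 1

_META_NAME = "clip.json"
_FRAME_FMT = "frame_{:05d}.png"
_FRAME_RE = re.compile(r"frame_(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


@dataclass
class VideoClip:
    """A stack of colour frames with a frame rate.

    Parameters
    ----------
    frames:
        Array of shape ``(T, H, W, 3)`` with intensities in ``[0, 1]``.
    fps:
        Frame rate in Hz.
    """

    frames: np.ndarray
    fps: float
    channel_order: tuple = field(default=CHANNEL_ORDER, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"frames must have shape (T, H, W, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("a clip needs at least 2 frames")
        if not np.isfinite(self.frames).all():
            raise ValueError("frame intensities must be finite")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities outside [0, 1]: min={lo}, max={hi}")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        self.fps = float(self.fps)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.n_frames / self.fps

    @property
    def green(self) -> np.ndarray:
        """The green-channel stack, shape ``(T, H, W)`` (a view)."""
        return self.frames[..., GREEN]


@dataclass
class VesselMask:
    """Binary labelmap of the segmented vessel on a reference frame."""

    mask: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("empty mask: no foreground pixels")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


def _to_unit(img: np.ndarray) -> np.ndarray:
    """Rescale an image array to float intensities in [0, 1]."""
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    out = img.astype(float)
    if out.size and out.max() > 1.0 + 1e-9:  # e.g. float frames stored 0..255
        out = out / 255.0
    return out


def _as_rgb(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return np.stack([frame] * 3, axis=-1)
    if frame.ndim == 3 and frame.shape[-1] == 4:
        return frame[..., :3]
    if frame.ndim == 3 and frame.shape[-1] == 3:
        return frame
    raise ValueError(f"cannot interpret frame with shape {frame.shape}")


def _frame_files(directory: Path) -> list[Path]:
    files = [p for p in directory.iterdir() if _FRAME_RE.search(p.name)]
    files.sort(key=lambda p: int(_FRAME_RE.search(p.name).group(1)))
    return files


def read_clip(path: str | Path, fps_override: float | None = None) -> VideoClip:
    """Read a video clip from a frame-stack directory or a video container.

    For a directory input the frame rate is taken from ``clip.json`` if
    present, else ``fps_override`` is required.  For container input an
    imageio video backend must be available.
    """
    path = Path(path)
    if path.is_dir():
        files = _frame_files(path)
        if not files:
            raise ValueError(f"no frame_%05d images found in {path}")
        frames = np.stack([_as_rgb(_to_unit(iio.imread(f))) for f in files])
        fps = fps_override
        meta = path / _META_NAME
        if fps is None and meta.exists():
            fps = json.loads(meta.read_text()).get("fps")
        if fps is None:
            raise ValueError("fps_override required for frame-stack input")
        return VideoClip(frames, float(fps))
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = iio.imread(path, plugin="pyav")  # container path
        meta = iio.immeta(path, plugin="pyav")
    except Exception:
        try:
            raw = iio.imread(path)
            meta = iio.immeta(path)
        except Exception as exc:  # pragma: no cover - backend-dependent
            raise ValueError(f"unreadable video file {path}: {exc}") from exc
    frames = np.stack([_as_rgb(_to_unit(f)) for f in np.atleast_3d(raw)])
    fps = fps_override or meta.get("fps")
    if fps is None:
        raise ValueError("frame rate not found in container; pass fps_override")
    return VideoClip(frames, float(fps))


def write_clip(clip: VideoClip, path: str | Path) -> None:
    """Write a clip as a lossless 8-bit PNG frame stack with metadata.

    Values are quantized with round-half-away (``np.rint``) so that the
    read/write round trip is exact on the 8-bit lattice.
    """
    if not isinstance(clip, VideoClip):
        raise TypeError("write_clip expects a VideoClip")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(clip.frames):
        data = np.rint(np.clip(frame, 0, 1) * 255).astype(np.uint8)
        iio.imwrite(path / _FRAME_FMT.format(i), data)
    (path / _META_NAME).write_text(json.dumps({"fps": clip.fps}))


def read_mask(path: str | Path, clip: VideoClip, frame_index: int = 0) -> VesselMask:
    """Read a segmentation labelmap; any nonzero pixel becomes foreground."""
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        img = img.any(axis=-1)
    mask = img != 0
    if mask.shape != (clip.height, clip.width):
        raise ValueError(
            f"mask shape {mask.shape} does not match clip "
            f"({clip.height}, {clip.width})"
        )
    return VesselMask(mask, frame_index=frame_index)


def write_mask(mask: VesselMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.mask.astype(np.uint8)) * 255)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a float [0,1] (or uint8) image as PNG."""
    img = np.asarray(img)
    if img.dtype != np.uint8:
        img = np.rint(np.clip(img, 0, 1) * 255).astype(np.uint8)
    iio.imwrite(Path(path), img)
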