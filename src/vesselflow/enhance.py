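"""Eulerian colour magnification in the cardiac frequency band.

The pulsatile colour change of a vessel is far below visual threshold.
Writing a frame as I_t and the per-pixel temporal mean as I_ref, the
band-passed deviation

    delta_t = bandpass(I_t - I_ref),   band default 0.8-3 Hz

is amplified and added back,

    I'_t = I_t + alpha * delta_t,

which magnifies any in-band sinusoid exactly (1 + alpha)-fold while
leaving out-of-band content unchanged.  The band-pass is an ideal
(brick-wall) frequency-domain filter, so these closed forms hold to
numerical precision.  The un-clipped amplified green channel is retained
separately so that display clipping can never corrupt the analysis
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .video_io import GREEN, VideoClip


@dataclass
class EnhancementConfig:
    """Magnification settings.

    alpha : dimensionless magnification factor (>= 0).
    band : (f_lo, f_hi) pass band in Hz.
    spatial_sigma : Gaussian blur sigma in px applied to delta before
        amplification (0 disables; coarse spatial pooling of the
        pulsation signal).
    channels : colour channels to amplify (default all three).
    """

    alpha: float = 50.0
    band: tuple[float, float] = (0.8, 3.0)
    spatial_sigma: float = 3.0
    channels: tuple[int, ...] = (0, 1, 2)

    def validate(self, fps: float) -> None:
        lo, hi = self.band
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (0 < lo < hi < fps / 2):
            raise ValueError(f"band {self.band} must satisfy 0 < lo < hi < fps/2")


@dataclass
class EnhancedClip:
    """Result of colour magnification.

    ``frames`` is the displayable clip (input + alpha*delta, clipped to
    [0,1]); ``delta`` the band-passed deviation stack; ``green_analysis``
    the un-clipped amplified green channel used by signal extraction.
    """

    frames: np.ndarray  # (T, H, W, 3), clipped
    reference_frame: np.ndarray  # (H, W, 3)
    delta: np.ndarray  # (T, H, W, 3)
    green_analysis: np.ndarray  # (T, H, W), un-clipped
    fps: float
    config: EnhancementConfig = field(default_factory=EnhancementConfig)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def as_clip(self) -> VideoClip:
        return VideoClip(self.frames, self.fps)


def temporal_bandpass(
    signal: np.ndarray,
    fps: float,
    band: tuple[float, float],
    axis: int = -1,
) -> np.ndarray:
    """Ideal frequency-domain band-pass along ``axis``.

    Fourier coefficients whose frequency lies inside [f_lo, f_hi]
    (inclusive) are kept, all others -- including DC -- are zeroed.
    Idempotent, linear, and exact on single FFT bins.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[axis]
    if n < 4:
        raise ValueError("time series too short for band-pass (need >= 4 samples)")
    lo, hi = band
    if not (0 < lo < hi < fps / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={fps / 2})")
    spec = np.fft.rfft(signal, axis=axis)
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    keep = (freqs >= lo) & (freqs <= hi)
    shape = [1] * signal.ndim
    shape[axis] = len(freqs)
    spec = spec * keep.reshape(shape)
    return np.fft.irfft(spec, n=n, axis=axis)


def magnify_colour(clip: VideoClip, cfg: EnhancementConfig) -> EnhancedClip:
    """Amplify in-band colour fluctuations of ``clip`` by ``cfg.alpha``."""
    cfg.validate(clip.fps)
    lo, _ = cfg.band
    if clip.duration < 2.0 / lo:
        raise ValueError(
            f"clip too short ({clip.duration:.2f} s) for band lower edge "
            f"{lo} Hz; need >= {2.0 / lo:.2f} s"
        )
    reference = clip.frames.mean(axis=0)
    delta = np.zeros_like(clip.frames)
    for c in cfg.channels:
        d = temporal_bandpass(clip.frames[..., c] - reference[..., c],
                              clip.fps, cfg.band, axis=0)
        if cfg.spatial_sigma > 0:
            d = ndi.gaussian_filter(d, sigma=(0, cfg.spatial_sigma, cfg.spatial_sigma))
        delta[..., c] = d
    amplified = clip.frames + cfg.alpha * delta
    green_analysis = amplified[..., GREEN].copy()
    frames = np.clip(amplified, 0.0, 1.0)
    return EnhancedClip(
        frames=frames,
        reference_frame=reference,
        delta=delta,
        green_analysis=green_analysis,
        fps=clip.fps,
        config=cfg,
    )
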