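"""Synthetic pulsatile-vessel videos with known ground-truth flow direction.

Software counterpart of a pump-driven silicone vessel phantom: a curved
tube in a tissue-coloured scene whose green channel carries a periodic
pulse wave propagating along the vessel at a known speed.  The pump
drive is a rectangular on/off cycle (default period 1 s, on for 1/3 s,
off for 2/3 s -- approximating the systolic/diastolic time fractions of
the cardiac cycle), optionally Gaussian-smoothed so the fundamental
dominates the analysis band.  The dye raises the red channel; blood
volume raises green absorption, so the pulse *decreases* the green
channel (direction inference is sign-agnostic, it uses relative phase
only).  Additive Gaussian pixel noise and slow global translational
camera jitter are optional.  Everything is seeded and bit-reproducible,
and the ground truth (direction, wave speed, per-px delay, seed) is
returned as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from scipy.special import erf

from .video_io import VesselMask, VideoClip

A_TO_B = "a_to_b"
B_TO_A = "b_to_a"

_CURVE_STEP_PX = 0.25  # arclength sampling step of the centre curve
_JITTER_FREQ_HZ = 0.3  # slow, breathing-like


@dataclass
class PumpParams:
    """Rectangular pump drive: period (s), duty cycle, Gaussian smoothing (s)."""

    period: float = 1.0
    on_fraction: float = 1.0 / 3.0
    smoothing_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("pump period must be positive")
        if not 0 < self.on_fraction < 1:
            raise ValueError("on_fraction must be in (0, 1)")


@dataclass
class SynthConfig:
    geometry: str = "straight"  # "straight" | "s_curve"
    control_points: np.ndarray | None = None  # optional (N, 2) (row, col)
    shape: tuple[int, int] = (96, 160)
    radius: float = 5.0
    fps: float = 60.0
    duration: float = 8.0
    pump: PumpParams = field(default_factory=PumpParams)
    wave_speed: float = 500.0  # px/s along the vessel
    pulse_amplitude: float = 0.05  # green-channel dip
    vessel_colour: tuple[float, float, float] = (0.55, 0.45, 0.30)
    background_colour: tuple[float, float, float] = (0.72, 0.62, 0.58)
    noise_sigma: float = 0.005
    texture_amplitude: float = 0.04  # static tissue-like spatial texture
    jitter_px: float = 0.0
    seed: int = 0
    true_direction: str = A_TO_B

    def __post_init__(self) -> None:
        if self.true_direction not in (A_TO_B, B_TO_A):
            raise ValueError("true_direction must be 'a_to_b' or 'b_to_a'")
        if self.radius < 2:
            raise ValueError("tube radius must be >= 2 px")
        if self.wave_speed <= 0:
            raise ValueError("wave_speed must be positive (np.inf allowed)")


def pump_waveform(t: np.ndarray | float, pump: PumpParams) -> np.ndarray:
    """Dimensionless pump drive in [0, 1] at time(s) ``t`` (seconds).

    A period-P rectangle (1 for the first on_fraction of each cycle)
    convolved with a Gaussian of width smoothing_sigma; sigma = 0 gives
    the hard on/off cycle exactly.
    """
    t = np.asarray(t, dtype=float)
    P = pump.period
    on = pump.on_fraction * P
    tau = np.mod(t, P)
    if pump.smoothing_sigma <= 0:
        return (tau < on).astype(float)
    s = pump.smoothing_sigma * np.sqrt(2.0)
    out = np.zeros_like(tau)
    for k in range(-2, 3):  # neighbouring cycles cover the boundary smoothing
        out += 0.5 * (erf((tau - k * P) / s) - erf((tau - k * P - on) / s))
    return np.clip(out, 0.0, 1.0)


def _centre_curve(cfg: SynthConfig) -> np.ndarray:
    """Densely sampled (row, col) control curve before arclength resampling."""
    H, W = cfg.shape
    margin = cfg.radius + 4
    if cfg.control_points is not None:
        pts = np.asarray(cfg.control_points, float)
        u = np.linspace(0, 1, len(pts))
        uu = np.linspace(0, 1, 2000)
        return np.column_stack([np.interp(uu, u, pts[:, 0]), np.interp(uu, u, pts[:, 1])])
    cols = np.linspace(margin, W - 1 - margin, 2000)
    if cfg.geometry == "straight":
        rows = np.full_like(cols, H / 2.0)
    elif cfg.geometry == "s_curve":
        span = cols[-1] - cols[0]
        amp = 0.15 * H
        rows = H / 2.0 + amp * np.sin(2 * np.pi * 0.75 * (cols - cols[0]) / span)
    else:
        raise ValueError(f"unknown geometry {cfg.geometry!r}")
    return np.column_stack([rows, cols])


def _resample_by_arclength(curve: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    seg = np.hypot(*np.diff(curve, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.arange(0.0, cum[-1], step)
    pts = np.column_stack([np.interp(s, cum, curve[:, 0]), np.interp(s, cum, curve[:, 1])])
    return pts, s


def generate_vessel_video(cfg: SynthConfig) -> tuple[VideoClip, VesselMask, dict]:
    """Render the synthetic clip, its vessel mask, and ground-truth metadata."""
    H, W = cfg.shape
    if 1.0 / cfg.pump.period >= cfg.fps / 2:
        raise ValueError("pump frequency unresolvable at this frame rate")
    fine_pts, s_fine = _resample_by_arclength(_centre_curve(cfg), _CURVE_STEP_PX)
    if (
        fine_pts[:, 0].min() < cfg.radius
        or fine_pts[:, 0].max() > H - 1 - cfg.radius
        or fine_pts[:, 1].min() < cfg.radius
        or fine_pts[:, 1].max() > W - 1 - cfg.radius
    ):
        raise ValueError("tube leaves the frame; shrink the curve or the radius")

    rr, cc = np.mgrid[0:H, 0:W]
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, idx = cKDTree(fine_pts).query(pix)
    mask = (dist <= cfg.radius).reshape(H, W)
    s_map = s_fine[idx].reshape(H, W)

    vrows, vcols = np.nonzero(mask)
    s_vessel = s_map[vrows, vcols]
    total_len = float(s_fine[-1])
    if cfg.true_direction == A_TO_B:
        delay = s_vessel / cfg.wave_speed
    else:
        delay = (total_len - s_vessel) / cfg.wave_speed

    base = np.empty((H, W, 3))
    base[:] = np.asarray(cfg.background_colour)
    base[mask] = np.asarray(cfg.vessel_colour)

    T = int(round(cfg.duration * cfg.fps))
    times = np.arange(T) / cfg.fps
    rng = np.random.default_rng(cfg.seed)

    if cfg.texture_amplitude > 0:
        # static smooth texture: real tissue is not featureless, and
        # registration needs spatial structure away from the vessel
        tex = ndi.gaussian_filter(rng.standard_normal((H, W)), 3.0)
        tex *= cfg.texture_amplitude / max(np.abs(tex).max(), 1e-12)
        base = np.clip(base + tex[:, :, None], 0.0, 1.0)

    if cfg.jitter_px > 0:
        phases = rng.uniform(0, 2 * np.pi, size=2)
        osc = np.sin(2 * np.pi * _JITTER_FREQ_HZ * times[:, None] + phases[None, :])
        jitter = cfg.jitter_px * (osc - osc[0])  # zero at frame 0: mask stays aligned
    else:
        jitter = None

    frames = np.empty((T, H, W, 3))
    green_base = cfg.vessel_colour[1]
    for i, t in enumerate(times):
        frame = base.copy()
        drive = pump_waveform(t - delay, cfg.pump)
        frame[vrows, vcols, 1] = green_base - cfg.pulse_amplitude * drive
        if jitter is not None and np.max(np.abs(jitter[i])) > 1e-9:
            for c in range(3):
                frame[:, :, c] = ndi.shift(frame[:, :, c], jitter[i], order=1,
                                           mode="nearest")
        if cfg.noise_sigma > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sigma, size=frame.shape)
        frames[i] = frame

    clip = VideoClip(np.clip(frames, 0.0, 1.0), cfg.fps)
    vmask = VesselMask(mask, frame_index=0)
    metadata = {
        "seed": cfg.seed,
        "true_direction": cfg.true_direction,
        "wave_speed_px_per_s": float(cfg.wave_speed),
        "delay_s_per_px": float(1.0 / cfg.wave_speed),
        "fps": cfg.fps,
        "duration_s": cfg.duration,
        "pump": asdict(cfg.pump),
        "pulse_amplitude": cfg.pulse_amplitude,
        "noise_sigma": cfg.noise_sigma,
        "texture_amplitude": cfg.texture_amplitude,
        "jitter_px": cfg.jitter_px,
        "arclength_px": total_len,
        "endpoint_a": [float(x) for x in fine_pts[0]],
        "endpoint_b": [float(x) for x in fine_pts[-1]],
        "geometry": cfg.geometry,
        "radius_px": cfg.radius,
    }
    return clip, vmask, metadata
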