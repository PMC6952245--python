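"""Per-vertex pulse signals, heart-rate estimation, and Fourier phase.

Oxyhemoglobin absorbs most strongly in the green part of the visible
spectrum, so the green channel carries the strongest plethysmographic
signal and is used exclusively.  Every mask pixel is assigned to its
nearest centerline vertex (Euclidean distance, ties to the lower vertex
index) and each vertex's time series is the mean green intensity of its
pixel cell.  The heart rate is the in-band DFT bin of largest magnitude
of the vertex-averaged signal (rectangular window, no zero padding, so
the estimate snaps to the grid fps/T).  The phase theta of each sampled
vertex (every ``stride``-th vertex, default every second one) is the
argument of its DFT coefficient at the heart-rate bin, under the forward
DFT sign convention in which delaying a signal by dt changes its phase
by -2*pi*f*dt -- so theta decreases downstream along the flow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .centerline import CenterlinePolyline
from .enhance import EnhancedClip
from .video_io import VesselMask, VideoClip

DEFAULT_BAND = (0.8, 3.0)
DEFAULT_STRIDE = 2


@dataclass
class VertexSignalSet:
    """Per-vertex mean green-channel time series.

    ``signals`` is V x T; ``vertex_pixel_counts`` sums to the mask's
    foreground pixel count (every mask pixel belongs to exactly one
    vertex); ``vertex_coords`` are the (row, col) polyline vertices the
    rows correspond to.
    """

    signals: np.ndarray  # (V, T)
    vertex_pixel_counts: np.ndarray  # (V,)
    vertex_coords: np.ndarray  # (V, 2)
    fps: float

    @property
    def n_vertices(self) -> int:
        return self.signals.shape[0]

    @property
    def n_frames(self) -> int:
        return self.signals.shape[1]


@dataclass
class PhaseProfile:
    """Phase at the heart-rate frequency for the sampled vertices."""

    f_heart: float  # Hz
    heart_bin: int  # DFT bin index
    sampled_vertex_indices: np.ndarray  # indices into the polyline
    theta: np.ndarray  # radians, in [-pi, pi]
    fps: float

    def __post_init__(self) -> None:
        self.sampled_vertex_indices = np.asarray(self.sampled_vertex_indices, int)
        self.theta = np.asarray(self.theta, float)
        if np.any(np.abs(self.theta) > np.pi + 1e-12):
            raise ValueError("theta outside [-pi, pi]")


def assign_pixels_to_vertices(
    mask: VesselMask, polyline: CenterlinePolyline
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-vertex partition of the mask's foreground pixels.

    Returns (pixel_rows, pixel_cols, vertex_index_per_pixel).  Ties in
    Euclidean distance go to the lower vertex index.
    """
    rows, cols = np.nonzero(mask.mask)
    v = polyline.vertices.astype(float)
    d2 = (rows[:, None] - v[None, :, 0]) ** 2 + (cols[:, None] - v[None, :, 1]) ** 2
    assign = np.argmin(d2, axis=1)  # argmin returns the first (lowest) index on ties
    return rows, cols, assign


def extract_vertex_signals(
    clip: VideoClip | EnhancedClip,
    mask: VesselMask,
    polyline: CenterlinePolyline,
) -> VertexSignalSet:
    """Mean green intensity per vertex cell per frame.

    Accepts either a raw clip or an enhanced clip; for the latter the
    un-clipped amplified green channel is analysed so that display
    clipping never distorts the signal.
    """
    if isinstance(clip, EnhancedClip):
        green = clip.green_analysis
        fps = clip.fps
    else:
        green = clip.green
        fps = clip.fps
    rows, cols, assign = assign_pixels_to_vertices(mask, polyline)
    V = polyline.n_vertices
    counts = np.bincount(assign, minlength=V)
    if (counts == 0).any():
        empty = np.flatnonzero(counts == 0)
        warnings.warn(f"vertices {empty.tolist()} have no assigned pixels; "
                      "their signals are zero and excluded from analysis")
    pix_ts = green[:, rows, cols]  # (T, N)
    T = pix_ts.shape[0]
    sums = np.zeros((V, T))
    np.add.at(sums, assign, pix_ts.T)
    signals = np.divide(
        sums, counts[:, None], out=np.zeros_like(sums), where=counts[:, None] > 0
    )
    return VertexSignalSet(
        signals=signals,
        vertex_pixel_counts=counts,
        vertex_coords=polyline.vertices.copy(),
        fps=fps,
    )


def estimate_heart_rate(
    vss: VertexSignalSet, band: tuple[float, float] = DEFAULT_BAND
) -> tuple[float, int]:
    """Dominant in-band frequency of the vertex-averaged signal.

    Returns (f_heart in Hz, DFT bin index).  DC is excluded; the search
    is restricted to bins whose frequency lies within ``band``.
    """
    lo, hi = band
    T = vss.n_frames
    if T < 2 * vss.fps / lo:
        raise ValueError(
            f"clip too short for heart-rate search: {T} frames at {vss.fps} fps "
            f"covers fewer than two periods of {lo} Hz"
        )
    used = vss.vertex_pixel_counts > 0
    avg = vss.signals[used].mean(axis=0)
    spec = np.fft.rfft(avg)
    freqs = np.fft.rfftfreq(T, d=1.0 / vss.fps)
    in_band = (freqs >= lo) & (freqs <= hi) & (np.arange(len(freqs)) > 0)
    if not in_band.any():
        raise ValueError("no DFT bin falls inside the search band (clip too short)")
    mags = np.abs(spec)
    if mags[in_band].max() < 1e-9 * T:
        raise ValueError("no in-band component (signal has no oscillation)")
    heart_bin = int(np.flatnonzero(in_band)[np.argmax(mags[in_band])])
    f_heart = heart_bin * vss.fps / T
    return f_heart, heart_bin


def vertex_phase(
    vss: VertexSignalSet, heart_bin: int, stride: int = DEFAULT_STRIDE
) -> PhaseProfile:
    """Phase of each sampled vertex at the heart-rate DFT bin."""
    T = vss.n_frames
    n_bins = T // 2 + 1
    if not 0 < heart_bin < n_bins:
        raise ValueError(f"heart_bin {heart_bin} out of range (1..{n_bins - 1})")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sampled = np.arange(0, vss.n_vertices, stride)
    sampled = sampled[vss.vertex_pixel_counts[sampled] > 0]
    spec = np.fft.rfft(vss.signals[sampled], axis=1)
    theta = np.angle(spec[:, heart_bin])
    return PhaseProfile(
        f_heart=heart_bin * vss.fps / T,
        heart_bin=heart_bin,
        sampled_vertex_indices=sampled,
        theta=theta,
        fps=vss.fps,
    )
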