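"""Automatic annotation: direction arrows and the phase colourmap.

Arrows are overlaid on a representative frame (by default the
stabilization reference frame), one per accepted vertex pair, tail at
the higher-phase vertex and head at the lower-phase vertex, so the
arrows point along the flow.  Rejected pairs leave gaps.  When no pair
is accepted the frame is returned with an "indeterminate" caption only.
The phase map colours every vessel pixel by the phase of its nearest
sampled vertex on a perceptually ordered colourmap spanning [-pi, pi]
(fixed range so colours are comparable across videos).  Rendering is a
pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image, ImageDraw, ImageFont

from .centerline import CenterlinePolyline
from .direction import ACCEPTED, FlowDirectionResult
from .signals import PhaseProfile, VertexSignalSet
from .video_io import VesselMask

DEFAULT_ARROW_COLOUR = (0, 255, 255)  # cyan: high contrast on tissue reds
PHASE_CMAP = "viridis"


@dataclass
class AnnotatedFrame:
    image: np.ndarray  # (H, W, 3) float in [0, 1]
    arrow_segments: list  # [((row, col) tail, (row, col) head), ...]
    colour: tuple


def _to_pil(frame: np.ndarray) -> Image.Image:
    arr = np.rint(np.clip(np.asarray(frame, float), 0, 1) * 255).astype(np.uint8)
    return Image.fromarray(arr, mode="RGB")


def _draw_arrow(draw: ImageDraw.ImageDraw, tail_rc, head_rc, colour, width) -> None:
    (r0, c0), (r1, c1) = tail_rc, head_rc
    # PIL works in (x, y) = (col, row)
    draw.line([(c0, r0), (c1, r1)], fill=colour, width=width)
    v = np.array([c1 - c0, r1 - r0], dtype=float)
    n = np.hypot(*v)
    if n < 1e-9:
        return
    v /= n
    size = max(4.0, 3.0 * width)
    perp = np.array([-v[1], v[0]])
    tip = np.array([c1, r1])
    left = tip - size * v + 0.5 * size * perp
    right = tip - size * v - 0.5 * size * perp
    draw.polygon([tuple(tip), tuple(left), tuple(right)], fill=colour)


def render_arrows(
    frame: np.ndarray,
    result: FlowDirectionResult,
    polyline: CenterlinePolyline,
    colour: tuple = DEFAULT_ARROW_COLOUR,
    arrow_width_px: int = 2,
) -> AnnotatedFrame:
    """Overlay one flow arrow per accepted pair on a representative frame."""
    img = _to_pil(frame)
    draw = ImageDraw.Draw(img)
    segments = []
    for pair in result.pairs:
        if pair.status != ACCEPTED:
            continue
        a = tuple(int(x) for x in polyline.vertices[pair.vertex_a])
        b = tuple(int(x) for x in polyline.vertices[pair.vertex_b])
        # delta_theta = theta_b - theta_a: negative means a is upstream
        tail, head = (a, b) if pair.delta_theta < 0 else (b, a)
        _draw_arrow(draw, tail, head, colour, arrow_width_px)
        segments.append((tail, head))
    if not segments:
        font = ImageFont.load_default()
        draw.text((4, 4), "flow direction indeterminate", fill=colour, font=font)
    return AnnotatedFrame(
        image=np.asarray(img, dtype=float) / 255.0,
        arrow_segments=segments,
        colour=colour,
    )


def render_phase_map(
    frame: np.ndarray,
    mask: VesselMask,
    profile: PhaseProfile,
    vss: VertexSignalSet,
) -> np.ndarray:
    """Colour each vessel pixel by the phase of its nearest sampled vertex.

    Background pixels are returned untouched; the colourmap spans the
    fixed range [-pi, pi].
    """
    out = np.clip(np.asarray(frame, float), 0, 1).copy()
    rows, cols = np.nonzero(mask.mask)
    coords = vss.vertex_coords[profile.sampled_vertex_indices].astype(float)
    d2 = (rows[:, None] - coords[None, :, 0]) ** 2 + (
        cols[:, None] - coords[None, :, 1]
    ) ** 2
    nearest = np.argmin(d2, axis=1)
    theta = profile.theta[nearest]
    cmap = colormaps[PHASE_CMAP]
    colours = cmap((theta + np.pi) / (2 * np.pi))[:, :3]
    out[rows, cols] = colours
    return out
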