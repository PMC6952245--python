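"""Vessel centerline extraction: labelmap -> skeleton -> ordered polyline.

The segmentation labelmap is thinned to a 1-px structural skeleton,
small spur branches left by thinning of hand-drawn polygons are pruned,
the skeleton is traced into an ordered pixel path (two-pass traversal:
walk from the first scanned pixel to one free end, then walk the whole
path from that end -- complete regardless of where the scan started),
and the path is downsampled by a factor k (default 25) into a polyline
whose vertices anchor all downstream per-vertex signal analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize

from .video_io import VesselMask

#: ring order (clockwise from north) used for neighbour counting and the
#: crossing-number junction test.
_RING = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)
#: traversal preference: 4-connected neighbours first (clockwise from
#: north), then diagonals.  Preferring edge-neighbours stops the greedy
#: walk from cutting right-angle corners and skipping the corner pixel.
_NEIGHBOURS = (
    (-1, 0), (0, 1), (1, 0), (0, -1), (-1, 1), (1, 1), (1, -1), (-1, -1),
)

DEFAULT_DOWNSAMPLE = 25
DEFAULT_PRUNE_PX = 10


@dataclass
class Skeleton:
    """1-px-wide, 8-connected structural skeleton of a vessel mask."""

    image: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image).astype(bool)
        if self.image.ndim != 2:
            raise ValueError("skeleton image must be 2-D")
        if not self.image.any():
            raise ValueError("empty skeleton")

    @property
    def n_pixels(self) -> int:
        return int(self.image.sum())


@dataclass
class CenterlinePolyline:
    """Ordered, downsampled centerline vertices in (row, col) coordinates."""

    vertices: np.ndarray  # (V, 2) int
    downsample_factor: int
    source_path_length: int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (V, 2)")
        if len(self.vertices) < 2:
            raise ValueError("polyline needs at least 2 vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def reversed(self) -> "CenterlinePolyline":
        return CenterlinePolyline(
            self.vertices[::-1].copy(),
            self.downsample_factor,
            self.source_path_length,
        )


def _neighbour_count(img: np.ndarray) -> np.ndarray:
    """Number of 8-connected skeleton neighbours at each skeleton pixel."""
    padded = np.pad(img.astype(int), 1)
    count = np.zeros_like(padded)
    for dr, dc in _RING:
        count += np.roll(np.roll(padded, -dr, axis=0), -dc, axis=1)
    return (count[1:-1, 1:-1]) * img


def _crossing_number(img: np.ndarray) -> np.ndarray:
    """Rutovitz crossing number: 0->1 transitions around each pixel's
    8-neighbour ring.  1 marks an endpoint, 2 a path pixel, >= 3 a true
    junction (right-angle corners stay at 2, unlike a raw neighbour count).
    """
    padded = np.pad(img.astype(int), 1)
    ring = [np.roll(np.roll(padded, -dr, axis=0), -dc, axis=1)[1:-1, 1:-1]
            for dr, dc in _RING]
    crossings = np.zeros(img.shape, dtype=int)
    for i in range(len(ring)):
        crossings += (ring[i - 1] == 0) & (ring[i] == 1)
    return crossings * img


def _prune_spurs(img: np.ndarray, min_len: int) -> np.ndarray:
    """Remove endpoint-to-junction branches shorter than ``min_len`` px."""
    img = img.copy()
    changed = True
    while changed:
        changed = False
        counts = _crossing_number(img)
        endpoints = np.argwhere(img & (counts == 1))
        for r0, c0 in endpoints:
            if not img[r0, c0]:
                continue
            path = [(int(r0), int(c0))]
            visited = {path[0]}
            while True:
                r, c = path[-1]
                nxt = None
                for dr, dc in _NEIGHBOURS:
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < img.shape[0]
                        and 0 <= cc < img.shape[1]
                        and img[rr, cc]
                        and (rr, cc) not in visited
                    ):
                        nxt = (rr, cc)
                        break
                if nxt is None:
                    break  # isolated path; leave intact
                if counts[nxt] >= 3:
                    # branch meets a junction: prune if short
                    if len(path) < min_len:
                        for pr, pc in path:
                            img[pr, pc] = False
                        changed = True
                    nxt = None
                    break
                path.append(nxt)
                visited.add(nxt)
                if len(path) >= min_len:
                    break  # long enough, keep
    return img


def skeletonize(mask: VesselMask, prune_spurs_px: int = DEFAULT_PRUNE_PX) -> Skeleton:
    """Thin the mask to its structural skeleton, pruning short spurs."""
    skel = _sk_skeletonize(mask.mask)
    if prune_spurs_px > 0:
        pruned = _prune_spurs(skel, prune_spurs_px)
        if pruned.any():
            skel = pruned
    if not skel.any():
        raise ValueError("mask eroded to an empty skeleton")
    return Skeleton(skel)


def _first_scan_pixel(img: np.ndarray) -> tuple[int, int]:
    """First nonzero pixel in column-major scan order (down columns,
    left to right)."""
    cols_first = np.argwhere(img.T)  # rows of img.T are columns of img
    c, r = cols_first[0]
    return int(r), int(c)


def _walk(img: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Greedy walk from ``start``: repeatedly step to the first unvisited
    8-neighbour on the skeleton (fixed clockwise order from north)."""
    path = [start]
    visited = {start}
    H, W = img.shape
    while True:
        r, c = path[-1]
        nxt = None
        for dr, dc in _NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and img[rr, cc] and (rr, cc) not in visited:
                nxt = (rr, cc)
                break
        if nxt is None:
            return path
        path.append(nxt)
        visited.add(nxt)


def trace_skeleton(
    skel: Skeleton, start: tuple[int, int] | None = None
) -> np.ndarray:
    """Trace the skeleton into an ordered (row, col) pixel path.

    Two passes: a first walk from the scan start finds one free end of
    the skeleton; a second walk restarted from that end covers the whole
    simple path.  For a simple-path skeleton the result contains every
    skeleton pixel exactly once, for any scan start.  Skeletons with
    junction pixels (>= 3 neighbours) are traversed deterministically
    with a warning; pixels on untaken branches may be skipped.
    """
    img = skel.image
    if start is None:
        start = _first_scan_pixel(img)
    else:
        start = (int(start[0]), int(start[1]))
        if not img[start]:
            raise ValueError("start pixel is not on the skeleton")
    if (_crossing_number(img) >= 3).any():
        warnings.warn("skeleton has junction pixels; traversal may skip branches")
    first_pass = _walk(img, start)
    path = _walk(img, first_pass[-1])
    return np.array(path, dtype=int)


def downsample_polyline(path: np.ndarray, k: int) -> CenterlinePolyline:
    """Keep every k-th path pixel, always including both endpoints.

    For a path of length L the vertex count is ceil((L-1)/k) + 1.
    """
    path = np.asarray(path, dtype=int)
    L = len(path)
    if L < 2:
        raise ValueError("path must contain at least 2 pixels")
    if k < 1:
        raise ValueError("downsample factor must be >= 1")
    if k >= L:
        warnings.warn(f"downsample factor {k} >= path length {L}; "
                      "polyline degenerates to the two endpoints")
        idx = [0, L - 1]
    else:
        idx = list(range(0, L, k))
        if idx[-1] != L - 1:
            idx.append(L - 1)
    return CenterlinePolyline(path[idx], downsample_factor=k, source_path_length=L)


def choose_auto_factor(path_length: int, k_max: int = DEFAULT_DOWNSAMPLE,
                       min_vertices: int = 5) -> int:
    """Largest k <= k_max whose downsampled polyline keeps >= min_vertices."""
    for k in range(k_max, 0, -1):
        if int(np.ceil((path_length - 1) / k)) + 1 >= min_vertices:
            return k
    return 1


def extract_centerline(
    mask: VesselMask,
    downsample_factor: int = DEFAULT_DOWNSAMPLE,
    auto_factor: bool = False,
    prune_spurs_px: int = DEFAULT_PRUNE_PX,
) -> CenterlinePolyline:
    """Full labelmap -> polyline workflow (thin, prune, trace, downsample)."""
    skel = skeletonize(mask, prune_spurs_px=prune_spurs_px)
    path = trace_skeleton(skel)
    k = downsample_factor
    if auto_factor:
        k = choose_auto_factor(len(path), k_max=downsample_factor)
    return downsample_polyline(path, k)
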