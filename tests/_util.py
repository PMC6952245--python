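"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi

import vesselflow as vf
from vesselflow.direction import A_TO_B, B_TO_A, INDETERMINATE


def make_texture(shape=(64, 64), seed=0, blur=3.0, lo=0.1, hi=0.9):
    """Smooth random texture with full dynamic range, for registration tests."""
    rng = np.random.default_rng(seed)
    img = ndi.gaussian_filter(rng.uniform(0, 1, shape), blur)
    img = (img - img.min()) / (img.max() - img.min())
    return lo + (hi - lo) * img


def textured_clip(T=10, shape=(64, 64), seed=0, fps=30.0):
    """A static textured colour clip (identical frames)."""
    tex = make_texture(shape, seed=seed)
    frames = np.repeat(np.stack([tex, tex * 0.9, tex * 0.8], axis=-1)[None], T, axis=0)
    return vf.VideoClip(frames, fps)


def shift_frames(clip: vf.VideoClip, shifts) -> vf.VideoClip:
    """Apply a known per-frame translation (row, col) to every frame."""
    out = np.empty_like(clip.frames)
    for t, sh in enumerate(shifts):
        for c in range(3):
            out[t, :, :, c] = ndi.shift(clip.frames[t, :, :, c], sh, order=3,
                                        mode="nearest")
    return vf.VideoClip(np.clip(out, 0, 1), clip.fps)


def analyse(clip, mask, run_cfg=None, polyline=None):
    """Enhance -> signals -> direction with an optional externally supplied
    polyline (for vertex-order invariance checks)."""
    cfg = run_cfg or default_run_config()
    enhanced = vf.magnify_colour(clip, cfg.enhance)
    if polyline is None:
        polyline = vf.extract_centerline(
            mask,
            downsample_factor=cfg.centerline.downsample_factor,
            auto_factor=cfg.centerline.auto_factor,
        )
    vss = vf.extract_vertex_signals(enhanced, mask, polyline)
    f_heart, heart_bin = vf.estimate_heart_rate(vss, band=cfg.signals.band)
    profile = vf.vertex_phase(vss, heart_bin, stride=cfg.signals.stride)
    result = vf.infer_direction(
        profile, vf.DirectionConfig(f_video=clip.fps, f_heart=f_heart)
    )
    result.endpoints = (
        tuple(int(x) for x in polyline.vertices[0]),
        tuple(int(x) for x in polyline.vertices[-1]),
    )
    return polyline, vss, profile, result


def default_run_config():
    cfg = vf.RunConfig()
    cfg.stabilize.enabled = False
    cfg.enhance.channels = (1,)  # analysis reads green only
    return cfg


def flip_label(overall: str) -> str:
    if overall == A_TO_B:
        return B_TO_A
    if overall == B_TO_A:
        return A_TO_B
    return INDETERMINATE


def physical_downstream(result):
    """(row, col) of the endpoint the inferred flow points toward."""
    if result.overall == A_TO_B:
        return np.asarray(result.endpoints[1], float)
    if result.overall == B_TO_A:
        return np.asarray(result.endpoints[0], float)
    return None


def direction_is_correct(result, meta) -> bool:
    """Compare the inferred direction with synth ground truth by geometry
    (the traced polyline's orientation is arbitrary)."""
    down = physical_downstream(result)
    if down is None:
        return False
    a = np.asarray(meta["endpoint_a"])
    b = np.asarray(meta["endpoint_b"])
    true_down = b if meta["true_direction"] == "a_to_b" else a
    true_up = a if meta["true_direction"] == "a_to_b" else b
    return np.linalg.norm(down - true_down) < np.linalg.norm(down - true_up)


def direction_is_reversed(result, meta) -> bool:
    down = physical_downstream(result)
    if down is None:
        return False
    return not direction_is_correct(result, meta)
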