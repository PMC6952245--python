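"""End-to-end orchestration: stabilize -> enhance -> centerline -> signals
-> direction -> annotate, with config validation and JSON/PNG artifacts.

The analysis itself contains no randomness, so a run is fully
reproducible from its inputs and configuration.  An indeterminate
direction (no adjacent-vertex phase difference inside the reliability
window) is a first-class, non-error outcome.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotate as _annotate
from .centerline import (DEFAULT_DOWNSAMPLE, DEFAULT_PRUNE_PX, CenterlinePolyline,
                         extract_centerline)
from .direction import DirectionConfig, FlowDirectionResult, infer_direction
from .enhance import EnhancementConfig, magnify_colour
from .signals import (DEFAULT_BAND, DEFAULT_STRIDE, estimate_heart_rate,
                      extract_vertex_signals, vertex_phase)
from .stabilize import attenuate_residual_motion, stabilize_affine
from .video_io import VesselMask, VideoClip, read_clip, read_mask, write_image

log = logging.getLogger("vesselflow")


@dataclass
class StabilizeConfig:
    enabled: bool = True
    reference_index: int | None = None  # default: the mask's frame
    pyramid_levels: int = 3
    max_iters: int = 50
    attenuate_residual: bool = False
    residual_cutoff_hz: float = 0.5


@dataclass
class CenterlineConfig:
    downsample_factor: int = DEFAULT_DOWNSAMPLE
    auto_factor: bool = False
    prune_spurs_px: int = DEFAULT_PRUNE_PX


@dataclass
class SignalsConfig:
    band: tuple[float, float] = DEFAULT_BAND
    band_units: str = "hz"  # "hz" | "bpm"
    stride: int = DEFAULT_STRIDE


@dataclass
class AnnotateConfig:
    colour: tuple[int, int, int] = _annotate.DEFAULT_ARROW_COLOUR
    arrow_width_px: int = 2


@dataclass
class RunConfig:
    clip_path: str | None = None
    mask_path: str | None = None
    fps_override: float | None = None
    out_dir: str = "vesselflow_out"
    stabilize: StabilizeConfig = field(default_factory=StabilizeConfig)
    enhance: EnhancementConfig = field(default_factory=EnhancementConfig)
    centerline: CenterlineConfig = field(default_factory=CenterlineConfig)
    signals: SignalsConfig = field(default_factory=SignalsConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("stabilize", StabilizeConfig),
            ("enhance", EnhancementConfig),
            ("centerline", CenterlineConfig),
            ("signals", SignalsConfig),
            ("annotate", AnnotateConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        cfg = cls(**d)
        cfg.enhance.band = tuple(cfg.enhance.band)
        cfg.signals.band = tuple(cfg.signals.band)
        cfg.annotate.colour = tuple(cfg.annotate.colour)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def validate_config(cfg: RunConfig, fps: float | None = None) -> list[str]:
    """Check a run configuration; returns a list of problems (empty = OK).

    Heart-rate bands given in beats per minute are converted to Hz in
    place (bpm / 60) and the units normalized to "hz".
    """
    problems: list[str] = []
    if cfg.signals.band_units.lower() == "bpm":
        lo, hi = cfg.signals.band
        cfg.signals.band = (lo / 60.0, hi / 60.0)
        cfg.signals.band_units = "hz"
    if cfg.enhance.alpha < 0:
        problems.append("enhance.alpha must be >= 0")
    for name, (lo, hi) in (("enhance", cfg.enhance.band), ("signals", cfg.signals.band)):
        if not 0 < lo < hi:
            problems.append(f"{name}.band must satisfy 0 < lo < hi")
        elif fps is not None and hi >= fps / 2:
            problems.append(f"{name}.band upper edge {hi} Hz >= Nyquist ({fps / 2} Hz)")
    if cfg.centerline.downsample_factor < 1:
        problems.append("centerline.downsample_factor must be >= 1")
    if cfg.signals.stride < 1:
        problems.append("signals.stride must be >= 1")
    if fps is not None and fps <= 0:
        problems.append("fps must be positive")
    if cfg.fps_override is not None and cfg.fps_override <= 0:
        problems.append("fps_override must be positive")
    return problems


@dataclass
class PipelineOutput:
    """Everything the pipeline computed, for inspection and testing."""

    result: FlowDirectionResult
    polyline: CenterlinePolyline
    vss: object
    profile: object
    f_heart: float
    stabilization: object | None
    annotated: np.ndarray | None = None
    phase_map: np.ndarray | None = None
    timings: dict = field(default_factory=dict)


def run_arrays(clip: VideoClip, mask: VesselMask, cfg: RunConfig,
               render: bool = True) -> PipelineOutput:
    """Run the full analysis on in-memory inputs."""
    problems = validate_config(cfg, fps=clip.fps)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    timings: dict[str, float] = {}

    def _tic(stage: str, t0: float) -> None:
        timings[stage] = time.perf_counter() - t0
        log.info("stage %-10s %.2f s", stage, timings[stage])

    report = None
    t0 = time.perf_counter()
    work = clip
    if cfg.stabilize.enabled:
        ref_idx = cfg.stabilize.reference_index
        if ref_idx is None:
            ref_idx = mask.frame_index
        work, report = stabilize_affine(
            work, reference_index=ref_idx,
            levels=cfg.stabilize.pyramid_levels, max_iters=cfg.stabilize.max_iters,
        )
        if cfg.stabilize.attenuate_residual:
            work = attenuate_residual_motion(work, cfg.stabilize.residual_cutoff_hz)
    _tic("stabilize", t0)

    t0 = time.perf_counter()
    enhanced = magnify_colour(work, cfg.enhance)
    _tic("enhance", t0)

    t0 = time.perf_counter()
    polyline = extract_centerline(
        mask,
        downsample_factor=cfg.centerline.downsample_factor,
        auto_factor=cfg.centerline.auto_factor,
        prune_spurs_px=cfg.centerline.prune_spurs_px,
    )
    _tic("centerline", t0)

    t0 = time.perf_counter()
    vss = extract_vertex_signals(enhanced, mask, polyline)
    f_heart, heart_bin = estimate_heart_rate(vss, band=cfg.signals.band)
    profile = vertex_phase(vss, heart_bin, stride=cfg.signals.stride)
    _tic("signals", t0)

    t0 = time.perf_counter()
    dcfg = DirectionConfig(f_video=clip.fps, f_heart=f_heart)
    result = infer_direction(profile, dcfg)
    a = polyline.vertices[0]
    b = polyline.vertices[-1]
    result.endpoints = (tuple(int(x) for x in a), tuple(int(x) for x in b))
    _tic("direction", t0)

    annotated = phase_map = None
    if render:
        t0 = time.perf_counter()
        ref_idx = report.reference_index if report is not None else mask.frame_index
        rep_frame = clip.frames[ref_idx]
        annotated = _annotate.render_arrows(
            rep_frame, result, polyline,
            colour=cfg.annotate.colour, arrow_width_px=cfg.annotate.arrow_width_px,
        ).image
        phase_map = _annotate.render_phase_map(rep_frame, mask, profile, vss)
        _tic("annotate", t0)

    return PipelineOutput(
        result=result, polyline=polyline, vss=vss, profile=profile,
        f_heart=f_heart, stabilization=report,
        annotated=annotated, phase_map=phase_map, timings=timings,
    )


def result_to_dict(out: PipelineOutput, polyline: CenterlinePolyline) -> dict:
    """JSON-serializable result record (no timing fields: byte-stable)."""
    r = out.result
    return {
        "f_heart_hz": r.f_heart,
        "f_video_hz": r.f_video,
        "overall_direction": r.overall,
        "n_accepted": r.n_accepted,
        "endpoint_a": list(r.endpoints[0]) if r.endpoints else None,
        "endpoint_b": list(r.endpoints[1]) if r.endpoints else None,
        "pairs": [
            {
                "vertex_a": p.vertex_a,
                "vertex_b": p.vertex_b,
                "coord_a": [int(x) for x in polyline.vertices[p.vertex_a]],
                "coord_b": [int(x) for x in polyline.vertices[p.vertex_b]],
                "delta_theta_rad": p.delta_theta,
                "status": p.status,
                "direction": p.direction,
            }
            for p in r.pairs
        ],
    }


def run_pipeline(cfg: RunConfig) -> PipelineOutput:
    """File-based entry point: read inputs, run, write artifacts."""
    if cfg.clip_path is None or cfg.mask_path is None:
        raise ValueError("clip_path and mask_path are required")
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    clip = read_clip(cfg.clip_path, fps_override=cfg.fps_override)
    mask = read_mask(cfg.mask_path, clip)
    out = run_arrays(clip, mask, cfg, render=True)

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "result.json").write_text(
        json.dumps(result_to_dict(out, out.polyline), indent=2, sort_keys=True)
    )
    if out.annotated is not None:
        write_image(out.annotated, out_dir / "annotated.png")
    if out.phase_map is not None:
        write_image(out.phase_map, out_dir / "phase_map.png")
    if out.stabilization is not None:
        rep = out.stabilization
        (out_dir / "stabilization.json").write_text(json.dumps({
            "reference_index": rep.reference_index,
            "params": rep.params.tolist(),
            "residual_before": rep.residual_before.tolist(),
            "residual_after": rep.residual_after.tolist(),
            "warnings": rep.warnings,
        }))
    (out_dir / "timings.json").write_text(json.dumps(out.timings))
    log.info("overall direction: %s (accepted pairs: %d)",
             out.result.overall, out.result.n_accepted)
    return out
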