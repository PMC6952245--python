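"""Flow-direction inference from adjacent-vertex phase differences.

A pulse wave travelling along the vessel delays the plethysmographic
signal by dt per vertex spacing, which appears as a phase difference

    dtheta = -2*pi*f_heart*dt

between adjacent sampled vertices.  A difference is accepted as reliable
only inside the window

    2*pi*f_heart/f_video <= |dtheta| <= pi :

below the lower bound the shift is within the temporal resolution of the
camera (likely noise); above pi it is consistent with phase wrapping
across the +/-pi boundary and is rejected rather than unwrapped.  Each
accepted pair votes for the direction from its higher-phase vertex to
its lower-phase vertex; the overall call is the unweighted majority of
accepted pairs, with ties or an empty set giving an explicit
"indeterminate" outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import PhaseProfile

ACCEPTED = "accepted"
TOO_SMALL = "too_small"
WRAPPED = "wrapped"

#: overall direction labels: a_end is the polyline's first vertex.
A_TO_B = "a_to_b"
B_TO_A = "b_to_a"
INDETERMINATE = "indeterminate"


@dataclass
class DirectionConfig:
    """Frequencies needed by the reliability window."""

    f_video: float  # Hz (clip frame rate)
    f_heart: float  # Hz

    def __post_init__(self) -> None:
        if self.f_heart <= 0 or self.f_video <= 0:
            raise ValueError("frequencies must be positive")
        if self.f_video <= 2 * self.f_heart:
            raise ValueError(
                f"f_video={self.f_video} must exceed twice f_heart={self.f_heart}"
            )

    @property
    def min_abs_dtheta(self) -> float:
        """Smallest reliably detectable phase shift, 2*pi*f_heart/f_video."""
        return 2 * np.pi * self.f_heart / self.f_video


@dataclass
class PairDirection:
    """One adjacent sampled-vertex pair's phase difference and verdict."""

    vertex_a: int  # polyline index of the lower-index sampled vertex
    vertex_b: int
    delta_theta: float  # theta_b - theta_a, raw difference in (-2pi, 2pi)
    status: str  # accepted | too_small | wrapped
    direction: str  # a_to_b | b_to_a | none


@dataclass
class FlowDirectionResult:
    pairs: list[PairDirection]
    overall: str  # a_to_b | b_to_a | indeterminate
    n_accepted: int
    f_heart: float
    f_video: float
    endpoints: tuple | None = None  # ((row,col) of a-end, (row,col) of b-end)
    votes: dict = field(default_factory=dict)

    @property
    def determinate(self) -> bool:
        return self.overall != INDETERMINATE


def phase_differences(profile: PhaseProfile) -> np.ndarray:
    """Raw differences theta_{i+1} - theta_i of consecutive sampled vertices.

    Values lie in (-2pi, 2pi) and are deliberately NOT re-wrapped into
    [-pi, pi]: re-wrapping would disguise wrapped pairs as plausible
    shifts, defeating the |dtheta| <= pi rejection rule.
    """
    if len(profile.theta) < 2:
        raise ValueError("need at least 2 sampled vertices for phase differences")
    return np.diff(profile.theta)


def reliability_filter(delta_theta: float, cfg: DirectionConfig) -> str:
    """Classify a phase difference against the reliability window."""
    mag = abs(float(delta_theta))
    if mag > np.pi:
        return WRAPPED
    if mag < cfg.min_abs_dtheta:
        return TOO_SMALL
    return ACCEPTED


def infer_direction(profile: PhaseProfile, cfg: DirectionConfig) -> FlowDirectionResult:
    """Per-pair verdicts and the overall majority direction.

    The direction of an accepted pair points from the higher-theta vertex
    to the lower-theta vertex (phase decreases downstream).
    """
    dthetas = phase_differences(profile)
    idx = profile.sampled_vertex_indices
    pairs: list[PairDirection] = []
    votes = {A_TO_B: 0, B_TO_A: 0}
    for i, dt in enumerate(dthetas):
        status = reliability_filter(dt, cfg)
        if status == ACCEPTED:
            # dt = theta_b - theta_a; negative means theta drops from a to b
            direction = A_TO_B if dt < 0 else B_TO_A
            votes[direction] += 1
        else:
            direction = "none"
        pairs.append(
            PairDirection(
                vertex_a=int(idx[i]),
                vertex_b=int(idx[i + 1]),
                delta_theta=float(dt),
                status=status,
                direction=direction,
            )
        )
    n_accepted = votes[A_TO_B] + votes[B_TO_A]
    if n_accepted == 0 or votes[A_TO_B] == votes[B_TO_A]:
        overall = INDETERMINATE
    elif votes[A_TO_B] > votes[B_TO_A]:
        overall = A_TO_B
    else:
        overall = B_TO_A
    return FlowDirectionResult(
        pairs=pairs,
        overall=overall,
        n_accepted=n_accepted,
        f_heart=cfg.f_heart,
        f_video=cfg.f_video,
        votes=dict(votes),
    )
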