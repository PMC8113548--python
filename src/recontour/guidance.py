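"""Real-time drill guidance: distance to the planned surface and colour state.

During recontouring the navigation display renders the model green while the
drill tip is still more than 1 mm away from the planned (mirrored) surface
and switches to red once the remaining distance is 1 mm or less — the cue
that the drill is about to reach the designed contour.  This module computes
that signal offline from a tracked pose stream, replacing the head-mounted
display with a logged sequence of samples and state transitions.

The distance is the *signed* distance to the planned surface (positive while
material remains above the plan, negative once the drill has cut past it),
so the red state persists through overshoot.  No hysteresis is applied by
default: state is a pure function of the current distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import GeometryError, signed_distance
from .planning import PlanModel
from .registration import (
    DRILL_DRF,
    FrameGraph,
    PoseStream,
    TimestampRangeError,
    TipCalibration,
    DisconnectedFramesError,
    drill_tip_in_image,
)

__all__ = [
    "GuidanceState",
    "GuidanceConfig",
    "GuidanceSample",
    "Transition",
    "GuidanceLog",
    "classify_state",
    "process_pose_stream",
]


class GuidanceState(str, Enum):
    GREEN = "GREEN"
    RED = "RED"


@dataclass(frozen=True)
class GuidanceConfig:
    """Threshold (mm) separating the green and red states.

    ``hysteresis_mm`` widens the switch-back band for noisy streams; it
    defaults to zero so the two-rule description is taken literally.
    """

    threshold_mm: float = 1.0
    hysteresis_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (self.threshold_mm > 0):
            raise GeometryError("guidance threshold must be positive")
        if self.hysteresis_mm < 0:
            raise GeometryError("hysteresis must be non-negative")


@dataclass(frozen=True)
class GuidanceSample:
    """One reading: tip position (IMAGE frame), signed distance, colour state."""

    timestamp: float
    tip: np.ndarray
    distance_mm: float
    state: GuidanceState

    @property
    def display_mm(self) -> float:
        """The value shown to the surgeon, rounded to 0.01 mm."""
        return round(self.distance_mm, 2)


@dataclass(frozen=True)
class Transition:
    """A GREEN<->RED crossing with its linearly interpolated instant."""

    time: float
    from_state: GuidanceState
    to_state: GuidanceState


@dataclass
class GuidanceLog:
    samples: list[GuidanceSample] = field(default_factory=list)
    transitions: list[Transition] = field(default_factory=list)
    skipped: int = 0

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "time_s": s.timestamp,
                    "tip_x": s.tip[0],
                    "tip_y": s.tip[1],
                    "tip_z": s.tip[2],
                    "distance_mm": s.distance_mm,
                    "state": s.state.value,
                }
                for s in self.samples
            ]
        ).to_csv(path, index=False)

    def transitions_to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_samples": len(self.samples),
                    "n_skipped": self.skipped,
                    "transitions": [
                        {"time_s": t.time, "from": t.from_state.value, "to": t.to_state.value}
                        for t in self.transitions
                    ],
                },
                fh,
                indent=1,
            )


def classify_state(
    distance_mm: float,
    cfg: GuidanceConfig = GuidanceConfig(),
    previous: GuidanceState | None = None,
) -> GuidanceState:
    """GREEN while the drill is more than ``threshold_mm`` from the planned
    surface, RED at or below it (the boundary value is RED).

    With hysteresis enabled and a previous state supplied, a RED state only
    reverts to GREEN above ``threshold_mm + hysteresis_mm``.
    """
    if not np.isfinite(distance_mm):
        raise GeometryError("distance must be finite")
    if previous is GuidanceState.RED and cfg.hysteresis_mm > 0:
        return GuidanceState.GREEN if distance_mm > cfg.threshold_mm + cfg.hysteresis_mm else GuidanceState.RED
    return GuidanceState.GREEN if distance_mm > cfg.threshold_mm else GuidanceState.RED


def process_pose_stream(
    stream: PoseStream,
    plan: PlanModel,
    frames: FrameGraph,
    tip: TipCalibration,
    cfg: GuidanceConfig = GuidanceConfig(),
) -> GuidanceLog:
    """Turn a tracked pose stream into per-sample guidance readings.

    One :class:`GuidanceSample` is produced per drill pose; samples whose
    frame chain cannot be resolved (e.g. the patient DRF track does not
    bracket the timestamp) are skipped and counted, never silently dropped.
    Every GREEN<->RED crossing is logged with the crossing time linearly
    interpolated between the bracketing samples, making the transition log
    independent of the sampling rate.
    """
    if plan.planned_surface.n_faces == 0:
        raise GeometryError("plan has an empty planned surface")
    graph = FrameGraph()
    graph._static = dict(frames._static)
    graph._tracked = dict(frames._tracked)
    graph.frames = set(frames.frames)
    graph.add_stream(stream)

    drill_track = next(
        (trk for (a, _b), trk in graph._tracked.items() if a == DRILL_DRF), None
    )
    if drill_track is None:
        raise DisconnectedFramesError("pose stream carries no DRILL_DRF track")

    log = GuidanceLog()
    for ts in drill_track.times:
        try:
            tip_img = drill_tip_in_image(graph, tip, float(ts))
        except (TimestampRangeError, DisconnectedFramesError):
            log.skipped += 1
            continue
        d = signed_distance(tip_img, plan.planned_surface)
        prev = log.samples[-1] if log.samples else None
        state = classify_state(d, cfg, prev.state if prev else None)
        sample = GuidanceSample(float(ts), tip_img, d, state)
        if prev is not None and prev.state != state:
            # linear interpolation of the instant distance == threshold
            d0, d1 = prev.distance_mm - cfg.threshold_mm, d - cfg.threshold_mm
            w = d0 / (d0 - d1) if d0 != d1 else 0.5
            t_cross = prev.timestamp + w * (sample.timestamp - prev.timestamp)
            log.transitions.append(Transition(float(t_cross), prev.state, state))
        log.samples.append(sample)
    return log
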