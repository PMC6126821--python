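"""Autonomous exploration loop with bug-style obstacle avoidance.

The robot advances in 0.5 m steps.  At every step it acquires echoes at
three headings (-60/0/+60 relative to travel, or their summed superposition
in wide-beam mode), localizes reflectors, and checks whether any detection
lies within 1.2 m inside a +/-30 degree frontal sector.  When blocked it
turns 90 degrees right, sidesteps 1 m (if that direction is clear), turns
back left and re-checks — continuing rightward until the way ahead clears,
then resumes its original heading.  Every 5 steps the buffered detections
are integrated into the occupancy map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

from shapely.geometry import LineString, Point

from . import acoustics
from .acoustics import BinauralRecording, Pose
from .config import RunConfig
from .mapping import OccupancyMap
from .perception import DetectedObject, process_acquisition
from .scene import Scene

logger = logging.getLogger(__name__)

CRUISE = "cruise"
AVOID = "avoid_right"
FORWARD_CHECK = "avoid_forward_check"


@dataclass
class RobotState:
    pose: Pose
    step_count: int = 0
    mode: str = CRUISE
    pre_avoidance_heading: float = 0.0
    moved_m: float = 0.0  # translation performed by the last transition


class MissionFailure(RuntimeError):
    """Raised when the robot enters an object footprint (a collision)."""

    def __init__(self, message: str, state: RobotState):
        super().__init__(f"{message}; state dump: {state}")
        self.state = state


@dataclass
class MissionResult:
    trajectory: List[Pose]
    map: OccupancyMap
    detections_log: List[Tuple[int, Pose, List[DetectedObject]]]
    status: str  # "max_steps" | "exited" | "boxed_in"


def obstacle_ahead(objects: Sequence[DetectedObject], map: Optional[OccupancyMap],
                   config: RunConfig) -> bool:
    """True iff a detection lies within the trigger range in the frontal sector.

    The trigger consults the most recent acquisition's detections (the map is
    accepted for reporting symmetry but not used for the trigger).
    """
    nav = config.navigation
    return any(
        obj.range_m < nav.trigger_range_m
        and abs(obj.azimuth_deg) <= nav.frontal_halfwidth_deg
        for obj in objects
    )


def _advance(pose: Pose, dist: float) -> Pose:
    x, y, h = pose
    a = math.radians(h)
    return (x + dist * math.cos(a), y + dist * math.sin(a), h)


def _turn(pose: Pose, delta_deg: float) -> Pose:
    x, y, h = pose
    return (x, y, (h + delta_deg) % 360.0)


def bug_step(state: RobotState, ahead: bool, config: RunConfig) -> RobotState:
    """One transition of the avoidance automaton.

    cruise+clear -> 0.5 m forward.  cruise+blocked -> turn 90 right, enter
    avoidance.  avoidance+clear -> 1 m sidestep then turn left, schedule the
    forward re-check.  avoidance+blocked -> turn right again (wall-following
    fallback).  re-check clear -> restore the pre-avoidance heading and
    resume cruising; re-check blocked -> turn right and continue rightward.
    """
    nav = config.navigation
    pose, mode, pre = state.pose, state.mode, state.pre_avoidance_heading
    moved = 0.0
    if mode == CRUISE:
        if ahead:
            pre = pose[2]
            pose = _turn(pose, -90.0)
            mode = AVOID
        else:
            pose = _advance(pose, nav.step_m)
            moved = nav.step_m
    elif mode == AVOID:
        if ahead:
            pose = _turn(pose, -90.0)
        else:
            pose = _advance(pose, nav.sidestep_m)
            pose = _turn(pose, 90.0)
            moved = nav.sidestep_m
            mode = FORWARD_CHECK
    elif mode == FORWARD_CHECK:
        if ahead:
            pose = _turn(pose, -90.0)
            mode = AVOID
        else:
            pose = (pose[0], pose[1], pre % 360.0)
            pose = _advance(pose, nav.step_m)
            moved = nav.step_m
            mode = CRUISE
    else:
        raise ValueError(f"unknown mode {mode!r}")
    step_count = state.step_count + (1 if moved > 0 else 0)
    return RobotState(pose=pose, step_count=step_count, mode=mode,
                      pre_avoidance_heading=pre, moved_m=moved)


def _check_collision(scene: Scene, a: Pose, b: Pose, state: RobotState) -> None:
    path = LineString([a[:2], b[:2]]) if a[:2] != b[:2] else Point(a[:2])
    for obj in scene.objects:
        if path.intersects(obj.polygon()):
            raise MissionFailure(f"collision with object {obj.id!r}", state)


def run_mission(scene: Scene, start_pose: Pose, config: RunConfig,
                max_steps: int, summed_beam: bool = False) -> MissionResult:
    """Run the full acquire -> localize -> avoid -> map loop.

    Terminates at ``max_steps`` translations, on leaving the scene bounds,
    or as boxed-in after too many consecutive rotations without progress.
    A collision raises :class:`MissionFailure`.
    """
    chirp = acoustics.generate_chirp(config.sonar)
    occ = OccupancyMap.centered_on(start_pose[:2], config.mapping)
    occ.trajectory_points.append(start_pose[:2])
    state = RobotState(pose=start_pose, pre_avoidance_heading=start_pose[2])
    trajectory = [start_pose]
    detections_log: List[Tuple[int, Pose, List[DetectedObject]]] = []
    noise_seed = RunConfig(seed=config.seed).subseed("noise")
    status = "max_steps"
    stalled = 0
    iteration = 0
    while state.step_count < max_steps:
        iteration += 1
        recs = acoustics.acquire_three_headings(
            scene, state.pose, config.sonar, noise_seed + 10 * iteration)
        if summed_beam:
            recs = [acoustics.sum_headings(recs)]
        detections = process_acquisition(recs, chirp, config.sonar, config.detection)
        detections_log.append((state.step_count, state.pose, detections))
        ahead = obstacle_ahead(detections, occ, config)
        prev = state
        state = bug_step(state, ahead, config)
        if state.moved_m > 0:
            _check_collision(scene, prev.pose, state.pose, state)
            occ.mark_trajectory_segment(prev.pose[:2], state.pose[:2])
            trajectory.append(state.pose)
            stalled = 0
        else:
            stalled += 1
            if stalled >= 8:  # two full revolutions without progress
                status = "boxed_in"
                break
        occ.update_cycle(state.step_count, detections, prev.pose,
                         every=config.navigation.map_update_every)
        xmin, ymin, xmax, ymax = scene.bounds
        x, y, _ = state.pose
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            status = "exited"
            break
    return MissionResult(trajectory=trajectory, map=occ,
                         detections_log=detections_log, status=status)
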