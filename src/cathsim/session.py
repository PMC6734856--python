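"""Catheter tip kinematics and the training-session loop.

A session follows the training flow: select a scenario, begin at the start
landmark A, move the tip until it reaches the destination C (the lesion) or
time runs out, then validate the results (cumulative collision count and
completion time).  Guided scenarios check containment against the tube
fixture; the free scenario has no fixture and collisions are organ contacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .anatomy import Environment, OrganPrimitive, OrganSet
from .errors import InvalidCommandError, InvalidParameterError
from .fixture import CollisionEvent, TubeFixture, containment
from .scenario import Scenario

SPEED_MULTIPLIER = {"1x": 1.0, "2x": 2.0}

RESULTS_COLUMNS = [
    "trainee_id", "group", "scenario", "repetition",
    "n_collisions", "completion_time_s", "completed", "seed",
]


@dataclass(eq=False)
class CatheterState:
    """Instantaneous tip state.  ``color`` is red exactly while outside."""

    tip: np.ndarray
    heading: np.ndarray
    speed_mode: str = "1x"
    inside: bool = True
    t: float = 0.0

    def __post_init__(self) -> None:
        self.tip = np.asarray(self.tip, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        n = np.linalg.norm(self.heading)
        if abs(n - 1.0) > 1e-9:
            raise InvalidParameterError("heading must be a unit vector")
        if self.speed_mode not in SPEED_MULTIPLIER:
            raise InvalidParameterError(f"unknown speed mode {self.speed_mode!r}")

    @property
    def color(self) -> str:
        return "white" if self.inside else "red"


@dataclass
class SessionConfig:
    dt: float = 0.05
    base_speed: float = 10.0        # mm/s
    completion_epsilon: float = 5.0  # mm
    max_time: float = 300.0          # s
    position_correction: bool = False
    correction_threshold: float | None = None  # default: 2 x tube radius
    seed: int = 0

    def validate(self) -> None:
        for name in ("dt", "base_speed", "completion_epsilon", "max_time"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.dt > 0.1:
            raise InvalidParameterError("dt must be <= 0.1 s")
        if self.correction_threshold is not None and self.correction_threshold <= 0:
            raise InvalidParameterError("correction_threshold must be positive")

    def to_dict(self) -> dict:
        return {
            "dt": self.dt, "base_speed": self.base_speed,
            "completion_epsilon": self.completion_epsilon, "max_time": self.max_time,
            "position_correction": self.position_correction,
            "correction_threshold": self.correction_threshold, "seed": self.seed,
        }


@dataclass(eq=False)
class SessionRecord:
    trainee_id: str
    group: str
    scenario_id: int | str
    repetition: int
    n_collisions: int
    completion_time: float
    completed: bool
    events: list[CollisionEvent]
    seed: int
    aborted: bool = False
    trajectory: np.ndarray | None = None  # (steps+1, 3) tip log when traced

    def __post_init__(self) -> None:
        if self.n_collisions != len(self.events):
            raise InvalidParameterError("n_collisions must equal len(events)")

    def to_row(self) -> dict:
        return {
            "trainee_id": self.trainee_id,
            "group": self.group,
            "scenario": self.scenario_id,
            "repetition": int(self.repetition),
            "n_collisions": int(self.n_collisions),
            "completion_time_s": float(self.completion_time),
            "completed": bool(self.completed),
            "seed": int(self.seed),
        }


def step(
    state: CatheterState,
    command,
    config: SessionConfig,
    fixture: TubeFixture | None = None,
    organs: Sequence[OrganPrimitive] | None = None,
) -> tuple[CatheterState, Optional[CollisionEvent]]:
    """Advance one timestep.

    The tip moves ``normalize(command) * base_speed * multiplier * dt`` (a
    zero command holds position); containment, color and the collision event
    follow from the fixture or the organ set.  With position correction on,
    a tip farther than the correction threshold from the centerline snaps to
    its nearest centerline point after the event is recorded.
    """
    cmd = np.asarray(command, dtype=float)
    if cmd.shape != (3,) or not np.all(np.isfinite(cmd)):
        raise InvalidCommandError("command must be a finite 3-vector")
    norm = math.sqrt(float(cmd @ cmd))
    t_next = state.t + config.dt
    if norm == 0.0:
        tip = state.tip.copy()
        heading = state.heading
    else:
        u = cmd / norm
        tip = state.tip + u * (config.base_speed * SPEED_MULTIPLIER[state.speed_mode] * config.dt)
        heading = u
    # fast construction: fields are already validated invariants of the step
    new = CatheterState.__new__(CatheterState)
    new.tip = tip
    new.heading = heading
    new.speed_mode = state.speed_mode
    new.inside = state.inside
    new.t = t_next
    # Single containment query; semantics identical to detect_collision().
    event = None
    if fixture is not None:
        d, _, seg, nearest = fixture.query(tip)
        inside = d <= fixture.radius
        if state.inside and not inside:
            event = CollisionEvent(time=t_next, position=tip.copy(),
                                   penetration=d - fixture.radius,
                                   source="fixture", segment_index=seg)
        new.inside = bool(inside)
        if config.position_correction:
            threshold = (config.correction_threshold
                         if config.correction_threshold is not None
                         else 2.0 * fixture.radius)
            if d > threshold:
                new.tip = nearest.copy()
                new.inside = True
    else:
        inside, pen, _, label = containment(tip, None, organs)
        if state.inside and not inside:
            event = CollisionEvent(time=t_next, position=tip.copy(),
                                   penetration=pen, source="organ",
                                   organ_label=label)
        new.inside = bool(inside)
    return new, event


def run_session(
    scenario: Scenario,
    controller: Callable[[CatheterState], np.ndarray],
    config: SessionConfig,
    env: Environment,
    *,
    trainee_id: str = "agent",
    group: str = "beginner",
    repetition: int = 1,
    speed_mode: str = "1x",
    trace: bool = False,
) -> SessionRecord:
    """Run one training session and return its record.

    Guided scenarios start at the first centerline point and use the tube
    fixture; the free scenario starts at landmark A and checks collisions
    against the environment organs.  A controller exception aborts the
    session, which is flagged incomplete.
    """
    config.validate()
    if scenario.is_free:
        fixture, organs = None, OrganSet(env.organs)
        start = env.landmark("A").position
    else:
        fixture = TubeFixture(scenario.centerline, scenario.tube_radius)
        organs = None
        start = scenario.centerline[0]
    dest = env.landmark("C").position
    inside0, _, _, _ = containment(start, fixture, organs)
    state = CatheterState(tip=start.copy(), heading=np.array([0.0, 0.0, 1.0]),
                          speed_mode=speed_mode, inside=bool(inside0), t=0.0)
    events: list[CollisionEvent] = []
    traj: list[np.ndarray] | None = [state.tip.copy()] if trace else None
    completed = False
    aborted = False
    eps2 = config.completion_epsilon**2
    while state.t < config.max_time - 0.5 * config.dt:
        delta = state.tip - dest
        if float(delta @ delta) <= eps2:
            completed = True
            break
        try:
            cmd = controller(state)
        except Exception:
            aborted = True
            break
        state, ev = step(state, cmd, config, fixture=fixture, organs=organs)
        if ev is not None:
            events.append(ev)
        if traj is not None:
            traj.append(state.tip.copy())
    completion_time = min(state.t, config.max_time) if completed else config.max_time
    if aborted:
        completion_time = min(state.t, config.max_time)
    return SessionRecord(
        trainee_id=trainee_id, group=group, scenario_id=scenario.id,
        repetition=int(repetition), n_collisions=len(events),
        completion_time=float(completion_time), completed=completed,
        events=events, seed=int(config.seed), aborted=aborted,
        trajectory=None if traj is None else np.asarray(traj),
    )


def finalize_results(record: SessionRecord) -> tuple[int, float]:
    """Cumulative (collision count, completion time) summary of a session."""
    return int(record.n_collisions), float(record.completion_time)


def records_to_frame(records: Sequence[SessionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records], columns=RESULTS_COLUMNS)


def write_results_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
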