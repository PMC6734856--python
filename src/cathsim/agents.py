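"""Synthetic trainees: noisy path-following controllers with group-specific
skill and learning dynamics, standing in for human beginner/expert subjects.

An agent aims at the centerline point a fixed lookahead ahead of its current
arc-length position and perturbs the aim by a Gaussian angular error whose
standard deviation decays exponentially with repetition (the learning
curve).  Cohort simulation derives every per-subject, per-repetition random
stream as a pure function of the base seed, so sessions are reproducible and
order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _fastpath as _fp
from .anatomy import Environment
from .errors import InvalidParameterError
from .fixture import TubeFixture
from .scenario import Scenario, build_scenario
from .session import (
    CatheterState,
    SessionConfig,
    SessionRecord,
    SPEED_MULTIPLIER,
    records_to_frame,
    run_session,
)

GROUPS = ("beginner", "expert")


@dataclass
class AgentProfile:
    """Noise/learning parameters of one trainee group.

    ``sigma0`` and ``sigma_inf`` are the initial and asymptotic angular
    noise standard deviations (radians); ``learn_rate`` is the
    per-repetition exponential decay.
    """

    group: str
    sigma0: float
    sigma_inf: float
    learn_rate: float
    lookahead: float = 10.0  # mm
    seed: int = 0

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise InvalidParameterError(f"unknown group {self.group!r}")
        if not (self.sigma0 >= self.sigma_inf >= 0.0):
            raise InvalidParameterError("need sigma0 >= sigma_inf >= 0")
        if self.learn_rate < 0:
            raise InvalidParameterError("learn_rate must be non-negative")
        if self.lookahead <= 0:
            raise InvalidParameterError("lookahead must be positive")


#: Synthetic calibration (not measured human parameters): chosen so the
#: default cohorts qualitatively reproduce the study's group ordering
#: (beginners collide more) and the beginner-only learning curve.
DEFAULT_PROFILES = {
    "beginner": AgentProfile("beginner", sigma0=0.45, sigma_inf=0.32, learn_rate=0.12),
    "expert": AgentProfile("expert", sigma0=0.30, sigma_inf=0.30, learn_rate=0.0),
}


@dataclass
class CohortDesign:
    n_per_group: int = 8
    repetitions: int = 20
    scenario_id: int | str = "free"
    base_seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise InvalidParameterError("n_per_group must be >= 1")
        if self.repetitions < 1:
            raise InvalidParameterError("repetitions must be >= 1")


def noise_schedule(profile: AgentProfile, repetition: int) -> float:
    """Angular noise sd at repetition k >= 1 (exponential learning curve)."""
    if repetition < 1:
        raise InvalidParameterError("repetition must be >= 1")
    k = repetition
    return profile.sigma_inf + (profile.sigma0 - profile.sigma_inf) * float(
        np.exp(-profile.learn_rate * (k - 1))
    )


def _rotate_about(u: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    # Rodrigues rotation; axis is unit and perpendicular to u.  The cross
    # product is unrolled: np.cross dominates the agent hot loop otherwise.
    ax, ay, az = axis
    ux, uy, uz = u
    cross = np.array([ay * uz - az * uy, az * ux - ax * uz, ax * uy - ay * ux])
    return u * math.cos(angle) + cross * math.sin(angle)


def make_controller(
    profile: AgentProfile,
    scenario: Scenario,
    repetition: int,
    rng: np.random.Generator,
    *,
    guide: Scenario | None = None,
):
    """Noisy path-following controller for one session.

    The agent follows the centerline of ``guide`` (defaults to *scenario*;
    in the free scenario a guided scenario's centerline must be supplied as
    the agent's intended path).  Each command aims ``lookahead`` mm ahead
    along the path and is rotated by an angle drawn from N(0, sigma_k^2)
    about a uniformly random perpendicular axis.  Deterministic given the
    rng state.
    """
    profile.validate()
    path_scn = guide if guide is not None else scenario
    if len(path_scn.centerline) < 2:
        raise InvalidParameterError("controller needs a scenario with a centerline")
    path = TubeFixture(path_scn.centerline, path_scn.tube_radius or 1.0)
    sigma = noise_schedule(profile, repetition)
    lookahead = profile.lookahead
    length = path.length
    end = path.centerline[-1]

    def controller(state: CatheterState) -> np.ndarray:
        # one 4-draw per call, consumed up front: keeps the noise stream
        # aligned with the compiled session kernel
        z = rng.standard_normal(4) if sigma > 0.0 else None
        _, s, _, _ = path.query(state.tip)
        target = end if s + lookahead >= length else path.point_at_arclength(s + lookahead)
        aim = target - state.tip
        n = float(np.linalg.norm(aim))
        if n < 1e-12:
            return np.zeros(3)
        aim /= n
        if z is not None:
            angle = sigma * z[0]
            v = z[1:]
            perp = v - (v @ aim) * aim
            pn = float(np.linalg.norm(perp))
            if pn < 1e-12:  # pragma: no cover - measure-zero draw
                return aim
            return _rotate_about(aim, perp / pn, angle)
        return aim

    return controller


def perfect_controller(scenario: Scenario, config: SessionConfig):
    """Noise-free follower that walks the centerline by exact arc-length
    steps, passing every vertex; completes in ceil(L / (v dt)) steps."""
    if len(scenario.centerline) < 2:
        raise InvalidParameterError("controller needs a scenario with a centerline")
    path = TubeFixture(scenario.centerline, scenario.tube_radius or 1.0)
    length = path.length
    end = path.centerline[-1]

    def controller(state: CatheterState) -> np.ndarray:
        step_len = config.base_speed * SPEED_MULTIPLIER[state.speed_mode] * config.dt
        _, s, _, _ = path.query(state.tip)
        target = end if s + step_len >= length else path.point_at_arclength(s + step_len)
        return target - state.tip

    return controller


def subject_seed(base_seed: int, group: str, subject: int, repetition: int) -> np.random.SeedSequence:
    """Pure function of (base seed, group, subject, repetition)."""
    return np.random.SeedSequence(
        entropy=int(base_seed),
        spawn_key=(GROUPS.index(group), int(subject), int(repetition)),
    )


def run_agent_session(
    profile: AgentProfile,
    scenario: Scenario,
    repetition: int,
    config: SessionConfig,
    env: Environment,
    seed_seq: np.random.SeedSequence,
    *,
    trainee_id: str = "agent",
    guide: Scenario | None = None,
    fast: bool = True,
    trace: bool = False,
) -> SessionRecord:
    """One session of the standard noisy follower.

    With ``fast=True`` (and numba importable) the session runs in the
    compiled kernel of :mod:`cathsim._fastpath`; otherwise through the
    interpreted ``run_session`` loop.  Both paths consume the same random
    stream and implement the same step semantics.
    """
    rng = np.random.default_rng(seed_seq)
    seed32 = int(seed_seq.generate_state(1)[0])
    cfg = SessionConfig(**{**config.to_dict(), "seed": seed32})
    if fast and _fp.NUMBA_OK and (guide is None or scenario.is_free):
        return _run_fast(profile, scenario, repetition, cfg, env,
                         rng, trainee_id, guide, trace)
    controller = make_controller(profile, scenario, repetition, rng, guide=guide)
    return run_session(
        scenario, controller, cfg, env,
        trainee_id=trainee_id, group=profile.group, repetition=repetition,
        trace=trace,
    )


def _run_fast(
    profile: AgentProfile,
    scenario: Scenario,
    repetition: int,
    cfg: SessionConfig,
    env: Environment,
    rng: np.random.Generator,
    trainee_id: str,
    guide: Scenario | None,
    trace: bool,
) -> SessionRecord:
    from .anatomy import OrganSet
    from .fixture import CollisionEvent

    profile.validate()
    cfg.validate()
    path_scn = guide if guide is not None else scenario
    if len(path_scn.centerline) < 2:
        raise InvalidParameterError("controller needs a scenario with a centerline")
    path = TubeFixture(path_scn.centerline, path_scn.tube_radius or 1.0)
    sigma = noise_schedule(profile, repetition)
    guided = not scenario.is_free
    radius = float(scenario.tube_radius) if guided else 1.0
    threshold = (cfg.correction_threshold if cfg.correction_threshold is not None
                 else 2.0 * radius)
    organset = OrganSet(env.organs)
    flat_labels = [organset.labels[j] for j in organset._order]
    start = path.centerline[0] if guided else env.landmark("A").position
    dest = env.landmark("C").position
    max_steps = int(np.ceil(cfg.max_time / cfg.dt)) + 2
    noise = (rng.standard_normal((max_steps, 4)) if sigma > 0.0
             else np.zeros((max_steps, 4)))
    completed, completion_time, n_ev, ev_t, ev_pen, ev_seg, ev_org, ev_pos, tips = (
        _fp._session_kernel(
            path.centerline, path.cumulative_arclength,
            float(profile.lookahead), float(sigma), noise,
            guided, radius, bool(cfg.position_correction), float(threshold),
            organset._cap_a, organset._cap_d, organset._cap_len2, organset._cap_r,
            organset._box_c, organset._box_h,
            np.asarray(start, dtype=float), np.asarray(dest, dtype=float),
            float(cfg.completion_epsilon), float(cfg.dt),
            float(cfg.base_speed * cfg.dt), float(cfg.max_time),
            bool(trace),
        )
    )
    events = []
    for i in range(n_ev):
        if guided:
            events.append(CollisionEvent(
                time=float(ev_t[i]), position=ev_pos[i].copy(),
                penetration=float(ev_pen[i]), source="fixture",
                segment_index=int(ev_seg[i])))
        else:
            events.append(CollisionEvent(
                time=float(ev_t[i]), position=ev_pos[i].copy(),
                penetration=float(ev_pen[i]), source="organ",
                organ_label=flat_labels[int(ev_org[i])]))
    return SessionRecord(
        trainee_id=trainee_id, group=profile.group, scenario_id=scenario.id,
        repetition=int(repetition), n_collisions=len(events),
        completion_time=float(completion_time), completed=bool(completed),
        events=events, seed=int(cfg.seed),
        trajectory=tips.copy() if trace else None,
    )


def simulate_cohort(
    design: CohortDesign,
    beginner: AgentProfile,
    expert: AgentProfile,
    config: SessionConfig,
    env: Environment,
    *,
    guide_scenario_id: int = 1,
) -> pd.DataFrame:
    """Simulate n_per_group x 2 groups x repetitions sessions.

    In the free scenario agents still intend the guided scenario's path
    (default scenario 1) but collisions are organ contacts.  Returns the
    results table (one row per session).
    """
    design.validate()
    scenario = build_scenario(design.scenario_id, env)
    guide = build_scenario(guide_scenario_id, env) if scenario.is_free else None
    records: list[SessionRecord] = []
    for profile in (beginner, expert):
        profile.validate()
        for subject in range(design.n_per_group):
            tid = f"{profile.group[0]}{subject + 1:02d}"
            for rep in range(1, design.repetitions + 1):
                seq = subject_seed(design.base_seed, profile.group, subject, rep)
                records.append(
                    run_agent_session(
                        profile, scenario, rep, config, env, seq,
                        trainee_id=tid, guide=guide,
                    )
                )
    return records_to_frame(records)
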