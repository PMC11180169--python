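"""Pursuit-task stimulus generation.

Two horizontal smooth-pursuit tasks are generated on a common time base:

* **Triangular-wave (full-ramp) trials** — the target sweeps back and forth
  at constant speed, reversing direction every ramp period.  Sustained,
  predictable tracking of this waveform is driven largely by prediction
  (closed-loop "predictive maintenance gain").
* **Foveo-petal step-ramp (Rashbass) trials** — the target steps a small
  distance away from fixation and immediately ramps back through the centre
  toward the opposite periphery.  Because the target re-crosses the fovea
  shortly after motion onset, pursuit can be initiated without a catch-up
  saccade, exposing open-loop initiation (latency, initial acceleration) and
  early feedback-driven velocity ("early maintenance gain").

Positions are horizontal gaze angles in degrees (rightward positive), times
are milliseconds from trial start, and every trial carries an explicit
``motion_onset`` so analysis windows can be anchored to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TaskConfig",
    "TargetTrajectory",
    "make_triangular_trajectory",
    "make_step_ramp_trajectory",
    "make_trial_sequence",
]

FULL_RAMP = "full_ramp"
STEP_RAMP = "step_ramp"


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and composition of one pursuit session.

    Defaults encode the standard protocol: 18.7 deg/s ramps, 2.4 deg
    foveo-petal steps, 1200 ms ramp period, 500 Hz sampling, 48 analysable
    full-ramp plus 32 analysable step-ramp trials, and enough extra
    attention trials (odd velocities or blanked targets) to make up 30 % of
    the session.  Attention trials are generated but flagged ineligible so
    downstream filtering is observable rather than implicit.
    """

    ramp_velocity: float = 18.7      # deg/s
    step_size: float = 2.4           # deg
    ramp_duration: float = 1200.0    # ms
    sampling_rate: float = 500.0     # Hz
    n_full_ramp: int = 48
    n_step_ramp: int = 32
    attention_fraction: float = 0.30
    attention_velocities: tuple[float, ...] = (9.7, 26.6)
    motion_onset: float = 400.0      # ms of central fixation before motion
    n_ramps_per_trial: int = 2       # full 1200 ms ramps per triangular trial

    def __post_init__(self) -> None:
        if self.ramp_velocity <= 0:
            raise ValueError("ramp_velocity must be positive")
        if self.step_size < 0:
            raise ValueError("step_size must be non-negative")
        if self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.attention_fraction < 1:
            raise ValueError("attention_fraction must lie in [0, 1)")
        if self.motion_onset < 200.0:
            raise ValueError("motion_onset must leave >=200 ms of fixation")

    @property
    def excursion(self) -> float:
        """Half-amplitude of the triangular sweep (deg).

        Derived from the ramp period: one full ramp at ``ramp_velocity``
        covers ``ramp_velocity * ramp_duration / 1000`` degrees, i.e. twice
        the excursion.
        """
        return self.ramp_velocity * self.ramp_duration / 2000.0

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate


@dataclass
class TargetTrajectory:
    """Sampled target position/velocity for one trial."""

    times: np.ndarray            # ms from trial start
    positions: np.ndarray        # deg, rightward positive
    velocities: np.ndarray       # deg/s
    motion_onset: float          # ms
    direction: int               # +1 right / -1 left (initial ramp direction)
    task_kind: str               # FULL_RAMP or STEP_RAMP
    analysis_eligible: bool = True
    ramp_velocity: float = 18.7
    sampling_rate: float = 500.0
    reversal_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    trial_id: int = 0

    def __post_init__(self) -> None:
        n = len(self.times)
        if len(self.positions) != n or len(self.velocities) != n:
            raise ValueError("times/positions/velocities length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.times)


def _time_base(config: TaskConfig, duration_ms: float) -> np.ndarray:
    n = int(round(duration_ms / config.dt_ms)) + 1
    return np.arange(n) * config.dt_ms


def make_triangular_trajectory(
    config: TaskConfig,
    direction: int,
    n_ramps: int | None = None,
    velocity: float | None = None,
    eligible: bool = True,
) -> TargetTrajectory:
    """Triangular-wave target: fixation, then constant-speed sweeps.

    Motion starts from centre toward ``direction``; the first reversal
    occurs at the excursion after half a ramp period, subsequent reversals
    every full ``ramp_duration``.  ``n_ramps`` counts the full-period ramps
    following the initial half ramp.  Analysis windows are anchored to the
    returned ``reversal_times``.
    """
    if n_ramps is None:
        n_ramps = config.n_ramps_per_trial
    if n_ramps < 1:
        raise ValueError("n_ramps must be >= 1")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    v = config.ramp_velocity if velocity is None else velocity

    half = config.ramp_duration / 2.0
    excursion = v * config.ramp_duration / 2000.0
    total = config.motion_onset + half + n_ramps * config.ramp_duration
    times = _time_base(config, total)
    pos = np.zeros_like(times)
    vel = np.zeros_like(times)

    reversal_times = config.motion_onset + half + np.arange(n_ramps) * config.ramp_duration
    moving = times >= config.motion_onset
    t_rel = times[moving] - config.motion_onset
    # phase within a 2*ramp_duration cycle that starts at centre moving +direction
    phase = np.mod(t_rel + half, 2.0 * config.ramp_duration)
    tri = np.where(
        phase < config.ramp_duration,
        -excursion + v * phase / 1000.0,
        excursion - v * (phase - config.ramp_duration) / 1000.0,
    )
    sign = np.where(phase < config.ramp_duration, 1.0, -1.0)
    pos[moving] = direction * tri
    vel[moving] = direction * sign * v

    return TargetTrajectory(
        times=times,
        positions=pos,
        velocities=vel,
        motion_onset=config.motion_onset,
        direction=direction,
        task_kind=FULL_RAMP,
        analysis_eligible=eligible,
        ramp_velocity=v,
        sampling_rate=config.sampling_rate,
        reversal_times=reversal_times,
    )


def make_step_ramp_trajectory(
    config: TaskConfig,
    direction: int,
    velocity: float | None = None,
    eligible: bool = True,
) -> TargetTrajectory:
    """Foveo-petal step-ramp: step opposite to the ramp, then constant ramp.

    At ``motion_onset`` the target jumps ``step_size`` degrees against
    ``direction`` and immediately ramps at ``ramp_velocity`` toward the
    opposite periphery, re-crossing centre ``step_size / ramp_velocity``
    seconds later.  The ramp ends at the sweep excursion, after which the
    target holds position briefly.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    v = config.ramp_velocity if velocity is None else velocity
    if config.step_size >= config.excursion and config.step_size > 0:
        raise ValueError("step_size must be smaller than the sweep excursion")

    ramp_ms = (config.excursion + config.step_size) / v * 1000.0
    total = config.motion_onset + ramp_ms + 100.0
    times = _time_base(config, total)
    pos = np.zeros_like(times)
    vel = np.zeros_like(times)

    moving = times >= config.motion_onset
    t_rel = (times[moving] - config.motion_onset) / 1000.0
    p = -direction * config.step_size + direction * v * t_rel
    end = direction * config.excursion
    ramping = np.abs(p) <= config.excursion
    p = np.where(ramping, p, end)
    pos[moving] = p
    vel[moving] = np.where(ramping, direction * v, 0.0)

    return TargetTrajectory(
        times=times,
        positions=pos,
        velocities=vel,
        motion_onset=config.motion_onset,
        direction=direction,
        task_kind=STEP_RAMP,
        analysis_eligible=eligible,
        ramp_velocity=v,
        sampling_rate=config.sampling_rate,
        reversal_times=np.array([config.motion_onset]),
    )


def make_trial_sequence(config: TaskConfig, seed: int) -> list[TargetTrajectory]:
    """Randomised session: eligible trials plus ineligible attention trials.

    The session contains exactly ``n_full_ramp`` eligible triangular and
    ``n_step_ramp`` eligible step-ramp trials at ``ramp_velocity``, and
    enough attention trials (step-ramps at the alternate velocities) that
    they form ``attention_fraction`` of the total (to one-trial rounding).
    Directions and ordering are randomised deterministically under ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_eligible = config.n_full_ramp + config.n_step_ramp
    frac = config.attention_fraction
    n_attention = int(round(n_eligible * frac / (1.0 - frac))) if frac > 0 else 0

    specs: list[tuple[str, float | None, bool]] = []
    specs += [(FULL_RAMP, None, True)] * config.n_full_ramp
    specs += [(STEP_RAMP, None, True)] * config.n_step_ramp
    vels = config.attention_velocities or (config.ramp_velocity,)
    for i in range(n_attention):
        specs.append((STEP_RAMP, vels[i % len(vels)], False))

    order = rng.permutation(len(specs))
    trials: list[TargetTrajectory] = []
    for tid, idx in enumerate(order):
        kind, vel, eligible = specs[idx]
        direction = 1 if rng.random() < 0.5 else -1
        if kind == FULL_RAMP:
            traj = make_triangular_trajectory(config, direction, eligible=eligible)
        else:
            traj = make_step_ramp_trajectory(config, direction, velocity=vel, eligible=eligible)
        traj.trial_id = tid
        trials.append(traj)
    return trials
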