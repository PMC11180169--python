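"""Synthetic oculomotor data with known ground truth.

Raw pursuit recordings from clinical cohorts are not redistributable, so
this module provides two generators:

* **Trace level** — :func:`simulate_trial` / :func:`simulate_session`
  produce eye-position traces for the stimulus trajectories with
  subject-level latency, initial acceleration, early and predictive gain,
  catch-up saccades (minimum-jerk, triggered by accumulated position
  error), blinks (runs of invalid samples) and Gaussian position noise.
  Because every generative parameter is known, the extraction chain can be
  validated by round-trip recovery.

* **Cohort level** — :func:`simulate_cohort_features` draws per-subject
  four-measure profiles from group-wise Gaussian distributions (truncated
  to physical ranges) with per-measure missingness, emulating published
  group means/SDs.  Measures are drawn independently per subject; real
  between-measure correlations are unknown and not modelled (an optional
  correlation matrix can be supplied).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import EyeTrace
from .stimulus import STEP_RAMP, TargetTrajectory, TaskConfig, make_trial_sequence

__all__ = [
    "SubjectProfile",
    "GroupSpec",
    "CohortSpec",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort_features",
    "FEATURES",
    "FEATURE_BOUNDS",
]

FEATURES = ("gain_pred", "gain_early", "accel", "latency")

# physical truncation ranges for cohort draws
FEATURE_BOUNDS = {
    "gain_pred": (1e-6, 1.5),
    "gain_early": (1e-6, 1.5),
    "accel": (1e-6, np.inf),
    "latency": (80.0, 400.0),
}

EARLY_PHASE_MS = 600.0  # step-ramp feedback phase governed by the early gain


@dataclass(frozen=True)
class SubjectProfile:
    """Generative ground truth for one subject's pursuit behaviour."""

    true_gain_predictive: float = 0.93
    true_gain_early: float = 0.79
    true_accel: float = 80.0          # deg/s^2
    true_latency: float = 176.0       # ms
    saccade_threshold: float = 2.0    # deg position error triggering a catch-up
    saccade_delay: float = 150.0      # ms sensorimotor lag before the catch-up fires
    blink_rate: float = 0.1           # events/s
    noise_sd: float = 0.01            # deg

    def __post_init__(self) -> None:
        for g in (self.true_gain_predictive, self.true_gain_early):
            if not 0 < g <= 1.5:
                raise ValueError("gains must lie in (0, 1.5]")
        if self.true_accel <= 0:
            raise ValueError("true_accel must be positive")
        if not 80.0 <= self.true_latency <= 400.0:
            raise ValueError("true_latency must lie in [80, 400] ms")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be non-negative")


def _min_jerk_velocity(amplitude: float, duration_s: float, t: np.ndarray) -> np.ndarray:
    """Minimum-jerk velocity profile covering ``amplitude`` in ``duration_s``."""
    s = np.clip(t / duration_s, 0.0, 1.0)
    return amplitude / duration_s * 30.0 * s**2 * (1.0 - s) ** 2


def simulate_trial(
    trajectory: TargetTrajectory, profile: SubjectProfile, seed: int
) -> EyeTrace:
    """Generate one eye trace for a target trajectory.

    The eye rests at zero until motion onset plus the subject's latency,
    then accelerates linearly at ``true_accel`` until reaching the
    gain-scaled target velocity (the early gain during the first 600 ms of
    step-ramp trials, the predictive gain thereafter and throughout
    triangular trials, whose reversals are tracked predictively).
    Catch-up saccades are inserted whenever position error exceeds the
    subject threshold; blinks appear as invalid-sample runs; Gaussian
    position noise is added last.
    """
    rng = np.random.default_rng(seed)
    t = trajectory.times
    dt = 1.0 / trajectory.sampling_rate
    n = len(t)
    onset_time = trajectory.motion_onset + profile.true_latency

    eye_vel = np.zeros(n)
    eye_pos = np.zeros(n)
    acquiring = True
    sac_vel = np.zeros(n)
    sac_end_idx = -1
    err_since: float | None = None  # time the error first exceeded threshold

    for i in range(1, n):
        if trajectory.task_kind == STEP_RAMP and t[i] < trajectory.motion_onset + EARLY_PHASE_MS:
            gain = profile.true_gain_early
        else:
            gain = profile.true_gain_predictive
        desired = gain * trajectory.velocities[i]
        if t[i] < onset_time:
            v = 0.0
        elif acquiring:
            prev = eye_vel[i - 1]
            step = profile.true_accel * dt
            if abs(desired - prev) <= step:
                v = desired
                acquiring = False
            else:
                v = prev + np.sign(desired - prev) * step
        else:
            v = desired
        eye_vel[i] = v
        eye_pos[i] = eye_pos[i - 1] + 0.5 * (eye_vel[i - 1] + eye_vel[i]) * dt + sac_vel[i - 1] * dt

        # catch-up saccade when position error has persisted beyond the
        # sensorimotor reaction delay
        if (
            t[i] >= onset_time
            and i > sac_end_idx
            and np.isfinite(profile.saccade_threshold)
        ):
            err = trajectory.positions[i] - eye_pos[i]
            if abs(err) > profile.saccade_threshold:
                if err_since is None:
                    err_since = t[i]
                if t[i] - err_since >= profile.saccade_delay:
                    dur = rng.uniform(0.030, 0.060)
                    n_sac = max(2, int(round(dur / dt)))
                    j = min(n, i + n_sac)
                    tt = (np.arange(j - i) + 1) * dt
                    sac_vel[i:j] += _min_jerk_velocity(err, n_sac * dt, tt)
                    sac_end_idx = j
                    err_since = None
            else:
                err_since = None

    valid = np.ones(n, dtype=bool)
    if profile.blink_rate > 0:
        duration_s = t[-1] / 1000.0
        n_blinks = rng.poisson(profile.blink_rate * duration_s)
        for _ in range(n_blinks):
            start = rng.uniform(0.0, t[-1])
            length = rng.uniform(100.0, 300.0)
            valid[(t >= start) & (t < start + length)] = False

    if profile.noise_sd > 0:
        eye_pos = eye_pos + rng.normal(0.0, profile.noise_sd, size=n)

    return EyeTrace(
        times=t.copy(),
        eye_positions=eye_pos,
        valid=valid,
        sampling_rate=trajectory.sampling_rate,
        trial=trajectory,
    )


def simulate_session(
    task: TaskConfig, profile: SubjectProfile, seed: int
) -> list[EyeTrace]:
    """Simulate a full randomized session (eligible + attention trials)."""
    rng = np.random.default_rng(seed)
    trials = make_trial_sequence(task, int(rng.integers(0, 2**31 - 1)))
    return [
        simulate_trial(traj, profile, int(rng.integers(0, 2**31 - 1)))
        for traj in trials
    ]


# ---------------------------------------------------------------------------
# Cohort-level feature simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One group's feature distribution: n, per-feature mean and SD."""

    name: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]
    label: str | None = None  # classification label; defaults to name

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for f in FEATURES:
            if self.sds.get(f, 0.0) < 0:
                raise ValueError("SDs must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition with per-feature missingness rates."""

    groups: tuple[GroupSpec, ...]
    missing_rates: dict[str, float] = field(default_factory=dict)
    correlation: np.ndarray | None = None  # optional 4x4 between-feature corr

    def __post_init__(self) -> None:
        for f, r in self.missing_rates.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missing rate for {f} must lie in [0, 1)")


def _truncated_draws(
    rng: np.random.Generator, mean: float, sd: float, n: int, bounds: tuple[float, float]
) -> np.ndarray:
    """Gaussian draws redrawn until inside the physical bounds."""
    lo, hi = bounds
    if sd == 0:
        return np.full(n, np.clip(mean, lo, hi))
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort_features(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw a subjects x features table from group-wise distributions.

    Features are sampled independently per feature (or with the optional
    correlation matrix via a Gaussian copula), truncated to physical
    ranges by redrawing, then thinned by the per-feature missingness
    rates.  Returns a DataFrame with ``subject_id``, ``group`` (the
    classification label), ``subgroup`` (the generating group name) and
    the four feature columns, NaN marking missing values.
    """
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for group in spec.groups:
        data: dict[str, np.ndarray] = {}
        if spec.correlation is not None:
            z = rng.multivariate_normal(np.zeros(len(FEATURES)), spec.correlation, size=group.n)
            from scipy.stats import norm

            u = norm.cdf(z)
            for j, f in enumerate(FEATURES):
                lo, hi = FEATURE_BOUNDS[f]
                mean, sd = group.means[f], group.sds[f]
                a = norm.cdf((lo - mean) / sd) if sd > 0 else 0.0
                b = norm.cdf((hi - mean) / sd) if sd > 0 else 1.0
                q = a + u[:, j] * (b - a)
                data[f] = mean + sd * norm.ppf(q) if sd > 0 else np.full(group.n, mean)
        else:
            for f in FEATURES:
                data[f] = _truncated_draws(
                    rng, group.means[f], group.sds[f], group.n, FEATURE_BOUNDS[f]
                )
        for f in FEATURES:
            rate = spec.missing_rates.get(f, 0.0)
            if rate > 0:
                miss = rng.random(group.n) < rate
                data[f] = np.where(miss, np.nan, data[f])
        frame = pd.DataFrame(data)
        frame.insert(0, "subject_id", [f"S{offset + i:05d}" for i in range(group.n)])
        frame.insert(1, "group", group.label or group.name)
        frame.insert(2, "subgroup", group.name)
        offset += group.n
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
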