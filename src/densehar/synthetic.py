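"""Synthetic dual-accelerometer cohort simulator.

Generates labelled recordings whose statistical structure mirrors the two
free-living cohorts the pipeline targets: six channels (lower back + right
thigh, tri-axial, units g) at 50 Hz, per-frame labels over nine activities
(young cohort) or a six-activity subset (old cohort), strong class imbalance,
realistic bout dwell times, and slower movement dynamics in the old cohort.

The generative model is deliberately simple — per-activity gravity orientation
plus a small harmonic stack at the movement cadence plus Gaussian noise — the
minimum that makes postures separable by orientation, locomotion separable by
cadence, and stair activities deliberately overlap walking so the confusion
structure of real data is qualitatively reproduced.  Activity bouts follow a
semi-Markov process: an embedded activity-to-activity Markov chain with
exponential dwell times truncated below at 1 s.

Axis convention: for each sensor site, x is vertical when standing; units are
g (9.81 m/s^2-normalised).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import CANONICAL_CHANNELS, LabelSequence, SignalWindow

# fixed activity ids shared by both cohorts
WALKING, RUNNING, STANDING = 0, 1, 2
STAIRS_UP, STAIRS_DOWN, SITTING = 3, 4, 5
LYING, CYCLING_SIT, CYCLING_STAND = 6, 7, 8

ACTIVITY_NAMES: dict[int, str] = {
    WALKING: "walking",
    RUNNING: "running",
    STANDING: "standing",
    STAIRS_UP: "stairs_up",
    STAIRS_DOWN: "stairs_down",
    SITTING: "sitting",
    LYING: "lying",
    CYCLING_SIT: "cycling_sit",
    CYCLING_STAND: "cycling_stand",
}

YOUNG_ACTIVITIES: tuple[int, ...] = tuple(range(9))
OLD_ACTIVITIES: tuple[int, ...] = (
    WALKING, STAIRS_UP, STAIRS_DOWN, STANDING, SITTING, LYING,
)

STAIR_ACTIVITIES = frozenset({STAIRS_UP, STAIRS_DOWN})


class ConfigurationError(ValueError):
    """A cohort profile references activities it has no model for."""


@dataclass(frozen=True)
class ActivityModel:
    """Signal signature of one activity.

    ``static_orientation`` and ``dynamic_amplitude`` are (2, 3) arrays over
    (lower back, thigh) x (x, y, z), in g.  ``fundamental_freq`` is the
    movement cadence in Hz (0 for static postures); each of ``harmonic_count``
    harmonics h carries amplitude ``dynamic_amplitude / h``.
    """

    activity_id: int
    static_orientation: np.ndarray
    dynamic_amplitude: np.ndarray
    fundamental_freq: float
    harmonic_count: int = 2
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        so = np.asarray(self.static_orientation, dtype=float).reshape(2, 3)
        da = np.asarray(self.dynamic_amplitude, dtype=float).reshape(2, 3)
        object.__setattr__(self, "static_orientation", so)
        object.__setattr__(self, "dynamic_amplitude", da)
        mags = np.linalg.norm(so, axis=1)
        if not np.all((mags >= 0.9) & (mags <= 1.1)):
            raise ValueError(
                f"activity {self.activity_id}: static orientation magnitudes {mags} "
                "outside the gravity-dominated band [0.9, 1.1] g"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.fundamental_freq < 0 or self.harmonic_count < 1:
            raise ValueError("fundamental_freq must be >= 0 and harmonic_count >= 1")


@dataclass(frozen=True)
class CohortProfile:
    """Statistical description of one cohort's activity process."""

    name: str
    activity_set: tuple[int, ...]
    cadence_scale: float
    amplitude_scale: float
    transition_matrix: np.ndarray  # row-stochastic over activity_set order
    dwell_mean: dict[int, float]  # seconds per activity
    participant_count: int
    duration_mean: float  # minutes
    duration_sd: float  # minutes
    stair_amplitude_factor: float = 1.0  # extra damping of stair dynamics

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        object.__setattr__(self, "transition_matrix", tm)
        k = len(self.activity_set)
        if tm.shape != (k, k):
            raise ValueError("transition matrix shape must match activity_set")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every transition-matrix row must sum to 1")
        if np.any(tm < 0):
            raise ValueError("transition probabilities must be non-negative")
        missing = set(self.activity_set) - set(self.dwell_mean)
        if missing:
            raise ConfigurationError(f"no dwell mean for activities {sorted(missing)}")


@dataclass(frozen=True)
class SyntheticRecording:
    """One participant's labelled recording."""

    participant_id: str
    cohort: str
    signal: SignalWindow
    labels: LabelSequence
    rate: float
    seed: int

    def __post_init__(self) -> None:
        if self.signal.n_frames != len(self.labels):
            raise ValueError("signal frame count must equal label count")


def _embedded_stationary(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of the embedded (bout-level) Markov chain."""
    vals, vecs = np.linalg.eig(transition_matrix.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _mean_truncated_dwell(mean: float) -> float:
    """E[max(1, X)] for X ~ Exponential(mean), the actual bout-length law."""
    return 1.0 + mean * np.exp(-1.0 / mean)


def expected_activity_shares(profile: CohortProfile) -> dict[int, float]:
    """Exact long-run frame share of each activity under the profile's process.

    The share of activity i is the embedded-chain stationary probability
    weighted by the mean truncated dwell time, normalised over the activity
    set.  Serves as the analytical reference for empirical label frequencies.
    """
    pi = _embedded_stationary(profile.transition_matrix)
    w = pi * np.array(
        [_mean_truncated_dwell(profile.dwell_mean[a]) for a in profile.activity_set]
    )
    w /= w.sum()
    return dict(zip(profile.activity_set, w))


def _bout_signal(
    model: ActivityModel,
    profile: CohortProfile,
    n_frames: int,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Acceleration for one bout: gravity + harmonics at cadence + noise."""
    t = np.arange(n_frames) / rate
    amp_scale = profile.amplitude_scale
    if model.activity_id in STAIR_ACTIVITIES:
        amp_scale *= profile.stair_amplitude_factor
    out = np.repeat(model.static_orientation.reshape(6, 1), n_frames, axis=1)
    freq = profile.cadence_scale * model.fundamental_freq
    if freq > 0:
        for h in range(1, model.harmonic_count + 1):
            phases = rng.uniform(0.0, 2.0 * np.pi, size=6)
            amps = (amp_scale * model.dynamic_amplitude / h).reshape(6)
            out += amps[:, None] * np.sin(
                2.0 * np.pi * h * freq * t[None, :] + phases[:, None]
            )
    out += rng.normal(0.0, model.noise_sd, size=out.shape)
    return out


def generate_recording(
    profile: CohortProfile,
    activity_models: dict[int, ActivityModel],
    duration_s: float,
    rate: float = 50.0,
    seed: int = 0,
) -> SyntheticRecording:
    """Simulate one participant: semi-Markov activity bouts + per-bout signal.

    Returns exactly round(duration_s * rate) frames.  Deterministic given
    ``seed``.  Dwell times are exponential with the per-activity mean,
    truncated below at 1 s; the initial activity is drawn from the
    dwell-weighted stationary distribution so short recordings are already
    close to the long-run activity mix.
    """
    if duration_s <= 0 or rate <= 0:
        raise ValueError("duration_s and rate must be positive")
    n_frames = int(round(duration_s * rate))
    if n_frames < 1:
        raise ValueError("duration shorter than one frame")
    missing = [a for a in profile.activity_set if a not in activity_models]
    if missing:
        raise ConfigurationError(f"no activity model for ids {missing}")

    rng = np.random.default_rng(seed)
    acts = list(profile.activity_set)
    shares = expected_activity_shares(profile)
    state = rng.choice(len(acts), p=np.array([shares[a] for a in acts]))

    values = np.empty((6, n_frames), dtype=float)
    labels = np.empty(n_frames, dtype=np.int64)
    filled = 0
    while filled < n_frames:
        act = acts[state]
        dwell = max(1.0, rng.exponential(profile.dwell_mean[act]))
        n_bout = min(max(1, int(round(dwell * rate))), n_frames - filled)
        values[:, filled : filled + n_bout] = _bout_signal(
            activity_models[act], profile, n_bout, rate, rng
        )
        labels[filled : filled + n_bout] = act
        filled += n_bout
        state = rng.choice(len(acts), p=profile.transition_matrix[state])

    signal = SignalWindow(values=values, channel_names=CANONICAL_CHANNELS, rate=rate)
    return SyntheticRecording(
        participant_id=f"{profile.name}_{seed}",
        cohort=profile.name,
        signal=signal,
        labels=LabelSequence(labels=labels, label_map=dict(ACTIVITY_NAMES)),
        rate=rate,
        seed=seed,
    )


def _child_seed(master_seed: int, index: int) -> int:
    """Fixed seed-splitting rule: one child stream per participant."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(
    profile: CohortProfile,
    activity_models: dict[int, ActivityModel],
    seed: int = 0,
    rate: float = 50.0,
) -> list[SyntheticRecording]:
    """Simulate a whole cohort with per-participant durations and seeds."""
    if profile.participant_count < 2:
        raise ValueError(
            "participant_count must be >= 2 (leave-one-participant-out needs folds)"
        )
    dur_rng = np.random.default_rng(_child_seed(seed, 10**6))
    recordings = []
    for i in range(profile.participant_count):
        duration_min = max(
            1.0, dur_rng.normal(profile.duration_mean, profile.duration_sd)
        )
        rec = generate_recording(
            profile,
            activity_models,
            duration_s=duration_min * 60.0,
            rate=rate,
            seed=_child_seed(seed, i),
        )
        object.__setattr__(rec, "participant_id", f"{profile.name}_p{i:02d}")
        recordings.append(rec)
    return recordings


# ---------------------------------------------------------------------------
# default profiles: the study conditions every downstream stage is run under
# ---------------------------------------------------------------------------

def default_activity_models() -> dict[int, ActivityModel]:
    """Nine activity signatures over (lower back, thigh) sensors.

    Orientations encode the posture geometry that makes single-sensor
    recognition asymmetric: the lower back stays upright in both standing and
    sitting (so it cannot separate them), while the thigh is vertical when
    standing but horizontal when sitting and lying (so it cannot separate
    those two).  Locomotor activities differ mainly by cadence and amplitude,
    with stair cadences adjacent to walking so the classes genuinely overlap.
    Thigh amplitudes exceed lower-back amplitudes throughout, reflecting the
    larger segment excursions at the thigh.
    """
    upright = [1.0, 0.0, 0.0]
    m = {
        WALKING: ActivityModel(
            WALKING, [upright, upright], [[0.25, 0.15, 0.10], [0.45, 0.22, 0.15]],
            fundamental_freq=1.8, harmonic_count=3,
        ),
        RUNNING: ActivityModel(
            RUNNING, [upright, upright], [[0.60, 0.30, 0.25], [1.00, 0.50, 0.35]],
            fundamental_freq=2.7, harmonic_count=3,
        ),
        STANDING: ActivityModel(
            STANDING, [upright, upright], [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
            fundamental_freq=0.0, harmonic_count=1,
        ),
        # stairs keep near-walking trunk orientation (only a slight thigh
        # pitch) and adjacent cadences, so walking/stairs genuinely overlap
        STAIRS_UP: ActivityModel(
            STAIRS_UP, [upright, [0.96, 0.08, 0.26]],
            [[0.28, 0.15, 0.12], [0.55, 0.25, 0.20]],
            fundamental_freq=1.4, harmonic_count=3,
        ),
        STAIRS_DOWN: ActivityModel(
            STAIRS_DOWN, [upright, [0.96, -0.08, 0.26]],
            [[0.30, 0.18, 0.12], [0.50, 0.30, 0.20]],
            fundamental_freq=1.6, harmonic_count=3,
        ),
        # the lower back stays near-upright in sitting (trunk posture barely
        # changes), so the back sensor can hardly separate sitting from
        # standing; the horizontal thigh separates them trivially
        SITTING: ActivityModel(
            SITTING, [[0.998, 0.0, 0.06], [0.08, 0.10, 0.99]],
            [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
            fundamental_freq=0.0, harmonic_count=1,
        ),
        LYING: ActivityModel(
            LYING, [[0.05, 0.12, 0.99], [0.05, 0.10, 0.99]],
            [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
            fundamental_freq=0.0, harmonic_count=1,
        ),
        CYCLING_SIT: ActivityModel(
            CYCLING_SIT, [[0.97, 0.05, 0.24], [0.30, 0.10, 0.95]],
            [[0.12, 0.08, 0.10], [0.50, 0.20, 0.50]],
            fundamental_freq=1.3, harmonic_count=2,
        ),
        CYCLING_STAND: ActivityModel(
            CYCLING_STAND, [[0.95, 0.05, 0.30], [0.85, 0.10, 0.52]],
            [[0.20, 0.12, 0.15], [0.60, 0.25, 0.40]],
            fundamental_freq=1.2, harmonic_count=2,
        ),
    }
    return m


# transitions over the young activity order (WALKING..CYCLING_STAND);
# ambulatory/postural hub structure yields the dominant sit/stand/walk mix
_YOUNG_ORDER = YOUNG_ACTIVITIES
_YOUNG_TRANSITIONS = np.array(
    #  walk   run  stand    up  down   sit   lie  csit  cstd
    [[0.00, 0.10, 0.35, 0.15, 0.15, 0.15, 0.00, 0.05, 0.05],  # walking
     [0.60, 0.00, 0.40, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],  # running
     [0.45, 0.00, 0.00, 0.05, 0.05, 0.35, 0.05, 0.00, 0.05],  # standing
     [0.50, 0.00, 0.30, 0.00, 0.20, 0.00, 0.00, 0.00, 0.00],  # stairs up
     [0.50, 0.00, 0.30, 0.20, 0.00, 0.00, 0.00, 0.00, 0.00],  # stairs down
     [0.25, 0.00, 0.50, 0.00, 0.00, 0.00, 0.15, 0.10, 0.00],  # sitting
     [0.00, 0.00, 0.40, 0.00, 0.00, 0.60, 0.00, 0.00, 0.00],  # lying
     [0.00, 0.00, 0.30, 0.00, 0.00, 0.50, 0.00, 0.00, 0.20],  # cycling sit
     [0.00, 0.00, 0.50, 0.00, 0.00, 0.00, 0.00, 0.50, 0.00]]  # cycling stand
)

_DWELL_MEANS = {
    WALKING: 30.0, RUNNING: 15.0, STANDING: 25.0, STAIRS_UP: 8.0,
    STAIRS_DOWN: 8.0, SITTING: 60.0, LYING: 45.0, CYCLING_SIT: 20.0,
    CYCLING_STAND: 6.0,
}


def _restrict_transitions(
    matrix: np.ndarray, full_order: tuple[int, ...], subset: tuple[int, ...]
) -> np.ndarray:
    """Restrict a transition matrix to a subset of states and renormalise rows."""
    idx = [full_order.index(a) for a in subset]
    sub = matrix[np.ix_(idx, idx)].copy()
    rowsums = sub.sum(axis=1, keepdims=True)
    if np.any(rowsums == 0):
        raise ValueError("restriction left an absorbing row")
    return sub / rowsums


def default_profiles() -> tuple[CohortProfile, CohortProfile, dict[int, ActivityModel]]:
    """The two cohorts at study scale: 22 young (nine activities, ~98 min each)
    and 18 old (six-activity subset, ~42 min each, slower and damped dynamics,
    with stair dynamics additionally damped so stairs drift toward
    standing-like signals)."""
    models = default_activity_models()
    young = CohortProfile(
        name="young",
        activity_set=YOUNG_ACTIVITIES,
        cadence_scale=1.0,
        amplitude_scale=1.0,
        transition_matrix=_YOUNG_TRANSITIONS,
        dwell_mean=dict(_DWELL_MEANS),
        participant_count=22,
        duration_mean=97.90,
        duration_sd=32.95,
    )
    old = CohortProfile(
        name="old",
        activity_set=OLD_ACTIVITIES,
        cadence_scale=0.78,
        amplitude_scale=0.85,
        transition_matrix=_restrict_transitions(
            _YOUNG_TRANSITIONS, _YOUNG_ORDER, OLD_ACTIVITIES
        ),
        dwell_mean=dict(_DWELL_MEANS),
        participant_count=18,
        duration_mean=41.84,
        duration_sd=5.77,
        stair_amplitude_factor=0.55,
    )
    return young, old, models


def desk_profiles(
    young_participants: int = 8,
    old_participants: int = 6,
    duration_min: float = 5.0,
) -> tuple[CohortProfile, CohortProfile, dict[int, ActivityModel]]:
    """Reduced-size cohorts (same dynamics as the defaults) for desk-scale runs."""
    young, old, models = default_profiles()
    from dataclasses import replace

    young = replace(
        young,
        participant_count=young_participants,
        duration_mean=duration_min,
        duration_sd=duration_min * 0.1,
    )
    old = replace(
        old,
        participant_count=old_participants,
        duration_mean=duration_min,
        duration_sd=duration_min * 0.1,
    )
    return young, old, models


def profile_to_yaml(profile: CohortProfile, path: str | Path) -> Path:
    """Serialise a cohort profile as a plain-text YAML config."""
    payload = {
        "name": profile.name,
        "activity_set": [int(a) for a in profile.activity_set],
        "cadence_scale": float(profile.cadence_scale),
        "amplitude_scale": float(profile.amplitude_scale),
        "transition_matrix": profile.transition_matrix.tolist(),
        "dwell_mean": {int(k): float(v) for k, v in profile.dwell_mean.items()},
        "participant_count": int(profile.participant_count),
        "duration_mean": float(profile.duration_mean),
        "duration_sd": float(profile.duration_sd),
        "stair_amplitude_factor": float(profile.stair_amplitude_factor),
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def profile_from_yaml(path: str | Path) -> CohortProfile:
    payload = yaml.safe_load(Path(path).read_text())
    payload["activity_set"] = tuple(payload["activity_set"])
    payload["transition_matrix"] = np.array(payload["transition_matrix"])
    payload["dwell_mean"] = {int(k): float(v) for k, v in payload["dwell_mean"].items()}
    return CohortProfile(**payload)
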