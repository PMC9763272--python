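"""Synthetic subacute-stroke cohort and trajectory generator.

Emulates the data structure of a single-centre robot-assisted-therapy study:
66 inpatients with subacute stroke, each contributing baseline demographics,
Motricity Index scores at admission (T1) and discharge (T2), and planar
point-to-point reaching trajectories in four directions from which the
kinematic metrics are extracted.

The generative model
--------------------
Each patient carries a latent impairment level ``u`` in [0, 1] (1 = most
impaired) that drives everything observable:

* T1 sub-item scores fall with ``u`` (uniform quantile binning of the latent
  into the six discrete classes, with configurable misclassification noise);
* the movement path errors rise with ``u`` ("the less accurate the movement,
  the weaker the limb") and the mean speed falls with it, each direction
  receiving its own jittered copy of the latent so the four metrics correlate
  without being collinear;
* discharge scores follow the published single-predictor relation:
  ``T2 = intercept + slope * MPE_C_std + noise``, where ``MPE_C_std`` is the
  path error toward the body standardized across the cohort, then clamped to
  the scale range and snapped to the nearest attainable discrete score --
  matching how a therapist can only award valid class values.

Trajectories are built so that metric extraction inverts generation: the
lateral deviation is a half-sine of amplitude ``a = pi * MPE / 2``
perpendicular to the straight line (its mean absolute value is ``2a/pi``,
i.e. exactly the requested path error), and the movement duration is chosen
so the path length over time equals the requested mean speed.  The
tangential progress follows a minimum-jerk bell, the standard model of
point-to-point reaching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .kinematics import DIRECTIONS, Trajectory
from .regression import PUBLISHED_LOOCV_MODELS
from .scales import SUBITEM_CLASSES, get_scale, mi_total, nearest_valid_score

__all__ = [
    "Demographics",
    "GeneratorConfig",
    "PatientRecord",
    "Cohort",
    "generate_trajectory",
    "generate_patient",
    "generate_cohort",
]

#: Unit chord vectors of each direction in the lesion frame.
_DIRECTION_UNIT: dict[str, tuple[float, float]] = {
    "A": (0.0, 1.0),   # away from the body
    "B": (-1.0, 0.0),  # medial
    "C": (0.0, -1.0),  # toward the body
    "D": (1.0, 0.0),   # lateral
}


@dataclass(frozen=True)
class Demographics:
    """Baseline cohort marginals (defaults mirror the study population)."""

    age_mean: float = 64.97
    age_sd: float = 12.75
    male_prop: float = 0.667
    right_prop: float = 0.591
    onset_mean_days: float = 15.27
    onset_sd_days: float = 18.07
    ischemic_prop: float = 0.712


def _default_coefficients() -> dict[str, tuple[float, float]]:
    return {k: tuple(v) for k, v in PUBLISHED_LOOCV_MODELS.items()}


def _default_noise() -> dict[str, float]:
    # Residual scales chosen so the fitted models explain roughly 60-75% of
    # the discharge-score variance, the regime the method operates in.
    return {"ELBOW": 3.0, "SHOULDER": 3.5, "UL": 7.0}


@dataclass
class GeneratorConfig:
    """Everything that determines a synthetic cohort.

    Parameters
    ----------
    n_patients:
        Cohort size (>= 2; discharge scores are generated from the
        cohort-standardized path error, undefined for a single patient).
    target_distance:
        Centre-to-peripheral-target distance in metres.
    movement_duration:
        Optional fixed movement duration in seconds; when ``None`` (default)
        the duration of each movement is derived from its requested mean
        speed.
    sample_rate:
        Nominal robot sampling rate in Hz.
    outcome_coefficients:
        Per-outcome ``(intercept, slope)`` of the generative relation on the
        standardized path error toward the body; defaults to the published
        models.
    noise_sd:
        Per-outcome Gaussian residual SD, in score points.
    class_noise:
        SD of the latent jitter applied before binning a sub-item score --
        the misclassification noise of therapist scoring.  0 makes the
        latent-to-class map deterministic.
    direction_noise:
        SD of the per-direction latent jitter; controls how strongly the
        four kinematic metrics correlate with each other.
    metric_noise:
        SD of the multiplicative log-normal measurement noise on each metric.
    mpe_range:
        (least, most impaired) movement path error in metres.
    ms_range:
        (most impaired, least impaired) mean speed in m/s.
    demographics:
        Marginal distributions for age, sex, side, onset and etiology.
    seed:
        Master seed; identical configs produce bitwise-identical cohorts.
    """

    n_patients: int = 66
    target_distance: float = 0.14
    movement_duration: float | None = None
    sample_rate: float = 200.0
    outcome_coefficients: dict[str, tuple[float, float]] = field(
        default_factory=_default_coefficients
    )
    noise_sd: dict[str, float] = field(default_factory=_default_noise)
    class_noise: float = 0.08
    direction_noise: float = 0.15
    metric_noise: float = 0.10
    mpe_range: tuple[float, float] = (0.005, 0.040)
    ms_range: tuple[float, float] = (0.06, 0.30)
    demographics: Demographics = field(default_factory=Demographics)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.movement_duration is not None and self.movement_duration <= 0:
            raise ValueError("movement_duration must be positive")
        if self.target_distance <= 0:
            raise ValueError("target_distance must be positive")
        for outcome in ("ELBOW", "SHOULDER", "UL"):
            if outcome not in self.outcome_coefficients:
                raise ValueError(f"missing outcome coefficients for {outcome}")
            if outcome not in self.noise_sd:
                raise ValueError(f"missing noise_sd for {outcome}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outcome_coefficients"] = {
            k: list(v) for k, v in self.outcome_coefficients.items()
        }
        d["mpe_range"] = list(self.mpe_range)
        d["ms_range"] = list(self.ms_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "demographics" in d and isinstance(d["demographics"], Mapping):
            d["demographics"] = Demographics(**d["demographics"])
        if "outcome_coefficients" in d:
            d["outcome_coefficients"] = {
                k: tuple(v) for k, v in d["outcome_coefficients"].items()
            }
        for key in ("mpe_range", "ms_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# trajectory synthesis


def _minjerk_progress(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _minjerk_pulse(tau: np.ndarray) -> np.ndarray:
    """Derivative of the minimum-jerk profile: the bell-shaped speed pulse."""
    return 30 * tau**2 * (1 - tau) ** 2


def generate_trajectory(
    direction: str,
    target_mpe: float,
    mean_speed: float,
    config: GeneratorConfig,
    side: str = "right",
) -> Trajectory:
    """Synthesize one point-to-point movement with prescribed metrics.

    The movement runs from the central target to the peripheral target of
    ``direction`` over the configured distance.  Lateral deviation from the
    chord is a half-sine in time with amplitude ``pi * target_mpe / 2``, so
    the extracted path error converges to ``target_mpe`` (the time-average
    of ``|a sin(pi t/T)|`` is ``2a/pi``); the duration is set so the
    extracted mean speed converges to ``mean_speed``.  Tangential progress
    along the chord follows a minimum-jerk bell.  Analytic velocities are
    stored alongside positions.

    Generation is deterministic given its parameters.  For a left-affected
    side the movement is expressed in the robot frame by mirroring x, so
    that :func:`rmkpredict.kinematics.to_lesion_frame` recovers the lesion
    frame geometry.
    """
    config.validate()
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if target_mpe < 0:
        raise ValueError("target_mpe must be non-negative")
    L = config.target_distance
    a = math.pi * target_mpe / 2.0

    if config.movement_duration is not None:
        T = config.movement_duration
    else:
        if mean_speed <= 0:
            raise ValueError("mean_speed must be positive")
        # path length of the deviated curve per unit time, integrated over
        # the normalized movement; duration scales it to the target speed
        tau = np.linspace(0.0, 1.0, 4001)
        speed_shape = np.hypot(
            L * _minjerk_pulse(tau), a * math.pi * np.cos(math.pi * tau)
        )
        T = float(np.trapezoid(speed_shape, tau)) / mean_speed
    if T <= 0:
        raise ValueError("derived movement duration must be positive")

    # midpoint sampling: the recorder's clock is not phase-locked to the
    # movement, so samples straddle rather than include the rest endpoints;
    # discrete time-averages then match their integrals to O(n^-2) instead
    # of carrying an O(1/n) endpoint deficit
    n = max(2, int(round(T * config.sample_rate)))
    dt = T / n
    t = (np.arange(n) + 0.5) * dt
    tau = t / T
    s = L * _minjerk_progress(tau)
    s_dot = L * _minjerk_pulse(tau) / T
    lat = a * np.sin(math.pi * tau)
    lat_dot = a * math.pi * np.cos(math.pi * tau) / T

    ux, uy = _DIRECTION_UNIT[direction]
    px, py = -uy, ux  # left-of-chord normal: the flexor side for direction C
    x = ux * s + px * lat
    y = uy * s + py * lat
    vx = ux * s_dot + px * lat_dot
    vy = uy * s_dot + py * lat_dot
    if side == "left":
        x, vx = -x, -vx

    return Trajectory(
        t=t, x=x, y=y, direction=direction, side=side,
        vx=vx, vy=vy, sample_rate=config.sample_rate,
    )


# ---------------------------------------------------------------------------
# patients and cohorts


@dataclass
class PatientRecord:
    """One patient's demographics, clinical scores and kinematic metrics.

    Discharge (T2) scores are filled in at cohort level, because the
    generative relation uses the path error standardized across the cohort.
    """

    id: str
    age: float
    sex: str
    side: str
    onset_days: float
    etiology: str
    mi_elbow_t1: int
    mi_shoulder_t1: int
    mi_ul_t1: int
    mpe_a: float
    mpe_c: float
    mpe_d: float
    ms_b: float
    latent_impairment: float
    mi_elbow_t2: int | None = None
    mi_shoulder_t2: int | None = None
    mi_ul_t2: int | None = None


_TABLE_COLUMNS = [
    "id", "age", "sex", "side", "onset_days", "etiology",
    "mi_elbow_t1", "mi_shoulder_t1", "mi_ul_t1",
    "mi_elbow_t2", "mi_shoulder_t2", "mi_ul_t2",
    "mpe_a", "mpe_c", "mpe_d", "ms_b", "latent_impairment",
]


@dataclass
class Cohort:
    """A generated cohort: one table row per patient plus raw trajectories.

    ``trajectories`` maps ``(patient_id, direction)`` to the recorded
    movement; it is empty when the cohort was generated table-only.
    """

    table: pd.DataFrame
    trajectories: dict[tuple[str, str], Trajectory]
    config: GeneratorConfig

    @property
    def n(self) -> int:
        return len(self.table)

    def patient_trajectories(self, patient_id: str) -> dict[str, Trajectory]:
        return {
            d: traj
            for (pid, d), traj in self.trajectories.items()
            if pid == patient_id
        }


def _subitem_from_latent(u: float, rng: np.random.Generator, class_noise: float) -> int:
    """Uniform quantile binning of ability (1 - impairment) into six classes."""
    jittered = u + (rng.normal(0.0, class_noise) if class_noise > 0 else 0.0)
    jittered = min(max(jittered, 0.0), 1.0)
    idx = min(5, int(math.floor((1.0 - jittered) * 6)))
    return SUBITEM_CLASSES[idx]


def generate_patient(
    latent_impairment: float,
    config: GeneratorConfig,
    seed: int | np.random.SeedSequence = 0,
    patient_id: str = "P001",
    include_trajectories: bool = True,
) -> tuple[PatientRecord, dict[str, Trajectory]]:
    """Generate one patient's record and movements from a latent impairment.

    ``latent_impairment`` lies in [0, 1] with 1 the most impaired.  Baseline
    sub-items decrease with impairment, path errors increase and mean speed
    decreases; trajectories realize the patient's metric values in all four
    directions.  Identical seeds reproduce the patient exactly.
    """
    config.validate()
    if not 0.0 <= latent_impairment <= 1.0:
        raise ValueError("latent_impairment must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    demo = config.demographics
    u = latent_impairment

    age = float(np.clip(rng.normal(demo.age_mean, demo.age_sd), 18.0, 95.0))
    sex = "male" if rng.random() < demo.male_prop else "female"
    side = "right" if rng.random() < demo.right_prop else "left"
    onset = float(max(1.0, rng.normal(demo.onset_mean_days, demo.onset_sd_days)))
    etiology = "ischemic" if rng.random() < demo.ischemic_prop else "hemorrhagic"

    elbow = _subitem_from_latent(u, rng, config.class_noise)
    shoulder = _subitem_from_latent(u, rng, config.class_noise)
    pinch = _subitem_from_latent(u, rng, config.class_noise)
    ul = mi_total(elbow, shoulder, pinch)

    # Each direction sees its own jittered copy of the latent, so metrics
    # correlate through the shared impairment without being collinear.
    mpe_lo, mpe_hi = config.mpe_range
    ms_lo, ms_hi = config.ms_range
    mpe: dict[str, float] = {}
    ms: dict[str, float] = {}
    for direction in DIRECTIONS:
        u_dir = float(np.clip(u + rng.normal(0.0, config.direction_noise), 0.0, 1.0))
        wobble = math.exp(rng.normal(0.0, config.metric_noise))
        mpe[direction] = (mpe_lo + (mpe_hi - mpe_lo) * u_dir) * wobble
        wobble_ms = math.exp(rng.normal(0.0, config.metric_noise))
        ms[direction] = (ms_hi - (ms_hi - ms_lo) * u_dir) * wobble_ms

    record = PatientRecord(
        id=patient_id,
        age=age,
        sex=sex,
        side=side,
        onset_days=onset,
        etiology=etiology,
        mi_elbow_t1=elbow,
        mi_shoulder_t1=shoulder,
        mi_ul_t1=ul,
        mpe_a=mpe["A"],
        mpe_c=mpe["C"],
        mpe_d=mpe["D"],
        ms_b=ms["B"],
        latent_impairment=u,
    )

    trajectories: dict[str, Trajectory] = {}
    if include_trajectories:
        for direction in DIRECTIONS:
            trajectories[direction] = generate_trajectory(
                direction, mpe[direction], ms[direction], config, side=side
            )
    return record, trajectories


def generate_cohort(
    config: GeneratorConfig, include_trajectories: bool = True
) -> Cohort:
    """Generate a full cohort with the configured statistical structure.

    Latent impairments are drawn uniformly on [0, 1]; each patient is then
    generated from an independently spawned random stream.  Discharge scores
    are produced at cohort level: the path error toward the body is
    standardized across patients (n-1 denominator), passed through each
    outcome's linear relation plus Gaussian noise, clamped to the scale
    range, and snapped to the nearest attainable discrete score.
    """
    config.validate()
    n = config.n_patients
    root = np.random.SeedSequence(config.seed)
    master_seq, *patient_seqs = root.spawn(n + 1)
    master = np.random.default_rng(master_seq)

    latents = master.uniform(0.0, 1.0, size=n)
    records: list[PatientRecord] = []
    trajectories: dict[tuple[str, str], Trajectory] = {}
    for i in range(n):
        pid = f"P{i + 1:03d}"
        record, trajs = generate_patient(
            latents[i],
            config,
            seed=patient_seqs[i],
            patient_id=pid,
            include_trajectories=include_trajectories,
        )
        records.append(record)
        for direction, traj in trajs.items():
            trajectories[(pid, direction)] = traj

    mpe_c = np.array([r.mpe_c for r in records])
    z = (mpe_c - mpe_c.mean()) / mpe_c.std(ddof=1)

    for outcome, attr in (
        ("ELBOW", "mi_elbow_t2"),
        ("SHOULDER", "mi_shoulder_t2"),
        ("UL", "mi_ul_t2"),
    ):
        scale = get_scale(outcome)
        intercept, slope = config.outcome_coefficients[outcome]
        sd = config.noise_sd[outcome]
        noise = master.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        raw = intercept + slope * z + noise
        clamped = np.clip(raw, scale.min_score, scale.max_score)
        for record, value in zip(records, clamped):
            setattr(record, attr, int(nearest_valid_score(float(value), scale)))

    table = pd.DataFrame(
        [{col: getattr(r, col) for col in _TABLE_COLUMNS} for r in records],
        columns=_TABLE_COLUMNS,
    )
    return Cohort(table=table, trajectories=trajectories, config=config)
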