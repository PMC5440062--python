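"""Synthetic behavioral cohorts with known ground truth.

The generator is the forward model of the analysis pipeline: each subject's
gain state evolves over the trial schedule under the viscoelastic primitive
model, and on every trained-direction error-clamp (EC) trial the lateral
force is synthesized from the current gains applied to that trial's own
minimum-jerk kinematics,

    f_lat(t) = sign * (k * 45 * pos(t) + b * 15 * vel(t)) + noise.

Emulated features of the real task: 14-subject groups, one field type per
subject with the field direction counterbalanced by subject parity, 10 cm
reaches with peak speeds drawn uniformly from the rewarded 0.25-0.35 m/s
band, EC probes placed by the schedule, baseline EC trials carrying pure
sensor noise (zero gains), and trial-to-trial gain variability plus a
between-subject scaling of the adaptation asymptote sized so that
cross-subject SEMs of epoch-mean gains land near the observed 0.02-0.05
range.  Not emulated: feedback corrections inside the clamp, trial
rejections/timeouts, fatigue or savings.

Model state updates happen on trained FF trials (learning) and on decay-
period EC trials (retention-only decay); interspersed EC probes during
training are measurement-only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .kinematics import B_DEFAULT, K_DEFAULT, min_jerk_reach
from .model import (
    GainState,
    ModelParams,
    VFF_PFF_ASYMMETRIC,
    adaptation_step,
    decay_step,
    goal_for,
    sample_primitives,
)
from .schedule import Schedule, build_schedule

__all__ = ["NoiseModel", "CohortSpec", "CohortData", "generate_subject", "generate_cohort"]


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes of the synthetic cohort.

    gain_noise_sd : per-trial SD added to the measured (k, b) gains
        (dimensionless; trial-to-trial motor output variability).
    force_noise_sd : additive white force noise, Newtons (sensor / residual
        feedback noise on the recorded lateral force).
    subject_scale_sd : SD of the multiplicative between-subject factor on
        the adaptation goal (spread of asymptotic adaptation levels).
    """

    gain_noise_sd: float = 0.05
    force_noise_sd: float = 0.10
    subject_scale_sd: float = 0.10

    def __post_init__(self) -> None:
        if min(self.gain_noise_sd, self.force_noise_sd, self.subject_scale_sd) < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def silent(self) -> bool:
        return self.gain_noise_sd == self.force_noise_sd == self.subject_scale_sd == 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of one synthetic group."""

    ff_type: str = "vFF"
    n_subjects: int = 14
    params: ModelParams = field(default_factory=lambda: VFF_PFF_ASYMMETRIC)
    noise: NoiseModel = field(default_factory=NoiseModel)
    schedule_seed: int = 0
    counterbalance: bool = True
    mode: str = "mean_field"  # or "ensemble"
    distance: float = 0.10
    speed_range: tuple[float, float] = (0.25, 0.35)
    dt: float = 0.001

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.mode not in ("mean_field", "ensemble"):
            raise ValueError("mode must be 'mean_field' or 'ensemble'")

    def to_json(self) -> str:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        d["noise"] = asdict(self.noise)
        return json.dumps(d, indent=2)


@dataclass
class CohortData:
    """Observable trial table, hidden ground truth, and per-subject metadata."""

    spec: CohortSpec
    trials: pd.DataFrame  # subject, trial_id, t, pos, vel, f_lat
    truth: pd.DataFrame  # subject, trial_id, block, phase, indices, k_true, b_true
    schedules: dict[int, Schedule]
    signs: dict[int, int]
    seed: int


def _subject_sign(spec: CohortSpec, subject_id: int) -> int:
    if not spec.counterbalance:
        return 1
    return 1 if subject_id % 2 == 1 else -1


def generate_subject(
    spec: CohortSpec, subject_id: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, Schedule, int]:
    """Simulate one subject's session.

    Returns the per-sample trial table (trained EC trials only -- the only
    trials the analysis consumes), the per-trial ground-truth gain table,
    the subject's schedule and the field sign.
    """
    rng = np.random.default_rng([seed, subject_id])
    schedule = build_schedule(spec.ff_type, spec.schedule_seed + subject_id)
    sign = _subject_sign(spec, subject_id)
    noise = spec.noise

    scale = 1.0 + (rng.normal(0.0, noise.subject_scale_sd) if noise.subject_scale_sd else 0.0)
    goal = goal_for(spec.ff_type)
    goal = GainState(goal.k * scale, goal.b * scale)
    ensemble = (
        sample_primitives(spec.params, rng) if spec.mode == "ensemble" else None
    )

    state = GainState(0.0, 0.0)
    cols: dict[str, list[np.ndarray]] = {"trial_id": [], "t": [], "pos": [], "vel": [], "f_lat": []}
    truth_rows: list[dict] = []
    for tr in schedule:
        if tr.direction != 270:
            continue  # untrained reaches carry no analyzed force data
        if tr.trial_type == "FF":
            state = adaptation_step(ensemble, state, goal, spec.params)
            continue
        if tr.trial_type != "EC":
            continue
        if tr.block == "decay":
            state = decay_step(state, spec.params)
        if tr.block == "baseline":
            k_meas, b_meas = 0.0, 0.0
        else:
            k_meas = state.k + rng.normal(0.0, noise.gain_noise_sd)
            b_meas = state.b + rng.normal(0.0, noise.gain_noise_sd)
        peak = rng.uniform(*spec.speed_range)
        kin = min_jerk_reach(spec.distance, peak, dt=spec.dt)
        f = sign * (k_meas * K_DEFAULT * kin.pos + b_meas * B_DEFAULT * kin.vel)
        if noise.force_noise_sd:
            f = f + rng.normal(0.0, noise.force_noise_sd, size=f.shape)
        cols["trial_id"].append(np.full(kin.t.size, tr.index))
        cols["t"].append(kin.t)
        cols["pos"].append(kin.pos)
        cols["vel"].append(kin.vel)
        cols["f_lat"].append(f)
        truth_rows.append(
            {
                "subject": subject_id,
                "trial_id": tr.index,
                "block": tr.block,
                "training_index": tr.training_index,
                "decay_index": tr.decay_index,
                "k_true": k_meas,
                "b_true": b_meas,
            }
        )
    trials = pd.DataFrame(
        {name: np.concatenate(arrs) for name, arrs in cols.items()}
    )
    trials["trial_id"] = trials["trial_id"].astype(int)
    trials.insert(0, "subject", subject_id)
    truth = pd.DataFrame(truth_rows)
    return trials, truth, schedule, sign


def generate_cohort(spec: CohortSpec, seed: int) -> CohortData:
    """Generate a full cohort; deterministic in (spec, seed)."""
    all_trials, all_truth = [], []
    schedules: dict[int, Schedule] = {}
    signs: dict[int, int] = {}
    for subject_id in range(1, spec.n_subjects + 1):
        trials, truth, schedule, sign = generate_subject(spec, subject_id, seed)
        all_trials.append(trials)
        all_truth.append(truth)
        schedules[subject_id] = schedule
        signs[subject_id] = sign
    return CohortData(
        spec=spec,
        trials=pd.concat(all_trials, ignore_index=True),
        truth=pd.concat(all_truth, ignore_index=True),
        schedules=schedules,
        signs=signs,
        seed=seed,
    )
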