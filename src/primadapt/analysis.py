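"""Error-clamp force-profile analysis: adaptation coefficients and gains.

The feedforward adaptive command is read out on error-clamp (EC) trials,
where the channel suppresses lateral motion and the lateral force the
subject presses into the wall is recorded.  Two measures are computed per
EC trial, both over a 1500 ms window centered on the trial's peak velocity
(signals are zero outside the recorded reach):

adaptation coefficient
    slope of the no-intercept regression of the subject's lateral force on
    the ideal compensatory force built from the trial's own kinematics;
    1 = full compensation.
gain decomposition
    no-intercept multiple regression of the lateral force on the position
    and velocity traces; the raw coefficients divided by K = 45 N/m and
    B = 15 N.s/m give the dimensionless gain-space point (k, b).  An
    optional acceleration regressor is reported separately and never folded
    into (k, b).

Baseline EC force profiles (mean per subject, per time sample) are
subtracted before regression, and forces are sign-corrected by the
counterbalanced field direction, so compensation of the trained field is
always positive.  Regressions are intercept-free because the baseline step
already removes any bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import acos, degrees, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import COUPLINGS, B_DEFAULT, K_DEFAULT
from .model import GainState

__all__ = [
    "AnalysisWindow",
    "EpochDef",
    "DEFAULT_EPOCHS",
    "GainDecomposition",
    "CompareResult",
    "adaptation_coefficient",
    "gain_decomposition",
    "goal_components",
    "trajectory_angle",
    "epoch_average",
    "normalize_series",
    "epoch_compare",
    "analyze_trials",
    "analyze_cohort",
    "decay_gain_matrix",
]

#: Peak-velocity band for trials admitted to analysis, m/s.
VELOCITY_FILTER = (0.2, 0.4)


@dataclass(frozen=True)
class AnalysisWindow:
    """Temporal analysis window: +/- half_width s around peak velocity.

    All windowed signals are linearly resampled onto the window's canonical
    uniform grid (default 1 ms step) and are zero outside the recorded
    trial, so trials with different durations and sampling grids become
    directly comparable.
    """

    half_width: float = 0.750
    dt: float = 0.001

    def __post_init__(self) -> None:
        if self.half_width <= 0 or self.dt <= 0:
            raise ValueError("half_width and dt must be positive")

    @property
    def grid(self) -> np.ndarray:
        n = round(self.half_width / self.dt)
        return np.arange(-n, n + 1) * self.dt

    def extract(self, t: np.ndarray, values: np.ndarray, center: float) -> np.ndarray:
        """Resample ``values(t)`` onto the window grid centered at ``center``."""
        return np.interp(self.grid + center, t, values, left=0.0, right=0.0)


@dataclass(frozen=True)
class EpochDef:
    """Inclusive 1-based trial-index interval used for epoch averages."""

    name: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo < 1 or self.hi < self.lo:
            raise ValueError("epoch interval must satisfy 1 <= lo <= hi")


#: Classical window conventions: training trials 1-15 / 150-160, decay
#: trials 11-20 / 50-60.  Callers pass their own EpochDef when the
#: schedule's training-trial count differs.
DEFAULT_EPOCHS = {
    "early_adapt": EpochDef("early_adapt", 1, 15),
    "late_adapt": EpochDef("late_adapt", 150, 160),
    "early_decay": EpochDef("early_decay", 11, 20),
    "late_decay": EpochDef("late_decay", 50, 60),
}


def adaptation_coefficient(f_subject: np.ndarray, f_ideal: np.ndarray) -> float:
    """No-intercept regression slope of subject force on the ideal force.

    Both inputs are windowed, baseline-subtracted, sign-corrected lateral
    force arrays on a common grid.  Returns sum(f_s * f_i) / sum(f_i^2).
    """
    f_subject = np.asarray(f_subject, dtype=float)
    f_ideal = np.asarray(f_ideal, dtype=float)
    if f_subject.shape != f_ideal.shape:
        raise ValueError("force arrays must share a grid")
    denom = float(f_ideal @ f_ideal)
    if denom == 0.0:
        raise ValueError("ideal force is identically zero in the window")
    return float(f_subject @ f_ideal) / denom


@dataclass(frozen=True)
class GainDecomposition:
    """Result of the position/velocity multiple regression."""

    k: float
    b: float
    r2: float
    accel_coef: float | None = None
    r2_with_accel: float | None = None

    @property
    def gain(self) -> GainState:
        return GainState(self.k, self.b)


def _uncentered_r2(f: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(f @ f)
    if ss_tot == 0.0:
        return 1.0
    return 1.0 - float(resid @ resid) / ss_tot


def gain_decomposition(
    f_subject: np.ndarray,
    pos: np.ndarray,
    vel: np.ndarray,
    include_acceleration: bool = False,
    accel: np.ndarray | None = None,
    dt: float | None = None,
    K: float = K_DEFAULT,
    B: float = B_DEFAULT,
    cond_threshold: float = 1e8,
) -> GainDecomposition:
    """Decompose a lateral EC force into position and velocity gains.

    Inputs are windowed arrays on a common grid.  The no-intercept least
    squares coefficients on (pos, vel) are rescaled by (K, B) to give the
    dimensionless gains; the uncentered R^2 of the two-regressor fit is
    reported.  With ``include_acceleration`` a third regressor (supplied, or
    differenced from ``vel`` using ``dt``) is fit alongside; its coefficient
    and the augmented R^2 are reported separately and (k, b) always come
    from the three-regressor fit's first two coefficients only when the
    acceleration column is present -- the headline (k, b, r2) are from the
    two-regressor fit regardless.
    """
    f = np.asarray(f_subject, dtype=float)
    pos = np.asarray(pos, dtype=float)
    vel = np.asarray(vel, dtype=float)
    if not (f.shape == pos.shape == vel.shape):
        raise ValueError("force and kinematic arrays must share a grid")
    X = np.column_stack([pos, vel])
    if np.linalg.cond(X) > cond_threshold:
        raise ValueError("position and velocity regressors are collinear in the window")
    coef, *_ = np.linalg.lstsq(X, f, rcond=None)
    resid = f - X @ coef
    r2 = _uncentered_r2(f, resid)
    k, b = float(coef[0]) / K, float(coef[1]) / B

    if not include_acceleration:
        return GainDecomposition(k=k, b=b, r2=r2)
    if accel is None:
        if dt is None:
            raise ValueError("provide accel or dt to build the acceleration regressor")
        accel = np.gradient(vel, dt)
    X3 = np.column_stack([pos, vel, np.asarray(accel, dtype=float)])
    coef3, *_ = np.linalg.lstsq(X3, f, rcond=None)
    resid3 = f - X3 @ coef3
    return GainDecomposition(
        k=k,
        b=b,
        r2=r2,
        accel_coef=float(coef3[2]),
        r2_with_accel=_uncentered_r2(f, resid3),
    )


def goal_components(g: GainState, ff_type: str) -> tuple[float, float]:
    """(goal-aligned, goal-misaligned) gains for single-state training.

    For pFF the aligned axis is position (abscissa) and the misaligned axis
    velocity; for vFF the roles are reversed.  Combination fields have no
    single goal axis, so they are rejected.
    """
    if ff_type == "pFF":
        return g.k, g.b
    if ff_type == "vFF":
        return g.b, g.k
    raise ValueError("goal components are defined only for pFF and vFF training")


def trajectory_angle(g: GainState, goal: GainState) -> float:
    """Unsigned angle in degrees between g and the straight path to the goal."""
    gv = g.as_array()
    tv = goal.as_array()
    ng, nt = np.linalg.norm(gv), np.linalg.norm(tv)
    if ng == 0.0 or nt == 0.0:
        raise ValueError("trajectory angle undefined for a zero-length vector")
    cosang = float(np.clip(gv @ tv / (ng * nt), -1.0, 1.0))
    return degrees(acos(cosang))


def epoch_average(
    measurements: pd.DataFrame,
    epoch: EpochDef,
    value: str,
    index_col: str = "training_index",
    subject_col: str = "subject",
) -> tuple[float, float, int]:
    """(mean, SEM, n) of a per-trial measure over an epoch window.

    Measurements whose ``index_col`` lies in [epoch.lo, epoch.hi] are
    averaged within subject first, then across subjects; SEM is the
    across-subject standard error (0 for a single subject).
    """
    sel = measurements[
        (measurements[index_col] >= epoch.lo) & (measurements[index_col] <= epoch.hi)
    ]
    if sel.empty:
        raise ValueError(f"no measurements fall in epoch {epoch.name} [{epoch.lo}, {epoch.hi}]")
    per_subject = sel.groupby(subject_col)[value].mean()
    n = len(per_subject)
    mean = float(per_subject.mean())
    sem = 0.0 if n < 2 else float(per_subject.std(ddof=1) / sqrt(n))
    return mean, sem, n


def normalize_series(series: np.ndarray) -> np.ndarray:
    """Normalize per-subject decay series by the cross-subject mean of the
    first decay trial (rows = subjects, columns = decay trials)."""
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[None, :]
    divisor = float(series[:, 0].mean())
    if divisor == 0.0:
        raise ZeroDivisionError("first-decay-trial cross-subject mean is zero")
    return series / divisor


@dataclass(frozen=True)
class CompareResult:
    t: float
    dof: float
    p: float
    p_corrected: float
    zero_variance: bool = False


def epoch_compare(
    group_a: np.ndarray,
    group_b: np.ndarray,
    paired: bool = False,
    n_comparisons: int = 1,
) -> CompareResult:
    """Two-tailed t-test between epoch values of two groups.

    Welch's test for independent groups, a paired test otherwise; with
    ``n_comparisons > 1`` a Bonferroni-corrected p-value is also reported.
    Degenerate zero-variance cases are flagged rather than returning an
    infinite statistic silently.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal group sizes")
        d = a - b
        if np.allclose(d, d[0]):
            if d[0] == 0.0:
                return CompareResult(0.0, float(a.size - 1), 1.0, 1.0)
            return CompareResult(
                float(np.inf) * np.sign(d[0]), float(a.size - 1), 0.0, 0.0, True
            )
        t, p = stats.ttest_rel(a, b)
        dof = float(a.size - 1)
    else:
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            if a[0] == b[0]:
                return CompareResult(0.0, float(a.size + b.size - 2), 1.0, 1.0)
            return CompareResult(
                float(np.inf) * np.sign(a[0] - b[0]),
                float(a.size + b.size - 2), 0.0, 0.0, True,
            )
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p = res.statistic, res.pvalue
        dof = float(res.df)
    p_corr = min(1.0, float(p) * max(1, int(n_comparisons)))
    return CompareResult(float(t), dof, float(p), p_corr)


# ---------------------------------------------------------------------------
# Trial-table pipeline


def _trial_windows(
    sub_trials: pd.DataFrame, window: AnalysisWindow, velocity_filter: tuple[float, float]
):
    """Windowed (pos, vel, f) arrays per admissible trial of one subject."""
    out = {}
    for trial_id, g in sub_trials.groupby("trial_id", sort=True):
        t = g["t"].to_numpy()
        vel = g["vel"].to_numpy()
        peak = float(np.max(np.abs(vel)))
        if not velocity_filter[0] <= peak <= velocity_filter[1]:
            continue
        center = float(t[int(np.argmax(np.abs(vel)))])
        out[int(trial_id)] = (
            window.extract(t, g["pos"].to_numpy(), center),
            window.extract(t, vel, center),
            window.extract(t, g["f_lat"].to_numpy(), center),
            peak,
        )
    return out


def analyze_trials(
    trials: pd.DataFrame,
    schedule: pd.DataFrame,
    ff_type: str,
    sign: int = 1,
    window: AnalysisWindow | None = None,
    include_acceleration: bool = False,
    velocity_filter: tuple[float, float] = VELOCITY_FILTER,
) -> pd.DataFrame:
    """Per-trial adaptation measures for one subject's EC trial table.

    Parameters
    ----------
    trials : DataFrame
        Tidy per-sample table with columns trial_id, t, pos, vel, f_lat
        (trained-direction error-clamp trials).
    schedule : DataFrame
        Schedule table (``Schedule.to_frame()``) mapping trial_id (session
        index) to block, training_index and decay_index.
    ff_type : str
        Trained field type; sets the ideal-force couplings.
    sign : int
        Counterbalanced field direction of this subject; forces are
        multiplied by it so compensation is positive.
    """
    window = window or AnalysisWindow()
    c_K, c_B = COUPLINGS[ff_type]
    sched = schedule.set_index("index")
    wins = _trial_windows(trials, window, velocity_filter)
    if not wins:
        return pd.DataFrame()

    baseline_ids = [
        tid for tid in wins if sched.loc[tid, "block"] == "baseline"
    ]
    if baseline_ids:
        baseline_profile = np.mean([wins[tid][2] for tid in baseline_ids], axis=0)
    else:
        baseline_profile = np.zeros_like(window.grid)

    rows = []
    for tid, (pos_w, vel_w, f_w, peak) in wins.items():
        f = sign * (f_w - baseline_profile)
        ideal = c_K * K_DEFAULT * pos_w + c_B * B_DEFAULT * vel_w
        coef = adaptation_coefficient(f, ideal)
        dec = gain_decomposition(
            f, pos_w, vel_w,
            include_acceleration=include_acceleration, dt=window.dt,
        )
        block = sched.loc[tid, "block"]
        phase = (
            "baseline" if block == "baseline"
            else "decay" if block == "decay"
            else "adaptation"
        )
        row = {
            "trial_id": tid,
            "block": block,
            "phase": phase,
            "training_index": int(sched.loc[tid, "training_index"]),
            "decay_index": int(sched.loc[tid, "decay_index"]),
            "peak_speed": peak,
            "coef": coef,
            "k": dec.k,
            "b": dec.b,
            "r2": dec.r2,
        }
        if include_acceleration:
            row["accel_coef"] = dec.accel_coef
            row["r2_with_accel"] = dec.r2_with_accel
        rows.append(row)
    return pd.DataFrame(rows).sort_values("trial_id").reset_index(drop=True)


def analyze_cohort(cohort, window: AnalysisWindow | None = None,
                   include_acceleration: bool = False) -> pd.DataFrame:
    """Run the per-trial analysis over a synthetic cohort.

    ``cohort`` is a :class:`primadapt.cohort.CohortData`; returns the tidy
    measurement table with a subject column.
    """
    frames = []
    for subject, sub_trials in cohort.trials.groupby("subject"):
        df = analyze_trials(
            sub_trials,
            cohort.schedules[subject].to_frame(),
            cohort.spec.ff_type,
            sign=cohort.signs[subject],
            window=window,
            include_acceleration=include_acceleration,
        )
        df.insert(0, "subject", subject)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def decay_gain_matrix(
    measurements: pd.DataFrame, value: str, n_trials: int = 60
) -> tuple[list, np.ndarray]:
    """Pivot decay-period measurements into a subjects x trials matrix."""
    dec = measurements[measurements["phase"] == "decay"]
    pivot = dec.pivot_table(index="subject", columns="decay_index", values=value)
    pivot = pivot.reindex(columns=range(1, n_trials + 1))
    return list(pivot.index), pivot.to_numpy()
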