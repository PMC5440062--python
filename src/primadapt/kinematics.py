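"""Reach kinematics and viscoelastic force-field laws.

The experimental unit is a 10 cm point-to-point reach along the body's
sagittal axis.  A robotic manipulandum perturbs the reach with a lateral
force that is a linear function of the along-axis position and velocity,

    f_lat(t) = sign * (c_K * K * pos(t) + c_B * B * vel(t)),

with stiffness K = 45 N/m and viscosity B = 15 N.s/m chosen so that pure
position- and pure velocity-dependent fields produce approximately equal
peak forces on a criterion reach (10 cm at 0.30 m/s peak speed: 4.5 N both).
Only the along-axis kinematics and the lateral force channel matter for the
analysis, so reaches are represented by scalar position/velocity traces and
forces by a scalar lateral trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "K_DEFAULT",
    "B_DEFAULT",
    "CLAMP_SPRING",
    "CLAMP_DAMPER",
    "COUPLINGS",
    "FIELD_TYPES",
    "FORCE_FIELD_TYPES",
    "ReachKinematics",
    "FieldSpec",
    "ForceProfile",
    "min_jerk_reach",
    "field_force",
    "ideal_compensatory_force",
]

#: Position stiffness of the force-field law, N/m.
K_DEFAULT = 45.0
#: Viscosity of the force-field law, N.s/m.
B_DEFAULT = 15.0

#: Error-clamp channel constants (metadata only; the servo itself is not
#: simulated -- clamp trials are modelled as perfectly straight reaches).
CLAMP_SPRING = 6000.0  # N/m
CLAMP_DAMPER = 150.0  # N.s/m

#: (c_K, c_B) couplings per field type.  ucFF weights both states equally,
#: pcFF is position-biased, vcFF velocity-biased.
COUPLINGS: dict[str, tuple[float, float]] = {
    "null": (0.0, 0.0),
    "error_clamp": (0.0, 0.0),
    "pFF": (1.0, 0.0),
    "vFF": (0.0, 1.0),
    "ucFF": (0.71, 0.71),
    "pcFF": (0.85, 0.53),
    "vcFF": (0.53, 0.85),
}

FIELD_TYPES = tuple(COUPLINGS)
#: Types that actually perturb the limb (i.e. excluding null / error clamp).
FORCE_FIELD_TYPES = ("pFF", "vFF", "ucFF", "pcFF", "vcFF")

_TOL = 1e-9


@dataclass
class ReachKinematics:
    """Along-axis kinematics of one reach on a uniform time grid.

    Attributes
    ----------
    t : ndarray
        Time in seconds, uniform and strictly increasing, starting at 0.
    pos : ndarray
        Position along the movement axis in metres, 0 at movement start.
    vel : ndarray
        Velocity along the movement axis in m/s.
    direction : int
        Reach direction in degrees, 90 (away) or 270 (trained, toward body).
    peak_speed : float
        Realized maximum speed, m/s.
    """

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    direction: int = 270
    peak_speed: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.vel = np.asarray(self.vel, dtype=float)
        if not (self.t.shape == self.pos.shape == self.vel.shape):
            raise ValueError("t, pos and vel must have identical shapes")
        if self.t.size < 2:
            raise ValueError("a reach needs at least two samples")
        steps = np.diff(self.t)
        if steps.min() <= 0 or np.ptp(steps) > _TOL:
            raise ValueError("time grid must be uniform and strictly increasing")
        if self.direction not in (90, 270):
            raise ValueError("direction must be 90 or 270 degrees")
        if not self.peak_speed:
            self.peak_speed = float(np.max(np.abs(self.vel)))

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def distance(self) -> float:
        return float(self.pos[-1] - self.pos[0])

    @property
    def peak_speed_time(self) -> float:
        """Time of peak speed; the analysis window is centered here."""
        return float(self.t[int(np.argmax(np.abs(self.vel)))])


@dataclass(frozen=True)
class FieldSpec:
    """A force-field law: type, couplings, direction sign and gains."""

    ff_type: str
    sign: int = 1
    K: float = K_DEFAULT
    B: float = B_DEFAULT

    def __post_init__(self) -> None:
        if self.ff_type not in COUPLINGS:
            raise ValueError(f"unknown field type {self.ff_type!r}")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 (clockwise) or -1 (counterclockwise)")
        if self.K <= 0 or self.B <= 0:
            raise ValueError("K and B must be positive")

    @property
    def c_K(self) -> float:
        return COUPLINGS[self.ff_type][0]

    @property
    def c_B(self) -> float:
        return COUPLINGS[self.ff_type][1]

    @property
    def is_force_field(self) -> bool:
        return self.ff_type in FORCE_FIELD_TYPES

    def to_dict(self) -> dict:
        return {
            "ff_type": self.ff_type,
            "sign": self.sign,
            "K": self.K,
            "B": self.B,
            "c_K": self.c_K,
            "c_B": self.c_B,
        }


@dataclass
class ForceProfile:
    """Lateral (perpendicular-to-target) force trace on a reach's grid."""

    t: np.ndarray
    f_lat: np.ndarray
    ideal_undefined: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f_lat = np.asarray(self.f_lat, dtype=float)
        if self.t.shape != self.f_lat.shape:
            raise ValueError("t and f_lat must have identical shapes")
        if not np.all(np.isfinite(self.f_lat)):
            raise ValueError("force profile contains non-finite values")


def min_jerk_reach(
    distance: float = 0.10,
    peak_speed: float = 0.30,
    dt: float = 0.001,
    direction: int = 270,
) -> ReachKinematics:
    """Generate a minimum-jerk reach of given amplitude and peak speed.

    The minimum-jerk position profile is ``x(tau) = D (10 tau^3 - 15 tau^4
    + 6 tau^5)`` with ``tau = t / T``; its peak speed is ``1.875 D / T``, so
    the duration is ``T = 1.875 D / peak_speed``.  The grid spans exactly
    [0, T] with an even number of steps as close to ``dt`` as possible, which
    places the peak-velocity sample exactly at ``tau = 1/2`` and makes every
    boundary condition hold to machine precision.

    Parameters
    ----------
    distance : float
        Movement amplitude in metres (default 0.10).
    peak_speed : float
        Target peak speed in m/s; the reward criterion band in the task is
        0.25--0.35 m/s.
    dt : float
        Nominal sampling step in seconds (default 0.001, i.e. 1 kHz).
    direction : int
        90 or 270 degrees.
    """
    if distance <= 0 or peak_speed <= 0 or dt <= 0:
        raise ValueError("distance, peak_speed and dt must be positive")
    T = 1.875 * distance / peak_speed
    n = 2 * max(1, round(T / (2.0 * dt)))
    tau = np.linspace(0.0, 1.0, n + 1)
    pos = distance * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    vel = (distance / T) * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    return ReachKinematics(
        t=tau * T, pos=pos, vel=vel, direction=direction, peak_speed=peak_speed
    )


def field_force(kin: ReachKinematics, spec: FieldSpec) -> ForceProfile:
    """Lateral force the robot applies to a reach under a field law.

    The sign convention fixes a clockwise (+1) field on a trained 270 degree
    reach to produce positive lateral force.  Null and error-clamp trials
    produce identically zero force.
    """
    f = spec.sign * (spec.c_K * spec.K * kin.pos + spec.c_B * spec.B * kin.vel)
    return ForceProfile(t=kin.t, f_lat=f)


def ideal_compensatory_force(kin: ReachKinematics, spec: FieldSpec) -> ForceProfile:
    """Force a fully adapted subject would press into the channel wall.

    Full compensation means the subject's lateral force exactly opposes the
    field that the trial's own kinematics would have produced, i.e.
    ``-field_force(kin, spec)``.  For null/error-clamp specs there is nothing
    to compensate; a zero profile is returned with ``ideal_undefined`` set.
    """
    if not spec.is_force_field:
        warnings.warn(
            "ideal compensatory force requested for a non-perturbing trial type",
            stacklevel=2,
        )
        return ForceProfile(t=kin.t, f_lat=np.zeros_like(kin.t), ideal_undefined=True)
    base = field_force(kin, spec)
    return ForceProfile(t=kin.t, f_lat=-base.f_lat)
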