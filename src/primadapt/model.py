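"""Symmetric and asymmetric viscoelastic motor-primitive model.

The feedforward lateral force a subject produces on trial n is a weighted
sum over N motor primitives with joint position/velocity tuning
``S_i = [K_i, B_i]`` drawn from a zero-mean bivariate normal with standard
deviations ``sigma_K, sigma_B`` and correlation ``rho``.  Because the
position/velocity trace is shared across primitives, the motor output
collapses to a 2-vector of dimensionless gains ``y = [k, b] = S^T W``
(k = 1 means full compensation of a pure position field, b = 1 of a pure
velocity field).

On each training trial the weights follow gradient descent on the gain-space
error to the adaptation goal ``y*``,

    dw_i = eta * S_i . (y* - y_n)
    y_{n+1} = diag(alpha_K, alpha_B) y_n + S^T dW
            = A y_n + eta (S^T S) (y* - y_n),

where ``alpha_K, alpha_B`` are per-trial retention factors.  The symmetric
model ties ``alpha_K = alpha_B`` and ``sigma_K = sigma_B``; the asymmetric
model lets retention differ between the position and velocity channels.
During error-clamp decay there is no error signal and the state simply
retains: ``y_{n+1} = A y_n``.

Replacing the sampled ``S^T S`` by its expectation ``N Sigma`` gives the
deterministic mean-field dynamics, a 2x2 linear recursion whose adaptation
asymptote is the closed form ``(I - A + eta N Sigma)^{-1} eta N Sigma y*``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GOALS",
    "ModelParams",
    "PrimitiveEnsemble",
    "GainState",
    "GainTrajectory",
    "goal_for",
    "sample_primitives",
    "adaptation_step",
    "decay_step",
    "simulate_experiment",
    "normalized_decay",
    "fixed_point",
]

#: Adaptation goal in (position-gain, velocity-gain) space per field type.
GOALS: dict[str, tuple[float, float]] = {
    "pFF": (1.0, 0.0),
    "vFF": (0.0, 1.0),
    "ucFF": (0.71, 0.71),
    "pcFF": (0.85, 0.53),
    "vcFF": (0.53, 0.85),
}


@dataclass(frozen=True)
class GainState:
    """Point in position/velocity gain space."""

    k: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.k, self.b], dtype=float)

    @staticmethod
    def from_array(y: np.ndarray) -> "GainState":
        return GainState(k=float(y[0]), b=float(y[1]))


def goal_for(ff_type: str) -> GainState:
    if ff_type not in GOALS:
        raise ValueError(f"no adaptation goal defined for {ff_type!r}")
    return GainState(*GOALS[ff_type])


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the viscoelastic primitive model.

    alpha_K, alpha_B : per-trial retention of the position / velocity gain,
        in (0, 1].
    sigma_K, sigma_B : primitive tuning standard deviations (dimensionless).
    rho : primitive K-B tuning correlation, in (-1, 1).
    eta : learning rate of the gradient-descent weight update.
    N : number of primitives.  Only the product eta * N * Sigma enters the
        mean-field dynamics, so eta and N are stored separately purely to
        keep the printed parameter conventions.
    symmetric : if True, alpha_K = alpha_B and sigma_K = sigma_B must hold.
    """

    alpha_K: float
    alpha_B: float
    sigma_K: float
    sigma_B: float
    rho: float
    eta: float = 1.5e-4
    N: int = 2000
    symmetric: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha_K", "alpha_B"):
            a = getattr(self, name)
            if not 0.0 < a <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {a}")
        for name in ("sigma_K", "sigma_B"):
            s = getattr(self, name)
            if s <= 0:
                raise ValueError(f"{name} must be positive, got {s}")
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (-1, 1), got {self.rho}")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.N <= 0:
            raise ValueError("N must be a positive integer")
        if self.symmetric and (
            self.alpha_K != self.alpha_B or self.sigma_K != self.sigma_B
        ):
            raise ValueError("symmetric model requires alpha_K=alpha_B, sigma_K=sigma_B")

    @property
    def Sigma(self) -> np.ndarray:
        """Primitive tuning covariance (positive definite by construction)."""
        off = self.rho * self.sigma_K * self.sigma_B
        return np.array([[self.sigma_K**2, off], [off, self.sigma_B**2]])

    @property
    def A(self) -> np.ndarray:
        return np.diag([self.alpha_K, self.alpha_B])

    def learning_operator(self, gram: np.ndarray | None = None) -> np.ndarray:
        """Effective per-trial learning matrix eta * S^T S (mean field:
        eta * N * Sigma)."""
        if gram is None:
            gram = self.N * self.Sigma
        return self.eta * gram

    def to_dict(self) -> dict:
        return {
            "alpha_K": self.alpha_K,
            "alpha_B": self.alpha_B,
            "sigma_K": self.sigma_K,
            "sigma_B": self.sigma_B,
            "rho": self.rho,
            "eta": self.eta,
            "N": self.N,
            "symmetric": self.symmetric,
        }

    @staticmethod
    def from_dict(d: dict) -> "ModelParams":
        return ModelParams(**d)


# Parameter sets estimated from the behavioral cohorts (joint fits unless
# noted).  Retentions are biased toward velocity (alpha_B >= alpha_K) in
# every asymmetric set.
VFF_PFF_SYMMETRIC = ModelParams(0.951, 0.951, 0.401, 0.401, rho=0.51, symmetric=True)
VFF_PFF_ASYMMETRIC = ModelParams(0.942, 0.951, 0.464, 0.379, rho=0.47)
UCFF_PCFF_ASYMMETRIC = ModelParams(0.914, 0.958, 0.546, 0.565, rho=0.48)
#: Asymmetric fits to the single-condition data (tuning SDs tied).
PFF_ONLY_ASYMMETRIC = ModelParams(0.951, 0.971, 0.40, 0.40, rho=0.45)
VFF_ONLY_ASYMMETRIC = ModelParams(0.885, 0.936, 0.40, 0.40, rho=0.52)
#: Set used for the velocity-biased combination field simulation.
VCFF_SIMULATION = ModelParams(0.9532, 0.9602, 0.3758, 0.3280, rho=0.50)

NAMED_PARAMS = {
    "vff_pff_symmetric": VFF_PFF_SYMMETRIC,
    "vff_pff_asymmetric": VFF_PFF_ASYMMETRIC,
    "ucff_pcff_asymmetric": UCFF_PCFF_ASYMMETRIC,
    "pff_only_asymmetric": PFF_ONLY_ASYMMETRIC,
    "vff_only_asymmetric": VFF_ONLY_ASYMMETRIC,
    "vcff_simulation": VCFF_SIMULATION,
}


@dataclass
class PrimitiveEnsemble:
    """Sampled primitive tuning gains and their adaptive weights."""

    K: np.ndarray
    B: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if not (self.K.shape == self.B.shape == self.w.shape):
            raise ValueError("K, B and w must share a shape")

    @property
    def S(self) -> np.ndarray:
        """N x 2 tuning matrix with rows S_i = [K_i, B_i]."""
        return np.column_stack([self.K, self.B])

    @property
    def gram(self) -> np.ndarray:
        """S^T S, the 2x2 sampled analogue of N * Sigma."""
        S = self.S
        return S.T @ S

    def output(self) -> GainState:
        """Current gain-space motor output y = S^T w."""
        return GainState(k=float(self.K @ self.w), b=float(self.B @ self.w))


def sample_primitives(params: ModelParams, seed: int | np.random.Generator) -> PrimitiveEnsemble:
    """Draw N primitives iid from N(0, Sigma); weights start at zero."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multivariate_normal(np.zeros(2), params.Sigma, size=params.N)
    return PrimitiveEnsemble(K=draws[:, 0], B=draws[:, 1], w=np.zeros(params.N))


def adaptation_step(
    ensemble: PrimitiveEnsemble | None,
    y: GainState,
    goal: GainState,
    params: ModelParams,
) -> GainState:
    """One force-field training trial.

    With an ensemble, the per-primitive weight change ``dw_i = eta S_i .
    (y* - y)`` is applied in place and the new state is ``A y + S^T dW``.
    With ``ensemble=None`` the mean-field operator ``eta N Sigma`` is used.
    """
    err = goal.as_array() - y.as_array()
    if ensemble is None:
        y_new = params.A @ y.as_array() + params.learning_operator() @ err
    else:
        dw = params.eta * (ensemble.S @ err)
        ensemble.w += dw
        y_new = params.A @ y.as_array() + ensemble.S.T @ dw
    return GainState.from_array(y_new)


def decay_step(y: GainState, params: ModelParams) -> GainState:
    """One error-clamp decay trial: retention only, no weight update."""
    return GainState.from_array(params.A @ y.as_array())


@dataclass
class GainTrajectory:
    """Per-trial gain states over adaptation and decay phases."""

    trial: np.ndarray  # 1-based within phase (training index / decay index)
    phase: np.ndarray  # "adaptation" | "decay"
    k: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.trial = np.asarray(self.trial, dtype=int)
        self.phase = np.asarray(self.phase, dtype=object)
        self.k = np.asarray(self.k, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = len(self.trial)
        if not (len(self.phase) == len(self.k) == len(self.b) == n):
            raise ValueError("trajectory arrays must be aligned")

    def _mask(self, phase: str) -> np.ndarray:
        return self.phase == phase

    def select(self, phase: str) -> "GainTrajectory":
        m = self._mask(phase)
        return GainTrajectory(self.trial[m], self.phase[m], self.k[m], self.b[m])

    @property
    def adaptation(self) -> "GainTrajectory":
        return self.select("adaptation")

    @property
    def decay(self) -> "GainTrajectory":
        return self.select("decay")

    def states(self) -> np.ndarray:
        """n x 2 array of (k, b) rows."""
        return np.column_stack([self.k, self.b])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial": self.trial, "phase": self.phase, "k": self.k, "b": self.b}
        )


def simulate_experiment(
    params: ModelParams,
    ff_type: str,
    n_adapt: int = 160,
    n_decay: int = 60,
    mode: str = "mean_field",
    seed: int | None = None,
) -> GainTrajectory:
    """Simulate adaptation followed by error-clamp decay from y0 = (0, 0).

    Parameters
    ----------
    mode : {"mean_field", "ensemble"}
        ``mean_field`` runs the deterministic 2x2 recursion; ``ensemble``
        samples N primitives (requires ``seed``) and uses the sampled
        ``S^T S``.
    """
    goal = goal_for(ff_type)
    if mode == "ensemble":
        if seed is None:
            raise ValueError("ensemble mode requires a seed")
        ensemble: PrimitiveEnsemble | None = sample_primitives(params, seed)
    elif mode == "mean_field":
        ensemble = None
    else:
        raise ValueError(f"unknown mode {mode!r}")

    trial, phase, ks, bs = [], [], [], []
    y = GainState(0.0, 0.0)
    for n in range(1, n_adapt + 1):
        y = adaptation_step(ensemble, y, goal, params)
        trial.append(n)
        phase.append("adaptation")
        ks.append(y.k)
        bs.append(y.b)
    for n in range(1, n_decay + 1):
        y = decay_step(y, params)
        trial.append(n)
        phase.append("decay")
        ks.append(y.k)
        bs.append(y.b)
    return GainTrajectory(np.array(trial), np.array(phase, dtype=object),
                          np.array(ks), np.array(bs))


def normalized_decay(traj: GainTrajectory) -> GainTrajectory:
    """Rescale the decay phase by its own first point, which becomes (1, 1).

    Isolates relative decay rates from the final adaptation level: with
    tied retentions the normalized path lies on the unity line, and with
    alpha_B > alpha_K it bows toward the velocity axis.
    """
    dec = traj.decay
    if len(dec.trial) == 0:
        raise ValueError("trajectory has no decay phase")
    k0, b0 = dec.k[0], dec.b[0]
    if k0 == 0.0 or b0 == 0.0:
        raise ZeroDivisionError("decay normalization undefined: zero initial gain")
    return GainTrajectory(dec.trial, dec.phase, dec.k / k0, dec.b / b0)


def fixed_point(params: ModelParams, ff_type: str) -> GainState:
    """Closed-form mean-field adaptation asymptote
    ``y_inf = (I - A + eta N Sigma)^{-1} eta N Sigma y*``."""
    H = params.learning_operator()
    y_star = goal_for(ff_type).as_array()
    y_inf = np.linalg.solve(np.eye(2) - params.A + H, H @ y_star)
    return GainState.from_array(y_inf)
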