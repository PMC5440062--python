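"""Exponential fits with subject bootstrap, and primitive-model estimation.

Exponential time constants of learning and decay come from a standard
rate-and-offset exponential, ``y(n) = a exp(-n/tau) + c`` for decaying
series and ``y(n) = c - a exp(-n/tau)`` for rising ones, fit by nonlinear
least squares with a multi-start over tau.  Parameter spreads are obtained
by resampling subjects with replacement (500 replicates by default),
averaging the resampled series pointwise, refitting, and taking the SD of
each parameter across replicates.

Primitive-model parameters are estimated by matching the deterministic
mean-field gain-space trajectories to observed (k, b) trajectories,
minimizing the summed squared error pooled over all supplied force-field
conditions (adaptation and decay weighted equally).  The learning rate eta
(and the primitive count N) are fixed because only the product
eta * N * Sigma is identifiable from gain trajectories.  The symmetric
variant ties alpha_K = alpha_B and sigma_K = sigma_B; the asymmetric
variant leaves the retentions free in either direction.  Optimization is
derivative-free simplex from Latin-hypercube multi-starts with a fixed
seed, followed by a polish from the best start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .model import GOALS, GainTrajectory, ModelParams

__all__ = [
    "ExpFit",
    "BootstrapSummary",
    "FitResult",
    "fit_exponential",
    "bootstrap_exponential",
    "fit_primitive_model",
]

TAU_STARTS = (2.0, 5.0, 10.0, 20.0, 40.0)
TAU_BOUNDS = (0.1, 500.0)


@dataclass(frozen=True)
class ExpFit:
    """Exponential fit result: y = a*exp(-n/tau) + c (fall) or
    c - a*exp(-n/tau) (rise)."""

    a: float
    tau: float
    c: float
    sse: float
    converged: bool
    degenerate: bool = False
    direction: str = "fall"

    def predict(self, n: np.ndarray) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        if self.degenerate:
            return np.full_like(n, self.c)
        e = self.a * np.exp(-n / self.tau)
        return e + self.c if self.direction == "fall" else self.c - e


def _exp_residuals(theta: np.ndarray, n: np.ndarray, y: np.ndarray, sgn: float) -> np.ndarray:
    a, tau, c = theta
    return c + sgn * a * np.exp(-n / tau) - y


def fit_exponential(
    values: np.ndarray,
    trials: np.ndarray | None = None,
    direction: str = "fall",
) -> ExpFit:
    """Fit the rate-and-offset exponential to a per-trial series.

    Parameters
    ----------
    values : array
        Series values (NaNs are dropped together with their trial indices).
    trials : array, optional
        1-based trial indices; defaults to 1..len(values).
    direction : {"fall", "rise"}
        Decaying or saturating form.
    """
    if direction not in ("fall", "rise"):
        raise ValueError("direction must be 'fall' or 'rise'")
    y = np.asarray(values, dtype=float)
    n = np.arange(1, y.size + 1, dtype=float) if trials is None else np.asarray(trials, dtype=float)
    keep = np.isfinite(y)
    y, n = y[keep], n[keep]
    if y.size < 4:
        raise ValueError("need at least 4 points for an exponential fit")

    if np.ptp(y) < 1e-12 * max(1.0, float(np.abs(y).max())):
        return ExpFit(a=0.0, tau=float("nan"), c=float(y.mean()), sse=0.0,
                      converged=True, degenerate=True, direction=direction)

    sgn = 1.0 if direction == "fall" else -1.0
    best = None
    for tau0 in TAU_STARTS:
        # linear-in-(a, c) warm start at fixed tau
        e = np.exp(-n / tau0)
        X = np.column_stack([sgn * e, np.ones_like(n)])
        (a0, c0), *_ = np.linalg.lstsq(X, y, rcond=None)
        try:
            res = optimize.least_squares(
                _exp_residuals,
                x0=[a0, tau0, c0],
                args=(n, y, sgn),
                bounds=([-np.inf, TAU_BOUNDS[0], -np.inf], [np.inf, TAU_BOUNDS[1], np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        return ExpFit(a=float("nan"), tau=float("nan"), c=float("nan"),
                      sse=float("inf"), converged=False, direction=direction)
    sse, res = best
    a, tau, c = (float(v) for v in res.x)
    return ExpFit(a=a, tau=tau, c=c, sse=sse, converged=bool(res.success),
                  direction=direction)


@dataclass(frozen=True)
class BootstrapSummary:
    """Subject-resampling bootstrap of exponential fit parameters."""

    n_boot: int
    n_failed: int
    seed: int
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "mean": dict(self.mean),
            "sd": dict(self.sd),
        }


def bootstrap_exponential(
    series: np.ndarray,
    n_boot: int = 500,
    seed: int = 0,
    direction: str = "fall",
    trials: np.ndarray | None = None,
) -> BootstrapSummary:
    """Bootstrap exponential fit parameters by resampling subjects.

    ``series`` is a subjects x trials matrix.  Each replicate draws
    n_subjects rows with replacement, averages them pointwise (NaNs
    ignored), and refits; replicates whose fit fails or degenerates are
    excluded and counted.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_subj = series.shape[0]
    if n_subj < 2:
        raise ValueError("bootstrap needs at least two subjects")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    params = {"a": [], "tau": [], "c": []}
    n_failed = 0
    for _ in range(n_boot):
        pick = rng.integers(0, n_subj, size=n_subj)
        with np.errstate(invalid="ignore"):
            avg = np.nanmean(series[pick], axis=0)
        try:
            fit = fit_exponential(avg, trials=trials, direction=direction)
        except ValueError:
            n_failed += 1
            continue
        if not fit.converged or fit.degenerate:
            n_failed += 1
            continue
        params["a"].append(fit.a)
        params["tau"].append(fit.tau)
        params["c"].append(fit.c)
    mean = {p: float(np.mean(v)) if v else float("nan") for p, v in params.items()}
    sd = {p: float(np.std(v, ddof=0)) if v else float("nan") for p, v in params.items()}
    return BootstrapSummary(n_boot=n_boot, n_failed=n_failed, seed=seed, mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# Primitive-model parameter estimation


@dataclass(frozen=True)
class FitResult:
    """Primitive-model fit: estimated parameters and diagnostics."""

    params: ModelParams
    sse: float
    conditions: tuple
    variant: str
    n_starts: int
    converged: bool
    seed: int


def _mean_field_states(
    alpha: np.ndarray, H: np.ndarray, y_star: np.ndarray, n_adapt: int, n_decay: int
) -> np.ndarray:
    """Fast mean-field recursion; returns (n_adapt + n_decay) x 2 states.

    Rows 0..n_adapt-1 are the states after training trials 1..n_adapt,
    followed by the states after decay trials 1..n_decay.
    """
    out = np.empty((n_adapt + n_decay, 2))
    y = np.zeros(2)
    drive = H @ y_star
    M = np.diag(alpha) - H
    for i in range(n_adapt):
        y = M @ y + drive
        out[i] = y
    for i in range(n_decay):
        y = alpha * y
        out[n_adapt + i] = y
    return out


_BOUNDS = {
    "alpha": (0.5, 1.0),
    "sigma": (0.02, 3.0),
    "rho": (-0.95, 0.95),
}
_START_RANGES = {
    "alpha": (0.85, 0.995),
    "sigma": (0.2, 0.8),
    "rho": (0.1, 0.9),
}


def _unpack(theta: np.ndarray, variant: str) -> tuple[np.ndarray, np.ndarray, float]:
    if variant == "symmetric":
        a, s, rho = theta
        return np.array([a, a]), np.array([s, s]), float(rho)
    aK, aB, sK, sB, rho = theta
    return np.array([aK, aB]), np.array([sK, sB]), float(rho)


def _penalty(alpha: np.ndarray, sigma: np.ndarray, rho: float) -> float:
    pen = 0.0
    for a in alpha:
        pen += max(0.0, _BOUNDS["alpha"][0] - a) + max(0.0, a - _BOUNDS["alpha"][1])
    for s in sigma:
        pen += max(0.0, _BOUNDS["sigma"][0] - s) + max(0.0, s - _BOUNDS["sigma"][1])
    pen += max(0.0, _BOUNDS["rho"][0] - rho) + max(0.0, rho - _BOUNDS["rho"][1])
    return pen


def fit_primitive_model(
    observed: dict[str, GainTrajectory],
    variant: str = "asymmetric",
    seed: int = 0,
    eta: float = 1.5e-4,
    N: int = 2000,
    n_starts: int = 8,
) -> FitResult:
    """Fit the primitive model to observed gain trajectories.

    Parameters
    ----------
    observed : dict
        Map from field type (pFF/vFF/ucFF/pcFF/vcFF) to the observed
        GainTrajectory (adaptation and decay phases, mean across subjects).
    variant : {"symmetric", "asymmetric"}
        Whether retentions and tuning SDs are tied.
    eta, N : float, int
        Fixed learning rate and primitive count (jointly unidentifiable
        with Sigma; conventionally eta = 1.5e-4).
    """
    if variant not in ("symmetric", "asymmetric"):
        raise ValueError("variant must be 'symmetric' or 'asymmetric'")
    if not observed:
        raise ValueError("at least one condition is required")
    for ff in observed:
        if ff not in GOALS:
            raise ValueError(f"no adaptation goal for condition {ff!r}")

    # Observed gains may sit at sparse trial indices (EC probes); the model
    # trajectory is simulated densely and sampled at those indices.
    targets = {}
    for ff, traj in observed.items():
        adapt, decay = traj.adaptation, traj.decay
        if np.any(adapt.trial < 1) or np.any(decay.trial < 1):
            raise ValueError("trial indices must be 1-based")
        n_adapt = int(adapt.trial.max()) if len(adapt.trial) else 0
        n_decay = int(decay.trial.max()) if len(decay.trial) else 0
        rows = np.concatenate([adapt.trial - 1, n_adapt + decay.trial - 1]).astype(int)
        targets[ff] = (
            np.asarray(GOALS[ff], dtype=float),
            n_adapt,
            n_decay,
            rows,
            np.concatenate([adapt.states(), decay.states()], axis=0),
        )

    scale = eta * N

    def objective(theta: np.ndarray) -> float:
        alpha, sigma, rho = _unpack(theta, variant)
        pen = _penalty(alpha, sigma, rho)
        if pen > 0.0:
            return 1e6 * (1.0 + pen) ** 2
        off = rho * sigma[0] * sigma[1]
        H = scale * np.array([[sigma[0] ** 2, off], [off, sigma[1] ** 2]])
        sse = 0.0
        for y_star, n_adapt, n_decay, rows, obs in targets.values():
            pred = _mean_field_states(alpha, H, y_star, n_adapt, n_decay)[rows]
            d = pred - obs
            sse += float(np.sum(d * d))
        return sse

    dim = 3 if variant == "symmetric" else 5
    sampler = qmc.LatinHypercube(d=dim, seed=seed)
    unit = sampler.random(n=n_starts)
    lows, highs = [], []
    keys = (
        ["alpha", "sigma", "rho"]
        if variant == "symmetric"
        else ["alpha", "alpha", "sigma", "sigma", "rho"]
    )
    for key in keys:
        lo, hi = _START_RANGES[key]
        lows.append(lo)
        highs.append(hi)
    starts = qmc.scale(unit, lows, highs)

    best = None
    nm_opts = dict(xatol=1e-10, fatol=1e-14, maxiter=8000, maxfev=12000, adaptive=True)
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="Nelder-Mead", options=nm_opts)
        if best is None or res.fun < best.fun:
            best = res
    # polish: restart the simplex at the best point
    polished = optimize.minimize(objective, best.x, method="Nelder-Mead", options=nm_opts)
    if polished.fun < best.fun:
        best = polished

    alpha, sigma, rho = _unpack(best.x, variant)
    params = ModelParams(
        alpha_K=float(alpha[0]), alpha_B=float(alpha[1]),
        sigma_K=float(sigma[0]), sigma_B=float(sigma[1]),
        rho=rho, eta=eta, N=N, symmetric=(variant == "symmetric"),
    )
    return FitResult(
        params=params,
        sse=float(best.fun),
        conditions=tuple(observed),
        variant=variant,
        n_starts=n_starts,
        converged=bool(best.success),
        seed=seed,
    )
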