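"""Maximum-likelihood estimation and the chi-square goodness-of-fit test.

The measurement model is Gaussian with known diagonal covariance: experiment
``i`` has ``N_y`` points with common standard deviation ``sigma_i`` (recorded
in the dataset), so the log-likelihood is

    Phi = -1/2 sum_i [ N_y ln(2 pi) + N_y ln(sigma_i^2)
                       + ||y_i - yhat_i(theta)||^2 / sigma_i^2 ]

and maximizing Phi is equivalent to minimizing the normalized squared
residuals chi^2 = sum_i ||y_i - yhat_i||^2 / sigma_i^2, which under a correct
model follows a chi-square law with DoF = N*N_y - N_theta. The single-tailed
95% test flags underfitting when chi^2 exceeds the critical quantile.

Estimation uses a multistart strategy: starting points are drawn from a
scrambled Sobol sequence over the (optionally log10-scaled) parameter bounds
box; each gets a short bound-constrained trust-region least-squares search
(finite-difference Jacobians), the most promising starts are polished to
convergence, and the best converged point wins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import qmc

from .column_model import (
    ModelValidityError,
    SimulationError,
    simulate_chromatogram,
)
from .insilico_experiments import Dataset
from .isotherm_models import IsothermSpec

__all__ = [
    "Bounds",
    "LikelihoodSpec",
    "FitResult",
    "StartRecord",
    "default_bounds",
    "log_likelihood",
    "multistart_mle",
    "chi2_statistic",
    "chi2_test",
]

_FAIL_OBJECTIVE = 1e12  # finite penalty used when the simulator fails


@dataclass(frozen=True)
class Bounds:
    """Box bounds per parameter with optional log10 sampling/search scale."""

    lower: Mapping[str, float]
    upper: Mapping[str, float]
    log_scale: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.lower:
            lo, hi = self.lower[name], self.upper[name]
            if not lo < hi:
                raise ValueError(f"bounds for {name!r} need lower < upper")
            if self.log_scale.get(name, False) and lo <= 0:
                raise ValueError(f"log-scaled parameter {name!r} needs lower > 0")

    def names(self, spec: IsothermSpec) -> tuple[str, ...]:
        missing = [n for n in spec.parameter_names if n not in self.lower]
        if missing:
            raise KeyError(f"bounds missing parameters {missing}")
        return spec.parameter_names

    def is_log(self, name: str) -> bool:
        return bool(self.log_scale.get(name, False))


#: Default box per parameter name: roughly one decade either side of
#: literature-plausible magnitudes; positive physical parameters are searched
#: on a log10 scale, sign-free ones linearly.
_DEFAULT_BOUNDS: dict[str, tuple[float, float, bool]] = {
    "K": (10.0, 1000.0, True),
    "q_sat": (5.0, 500.0, True),
    "S_a": (1.0, 30.0, True),
    "S_b": (0.5, 30.0, True),
    "S_c": (-30.0, 30.0, False),
    "b": (1e-3, 10.0, True),
    "b_prime": (1e-4, 1.0, True),
    "a_1": (0.1, 50.0, True),
    "a_2": (-20.0, 20.0, False),
    "a_3": (-5.0, 5.0, False),
    "a_4": (-2.0, 2.0, False),
    "a_5": (-1.0, 1.0, False),
    "H": (1e-3, 100.0, True),
}


def default_bounds(spec: IsothermSpec,
                   overrides: Optional[Mapping[str, tuple]] = None) -> Bounds:
    """Default estimation bounds for every parameter of ``spec``."""
    lower, upper, log = {}, {}, {}
    table = dict(_DEFAULT_BOUNDS)
    if overrides:
        table.update({k: tuple(v) for k, v in overrides.items()})
    for name in spec.parameter_names:
        if name not in table:
            raise KeyError(f"no default bounds known for parameter {name!r}")
        lo, hi, is_log = table[name]
        lower[name], upper[name], log[name] = lo, hi, is_log
    return Bounds(lower, upper, log)


class _Predictor:
    """Simulates every dataset experiment at a parameter vector, with a cache."""

    def __init__(self, dataset: Dataset, spec: IsothermSpec):
        self.dataset = dataset
        self.spec = spec
        self._cache: dict[tuple, list[np.ndarray]] = {}
        self.n_sim_calls = 0

    def __call__(self, theta: Mapping[str, float]) -> list[np.ndarray]:
        key = tuple(float(theta[n]) for n in self.spec.parameter_names)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        preds = []
        for exp in self.dataset.experiments:
            ch = simulate_chromatogram(
                self.dataset.column, exp.design.operating_conditions(),
                self.spec, dict(zip(self.spec.parameter_names, key)),
                self.dataset.grid)
            preds.append(ch.outlet_concentration)
            self.n_sim_calls += 1
        if len(self._cache) > 4096:  # keep memory bounded on long fits
            self._cache.clear()
        self._cache[key] = preds
        return preds


@dataclass
class LikelihoodSpec:
    """Dataset + model: everything Phi(theta) needs."""

    dataset: Dataset
    isotherm: IsothermSpec

    def __post_init__(self) -> None:
        if np.any(self.dataset.sigmas <= 0):
            raise ValueError("all measurement sigmas must be positive")
        self._predictor = _Predictor(self.dataset, self.isotherm)

    @property
    def n_experiments(self) -> int:
        return self.dataset.n_experiments

    @property
    def n_points(self) -> int:
        return self.dataset.n_points

    @property
    def predictor(self) -> _Predictor:
        return self._predictor

    def constant_term(self) -> float:
        """Residual-independent part of Phi."""
        n_y = self.n_points
        return -0.5 * float(np.sum(
            n_y * math.log(2.0 * math.pi) + n_y * np.log(self.dataset.sigmas**2)
        ))

    def residuals(self, theta: Mapping[str, float]) -> list[np.ndarray]:
        preds = self._predictor(theta)
        return [exp.values - p for exp, p in zip(self.dataset.experiments, preds)]


def log_likelihood(spec: LikelihoodSpec, theta: Mapping[str, float]) -> float:
    """Gaussian log-likelihood Phi(Y|theta); -inf if the simulator fails."""
    try:
        res = spec.residuals(theta)
    except (SimulationError, ModelValidityError):
        return -math.inf
    quad = sum(float(r @ r) / s**2
               for r, s in zip(res, spec.dataset.sigmas))
    return spec.constant_term() - 0.5 * quad


def chi2_statistic(spec: LikelihoodSpec, theta: Mapping[str, float]) -> float:
    """Normalized squared residuals sum_i ||r_i||^2 / sigma_i^2."""
    res = spec.residuals(theta)
    return float(sum(float(r @ r) / s**2
                     for r, s in zip(res, spec.dataset.sigmas)))


def chi2_test(chi2: float, N: int, N_y: int, N_theta: int,
              alpha: float = 0.05) -> tuple[bool, float]:
    """Single-tailed underfitting test.

    Returns ``(passed, critical_value)`` with DoF = N*N_y - N_theta; the
    model fails only on strict exceedance of the (1-alpha) quantile.
    """
    dof = N * N_y - N_theta
    if dof < 1:
        raise ValueError(f"non-positive degrees of freedom: {dof}")
    crit = float(chi2_dist.ppf(1.0 - alpha, dof))
    return bool(chi2 <= crit), crit


@dataclass(frozen=True)
class StartRecord:
    """One multistart local search: where it started and where it converged."""

    start: dict[str, float]
    converged: dict[str, float]
    log_likelihood: float
    success: bool
    message: str = ""


@dataclass(frozen=True)
class FitResult:
    """Best multistart MLE with its goodness-of-fit verdict."""

    isotherm: IsothermSpec
    parameters: dict[str, float]
    log_likelihood: float
    chi2: float
    dof: int
    critical_value: float
    passed: bool
    starts: tuple[StartRecord, ...]
    n_sim_calls: int = 0

    def to_dict(self) -> dict:
        return {
            "isotherm": self.isotherm.to_dict(),
            "parameters": self.parameters,
            "log_likelihood": self.log_likelihood,
            "chi2": self.chi2,
            "dof": self.dof,
            "critical_value": self.critical_value,
            "passed": bool(self.passed),
            "starts": [
                {"start": s.start, "converged": s.converged,
                 "log_likelihood": s.log_likelihood, "success": bool(s.success)}
                for s in self.starts
            ],
        }


class EstimationError(RuntimeError):
    """Every multistart local search failed."""


def _transforms(names: Sequence[str], bounds: Bounds):
    lo = np.array([bounds.lower[n] for n in names])
    hi = np.array([bounds.upper[n] for n in names])
    is_log = np.array([bounds.is_log(n) for n in names])
    zlo = np.where(is_log, np.log10(np.where(is_log, lo, 1.0)), lo)
    zhi = np.where(is_log, np.log10(np.where(is_log, hi, 1.0)), hi)

    def to_unit(x: np.ndarray) -> np.ndarray:
        z = np.where(is_log, np.log10(np.where(is_log, np.maximum(x, 1e-300), 1.0)), x)
        return (z - zlo) / (zhi - zlo)

    def from_unit(u: np.ndarray) -> np.ndarray:
        z = zlo + np.clip(u, 0.0, 1.0) * (zhi - zlo)
        return np.where(is_log, 10.0**z, z)

    return to_unit, from_unit


def multistart_mle(spec: LikelihoodSpec, bounds: Bounds, n_starts: int = 10,
                   seed: Optional[int] = None,
                   extra_starts: Sequence[Mapping[str, float]] = (),
                   gtol: float = 1e-5, max_nfev: int = 200,
                   screen_nfev: int = 10,
                   include_center: bool = True) -> FitResult:
    """Sobol-multistart maximum-likelihood fit of ``spec.isotherm``.

    Draws ``n_starts`` scrambled-Sobol points in the bounds box (log10 scale
    where flagged), prepends any ``extra_starts`` (e.g. warm starts from a
    previous fit), and runs a bound-constrained trust-region least-squares
    refinement of the standardized residuals (equivalent to maximizing the
    log-likelihood, since the noise covariance is fixed) from each.

    Sobol starts are triaged: every one gets a short local search
    (``screen_nfev`` trust-region iterations), and the most promising
    third -- together with all ``extra_starts``, which are assumed
    deliberate -- is continued to convergence (``max_nfev``). With
    ``include_center`` (default) the centre of the scaled bounds box is
    added as one more deliberate start, making the search robust even at
    small Sobol budgets. Returns the best converged point with the full
    per-start trace and the chi-square verdict.
    """
    if n_starts < 1 and not extra_starts:
        raise ValueError("need at least one start")
    names = bounds.names(spec.isotherm)
    to_unit, from_unit = _transforms(names, bounds)

    starts_u: list[tuple[np.ndarray, bool]] = []
    for s in extra_starts:
        u = np.clip(to_unit(np.array([float(s[n]) for n in names])), 0.0, 1.0)
        starts_u.append((u, True))
        # a warm start pinned to a bound often traps the trust region in the
        # bound corner; offer a variant with the pinned coordinates recentred
        pinned = (u < 1e-3) | (u > 1.0 - 1e-3)
        if np.any(pinned):
            starts_u.append((np.where(pinned, 0.5, u), True))
    if include_center:
        starts_u.append((np.full(len(names), 0.5), True))
    if n_starts >= 1:
        sampler = qmc.Sobol(d=len(names), scramble=True,
                            rng=np.random.default_rng(seed))
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*balance properties.*")
            starts_u.extend((u, False)
                            for u in np.atleast_2d(sampler.random(n_starts)))

    sig = spec.dataset.sigmas

    def residual_vector(u: np.ndarray) -> np.ndarray:
        """Standardized residuals; maximizing Phi = minimizing their SSQ."""
        theta = dict(zip(names, from_unit(u)))
        try:
            res = spec.residuals(theta)
        except (SimulationError, ModelValidityError):
            total = spec.n_experiments * spec.n_points
            return np.full(total, math.sqrt(_FAIL_OBJECTIVE / total))
        return np.concatenate([r / s for r, s in zip(res, sig)])

    def local_search(u0: np.ndarray, budget: int):
        res = optimize.least_squares(
            residual_vector, np.clip(u0, 1e-9, 1 - 1e-9),
            bounds=(0.0, 1.0), method="trf", diff_step=1e-4,
            xtol=1e-9, ftol=1e-9, gtol=gtol, max_nfev=budget,
        )
        phi = const - float(res.cost)
        # status 0 means the iteration budget ran out at a valid point --
        # usable (and expected for screened starts), just not converged
        ok = bool(res.status >= 0 and res.cost < _FAIL_OBJECTIVE / 4)
        return phi, ok, str(res.message), res.x.copy()

    const = spec.constant_term()
    screened: list[dict] = []
    for u0, deliberate in starts_u:
        try:
            phi, ok, msg, x = local_search(
                u0, max_nfev if deliberate else screen_nfev)
        except Exception as exc:  # pragma: no cover - solver-internal failure
            phi, ok, msg, x = -math.inf, False, str(exc), u0
        screened.append({"u0": u0, "deliberate": deliberate, "phi": phi,
                         "ok": ok, "msg": msg, "x": x, "deep": deliberate})

    # continue the best-screened Sobol starts; they are insurance against a
    # poor deliberate start, so they get half the full budget
    sobol_idx = [i for i, s in enumerate(screened) if not s["deliberate"]]
    sobol_idx.sort(key=lambda i: -screened[i]["phi"])
    n_deep = max(1, round(len(sobol_idx) / 3)) if sobol_idx else 0
    for i in sobol_idx[:n_deep]:
        s = screened[i]
        if not s["ok"]:
            continue
        try:
            phi, ok, msg, x = local_search(s["x"], max(60, max_nfev // 2))
        except Exception as exc:  # pragma: no cover
            continue
        if ok and phi >= s["phi"]:
            s.update(phi=phi, msg=msg, x=x)
        s["deep"] = True

    records: list[StartRecord] = []
    best: Optional[tuple[float, np.ndarray]] = None
    for s in screened:
        records.append(StartRecord(
            start=dict(zip(names, map(float, from_unit(s["u0"])))),
            converged=dict(zip(names, map(float, from_unit(s["x"])))),
            log_likelihood=s["phi"],
            success=bool(s["ok"]),
            message=s["msg"],
        ))
        if s["ok"] and s["deep"] and (best is None or s["phi"] > best[0]):
            best = (s["phi"], s["x"])
    if best is None:
        # fall back to the best screened point if nothing went deep
        for s in screened:
            if s["ok"] and (best is None or s["phi"] > best[0]):
                best = (s["phi"], s["x"])
    if best is None:
        raise EstimationError(
            "all multistart searches failed; per-start log: "
            + "; ".join(f"{r.start} -> {r.message}" for r in records)
        )
    # final tight polish of the winner so reported optima are reproducible
    # to well below the statistical uncertainty
    try:
        res = optimize.least_squares(
            residual_vector, np.clip(best[1], 1e-9, 1 - 1e-9),
            bounds=(0.0, 1.0), method="trf", diff_step=1e-4,
            xtol=1e-12, ftol=1e-12, gtol=1e-8, max_nfev=50,
        )
        if res.status >= 0 and const - float(res.cost) >= best[0]:
            best = (const - float(res.cost), res.x.copy())
    except Exception:  # pragma: no cover - polish is best-effort
        pass
    theta_hat = dict(zip(names, map(float, from_unit(best[1]))))
    chi2 = chi2_statistic(spec, theta_hat)
    passed, crit = chi2_test(chi2, spec.n_experiments, spec.n_points,
                             len(names))
    return FitResult(
        isotherm=spec.isotherm, parameters=theta_hat,
        log_likelihood=best[0], chi2=chi2,
        dof=spec.n_experiments * spec.n_points - len(names),
        critical_value=crit, passed=passed, starts=tuple(records),
        n_sim_calls=spec.predictor.n_sim_calls,
    )
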