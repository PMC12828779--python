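"""Lagrange-multiplier (score) test and Model Modification Index.

The test asks, for each fitted parameter theta_k, whether the data support
letting theta_k vary across the N experiments (i.e. whether it is secretly a
function of the state) while all other parameters stay at their maximum-
likelihood values. Writing theta_d = [theta_{k,1}, ..., theta_{k,N}] for the
relaxed per-experiment copies, the constrained optimum of the relaxed
likelihood is the original MLE itself, so the statistic needs no refit:

    xi = grad(Phi_d)^T  H_d^{-1}  grad(Phi_d)

where element i of the score grad(Phi_d) is sens_i^T Sigma_y^{-1} r_i (the
per-experiment score of theta_{k,i}) and H_d is the expected Fisher
information of theta_d, diagonal here because experiment i depends only on
its own copy: H_d[i,i] = sens_i^T Sigma_y^{-1} sens_i. Under the
constant-parameter null, xi is asymptotically chi-square with N-1 degrees of
freedom, and the Model Modification Index

    MMI = xi / chi2_{N-1}(95%)

flags the parameter for replacement by a state-dependent function when it
exceeds 1. The Lagrange multipliers themselves never need to be computed.

Output sensitivities d(yhat_i)/d(theta_k) are obtained by central finite
differences on the simulator (relative step 1e-4 with an absolute floor of
1e-7 on the parameter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .estimation import LikelihoodSpec

__all__ = [
    "SensitivityBlock",
    "LMResult",
    "MMIReport",
    "per_experiment_sensitivities",
    "score_vector",
    "expected_fim",
    "xi_statistic",
    "mmi",
    "mmi_report",
]

_REL_STEP = 1e-4
_ABS_FLOOR = 1e-7


@dataclass(frozen=True)
class SensitivityBlock:
    """d(yhat_i)/d(theta_k) at theta_hat, one length-N_y array per experiment."""

    parameter: str
    sensitivities: tuple[np.ndarray, ...]
    step: float

    def __post_init__(self) -> None:
        for s in self.sensitivities:
            if not np.all(np.isfinite(s)):
                raise ValueError("sensitivities contain non-finite values")


@dataclass(frozen=True)
class LMResult:
    """Score test of one parameter: per-experiment scores, FIM, xi and MMI."""

    parameter: str
    score: np.ndarray  # length N
    fim: np.ndarray  # N x N (diagonal)
    xi: float
    dof: int
    mmi: float
    singular: bool = False


@dataclass(frozen=True)
class MMIReport:
    """Per-parameter LM results, sorted by decreasing MMI."""

    results: tuple[LMResult, ...]

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def mmi_by_parameter(self) -> dict[str, float]:
        return {r.parameter: r.mmi for r in self.results}

    def max_result(self) -> LMResult:
        return self.results[0]

    def to_dict(self) -> dict:
        return {
            r.parameter: {"xi": r.xi, "mmi": r.mmi, "dof": r.dof,
                          "score": r.score.tolist(),
                          "fim_diag": np.diag(r.fim).tolist()}
            for r in self.results
        }


def per_experiment_sensitivities(spec: LikelihoodSpec,
                                 theta_hat: Mapping[str, float],
                                 param_name: str,
                                 rel_step: float = _REL_STEP) -> SensitivityBlock:
    """Central-difference d(yhat_i)/d(theta_k) at the MLE, per experiment."""
    if param_name not in spec.isotherm.parameter_names:
        raise KeyError(f"unknown parameter {param_name!r}")
    theta = {k: float(v) for k, v in theta_hat.items()}
    h = max(rel_step * abs(theta[param_name]), _ABS_FLOOR)
    hi = dict(theta)
    lo = dict(theta)
    hi[param_name] = theta[param_name] + h
    lo[param_name] = theta[param_name] - h
    try:
        y_hi = spec.predictor(hi)
        y_lo = spec.predictor(lo)
    except Exception as exc:
        raise RuntimeError(
            f"simulation failed while perturbing {param_name!r} by ±{h:g}"
        ) from exc
    sens = tuple((a - b) / (2.0 * h) for a, b in zip(y_hi, y_lo))
    return SensitivityBlock(param_name, sens, h)


def score_vector(spec: LikelihoodSpec, theta_hat: Mapping[str, float],
                 param_name: str,
                 sens: Optional[SensitivityBlock] = None) -> np.ndarray:
    """Per-experiment score d(Phi_d)/d(theta_{k,i}) = sens_i^T r_i / sigma_i^2."""
    if sens is None:
        sens = per_experiment_sensitivities(spec, theta_hat, param_name)
    residuals = spec.residuals(theta_hat)
    sig = spec.dataset.sigmas
    return np.array([
        float(s @ r) / sg**2
        for s, r, sg in zip(sens.sensitivities, residuals, sig)
    ])


def expected_fim(sens: SensitivityBlock, sigmas: Sequence[float]) -> np.ndarray:
    """Diagonal expected Fisher information of the relaxed parameter vector."""
    sigmas = np.asarray(sigmas, dtype=float)
    if len(sens.sensitivities) != sigmas.size:
        raise ValueError("sensitivity block and sigmas disagree on N")
    diag = np.array([
        float(s @ s) / sg**2 for s, sg in zip(sens.sensitivities, sigmas)
    ])
    return np.diag(diag)


def _is_near_singular(fim: np.ndarray) -> bool:
    d = np.diag(fim)
    return bool(np.any(d <= 1e-12 * max(float(np.max(d)), 1e-300)))


def xi_statistic(score: np.ndarray, fim: np.ndarray) -> float:
    """Quadratic form xi = score^T H_d^{-1} score (>= 0)."""
    score = np.asarray(score, dtype=float)
    if _is_near_singular(fim):
        warnings.warn(
            "near-singular Fisher information (parameter locally "
            "unidentifiable in some experiment); using a pseudo-inverse",
            RuntimeWarning, stacklevel=2,
        )
        xi = float(score @ np.linalg.pinv(fim) @ score)
    else:
        xi = float(score @ np.linalg.solve(fim, score))
    return max(xi, 0.0)


def mmi(xi: float, N: int, alpha: float = 0.05) -> float:
    """Model Modification Index xi / chi2_{N-1}(1-alpha); > 1 flags the parameter."""
    if N < 2:
        raise ValueError("MMI needs at least two experiments")
    return float(xi / chi2_dist.ppf(1.0 - alpha, N - 1))


def mmi_report(spec: LikelihoodSpec, theta_hat: Mapping[str, float],
               alpha: float = 0.05) -> MMIReport:
    """LM test of every estimated parameter, sorted by decreasing MMI."""
    N = spec.n_experiments
    results = []
    for name in spec.isotherm.parameter_names:
        sens = per_experiment_sensitivities(spec, theta_hat, name)
        fim = expected_fim(sens, spec.dataset.sigmas)
        score = score_vector(spec, theta_hat, name, sens)
        singular = _is_near_singular(fim)
        xi = xi_statistic(score, fim)
        results.append(LMResult(
            parameter=name, score=score, fim=fim, xi=xi, dof=N - 1,
            mmi=mmi(xi, N, alpha), singular=singular,
        ))
    results.sort(key=lambda r: r.mmi, reverse=True)
    return MMIReport(tuple(results))
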