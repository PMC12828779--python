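"""Iterative model diagnosis: fit, test, locate the faulty parameter, modify.

One iteration of the loop is: multistart maximum-likelihood fit of the
current isotherm; chi-square goodness-of-fit test; on failure, a Lagrange-
multiplier/MMI scan of every parameter; the parameter with the largest MMI
(if above 1) is replaced by a state-dependent expression taken from an
ordered rule library, and the extended model is refit. The loop stops when a
model passes the chi-square test (even if some MMI remain above 1) or after
``n_max`` modifications.

Each refit is warm-started: the previous estimate, extended with the new
parameter at its neutral value, is included among the starting points, so
the best log-likelihood never decreases along a trace (each modified model
nests its parent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .estimation import (
    Bounds,
    FitResult,
    LikelihoodSpec,
    default_bounds,
    multistart_mle,
)
from .insilico_experiments import Dataset
from .isotherm_models import (
    IsothermSpec,
    ModificationRule,
    apply_modification,
    default_rule_library,
)
from .lm_diagnostics import MMIReport, mmi_report

__all__ = [
    "LoopConfig",
    "LoopIteration",
    "LoopTrace",
    "LoopError",
    "select_candidate",
    "run_diagnosis",
]


class LoopError(RuntimeError):
    """A faulty parameter was found but no modification rule covers it."""


@dataclass(frozen=True)
class LoopConfig:
    """Settings of the diagnostic loop.

    ``rule_library`` maps parameter names to ordered candidate rules; when
    empty, :func:`isodx.isotherm_models.default_rule_library` of the current
    model is used at each iteration. ``bounds_overrides`` supplies
    (lower, upper, log) triples for parameters (e.g. ones a rule introduces)
    that should not use the package defaults.
    """

    n_max: int = 5
    alpha: float = 0.05
    n_starts: int = 10
    rule_library: Mapping[str, Sequence[ModificationRule]] = field(
        default_factory=dict)
    bounds_overrides: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_max < 0:
            raise ValueError("n_max must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class LoopIteration:
    """Everything one loop pass produced."""

    isotherm: IsothermSpec
    fit: FitResult
    report: Optional[MMIReport]  # None when the chi-square test passed
    selected: Optional[str]
    rule: Optional[ModificationRule]
    tie: bool = False


@dataclass(frozen=True)
class LoopTrace:
    """Ordered record of the diagnostic run."""

    iterations: tuple[LoopIteration, ...]
    status: str  # passed | exhausted_n_max | no_candidate

    @property
    def final(self) -> LoopIteration:
        return self.iterations[-1]

    @property
    def n_modifications(self) -> int:
        return len(self.iterations) - 1

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "iterations": [
                {
                    "form_id": it.isotherm.form_id,
                    "fit": it.fit.to_dict(),
                    "mmi": it.report.to_dict() if it.report else None,
                    "selected": it.selected,
                    "rule": it.rule.name if it.rule else None,
                    "tie": it.tie,
                }
                for it in self.iterations
            ],
        }


def select_candidate(report: MMIReport) -> tuple[Optional[str], bool]:
    """Parameter with the largest MMI if that MMI exceeds 1, else None.

    Ties at the maximum resolve to the parameter listed first in the model's
    declared order is not recoverable from the sorted report, so the first
    of the tied entries (stable sort order) is taken; the second return
    value flags the tie.
    """
    if len(report) == 0:
        raise ValueError("empty MMI report")
    top = report.results[0]
    if top.mmi <= 1.0:
        return None, False
    tie = any(r.mmi == top.mmi for r in report.results[1:])
    return top.parameter, tie


def run_diagnosis(dataset: Dataset, initial_model: IsothermSpec,
                  config: LoopConfig = LoopConfig(),
                  seed: Optional[int] = None) -> LoopTrace:
    """Run the fit -> test -> diagnose -> modify loop to a verdict.

    Returns the full trace; ``status`` is ``"passed"`` when a model satisfied
    the chi-square test, ``"exhausted_n_max"`` after ``n_max`` modifications
    without a pass, and ``"no_candidate"`` when the test failed but no
    parameter's MMI exceeded 1 (nothing to modify).
    """
    model = initial_model
    iterations: list[LoopIteration] = []
    warm: list[dict[str, float]] = []
    rng = np.random.default_rng(seed)
    used_rules: dict[str, int] = {}
    for n_mod in range(config.n_max + 1):
        spec = LikelihoodSpec(dataset, model)
        bounds = default_bounds(model, overrides=config.bounds_overrides)
        fit = multistart_mle(
            spec, bounds, n_starts=config.n_starts,
            seed=int(rng.integers(2**31 - 1)), extra_starts=warm,
            include_center=not warm,  # warm refits lean on the nested start
        )
        if fit.passed:
            iterations.append(LoopIteration(model, fit, None, None, None))
            return LoopTrace(tuple(iterations), "passed")
        report = mmi_report(spec, fit.parameters, alpha=config.alpha)
        candidate, tie = select_candidate(report)
        if candidate is None:
            iterations.append(LoopIteration(model, fit, report, None, None))
            return LoopTrace(tuple(iterations), "no_candidate")
        if n_mod == config.n_max:
            iterations.append(LoopIteration(model, fit, report, candidate,
                                            None, tie))
            return LoopTrace(tuple(iterations), "exhausted_n_max")
        library = dict(config.rule_library) or default_rule_library(model)
        rules = list(library.get(candidate, ()))
        k = used_rules.get(candidate, 0)
        if k >= len(rules):
            raise LoopError(
                f"parameter {candidate!r} selected (MMI "
                f"{report.results[0].mmi:.3g}) but no untried rule remains; "
                f"library: { {p: [r.name for r in rs] for p, rs in library.items()} }"
            )
        rule = rules[k]
        used_rules[candidate] = k + 1
        iterations.append(LoopIteration(model, fit, report, candidate, rule,
                                        tie))
        model = apply_modification(model, rule)
        warm = [dict(fit.parameters, **{rule.new_parameter: rule.neutral})]
    raise AssertionError("unreachable")  # pragma: no cover
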