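"""Shared fixtures.

The expensive end-to-end objects (case datasets and their maximum-likelihood
fits) are session-scoped and shared by the unit and acceptance tests; the
fits deliberately use a small multistart budget to stay at desk-scale
runtime: cold fits get the box centre plus one or two Sobol starts, and
warm-started refits rely on the nested parent estimate alone (with its
bound-released variant where applicable).
"""

from __future__ import annotations

import time

import numpy as np
import pytest

import isodx
from isodx import (
    LikelihoodSpec,
    LoopConfig,
    NoiseModel,
    SimGrid,
    default_bounds,
    generate_case_dataset,
    lss_langmuir,
    multistart_mle,
    polynomial,
    run_diagnosis,
)
from isodx.isotherm_models import apply_modification, rule_qsat_lss_phi2, rule_sb_linear_phi
from isodx.lm_diagnostics import mmi_report

#: Seeds fixed once for the whole suite.
SEED_A, SEED_B, SEED_C = 101, 202, 303


@pytest.fixture(scope="session")
def case_a_dataset():
    return generate_case_dataset("A", seed=SEED_A)


@pytest.fixture(scope="session")
def case_b_dataset():
    return generate_case_dataset("B", seed=SEED_B)


@pytest.fixture(scope="session")
def case_c_dataset():
    return generate_case_dataset("C_factorial", seed=SEED_C)


@pytest.fixture(scope="session")
def case_a_trace(case_a_dataset):
    """Full diagnostic run on Case A from the fixed-capacity model.

    Returns (trace, wall-clock seconds). The trace holds the misspecified
    fit, its MMI report, and the refit of the modified model.
    """
    t0 = time.time()
    trace = run_diagnosis(
        case_a_dataset, lss_langmuir("fixed_qsat"),
        LoopConfig(n_max=2, n_starts=2), seed=SEED_A,
    )
    return trace, time.time() - t0


@pytest.fixture(scope="session")
def case_a_modified_fit(case_a_trace):
    """The fit of the capacity-modulated model reached by the loop."""
    trace, _ = case_a_trace
    return trace.final


@pytest.fixture(scope="session")
def case_a_modified_mmi(case_a_dataset, case_a_modified_fit):
    spec = LikelihoodSpec(case_a_dataset, case_a_modified_fit.isotherm)
    return mmi_report(spec, case_a_modified_fit.fit.parameters)


@pytest.fixture(scope="session")
def case_b_fits(case_b_dataset):
    """Case B: the underfitting parent fit and its two rule-modified refits.

    The parent is the capacity-modulated form (no phi^2 term); the two
    children make S_b linear in phi or give the capacity a quadratic-exponent
    law -- the same function up to the sign of the new parameter. Both
    children are warm-started from the parent estimate with the new
    parameter at its neutral value, as the diagnostic loop would do.
    """
    base = lss_langmuir("modulated_qsat")
    spec_parent = LikelihoodSpec(case_b_dataset, base)
    fit_parent = multistart_mle(spec_parent, default_bounds(base), n_starts=2,
                                seed=SEED_B)
    warm = [dict(fit_parent.parameters, S_c=0.0)]
    fits = {"parent": fit_parent}
    for key, rule in (("sb_linear", rule_sb_linear_phi()),
                      ("qsat_quadratic", rule_qsat_lss_phi2())):
        model = apply_modification(base, rule)
        spec = LikelihoodSpec(case_b_dataset, model)
        fits[key] = multistart_mle(spec, default_bounds(model), n_starts=0,
                                   seed=SEED_B, extra_starts=warm,
                                   include_center=False)
    return fits


@pytest.fixture(scope="session")
def case_c_polynomial_fits(case_c_dataset):
    """Polynomial ladder fitted to the Case C factorial data.

    Returns {form: FitResult} for degrees 2-4 plus the tanh-damped cubic;
    each higher model is warm-started from its parent with the new
    coefficient at zero, mirroring the diagnostic loop's nesting.
    """
    fits = {}
    warm = []
    fit3_params = None
    for deg in (2, 3, 4):
        spec = LikelihoodSpec(case_c_dataset, polynomial(deg))
        fits[f"deg{deg}"] = multistart_mle(
            spec, default_bounds(spec.isotherm), n_starts=0 if warm else 1,
            seed=SEED_C + deg, extra_starts=warm,
            include_center=not warm,
        )
        params = fits[f"deg{deg}"].parameters
        if deg == 3:
            fit3_params = dict(params)
        warm = [dict(params, **{f"a_{deg + 1}": 0.0})]
    spec_t = LikelihoodSpec(case_c_dataset, polynomial(3, damping="tanh_on_cubic"))
    fits["deg3_tanh"] = multistart_mle(
        spec_t, default_bounds(spec_t.isotherm), n_starts=0, seed=SEED_C + 9,
        extra_starts=[dict(fit3_params, a_4=0.0)], include_center=False,
    )
    return fits
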