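"""Adsorption-isotherm functional forms and the parameter-to-function
modification algebra.

An isotherm is an equilibrium relation ``q = f(C_m, phi; theta)`` between the
stationary-phase loading ``q`` (mg/mL) and the mobile-phase concentration
``C_m`` (mg/mL), possibly modulated by the organic-modifier fraction ``phi``.
Forms are held as :mod:`sympy` expressions, which makes three things exact and
cheap at once:

* evaluation and the slope ``dq/dC_m`` (needed by the chain-rule form of the
  column mass balance) via analytic differentiation and ``lambdify``;
* the diagnostic loop's model modifications -- replacing a constant parameter
  by a state-dependent expression -- as plain symbolic substitution;
* identity checks between nominally different parameterizations.

The linear-solvent-strength (LSS) modulated Langmuir family writes the
retention factor as ``K * exp(-S_a*phi)`` and the denominator term as
``(K/q_sat) * exp(...)``, so that ``q_sat`` is the saturation capacity and
``b = K/q_sat`` the Langmuir retention-factor parameter.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "C_M",
    "PHI",
    "IsothermSpec",
    "ModificationRule",
    "langmuir",
    "langmuir_freundlich",
    "lss_langmuir",
    "quadratic",
    "polynomial",
    "eval_modulated_langmuir",
    "eval_quadratic",
    "eval_simple_isotherm",
    "eval_polynomial",
    "isotherm_slope",
    "apply_modification",
    "rule_qsat_lss_phi",
    "rule_sb_linear_phi",
    "rule_qsat_lss_phi2",
    "rule_polynomial_growth",
    "rule_tanh_damping",
    "default_rule_library",
    "taylor_coefficients",
    "radius_of_convergence",
    "validate_parameters",
]

#: State symbols shared by every isotherm expression.
C_M = sp.Symbol("C_m", real=True)
PHI = sp.Symbol("phi", real=True)

#: Parameters that must be strictly positive wherever they appear.
_POSITIVE_PARAMS = frozenset({"q_sat", "K"})
#: Parameters that must be non-negative wherever they appear.
_NONNEGATIVE_PARAMS = frozenset({"b", "b_prime"})


class IsothermDomainError(ValueError):
    """Isotherm evaluated outside its mathematical domain."""


@dataclass(frozen=True)
class IsothermSpec:
    """A named isotherm functional form ``q = f(C_m, phi; theta)``.

    Parameters are identified by name; ``parameter_names`` fixes their order
    (estimation, reporting and tie-breaking all use this order).
    ``modification_history`` records the rules applied so a diagnostic run is
    replayable.
    """

    form_id: str
    expression: sp.Expr
    parameter_names: tuple[str, ...]
    modification_history: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.parameter_names)) != len(self.parameter_names):
            raise ValueError("parameter names must be unique")
        allowed = {C_M, PHI} | {sp.Symbol(n, real=True) for n in self.parameter_names}
        free = self.expression.free_symbols
        if not free <= allowed:
            raise ValueError(
                f"expression has undeclared symbols: {free - allowed}"
            )

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def _values(self, params: Mapping[str, float]) -> tuple[float, ...]:
        try:
            return tuple(float(params[n]) for n in self.parameter_names)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"missing isotherm parameter {exc}") from exc

    def evaluate(self, params: Mapping[str, float], C_m, phi=0.0):
        """Stationary-phase loading q (mg/mL) at ``(C_m, phi)``."""
        f = _lambdified(self.expression, self.parameter_names, 0)
        return _broadcast(f, C_m, phi, self._values(params))

    def slope(self, params: Mapping[str, float], C_m, phi=0.0):
        """Analytic isotherm slope dq/dC_m at ``(C_m, phi)``."""
        f = _lambdified(self.expression, self.parameter_names, 1)
        return _broadcast(f, C_m, phi, self._values(params))

    def to_dict(self) -> dict:
        """JSON-serializable description (replayable spec)."""
        return {
            "form_id": self.form_id,
            "expression": sp.srepr(self.expression),
            "parameter_names": list(self.parameter_names),
            "modification_history": list(self.modification_history),
        }

    @staticmethod
    def from_dict(d: Mapping) -> "IsothermSpec":
        return IsothermSpec(
            form_id=str(d["form_id"]),
            expression=sp.sympify(d["expression"]),
            parameter_names=tuple(d["parameter_names"]),
            modification_history=tuple(d["modification_history"]),
        )


@functools.lru_cache(maxsize=256)
def _lambdified(expr: sp.Expr, names: tuple[str, ...], deriv: int) -> Callable:
    e = sp.diff(expr, C_M, deriv) if deriv else expr
    syms = [C_M, PHI] + [sp.Symbol(n, real=True) for n in names]
    return sp.lambdify(syms, e, modules="numpy")


def _broadcast(f: Callable, C_m, phi, values: tuple[float, ...]):
    out = f(np.asarray(C_m, dtype=float), np.asarray(phi, dtype=float), *values)
    # lambdify collapses expressions that are constant in C_m
    out = np.broadcast_to(np.asarray(out, dtype=float), np.broadcast_shapes(
        np.shape(C_m), np.shape(phi))).copy() if np.ndim(out) == 0 and (
        np.ndim(C_m) or np.ndim(phi)) else out
    if np.ndim(out) == 0:
        out = float(out)
    if not np.all(np.isfinite(out)):
        raise IsothermDomainError(
            f"isotherm '{f.__name__ if hasattr(f, '__name__') else '?'}' "
            "evaluated to a non-finite value"
        )
    return out


def validate_parameters(spec: IsothermSpec, params: Mapping[str, float]) -> None:
    """Check finiteness and the physical sign constraints of ``params``."""
    for name in spec.parameter_names:
        v = float(params[name])
        if not np.isfinite(v):
            raise ValueError(f"parameter {name} is not finite")
        if name in _POSITIVE_PARAMS and v <= 0:
            raise ValueError(f"parameter {name} must be > 0, got {v}")
        if name in _NONNEGATIVE_PARAMS and v < 0:
            raise ValueError(f"parameter {name} must be >= 0, got {v}")


# ---------------------------------------------------------------------------
# Built-in functional forms
# ---------------------------------------------------------------------------

def _sym(*names: str) -> list[sp.Symbol]:
    return [sp.Symbol(n, real=True) for n in names]


def langmuir() -> IsothermSpec:
    """Langmuir isotherm ``q = q_sat*b*C_m / (1 + b*C_m)``."""
    q_sat, b = _sym("q_sat", "b")
    return IsothermSpec(
        "langmuir", q_sat * b * C_M / (1 + b * C_M), ("q_sat", "b")
    )


def langmuir_freundlich() -> IsothermSpec:
    """Second-order Langmuir-Freundlich ``q = q_sat*(b*C_m)^2/(1+(b*C_m)^2)``."""
    q_sat, b = _sym("q_sat", "b")
    return IsothermSpec(
        "langmuir_freundlich",
        q_sat * (b * C_M) ** 2 / (1 + (b * C_M) ** 2),
        ("q_sat", "b"),
    )


_LSS_VARIANTS = {
    "fixed_qsat": ("K", "q_sat", "S_a"),
    "modulated_qsat": ("K", "q_sat", "S_a", "S_b"),
    "quadratic_qsat": ("K", "q_sat", "S_a", "S_b", "S_c"),
}


def lss_langmuir(variant: str = "fixed_qsat") -> IsothermSpec:
    """LSS-modulated Langmuir isotherm.

    ``fixed_qsat``
        q = K e^{-S_a phi} C_m / (1 + (K/q_sat) e^{-S_a phi} C_m); the
        saturation capacity does not depend on the modifier.
    ``modulated_qsat``
        denominator exponent -S_b phi (capacity follows its own LSS law).
    ``quadratic_qsat``
        denominator exponent -S_b phi + S_c phi^2.
    """
    if variant not in _LSS_VARIANTS:
        raise ValueError(f"unknown LSS variant {variant!r}")
    K, q_sat, S_a = _sym("K", "q_sat", "S_a")
    num = K * sp.exp(-S_a * PHI) * C_M
    if variant == "fixed_qsat":
        den_exp = -S_a * PHI
    elif variant == "modulated_qsat":
        (S_b,) = _sym("S_b")
        den_exp = -S_b * PHI
    else:
        S_b, S_c = _sym("S_b", "S_c")
        den_exp = -S_b * PHI + S_c * PHI**2
    expr = num / (1 + (K / q_sat) * sp.exp(den_exp) * C_M)
    return IsothermSpec(f"lss_langmuir_{variant}", expr, _LSS_VARIANTS[variant])


def quadratic() -> IsothermSpec:
    """Quadratic isotherm ``q = q_sat(b C + 2 b' C^2)/(1 + b C + b' C^2)``.

    Langmuir-like (tailing) at low concentration, anti-Langmuirian
    (fronting) at high concentration; plateau 2*q_sat.
    """
    q_sat, b, bp = _sym("q_sat", "b", "b_prime")
    expr = q_sat * (b * C_M + 2 * bp * C_M**2) / (1 + b * C_M + bp * C_M**2)
    return IsothermSpec("quadratic", expr, ("q_sat", "b", "b_prime"))


def polynomial(degree: int, damping: str = "none") -> IsothermSpec:
    """Polynomial isotherm ``q = sum_k a_k C_m^k`` (no constant term).

    ``a_0`` is identically zero: a clean mobile phase must equilibrate a
    clean stationary phase. With ``damping="tanh_on_cubic"`` (requires
    degree 3) an extra bounded term ``a_4 tanh(C_m) C_m^3`` is appended,
    damping high-order growth.
    """
    if degree < 1:
        raise ValueError("polynomial degree must be >= 1")
    names = tuple(f"a_{k}" for k in range(1, degree + 1))
    expr = sum(sp.Symbol(n, real=True) * C_M**k for k, n in enumerate(names, 1))
    form_id = f"polynomial_deg{degree}"
    if damping == "tanh_on_cubic":
        if degree != 3:
            raise ValueError("tanh damping is defined on the cubic polynomial")
        a4 = sp.Symbol("a_4", real=True)
        expr = expr + a4 * sp.tanh(C_M) * C_M**3
        names = names + ("a_4",)
        form_id += "_tanh"
    elif damping != "none":
        raise ValueError(f"unknown damping {damping!r}")
    return IsothermSpec(form_id, sp.expand(expr), names)


# ---------------------------------------------------------------------------
# Direct evaluation surface (convenience wrappers over the specs)
# ---------------------------------------------------------------------------

def eval_modulated_langmuir(params: Mapping[str, float], C_m, phi,
                            variant: str = "fixed_qsat"):
    """Evaluate the LSS-modulated Langmuir family; see :func:`lss_langmuir`."""
    spec = lss_langmuir(variant)
    _check_lss_domain(spec, params, C_m, phi)
    return spec.evaluate(params, C_m, phi)


def _check_lss_domain(spec, params, C_m, phi) -> None:
    if np.any(np.asarray(C_m) < 0):
        raise IsothermDomainError("C_m must be >= 0")
    den = spec.expression.as_numer_denom()[1]
    f = _lambdified(den, spec.parameter_names, 0)
    d = f(np.asarray(C_m, float), np.asarray(phi, float),
          *(float(params[n]) for n in spec.parameter_names))
    if np.any(np.asarray(d) <= 0):
        raise IsothermDomainError("isotherm denominator is not positive")


def eval_quadratic(params: Mapping[str, float], C_m):
    """Evaluate the quadratic isotherm (phi-independent)."""
    b = float(params["b"])
    bp = float(params["b_prime"])
    c = np.asarray(C_m, dtype=float)
    if np.any(c < 0):
        raise IsothermDomainError("C_m must be >= 0")
    if np.any(1 + b * c + bp * c**2 <= 0):
        raise IsothermDomainError("quadratic isotherm denominator <= 0")
    return quadratic().evaluate(params, C_m, 0.0)


def eval_simple_isotherm(params: Mapping[str, float], C_m, variant: str = "langmuir"):
    """Evaluate the plain Langmuir or Langmuir-Freundlich isotherm."""
    if variant == "langmuir":
        spec = langmuir()
    elif variant == "langmuir_freundlich":
        spec = langmuir_freundlich()
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if np.any(np.asarray(C_m) < 0):
        raise IsothermDomainError("C_m must be >= 0")
    return spec.evaluate(params, C_m, 0.0)


def eval_polynomial(coeffs: Sequence[float], C_m, damping: str = "none"):
    """Evaluate ``sum a_k C^k`` from ``coeffs = (a_1, ..., a_n)``.

    With ``damping="tanh_on_cubic"`` the last coefficient is the damped
    term's ``a_4`` and the first three are the cubic's coefficients.
    """
    coeffs = list(coeffs)
    if damping == "tanh_on_cubic":
        spec = polynomial(3, damping="tanh_on_cubic")
        if len(coeffs) != 4:
            raise ValueError("tanh-damped cubic takes exactly 4 coefficients")
    else:
        spec = polynomial(len(coeffs))
    params = dict(zip(spec.parameter_names, coeffs))
    return spec.evaluate(params, C_m, 0.0)


def isotherm_slope(spec: IsothermSpec, params: Mapping[str, float], C_m, phi=0.0):
    """Analytic ``dq/dC_m`` for any spec (chain-rule term of the column model)."""
    return spec.slope(params, C_m, phi)


# ---------------------------------------------------------------------------
# Modification algebra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModificationRule:
    """Replace a constant parameter by a state-dependent expression.

    ``template`` is a sympy-parsable expression over the target parameter,
    exactly one new parameter, and the state symbols ``C_m``/``phi``.
    ``neutral`` is the new parameter's value at which the modified model
    reproduces the unmodified one (used to warm-start refits).
    """

    name: str
    target: str
    new_parameter: str
    template: str
    neutral: float = 0.0

    def expression(self) -> sp.Expr:
        local = {
            "C_m": C_M,
            "phi": PHI,
            self.target: sp.Symbol(self.target, real=True),
            self.new_parameter: sp.Symbol(self.new_parameter, real=True),
        }
        return sp.sympify(self.template, locals=local)


def apply_modification(spec: IsothermSpec, rule: ModificationRule) -> IsothermSpec:
    """Return ``spec`` with ``rule.target`` replaced by ``rule.expression()``.

    The new spec evaluates identically to the old one when the new parameter
    is set to ``rule.neutral``; its parameter list is the old one with the
    new parameter appended.
    """
    if rule.target not in spec.parameter_names:
        raise KeyError(f"target parameter {rule.target!r} not in {spec.form_id}")
    if rule.new_parameter in spec.parameter_names:
        raise ValueError(
            f"new parameter {rule.new_parameter!r} already exists in the spec"
        )
    repl = rule.expression()
    new_syms = repl.free_symbols - {C_M, PHI, sp.Symbol(rule.target, real=True)}
    if new_syms != {sp.Symbol(rule.new_parameter, real=True)}:
        raise ValueError(
            "modification rule must introduce exactly one new parameter; "
            f"template introduces {sorted(map(str, new_syms))}"
        )
    expr = spec.expression.subs(sp.Symbol(rule.target, real=True), repl)
    return IsothermSpec(
        form_id=f"{spec.form_id}+{rule.name}",
        expression=expr,
        parameter_names=spec.parameter_names + (rule.new_parameter,),
        modification_history=spec.modification_history + (rule.name,),
    )


def rule_qsat_lss_phi(new_parameter: str = "S_c") -> ModificationRule:
    """q_sat -> q_sat * exp(-S_c * phi): capacity follows its own LSS law."""
    return ModificationRule(
        "qsat_lss_phi", "q_sat", new_parameter,
        f"q_sat*exp(-{new_parameter}*phi)",
    )


def rule_sb_linear_phi(new_parameter: str = "S_c") -> ModificationRule:
    """S_b -> S_b + S_c * phi: solvent-strength parameter linear in phi."""
    return ModificationRule(
        "sb_linear_phi", "S_b", new_parameter, f"S_b + {new_parameter}*phi"
    )


def rule_qsat_lss_phi2(new_parameter: str = "S_c") -> ModificationRule:
    """q_sat -> q_sat * exp(-S_c * phi^2): quadratic-exponent capacity law."""
    return ModificationRule(
        "qsat_lss_phi2", "q_sat", new_parameter,
        f"q_sat*exp(-{new_parameter}*phi**2)",
    )


def rule_polynomial_growth(k: int) -> ModificationRule:
    """a_k -> a_k + a_{k+1} C_m: raise the polynomial degree by one."""
    return ModificationRule(
        f"poly_growth_a{k}", f"a_{k}", f"a_{k + 1}",
        f"a_{k} + a_{k + 1}*C_m",
    )


def rule_tanh_damping() -> ModificationRule:
    """a_3 -> a_3 + a_4 tanh(C_m): bounded (damped) quartic-like term."""
    return ModificationRule(
        "tanh_damping_a3", "a_3", "a_4", "a_3 + a_4*tanh(C_m)"
    )


def default_rule_library(spec: IsothermSpec) -> dict[str, list[ModificationRule]]:
    """Ordered candidate rules per parameter for the diagnostic loop.

    LSS-family capacity parameters get the exponential modifier laws;
    polynomial coefficients get degree growth (with the tanh alternative on
    the cubic term listed after plain growth).
    """
    lib: dict[str, list[ModificationRule]] = {}
    names = set(spec.parameter_names)
    if "q_sat" in names and "K" in names:
        lib["q_sat"] = [rule_qsat_lss_phi(), rule_qsat_lss_phi2()]
    if "S_b" in names:
        lib["S_b"] = [rule_sb_linear_phi()]
    for n in spec.parameter_names:
        if n.startswith("a_"):
            k = int(n.split("_")[1])
            rules = [rule_polynomial_growth(k)]
            if k == 3:
                rules.append(rule_tanh_damping())
            lib[n] = rules
    return lib


# ---------------------------------------------------------------------------
# Taylor machinery for the quadratic isotherm
# ---------------------------------------------------------------------------

def taylor_coefficients(b: float, b_prime: float, q_sat: float,
                        order: int) -> np.ndarray:
    """Maclaurin coefficients ``c_1..c_order`` of the quadratic isotherm.

    Computed exactly by power-series division: with numerator coefficients
    ``n_1 = q_sat*b``, ``n_2 = 2*q_sat*b'`` and denominator ``1 + b C + b' C^2``
    the coefficients satisfy ``c_k = n_k - b c_{k-1} - b' c_{k-2}``.
    The leading terms are ``q_sat*b``, ``q_sat(2b'-b^2)``,
    ``q_sat(b^3-3bb')``, ``q_sat(4b^2 b' - 2b'^2 - b^4)``.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    c = np.zeros(order + 1)
    n = np.zeros(order + 1)
    if order >= 1:
        n[1] = q_sat * b
    if order >= 2:
        n[2] = 2.0 * q_sat * b_prime
    for k in range(1, order + 1):
        c[k] = n[k] - b * c[k - 1] - (b_prime * c[k - 2] if k >= 2 else 0.0)
    return c[1:]


def taylor_series(b: float, b_prime: float, q_sat: float, order: int,
                  C_m) -> np.ndarray:
    """Truncated Maclaurin series of the quadratic isotherm at ``C_m``."""
    coeffs = taylor_coefficients(b, b_prime, q_sat, order)
    c = np.asarray(C_m, dtype=float)
    powers = np.power.outer(c, np.arange(1, order + 1))
    return powers @ coeffs


def radius_of_convergence(b: float, b_prime: float) -> float:
    """Convergence radius of the quadratic isotherm's Maclaurin series.

    The radius equals the smallest modulus among the complex roots of the
    denominator ``1 + b z + b' z^2`` (``1/b`` when ``b' = 0``; infinite when
    both vanish).
    """
    if b == 0 and b_prime == 0:
        return float("inf")
    if b_prime == 0:
        return 1.0 / abs(b)
    roots = np.roots([b_prime, b, 1.0])
    return float(np.min(np.abs(roots)))
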