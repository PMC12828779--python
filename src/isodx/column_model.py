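"""Equilibrium Dispersive Model (EDM) of single-component elution.

The EDM lumps all band broadening into an apparent dispersion coefficient
``D_app`` and assumes instantaneous adsorption equilibrium ``q = f(C_m, phi)``,
so the mass balance in chain-rule form reads

    (1 + F * dq/dC_m) dC_m/dt = -u_int dC_m/dx + D_app d2C_m/dx2

on ``0 < x < L`` with a Danckwerts inlet condition and a zero-gradient outlet
condition, where ``F = (1 - eps_t)/eps_t`` is the volumetric phase ratio and
``u_int = Q / (S * eps_t)`` the interstitial velocity.

Discretization: cell-centred finite volumes on a uniform grid (default 100
cells), first-order backward differences for convection, second-order central
differences for dispersion; ghost values impose the Danckwerts inlet through
the first cell and the zero outlet gradient through the last two cells. Time
integration is stiff-adaptive (LSODA) on the method-of-lines system with a
tridiagonal Jacobian band.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import odeint

from .isotherm_models import IsothermSpec, C_M, PHI


@functools.lru_cache(maxsize=512)
def _slope_in_c(expr: sp.Expr, names: tuple[str, ...],
                pvals: tuple[float, ...], phi: float):
    """dq/dC_m with parameters and phi substituted, lambdified in C_m only."""
    d = sp.diff(expr, C_M)
    subs = {sp.Symbol(n, real=True): v for n, v in zip(names, pvals)}
    subs[PHI] = phi
    return sp.lambdify(C_M, d.subs(subs), modules="numpy")

__all__ = [
    "ColumnConfig",
    "OperatingConditions",
    "SimGrid",
    "Chromatogram",
    "SimulationError",
    "ModelValidityError",
    "phase_ratio",
    "interstitial_velocity",
    "apparent_dispersion",
    "inlet_concentration",
    "simulate_chromatogram",
    "linear_retention_time",
]


class SimulationError(RuntimeError):
    """The time integrator failed; carries the offending parameter vector."""

    def __init__(self, message: str, params: Optional[Mapping[str, float]] = None):
        super().__init__(message)
        self.params = dict(params) if params is not None else None


class ModelValidityError(ValueError):
    """Isotherm slope <= -1/F somewhere on the simulated range.

    The chain-rule EDM loses parabolicity when ``1 + F*dq/dC_m <= 0``; such a
    parameter vector is physically inadmissible for this model.
    """


@dataclass(frozen=True)
class ColumnConfig:
    """Column geometry and transport constants.

    Exactly one of ``apparent_dispersion`` (cm^2/min) or ``plate_number``
    must be given; the plate-number route converts per operating point via
    ``D_app = u_int * L / (2 * N_p)``.
    """

    length: float  # L, cm
    inner_diameter: float  # D, cm
    total_porosity: float  # eps_t, dimensionless
    apparent_dispersion: Optional[float] = None  # D_app, cm^2/min
    plate_number: Optional[float] = None  # N_p, dimensionless

    def __post_init__(self) -> None:
        if self.length <= 0 or self.inner_diameter <= 0:
            raise ValueError("column length and diameter must be positive")
        if not 0 < self.total_porosity < 1:
            raise ValueError("total porosity must lie in (0, 1)")
        given = (self.apparent_dispersion is not None) + (self.plate_number is not None)
        if given != 1:
            raise ValueError("give exactly one of apparent_dispersion / plate_number")
        if self.apparent_dispersion is not None and self.apparent_dispersion <= 0:
            raise ValueError("apparent dispersion must be positive")
        if self.plate_number is not None and self.plate_number <= 0:
            raise ValueError("plate number must be positive")

    @property
    def cross_section(self) -> float:
        """Cross-sectional area S = pi D^2 / 4 (cm^2)."""
        return math.pi * self.inner_diameter**2 / 4.0

    @property
    def phase_ratio(self) -> float:
        return phase_ratio(self.total_porosity)

    def dispersion_for(self, u_int: float) -> float:
        """D_app (cm^2/min) for a given interstitial velocity."""
        if self.apparent_dispersion is not None:
            return self.apparent_dispersion
        return apparent_dispersion(u_int, self.length, self.plate_number)

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "inner_diameter": self.inner_diameter,
            "total_porosity": self.total_porosity,
            "apparent_dispersion": self.apparent_dispersion,
            "plate_number": self.plate_number,
        }


@dataclass(frozen=True)
class OperatingConditions:
    """Manipulated inputs of one experiment."""

    flow_rate: float  # Q, mL/min
    sample_volume: float  # V, mL
    inlet_concentration: float  # C_in_star, mg/mL
    injection_start: float = 0.0  # t_inj, min
    modifier_fraction: float = 0.0  # phi, dimensionless

    def __post_init__(self) -> None:
        if self.flow_rate <= 0:
            raise ValueError("flow rate must be positive")
        if self.sample_volume < 0 or self.inlet_concentration < 0:
            raise ValueError("sample volume and inlet concentration must be >= 0")
        if self.injection_start < 0:
            raise ValueError("injection start must be >= 0")
        if not 0 <= self.modifier_fraction <= 1:
            raise ValueError("modifier fraction must lie in [0, 1]")

    @property
    def pulse_duration(self) -> float:
        """Feed-pulse duration V/Q (min)."""
        return self.sample_volume / self.flow_rate

    def to_dict(self) -> dict:
        return {
            "flow_rate": self.flow_rate,
            "sample_volume": self.sample_volume,
            "inlet_concentration": self.inlet_concentration,
            "injection_start": self.injection_start,
            "modifier_fraction": self.modifier_fraction,
        }


@dataclass(frozen=True)
class SimGrid:
    """Spatial/temporal discretization and integrator tolerances."""

    n_cells: int = 100
    time_points: Optional[np.ndarray] = None  # min; must start at 0
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self) -> None:
        if self.n_cells < 10:
            raise ValueError("need at least 10 cells")
        if self.time_points is not None:
            t = np.asarray(self.time_points, dtype=float)
            if t.ndim != 1 or t.size < 2:
                raise ValueError("time_points must be a 1-D array of >= 2 points")
            if t[0] != 0.0:
                raise ValueError("time_points must start at 0")
            if np.any(np.diff(t) <= 0):
                raise ValueError("time_points must be strictly increasing")
            object.__setattr__(self, "time_points", t)

    def with_times(self, t) -> "SimGrid":
        return SimGrid(self.n_cells, np.asarray(t, dtype=float), self.rtol, self.atol)


@dataclass(frozen=True)
class Chromatogram:
    """Outlet concentration versus time for one experiment."""

    times: np.ndarray  # min
    outlet_concentration: np.ndarray  # mg/mL
    conditions: OperatingConditions

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.outlet_concentration, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must have equal length")
        if not np.all(np.isfinite(c)):
            raise ValueError("chromatogram contains non-finite concentrations")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "outlet_concentration", c)

    @property
    def peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.outlet_concentration))])

    @property
    def peak_height(self) -> float:
        return float(np.max(self.outlet_concentration))

    def eluted_mass(self) -> float:
        """Q * integral of the outlet profile (mg), trapezoidal."""
        return self.conditions.flow_rate * float(
            np.trapezoid(self.outlet_concentration, self.times)
        )


def phase_ratio(eps_t: float) -> float:
    """Volumetric phase ratio F = (1 - eps_t) / eps_t."""
    if not 0 < eps_t < 1:
        raise ValueError("total porosity must lie in (0, 1)")
    return (1.0 - eps_t) / eps_t


def interstitial_velocity(Q: float, D: float, eps_t: float) -> float:
    """Interstitial velocity u_int = Q / (S * eps_t), S = pi D^2/4 (cm/min)."""
    if Q <= 0 or D <= 0:
        raise ValueError("flow rate and diameter must be positive")
    if not 0 < eps_t < 1:
        raise ValueError("total porosity must lie in (0, 1)")
    return Q / (math.pi * D**2 / 4.0 * eps_t)


def apparent_dispersion(u_int: float, L: float, N_p: float) -> float:
    """Plate-number approximation D_app = u_int * L / (2 * N_p) (cm^2/min)."""
    if u_int <= 0 or L <= 0 or N_p <= 0:
        raise ValueError("all inputs must be positive")
    return u_int * L / (2.0 * N_p)


def inlet_concentration(t: float, oc: OperatingConditions) -> float:
    """Rectangular feed pulse: C_in_star on [t_inj, t_inj + V/Q], else 0."""
    if t < 0:
        raise ValueError("time must be >= 0")
    t0 = oc.injection_start
    t1 = t0 + oc.pulse_duration
    if t0 <= t <= t1 and oc.sample_volume > 0:
        return oc.inlet_concentration
    return 0.0


def linear_retention_time(col: ColumnConfig, oc: OperatingConditions,
                          henry_coefficient: float) -> float:
    """Closed-form retention time (L/u_int)(1 + F*H) of a linear isotherm.

    Oracle for the simulator in the linear limit; excludes the injection
    centroid offset t_inj + (V/Q)/2.
    """
    if henry_coefficient < 0:
        raise ValueError("Henry coefficient must be >= 0")
    u = interstitial_velocity(oc.flow_rate, col.inner_diameter, col.total_porosity)
    return col.length / u * (1.0 + col.phase_ratio * henry_coefficient)


def simulate_chromatogram(col: ColumnConfig, oc: OperatingConditions,
                          isotherm: IsothermSpec, params: Mapping[str, float],
                          grid: SimGrid) -> Chromatogram:
    """Solve the EDM and return the outlet series at ``grid.time_points``.

    The column starts clean (C_m = 0 everywhere). Raises
    :class:`ModelValidityError` if ``1 + F*dq/dC_m`` is non-positive anywhere
    on the concentration range swept by the feed, and
    :class:`SimulationError` (carrying ``params``) if the integrator fails.
    """
    if grid.time_points is None:
        raise ValueError("grid.time_points must be set for simulation")
    t_report = grid.time_points
    n = grid.n_cells
    u = interstitial_velocity(oc.flow_rate, col.inner_diameter, col.total_porosity)
    D = col.dispersion_for(u)
    F = col.phase_ratio
    dx = col.length / n
    phi = oc.modifier_fraction

    pvals = tuple(float(params[k]) for k in isotherm.parameter_names)
    slope_c = _slope_in_c(isotherm.expression, isotherm.parameter_names,
                          pvals, phi)

    def slope(c: np.ndarray) -> np.ndarray:
        s = slope_c(c)
        if np.ndim(s) == 0:  # expressions whose slope is constant in C_m
            return np.full(c.shape, float(s))
        return s

    # admissibility pre-check on the concentration range the feed can reach
    c_max = max(oc.inlet_concentration, 1e-12)
    c_probe = np.linspace(0.0, 1.05 * c_max, 64)
    s_probe = slope(c_probe)
    if not np.all(np.isfinite(s_probe)):
        raise ModelValidityError("isotherm slope is not finite on the feed range")
    if np.min(1.0 + F * s_probe) <= 1e-3:
        raise ModelValidityError(
            "isotherm slope <= -1/F on the feed range: EDM loses parabolicity"
        )

    # The semi-discrete operator is tridiagonal: upwind convection plus
    # central dispersion, with the Danckwerts inlet folded into row 0 via the
    # ghost value cg = (c_in + beta*c0)/(1+beta) that makes the scheme's
    # inlet face flux exactly u*C_in, and the zero-gradient outlet folded
    # into the last row (ghost c[n] = c[n-1]).
    beta = D / (u * dx)
    alpha = u / dx
    mu = D / dx**2
    sub = alpha + mu  # coefficient of c[j-1]
    sup = mu  # coefficient of c[j+1]
    diag = np.full(n, -(alpha + 2.0 * mu))
    gamma = beta / (1.0 + beta)
    diag[0] += (alpha + mu) * gamma
    diag[-1] = -(alpha + mu)
    inlet_gain = (alpha + mu) / (1.0 + beta)  # times c_in, into cell 0

    def rhs(c: np.ndarray, t: float, c_in: float) -> np.ndarray:
        y = diag * c
        y[:-1] += sup * c[1:]
        y[1:] += sub * c[:-1]
        y[0] += inlet_gain * c_in
        s = slope(np.maximum(c, 0.0))
        np.divide(y, np.maximum(1.0 + F * s, 1e-3), out=y)
        return y

    # integrate segment-wise so the pulse edges fall on segment boundaries
    t_end = float(t_report[-1])
    edges = [0.0]
    for te in (oc.injection_start, oc.injection_start + oc.pulse_duration):
        if 0.0 < te < t_end:
            edges.append(te)
    edges.append(t_end)
    edges = sorted(set(edges))

    c = np.zeros(n)
    outlet = np.empty_like(t_report)
    outlet[0] = 0.0
    reported = t_report > 0
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        c_in = inlet_concentration(mid, oc)
        mask = reported & (t_report > a) & (t_report <= b)
        t_eval = t_report[mask]
        # segment time points for lsoda: start, interior reports, end; collapse
        # near-duplicates from floating-point grid construction
        t_seg = [a]
        for tv in t_eval:
            if tv - t_seg[-1] > 1e-9:
                t_seg.append(float(tv))
        if b - t_seg[-1] > 1e-9:
            t_seg.append(b)
        t_seg = np.asarray(t_seg)
        if t_seg.size == 1:  # zero-length segment
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # lsoda emits its own warnings
            y_seg, info = odeint(
                rhs, c, t_seg, args=(c_in,), rtol=grid.rtol, atol=grid.atol,
                ml=1, mu=1, full_output=True, printmessg=False,
            )
        if info["message"] != "Integration successful.":
            raise SimulationError(
                f"integrator failed on [{a:g}, {b:g}] min: {info['message']}",
                params)
        if t_eval.size:
            outlet[mask] = np.interp(t_eval, t_seg, y_seg[:, -1])
        c = y_seg[-1]
    # guard: concentrations should stay within the pre-checked range
    if np.any(outlet > 1.10 * c_max + 10 * grid.atol):
        raise SimulationError(
            "outlet exceeded the admissibility pre-check range", params
        )
    tol = 10.0 * grid.atol
    if np.min(outlet) < -1e-6 * max(oc.inlet_concentration, 1.0) - tol:
        # small dispersive undershoot is tolerated; large negatives are a bug
        raise SimulationError("outlet concentration strongly negative", params)
    return Chromatogram(t_report.copy(), outlet, oc)
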