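"""In-silico experiment designs and noisy chromatogram datasets.

This module is the synthetic-data surface of the package: it carries the
three case studies' designs and ground-truth isotherms, simulates each design
point with the column model, and adds homoscedastic Gaussian measurement
noise with per-experiment standard deviation equal to 1% of that
experiment's noiseless peak maximum (so the noise covariance stays diagonal
and known to the likelihood).

All experiments of one dataset share a common reporting grid (uniform 0.05
min spacing, horizon rounded up to a whole minute past the point where every
outlet has fallen below 1e-4 of its feed concentration), so the number of
measured points N_y is the same for every experiment.

Case definitions:

* Case A -- LSS-modulated Langmuir with capacity modulation (truth
  K=118.58, q_sat=34.45, S_a=9.36, S_b=7.50); five (V, phi) experiments at
  C_in*=5 mg/mL, Q=1 mL/min.
* Case B -- quadratic-exponent capacity law (S_b=3.10, S_c=4.20), same
  layout with a slightly different design.
* Case C -- quadratic isotherm (q_sat=123.2, b=0.04, b'=0.02 mL/mg), eight
  isocratic experiments at the 2^3 factorial corners of
  V={0.5,2} mL x C_in*={1,6} mg/mL x Q={0.5,2} mL/min.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .column_model import (
    Chromatogram,
    ColumnConfig,
    OperatingConditions,
    SimGrid,
    interstitial_velocity,
    linear_retention_time,
    simulate_chromatogram,
)
from .isotherm_models import IsothermSpec, lss_langmuir, quadratic

__all__ = [
    "load_run_config",
    "DesignPoint",
    "DesignTable",
    "NoiseModel",
    "Experiment",
    "Dataset",
    "TABLE_COLUMN",
    "CASE_TRUTH",
    "case_design",
    "case_truth",
    "sobol_design",
    "generate_dataset",
    "generate_case_dataset",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class DesignPoint:
    """Manipulated inputs of one experiment."""

    sample_volume: float  # V, mL
    modifier_fraction: float  # phi
    inlet_concentration: float  # C_in_star, mg/mL
    flow_rate: float  # Q, mL/min

    def operating_conditions(self, injection_start: float = 0.0) -> OperatingConditions:
        return OperatingConditions(
            flow_rate=self.flow_rate,
            sample_volume=self.sample_volume,
            inlet_concentration=self.inlet_concentration,
            injection_start=injection_start,
            modifier_fraction=self.modifier_fraction,
        )

    def to_dict(self) -> dict:
        return {
            "sample_volume": self.sample_volume,
            "modifier_fraction": self.modifier_fraction,
            "inlet_concentration": self.inlet_concentration,
            "flow_rate": self.flow_rate,
        }


@dataclass(frozen=True)
class DesignTable:
    """Ordered collection of design points."""

    points: tuple[DesignPoint, ...]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("design table must be non-empty")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def __getitem__(self, i: int) -> DesignPoint:
        return self.points[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.to_dict() for p in self.points])


@dataclass(frozen=True)
class NoiseModel:
    """Homoscedastic Gaussian noise, sigma = relative_level * peak height."""

    relative_level: float = 0.01

    def __post_init__(self) -> None:
        if self.relative_level < 0:
            raise ValueError("relative noise level must be >= 0")


@dataclass(frozen=True)
class Experiment:
    """One design point's measured (noisy) chromatogram."""

    design: DesignPoint
    chromatogram: Chromatogram  # noisy outlet values
    sigma: float  # measurement SD, mg/mL
    noiseless: Optional[np.ndarray] = None

    @property
    def times(self) -> np.ndarray:
        return self.chromatogram.times

    @property
    def values(self) -> np.ndarray:
        return self.chromatogram.outlet_concentration


@dataclass(frozen=True)
class Dataset:
    """A case's full in-silico measurement set Y = [y_1, ..., y_N]."""

    experiments: tuple[Experiment, ...]
    column: ColumnConfig
    case: str
    seed: Optional[int]
    noise: NoiseModel
    grid: SimGrid

    def __post_init__(self) -> None:
        n_y = {e.values.size for e in self.experiments}
        if len(n_y) != 1:
            raise ValueError("all experiments must share one reporting grid")

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    @property
    def n_points(self) -> int:
        """Measured points per experiment (N_y)."""
        return self.experiments[0].values.size

    @property
    def times(self) -> np.ndarray:
        return self.experiments[0].times

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([e.sigma for e in self.experiments])


def load_run_config(path):
    """Read a YAML/JSON run configuration.

    The file holds a ``column`` block (ColumnConfig fields), an optional
    ``operating`` block (OperatingConditions fields) and an optional ``grid``
    block (SimGrid fields); returns ``(column, operating_or_None,
    grid)``.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "column" not in raw:
        raise ManifestError("run configuration needs a 'column' block")
    column = ColumnConfig(**raw["column"])
    operating = (OperatingConditions(**raw["operating"])
                 if "operating" in raw else None)
    grid = SimGrid(**raw.get("grid", {}))
    return column, operating, grid


#: Column used by all case studies (L=15 cm, D=0.46 cm, eps_t=0.635,
#: D_app=0.006 cm^2/min).
TABLE_COLUMN = ColumnConfig(
    length=15.0, inner_diameter=0.46, total_porosity=0.635,
    apparent_dispersion=0.006,
)

_CASE_A_DESIGN = [(0.5, 0.1), (0.8, 0.2), (1.0, 0.3), (1.0, 0.4), (1.2, 0.5)]
_CASE_B_DESIGN = [(0.5, 0.1), (0.8, 0.2), (1.0, 0.3), (1.2, 0.5), (1.2, 0.3)]

#: Ground-truth isotherm (spec builder, parameter values) per case.
CASE_TRUTH: dict[str, tuple] = {
    "A": (lambda: lss_langmuir("modulated_qsat"),
          {"K": 118.58, "q_sat": 34.45, "S_a": 9.36, "S_b": 7.50}),
    "B": (lambda: lss_langmuir("quadratic_qsat"),
          {"K": 118.58, "q_sat": 34.45, "S_a": 9.36, "S_b": 3.10, "S_c": 4.20}),
    "C_factorial": (quadratic,
                    {"q_sat": 123.2, "b": 0.04, "b_prime": 0.02}),
}


def case_truth(case_id: str) -> tuple[IsothermSpec, dict[str, float]]:
    """Ground-truth isotherm spec and parameter values for a case."""
    if case_id not in CASE_TRUTH:
        raise KeyError(f"unknown case {case_id!r}")
    builder, params = CASE_TRUTH[case_id]
    return builder(), dict(params)


def case_design(case_id: str) -> DesignTable:
    """The printed experiment design of a case, verbatim.

    Cases A and B vary (V, phi) at C_in*=5 mg/mL, Q=1 mL/min; Case C
    ("C_factorial") is the 2^3 full factorial over (V, C_in*, Q) at phi=0.
    """
    if case_id == "A":
        pts = [DesignPoint(V, phi, 5.0, 1.0) for V, phi in _CASE_A_DESIGN]
    elif case_id == "B":
        pts = [DesignPoint(V, phi, 5.0, 1.0) for V, phi in _CASE_B_DESIGN]
    elif case_id == "C_factorial":
        pts = [
            DesignPoint(V, 0.0, C, Q)
            for V in (0.5, 2.0) for C in (1.0, 6.0) for Q in (0.5, 2.0)
        ]
    else:
        raise KeyError(f"unknown case {case_id!r}")
    return DesignTable(tuple(pts))


def sobol_design(bounds: Mapping[str, tuple[float, float]], n: int,
                 seed: Optional[int] = None) -> DesignTable:
    """Quasi-random (Sobol) design over a box of factors.

    ``bounds`` maps factor names (among sample_volume, inlet_concentration,
    flow_rate, modifier_fraction) to (lower, upper); omitted factors default
    to phi=0 and must otherwise be given.
    """
    if n < 1:
        raise ValueError("need at least one point")
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names], dtype=float)
    hi = np.array([bounds[k][1] for k in names], dtype=float)
    if np.any(lo >= hi):
        raise ValueError("each factor needs lower < upper")
    sampler = qmc.Sobol(d=len(names), scramble=True, rng=np.random.default_rng(seed))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*balance properties.*")
        u = sampler.random(n)
    x = qmc.scale(u, lo, hi)
    pts = []
    for row in x:
        kv = dict(zip(names, row))
        pts.append(DesignPoint(
            sample_volume=kv.get("sample_volume", 1.0),
            modifier_fraction=kv.get("modifier_fraction", 0.0),
            inlet_concentration=kv.get("inlet_concentration", 5.0),
            flow_rate=kv.get("flow_rate", 1.0),
        ))
    return DesignTable(tuple(pts))


def _horizon(col: ColumnConfig, dp: DesignPoint, spec: IsothermSpec,
             params: Mapping[str, float], grid: SimGrid,
             tail_fraction: float = 1e-4) -> float:
    """Whole-minute horizon after which the outlet stays below
    ``tail_fraction * C_in_star``."""
    oc = dp.operating_conditions()
    u = interstitial_velocity(dp.flow_rate, col.inner_diameter, col.total_porosity)
    # linear-limit bound on retention from the largest slope the feed reaches
    c_probe = np.linspace(0.0, max(dp.inlet_concentration, 1e-9), 64)
    s_max = float(np.max(spec.slope(params, c_probe, dp.modifier_fraction)))
    t_guess = (col.length / u) * (1.0 + col.phase_ratio * max(s_max, 0.0))
    t_guess = 1.4 * (t_guess + oc.injection_start + oc.pulse_duration) + 2.0
    thresh = tail_fraction * max(dp.inlet_concentration, 1e-9)
    for _ in range(6):
        t_coarse = np.arange(0.0, t_guess + 1e-9, 0.1)
        ch = simulate_chromatogram(col, oc, spec, params, grid.with_times(t_coarse))
        y = ch.outlet_concentration
        if y[-1] < thresh:
            above = np.nonzero(y >= thresh)[0]
            t_last = t_coarse[above[-1]] if above.size else ch.peak_time
            return float(np.ceil(t_last + 1e-9))
        t_guess *= 1.5
    raise RuntimeError(f"could not bracket the elution horizon for {dp}")


def generate_dataset(design: DesignTable, truth: IsothermSpec,
                     params: Mapping[str, float], col: ColumnConfig,
                     noise: NoiseModel, grid: SimGrid,
                     seed: Optional[int] = None, case: str = "custom",
                     reporting_interval: float = 0.05) -> Dataset:
    """Simulate a design with the ground truth and add measurement noise.

    Every experiment is reported on the case-common grid (the longest
    per-experiment horizon, uniform ``reporting_interval``); noise is i.i.d.
    Gaussian per point with sigma_i = relative_level * (noiseless peak of
    experiment i).
    """
    horizons = [_horizon(col, dp, truth, params, grid) for dp in design]
    t_common = np.arange(0.0, max(horizons) + 1e-9, reporting_interval)
    g = grid.with_times(t_common)
    rng = np.random.default_rng(seed)
    experiments = []
    for dp in design:
        try:
            ch = simulate_chromatogram(col, dp.operating_conditions(), truth,
                                       params, g)
        except Exception as exc:
            raise RuntimeError(f"simulation failed at design point {dp}") from exc
        clean = ch.outlet_concentration
        sigma = noise.relative_level * float(np.max(clean))
        noisy = clean + rng.normal(0.0, sigma, size=clean.shape) if sigma > 0 \
            else clean.copy()
        experiments.append(Experiment(
            design=dp,
            chromatogram=Chromatogram(t_common.copy(), noisy,
                                      dp.operating_conditions()),
            # positive floor keeps the noise covariance invertible for
            # noiseless (relative_level=0) datasets
            sigma=sigma if sigma > 0 else 1e-8,
            noiseless=clean,
        ))
    return Dataset(tuple(experiments), col, case, seed, noise, g)


def generate_case_dataset(case_id: str, seed: Optional[int] = None,
                          noise: NoiseModel = NoiseModel(),
                          grid: SimGrid = SimGrid()) -> Dataset:
    """Generate a full case dataset from its printed design and ground truth."""
    spec, params = case_truth(case_id)
    return generate_dataset(case_design(case_id), spec, params, TABLE_COLUMN,
                            noise, grid, seed=seed, case=case_id)


# ---------------------------------------------------------------------------
# Dataset files: one CSV per chromatogram plus a JSON manifest
# ---------------------------------------------------------------------------

_CSV_HEADER = ["time_min", "concentration_mg_per_ml"]


class ManifestError(ValueError):
    """Dataset manifest is missing or malformed; names the offending field."""


def write_dataset(ds: Dataset, path) -> list[Path]:
    """Write ``exp_XX.csv`` per experiment and ``manifest.json`` to ``path``."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    files = []
    manifest: dict = {
        "case": ds.case,
        "seed": ds.seed,
        "noise_relative_level": ds.noise.relative_level,
        "column": ds.column.to_dict(),
        "grid": {"n_cells": ds.grid.n_cells, "rtol": ds.grid.rtol,
                 "atol": ds.grid.atol},
        "experiments": [],
    }
    for i, exp in enumerate(ds.experiments, 1):
        name = f"exp_{i:02d}.csv"
        df = pd.DataFrame({
            _CSV_HEADER[0]: exp.times, _CSV_HEADER[1]: exp.values,
        })
        if exp.noiseless is not None:
            df["noiseless_mg_per_ml"] = exp.noiseless
        f = root / name
        df.to_csv(f, index=False, float_format="%.10g")
        files.append(f)
        manifest["experiments"].append({
            "file": name, "sigma": exp.sigma, "design": exp.design.to_dict(),
        })
    mf = root / "manifest.json"
    mf.write_text(json.dumps(manifest, indent=1))
    files.append(mf)
    return files


def read_dataset(path) -> Dataset:
    """Read a dataset written by :func:`write_dataset`."""
    root = Path(path)
    try:
        manifest = json.loads((root / "manifest.json").read_text())
    except FileNotFoundError as exc:
        raise ManifestError("manifest.json not found") from exc
    for key in ("case", "seed", "noise_relative_level", "column", "grid",
                "experiments"):
        if key not in manifest:
            raise ManifestError(f"manifest missing field {key!r}")
    col = ColumnConfig(**manifest["column"])
    grid_d = manifest["grid"]
    experiments = []
    for entry in manifest["experiments"]:
        for key in ("file", "sigma", "design"):
            if key not in entry:
                raise ManifestError(f"experiment entry missing field {key!r}")
        df = pd.read_csv(root / entry["file"])
        for col_name in _CSV_HEADER:
            if col_name not in df.columns:
                raise ManifestError(
                    f"{entry['file']} missing column {col_name!r}")
        dp = DesignPoint(**entry["design"])
        noiseless = (df["noiseless_mg_per_ml"].to_numpy()
                     if "noiseless_mg_per_ml" in df.columns else None)
        experiments.append(Experiment(
            design=dp,
            chromatogram=Chromatogram(
                df[_CSV_HEADER[0]].to_numpy(), df[_CSV_HEADER[1]].to_numpy(),
                dp.operating_conditions()),
            sigma=float(entry["sigma"]),
            noiseless=noiseless,
        ))
    times = experiments[0].times
    grid = SimGrid(int(grid_d["n_cells"]), times, float(grid_d["rtol"]),
                   float(grid_d["atol"]))
    return Dataset(tuple(experiments), col, manifest["case"], manifest["seed"],
                   NoiseModel(float(manifest["noise_relative_level"])), grid)
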