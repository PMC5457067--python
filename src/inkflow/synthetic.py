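"""Synthetic flow curves and print-run datasets with known ground truth.

The generator emulates the two kinds of measurements the package consumes:

* rheometer flow sweeps — apparent viscosity sampled on a log-spaced
  shear-rate grid from a known power-law fluid, with multiplicative
  lognormal noise (viscosities are strictly positive and rheometer scatter
  scales roughly with the mean);
* printed-line width tables — widths generated by the capillary model over
  a factorial design, again with multiplicative lognormal noise, all runs
  labelled continuous.

Default conditions mirror the shipped Pluronic F-127 study: ground truth
(n, η₀) = (0.0511, 1.04 Pa·s), a 50-point grid spanning 10⁻² to
1.5×10³ s⁻¹, 5 % noise, and the 3 nozzles × 3 pressures × 3 speeds design.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import DomainError, ValidationError
from .experiment import PrintRun
from .flow import NozzleSpec, PrintCondition, predict_width
from .rheology import FlowCurve, InkParams
from .units import m_to_um

__all__ = ["SyntheticSpec", "make_flow_curve", "make_print_runs", "default_design"]


def default_design() -> tuple[list[NozzleSpec], list[float], list[float]]:
    """The reference 3×3×3 factorial: 21G/25G/27G nozzles, 1–3 ×10⁵ Pa,
    0.01–0.03 m/s."""
    nozzles = [NozzleSpec.from_gauge(g) for g in ("21G", "25G", "27G")]
    pressures = [1e5, 2e5, 3e5]
    speeds = [0.01, 0.02, 0.03]
    return nozzles, pressures, speeds


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and design of a synthetic dataset.

    Attributes
    ----------
    true_n, true_eta0 : float
        Power-law index and viscosity at the reference shear rate of the
        generating fluid.
    shear_rate_min, shear_rate_max, n_points : float, float, int
        Log-spaced shear-rate grid of the flow curve [1/s].
    noise_sigma : float
        Scale of the lognormal multiplicative noise on viscosities
        (0 ⇒ exact power law).
    width_noise_sigma : float
        Scale of the lognormal multiplicative noise on generated widths.
    seed : int
        RNG seed; identical (spec, seed) gives bit-identical output.
    nozzles, pressures, speeds : sequences
        Factorial design of the generated print runs (defaults to the
        reference 3×3×3 grid).
    """

    true_n: float = 0.0511
    true_eta0: float = 1.04
    shear_rate_min: float = 1e-2
    shear_rate_max: float = 1.5e3
    n_points: int = 50
    noise_sigma: float = 0.05
    width_noise_sigma: float = 0.05
    seed: int = 0
    nozzles: tuple[NozzleSpec, ...] = field(
        default_factory=lambda: tuple(default_design()[0])
    )
    pressures: tuple[float, ...] = (1e5, 2e5, 3e5)
    speeds: tuple[float, ...] = (0.01, 0.02, 0.03)

    def __post_init__(self) -> None:
        if not (self.true_n > 0 and self.true_eta0 > 0):
            raise ValidationError("ground-truth n and eta0 must be positive")
        if not (0 < self.shear_rate_min < self.shear_rate_max):
            raise ValidationError("shear-rate grid bounds must satisfy 0 < min < max")
        if self.n_points < 2:
            raise ValidationError("flow curve needs at least 2 grid points")
        if self.noise_sigma < 0 or self.width_noise_sigma < 0:
            raise ValidationError("noise scales must be non-negative")
        if not (self.nozzles and self.pressures and self.speeds):
            raise ValidationError("design lists must be non-empty")
        if any(p <= 0 for p in self.pressures) or any(v <= 0 for v in self.speeds):
            raise ValidationError("design pressures and speeds must be positive")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)

    @property
    def true_ink(self) -> InkParams:
        return InkParams(n=self.true_n, eta=self.true_eta0, label="synthetic truth")

    @property
    def shear_rate_grid(self) -> np.ndarray:
        return np.geomspace(self.shear_rate_min, self.shear_rate_max, self.n_points)


def make_flow_curve(spec: SyntheticSpec) -> FlowCurve:
    """Generate a flow curve η_i = η₀·γ̇_i^(n−1)·exp(ε_i), ε_i ~ N(0, σ²)."""
    rng = np.random.default_rng(spec.seed)
    gamma = spec.shear_rate_grid
    eta = spec.true_eta0 * gamma ** (spec.true_n - 1.0)
    if spec.noise_sigma > 0:
        eta = eta * np.exp(rng.normal(0.0, spec.noise_sigma, size=gamma.size))
    return FlowCurve(gamma, eta, label=f"synthetic(seed={spec.seed})")


def make_print_runs(ink: InkParams, spec: SyntheticSpec) -> list[PrintRun]:
    """Generate print runs whose widths are the model prediction times
    lognormal noise; every run is labelled continuous.

    The design grid is ordered (nozzle, speed, pressure) like
    :func:`inkflow.experiment.enumerate_design`.
    """
    rng = np.random.default_rng(spec.seed)
    runs: list[PrintRun] = []
    for nozzle in spec.nozzles:
        for speed in spec.speeds:
            for pressure in spec.pressures:
                report = predict_width(ink, nozzle, pressure, speed)
                width_um = m_to_um(report.predicted_width)
                if spec.width_noise_sigma > 0:
                    width_um *= float(
                        np.exp(rng.normal(0.0, spec.width_noise_sigma))
                    )
                runs.append(
                    PrintRun(
                        condition=PrintCondition(
                            nozzle=nozzle,
                            gauge_pressure=pressure,
                            stage_speed=speed,
                        ),
                        measured_width_mean=width_um,
                        measured_width_sd=0.0,
                        status="continuous",
                    )
                )
    return runs


def estimate_viscosity(runs: Sequence[PrintRun], n: float) -> float:
    """Recover the apparent viscosity η from measured widths by least squares.

    Since d² = C/η with C = D⁴·ΔP·(4n/(3n+1))/(32·L·v̇) known per run, the
    least-squares estimate over runs is 1/η̂ = Σ C_i d_i² / Σ C_i². Exact on
    noiseless model-generated runs; used for parameter-recovery checks and
    for calibrating η from printing data when no rheometer is available.
    """
    if not (n > 0):
        raise DomainError(f"power-law index must be positive, got {n}")
    rabino = (3.0 * n + 1.0) / (4.0 * n)
    c_vals, d2_vals = [], []
    for run in runs:
        if not run.measured:
            continue
        cond = run.condition
        c = (
            cond.nozzle.inner_diameter**4
            * cond.gauge_pressure
            / (32.0 * cond.nozzle.length * cond.stage_speed * rabino)
        )
        c_vals.append(c)
        d2_vals.append((run.measured_width_mean * 1e-6) ** 2)
    if not c_vals:
        raise DomainError("no measured runs to estimate viscosity from")
    c_arr = np.asarray(c_vals)
    d2_arr = np.asarray(d2_vals)
    inv_eta = float(c_arr @ d2_arr / (c_arr @ c_arr))
    if inv_eta <= 0:
        raise DomainError("viscosity estimate is non-positive; data inconsistent")
    return 1.0 / inv_eta


__all__.append("estimate_viscosity")
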