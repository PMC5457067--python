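"""Capillary-flow model of pneumatic extrusion and the strand-width prediction.

The dispensing nozzle is treated as a capillary of inner diameter D and
length L through which a power-law fluid is driven by the gauge pressure ΔP,
under the standard assumptions of capillary rheometry: no wall slip,
incompressible fluid, steady laminar fully developed flow, negligible
entrance/exit losses, and a deposited strand of constant circular cross
section whose diameter d equals the printed line width.

The chain of relations:

    wall shear stress        τ_w = D·ΔP / (4L)
    wall shear rate          γ̇_w = ((3n+1)/4n) · 32Q̇/(πD³)   (Rabinowitsch)
    mass conservation        Q̇ = π d² v̇ / 4                  (stage speed v̇)
    constitutive closure     τ_w = η · γ̇_w

eliminating τ_w, γ̇_w and Q̇ gives the printed width

    d² = (D⁴ / (32 η L v̇)) · (4n/(3n+1)) · ΔP

so d ∝ D²·√ΔP and d ∝ 1/√v̇. The apparent viscosity η is a constant
parameter here (evaluated at the reference shear rate), not re-evaluated at
the wall; at n = 1 the expression reduces to the Hagen–Poiseuille result.
The same relation is solved for ΔP or v̇ for inverse process design.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .rheology import InkParams
from .units import m_to_um, um_to_m

__all__ = [
    "NozzleSpec",
    "PrintCondition",
    "PredictionReport",
    "ResolutionModel",
    "NOZZLE_REGISTRY",
    "DEFAULT_NOZZLE_LENGTH_M",
    "wall_shear_stress",
    "wall_shear_rate_from_flow",
    "strand_flow_rate",
    "rabinowitsch_factor",
    "predict_width",
    "required_pressure",
    "required_speed",
    "sweep",
]

#: default capillary length of the dispensing needles [m]
DEFAULT_NOZZLE_LENGTH_M = 0.005

#: gauge label -> inner diameter [m] for the blunt dispensing needles used in
#: pneumatic bioprinting; gauge-to-ID mappings vary by vendor, so this
#: registry is user-extensible (pass your own dict to NozzleSpec.from_gauge).
NOZZLE_REGISTRY: dict[str, float] = {
    "21G": 514e-6,
    "25G": 260e-6,
    "27G": 210e-6,
}

#: warn below this power-law index: the Rabinowitsch factor (3n+1)/4n
#: amplifies numerical noise as n -> 0
_SMALL_N_WARN = 1e-4


def _require_positive(**quantities: float) -> None:
    for name, value in quantities.items():
        if not (np.isfinite(value) and value > 0):
            raise DomainError(f"{name} must be a positive finite number, got {value}")


@dataclass(frozen=True)
class NozzleSpec:
    """A dispensing nozzle: gauge label, inner diameter D [m], length L [m]."""

    gauge: str
    inner_diameter: float
    length: float = DEFAULT_NOZZLE_LENGTH_M

    def __post_init__(self) -> None:
        _require_positive(inner_diameter=self.inner_diameter, length=self.length)

    @property
    def radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def inner_diameter_um(self) -> float:
        return m_to_um(self.inner_diameter)

    @classmethod
    def from_gauge(
        cls,
        gauge: str,
        length: float = DEFAULT_NOZZLE_LENGTH_M,
        registry: Optional[dict[str, float]] = None,
    ) -> "NozzleSpec":
        """Look a gauge label up in the (user-extensible) registry."""
        table = NOZZLE_REGISTRY if registry is None else registry
        key = gauge.upper()
        if key not in table:
            raise DomainError(
                f"unknown nozzle gauge {gauge!r}; known gauges: {sorted(table)}"
            )
        return cls(gauge=key, inner_diameter=table[key], length=length)


@dataclass(frozen=True)
class PrintCondition:
    """One printing condition: nozzle, gauge pressure ΔP [Pa], stage speed v̇ [m/s]."""

    nozzle: NozzleSpec
    gauge_pressure: float
    stage_speed: float

    def __post_init__(self) -> None:
        _require_positive(
            gauge_pressure=self.gauge_pressure, stage_speed=self.stage_speed
        )

    @property
    def abscissa(self) -> float:
        """D²·√ΔP [m²·Pa^½] — the collapse variable of the width model."""
        return self.nozzle.inner_diameter**2 * math.sqrt(self.gauge_pressure)


@dataclass(frozen=True)
class PredictionReport:
    """Full output of the forward model at one condition (all SI)."""

    predicted_width: float
    wall_shear_stress: float
    wall_shear_rate: float
    volumetric_flow_rate: float
    over_extrusion: bool

    def __post_init__(self) -> None:
        _require_positive(
            predicted_width=self.predicted_width,
            wall_shear_stress=self.wall_shear_stress,
            wall_shear_rate=self.wall_shear_rate,
            volumetric_flow_rate=self.volumetric_flow_rate,
        )

    @property
    def predicted_width_um(self) -> float:
        return m_to_um(self.predicted_width)

    def to_dict(self) -> dict:
        return {
            "d_pred_um": self.predicted_width_um,
            "tau_w_Pa": self.wall_shear_stress,
            "gamma_w_1_s": self.wall_shear_rate,
            "Q_m3_s": self.volumetric_flow_rate,
            "over_extrusion": self.over_extrusion,
        }


def rabinowitsch_factor(n: float) -> float:
    """(3n+1)/(4n): converts the Newtonian wall shear rate to the power-law one."""
    _require_positive(n=n)
    if n < _SMALL_N_WARN:
        warnings.warn(
            f"power-law index n = {n:g} is extremely small; the Rabinowitsch "
            "factor (3n+1)/4n amplifies numerical noise",
            stacklevel=2,
        )
    return (3.0 * n + 1.0) / (4.0 * n)


def wall_shear_stress(nozzle: NozzleSpec, gauge_pressure: float) -> float:
    """Wall shear stress τ_w = D·ΔP/(4L) [Pa] of fully developed capillary flow."""
    _require_positive(gauge_pressure=gauge_pressure)
    return nozzle.inner_diameter * gauge_pressure / (4.0 * nozzle.length)


def wall_shear_rate_from_flow(n: float, flow_rate: float, nozzle: NozzleSpec) -> float:
    """Rabinowitsch-corrected wall shear rate γ̇_w = ((3n+1)/4n)·32Q̇/(πD³) [1/s]."""
    _require_positive(flow_rate=flow_rate)
    return rabinowitsch_factor(n) * 32.0 * flow_rate / (
        math.pi * nozzle.inner_diameter**3
    )


def strand_flow_rate(width: float, stage_speed: float) -> float:
    """Volumetric flow rate Q̇ = π d² v̇ / 4 [m³/s] of a deposited strand of
    constant circular cross-section d moving with the stage at v̇."""
    _require_positive(width=width, stage_speed=stage_speed)
    return math.pi * width**2 * stage_speed / 4.0


def predict_width(
    ink: InkParams,
    nozzle: NozzleSpec,
    gauge_pressure: float,
    stage_speed: float,
) -> PredictionReport:
    """Forward model: printed strand width and the flow state behind it.

    Solves d² = (D⁴/(32ηLv̇))·(4n/(3n+1))·ΔP and reports, alongside d, the
    wall shear stress, the wall shear rate and the volumetric flow rate at
    that width, plus an over-extrusion flag (d > D).
    """
    _require_positive(gauge_pressure=gauge_pressure, stage_speed=stage_speed)
    d_squared = (
        nozzle.inner_diameter**4
        * gauge_pressure
        / (32.0 * ink.eta * nozzle.length * stage_speed * rabinowitsch_factor(ink.n))
    )
    d = math.sqrt(d_squared)
    flow = strand_flow_rate(d, stage_speed)
    return PredictionReport(
        predicted_width=d,
        wall_shear_stress=wall_shear_stress(nozzle, gauge_pressure),
        wall_shear_rate=wall_shear_rate_from_flow(ink.n, flow, nozzle),
        volumetric_flow_rate=flow,
        over_extrusion=d > nozzle.inner_diameter,
    )


def required_pressure(
    ink: InkParams,
    nozzle: NozzleSpec,
    target_width: float,
    stage_speed: float,
) -> float:
    """Inverse design: gauge pressure ΔP = 32ηL·((3n+1)/4n)·(d²/D⁴)·v̇ [Pa]
    producing the target width at the given stage speed."""
    _require_positive(target_width=target_width, stage_speed=stage_speed)
    return (
        32.0
        * ink.eta
        * nozzle.length
        * rabinowitsch_factor(ink.n)
        * target_width**2
        / nozzle.inner_diameter**4
        * stage_speed
    )


def required_speed(
    ink: InkParams,
    nozzle: NozzleSpec,
    target_width: float,
    gauge_pressure: float,
) -> float:
    """Inverse design: stage speed v̇ = (D⁴/(32ηLd²))·(4n/(3n+1))·ΔP [m/s]
    producing the target width at the given gauge pressure."""
    _require_positive(target_width=target_width, gauge_pressure=gauge_pressure)
    return (
        nozzle.inner_diameter**4
        * gauge_pressure
        / (32.0 * ink.eta * nozzle.length * target_width**2 * rabinowitsch_factor(ink.n))
    )


#: column order of the sweep table
SWEEP_COLUMNS = [
    "gauge",
    "D_um",
    "L_m",
    "pressure_Pa",
    "speed_m_s",
    "d_pred_um",
    "tau_w_Pa",
    "gamma_w_1_s",
    "Q_m3_s",
    "D2sqrtP",
    "over_extrusion",
]


def sweep(
    ink: InkParams,
    nozzles: Sequence[NozzleSpec],
    pressures: Sequence[float],
    speeds: Sequence[float],
) -> pd.DataFrame:
    """Forward model over the Cartesian product of conditions.

    Returns one row per (nozzle, speed, pressure), sorted in that order,
    carrying the predicted width, the flow state, and the collapse abscissa
    D²√ΔP (so width-vs-D²√ΔP plots fall on one straight line per speed).
    """
    if not nozzles or not len(pressures) or not len(speeds):
        raise DomainError("sweep requires non-empty nozzle, pressure and speed lists")
    rows = []
    for nozzle, speed, pressure in itertools.product(nozzles, speeds, pressures):
        report = predict_width(ink, nozzle, pressure, speed)
        rows.append(
            {
                "gauge": nozzle.gauge,
                "D_um": nozzle.inner_diameter_um,
                "L_m": nozzle.length,
                "pressure_Pa": float(pressure),
                "speed_m_s": float(speed),
                "d_pred_um": report.predicted_width_um,
                "tau_w_Pa": report.wall_shear_stress,
                "gamma_w_1_s": report.wall_shear_rate,
                "Q_m3_s": report.volumetric_flow_rate,
                "D2sqrtP": nozzle.inner_diameter**2 * math.sqrt(pressure),
                "over_extrusion": report.over_extrusion,
            }
        )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


class ResolutionModel:
    """The width model bound to one ink and one nozzle.

    Convenience object wrapping the forward prediction and its two inverses
    for interactive process design::

        model = ResolutionModel(ink, NozzleSpec.from_gauge("21G"))
        report = model.predict(gauge_pressure=1e5, stage_speed=0.01)
        dp = model.required_pressure(target_width_um=500, stage_speed=0.01)
    """

    def __init__(self, ink: InkParams, nozzle: NozzleSpec):
        self.ink = ink
        self.nozzle = nozzle

    def predict(self, gauge_pressure: float, stage_speed: float) -> PredictionReport:
        return predict_width(self.ink, self.nozzle, gauge_pressure, stage_speed)

    def required_pressure(self, target_width_um: float, stage_speed: float) -> float:
        return required_pressure(
            self.ink, self.nozzle, um_to_m(target_width_um), stage_speed
        )

    def required_speed(self, target_width_um: float, gauge_pressure: float) -> float:
        return required_speed(
            self.ink, self.nozzle, um_to_m(target_width_um), gauge_pressure
        )

    def sweep(self, pressures: Sequence[float], speeds: Sequence[float]) -> pd.DataFrame:
        return sweep(self.ink, [self.nozzle], pressures, speeds)
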