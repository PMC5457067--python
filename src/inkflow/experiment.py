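"""Print-run tables, reference fixtures, and model-vs-measurement comparison.

A *print run* is one factorial condition (nozzle gauge, stage speed, gauge
pressure) together with the measured line width (mean ± sd, μm) and a
continuity label: ``continuous`` for a uniform strand, ``discontinuous`` for
a defect/droplet strand that still yielded a measurable width, and
``not_printed`` when the pressure was insufficient to dispense anything.
Continuity is a data-provided label, never predicted.

The package ships the full 3×3×3 factorial of measured widths for
24.5 wt % Pluronic F-127 (a thermo-responsive triblock-copolymer hydrogel
widely used as a sacrificial bioink) plus the rheological constants of the
24.5 wt % and 30 wt % formulations, so comparisons run without any
downloads. ``compare_runs`` scores the capillary model against the measured
widths and groups the errors by stage speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError
from .flow import (
    DEFAULT_NOZZLE_LENGTH_M,
    NozzleSpec,
    PrintCondition,
    predict_width,
)
from .rheology import InkParams
from .units import um_to_m

__all__ = [
    "PrintRun",
    "ComparisonRow",
    "ComparisonResult",
    "REFERENCE_INKS",
    "reference_ink",
    "reference_print_runs_path",
    "synthetic_flow_curve_path",
    "load_reference_print_runs",
    "load_print_runs",
    "write_print_runs",
    "classify_over_extrusion",
    "compare_runs",
    "enumerate_design",
]

STATUSES = ("continuous", "discontinuous", "not_printed")

#: rheological constants of the shipped Pluronic F-127 formulations:
#: power-law index n and apparent viscosity eta [Pa s] at the reference
#: shear rate, with needle length L = 0.005 m throughout.
REFERENCE_INKS: dict[str, InkParams] = {
    "24.5": InkParams(n=0.0511, eta=1.04, label="pluronic F-127 24.5 wt%"),
    "30": InkParams(n=0.1656, eta=1.46, label="pluronic F-127 30 wt%"),
}

_FIXTURE_NAME = "pluronic_f127_24p5_print_runs.csv"

PRINT_RUN_COLUMNS = [
    "gauge",
    "speed_m_s",
    "pressure_1e5Pa",
    "width_um",
    "width_sd_um",
    "status",
]


def reference_ink(concentration: str = "24.5") -> InkParams:
    """Rheological constants of a shipped Pluronic F-127 formulation
    (``"24.5"`` or ``"30"`` wt %)."""
    try:
        return REFERENCE_INKS[concentration]
    except KeyError:
        raise DomainError(
            f"no reference ink at {concentration!r} wt%; "
            f"available: {sorted(REFERENCE_INKS)}"
        ) from None


def reference_print_runs_path() -> Path:
    """Filesystem path of the packaged measured-width table."""
    return Path(resources.files("inkflow.data") / _FIXTURE_NAME)


def synthetic_flow_curve_path() -> Path:
    """Filesystem path of the packaged SYNTHETIC noiseless flow curve.

    The curve is generated from the power-law model with the 24.5 wt %
    constants (not a measured rheometer sweep); fitting it recovers
    (n, η₀) = (0.0511, 1.04) exactly, which makes it a convenient smoke
    input for the ``fit`` workflow.
    """
    return Path(resources.files("inkflow.data") / "flow_curve_pluronic_24p5_synthetic.csv")


@dataclass(frozen=True)
class PrintRun:
    """One printing condition with its measured outcome.

    ``measured_width_mean``/``measured_width_sd`` are in μm and present iff
    ``status != "not_printed"``.
    """

    condition: PrintCondition
    measured_width_mean: Optional[float]
    measured_width_sd: Optional[float]
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(
                f"unknown status {self.status!r}; expected one of {STATUSES}"
            )
        has_width = self.measured_width_mean is not None
        if self.status == "not_printed":
            if has_width or self.measured_width_sd is not None:
                raise ValidationError("not_printed runs must carry no width")
        else:
            if not has_width:
                raise ValidationError(f"{self.status} run missing measured width")
            if not self.measured_width_mean > 0:
                raise ValidationError(
                    f"measured width must be positive, got {self.measured_width_mean}"
                )
            if self.measured_width_sd is not None and self.measured_width_sd < 0:
                raise ValidationError("width sd must be non-negative")

    @property
    def measured(self) -> bool:
        return self.status != "not_printed"


@dataclass(frozen=True)
class ComparisonRow:
    """Measured vs predicted width at one condition (widths in μm)."""

    gauge: str
    speed_m_s: float
    pressure_Pa: float
    status: str
    measured_um: float
    predicted_um: float
    relative_error: float  # (pred - meas) / meas
    abscissa: float  # D^2 * sqrt(dP), m^2 Pa^0.5


def _make_nozzle(gauge: str, registry: Optional[dict[str, float]],
                 length: float) -> NozzleSpec:
    return NozzleSpec.from_gauge(gauge, length=length, registry=registry)


def load_print_runs(
    source: str | Path,
    registry: Optional[dict[str, float]] = None,
    nozzle_length: float = DEFAULT_NOZZLE_LENGTH_M,
) -> list[PrintRun]:
    """Read a delimited print-run table into validated records.

    The schema is ``gauge, speed_m_s, pressure_1e5Pa, width_um, width_sd_um,
    status``; pressures are given in multiples of 10⁵ Pa and converted to Pa,
    widths stay in μm. Comment lines start with ``#``. Malformed rows raise a
    :class:`ValidationError` listing every offending row; an empty file
    returns an empty list with a warning.
    """
    source = Path(source)
    try:
        frame = pd.read_csv(source, sep=None, engine="python", comment="#")
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=PRINT_RUN_COLUMNS)
    missing = set(PRINT_RUN_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{source}: missing columns {sorted(missing)}")
    if frame.empty:
        warnings.warn(f"{source}: no print runs found", stacklevel=2)
        return []

    runs: list[PrintRun] = []
    problems: list[str] = []
    for idx, row in frame.iterrows():
        try:
            nozzle = _make_nozzle(str(row["gauge"]), registry, nozzle_length)
            condition = PrintCondition(
                nozzle=nozzle,
                gauge_pressure=float(row["pressure_1e5Pa"]) * 1e5,
                stage_speed=float(row["speed_m_s"]),
            )
            width = row["width_um"]
            sd = row["width_sd_um"]
            runs.append(
                PrintRun(
                    condition=condition,
                    measured_width_mean=None if pd.isna(width) else float(width),
                    measured_width_sd=None if pd.isna(sd) else float(sd),
                    status=str(row["status"]).strip(),
                )
            )
        except (DomainError, ValidationError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise ValidationError(
            f"{source}: {len(problems)} invalid row(s):\n  " + "\n  ".join(problems)
        )
    return runs


def write_print_runs(runs: Sequence[PrintRun], destination: str | Path) -> None:
    """Write print runs back out in the canonical CSV schema."""
    frame = runs_to_frame(runs)
    frame.to_csv(destination, index=False)


def runs_to_frame(runs: Sequence[PrintRun]) -> pd.DataFrame:
    rows = [
        {
            "gauge": run.condition.nozzle.gauge,
            "speed_m_s": run.condition.stage_speed,
            "pressure_1e5Pa": run.condition.gauge_pressure / 1e5,
            "width_um": run.measured_width_mean,
            "width_sd_um": run.measured_width_sd,
            "status": run.status,
        }
        for run in runs
    ]
    return pd.DataFrame(rows, columns=PRINT_RUN_COLUMNS)


def load_reference_print_runs() -> list[PrintRun]:
    """The packaged 3×3×3 Pluronic F-127 (24.5 wt %) measured-width table."""
    return load_print_runs(reference_print_runs_path())


def classify_over_extrusion(width_um: float, nozzle: NozzleSpec) -> bool:
    """True iff a printed width (μm) strictly exceeds the nozzle inner
    diameter — the over-extrusion regime. A width exactly equal to the
    nozzle diameter is, by this strict convention, not over-extruded."""
    if not width_um > 0:
        raise DomainError(f"width must be positive, got {width_um}")
    return um_to_m(width_um) > nozzle.inner_diameter


class ComparisonResult:
    """Results object of a model-vs-measurement comparison.

    Wraps the per-condition rows and the summary metrics: root-mean-square
    error of the width in μm and mean absolute relative error, overall and
    per stage speed.
    """

    def __init__(self, rows: list[ComparisonRow], ink: InkParams):
        if not rows:
            raise DomainError("comparison requires at least one measured run")
        self.rows = rows
        self.ink = ink
        self._frame = pd.DataFrame([vars(r) for r in rows]).sort_values(
            "abscissa", kind="stable", ignore_index=True
        )

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def rmse_um(self) -> float:
        diff = self._frame["predicted_um"] - self._frame["measured_um"]
        return float(np.sqrt(np.mean(diff**2)))

    @property
    def mean_abs_relative_error(self) -> float:
        return float(np.mean(np.abs(self._frame["relative_error"])))

    def by_speed(self) -> pd.DataFrame:
        """RMSE [μm], mean |relative error| and row count per stage speed."""
        def _agg(group: pd.DataFrame) -> pd.Series:
            diff = group["predicted_um"] - group["measured_um"]
            return pd.Series(
                {
                    "rmse_um": float(np.sqrt(np.mean(diff**2))),
                    "mean_abs_rel_err": float(np.mean(np.abs(group["relative_error"]))),
                    "n_runs": int(len(group)),
                }
            )

        grouped = (
            self._frame.groupby("speed_m_s")[
                ["predicted_um", "measured_um", "relative_error"]
            ]
            .apply(_agg)
            .reset_index()
        )
        grouped["n_runs"] = grouped["n_runs"].astype(int)
        return grouped

    def summary(self) -> str:
        lines = [
            f"Model vs measurement: {self.ink.label or 'ink'} "
            f"(n={self.ink.n:g}, eta={self.ink.eta:g} Pa s)",
            "-" * 56,
            f"  conditions compared      {len(self)}",
            f"  RMSE                     {self.rmse_um:.1f} um",
            f"  mean |relative error|    {self.mean_abs_relative_error:.3f}",
            "  per stage speed:",
        ]
        for _, row in self.by_speed().iterrows():
            lines.append(
                f"    v = {row['speed_m_s']:g} m/s : RMSE {row['rmse_um']:.1f} um, "
                f"mean |rel err| {row['mean_abs_rel_err']:.3f} "
                f"({int(row['n_runs'])} runs)"
            )
        return "\n".join(lines)


def compare_runs(
    ink: InkParams,
    runs: Sequence[PrintRun],
    include_discontinuous: bool = True,
) -> ComparisonResult:
    """Score the capillary width model against measured print runs.

    One :class:`ComparisonRow` per run with a measured width; ``not_printed``
    runs are always excluded. Whether discontinuous (droplet/defect) strands
    belong in the comparison is genuinely ambiguous — their widths are
    measurable but violate the continuous-strand assumption — so
    ``include_discontinuous`` exposes the choice; by default they are
    included so the full measured factorial is scored.
    """
    rows: list[ComparisonRow] = []
    for run in runs:
        if not run.measured:
            continue
        if run.status == "discontinuous" and not include_discontinuous:
            continue
        cond = run.condition
        report = predict_width(ink, cond.nozzle, cond.gauge_pressure, cond.stage_speed)
        predicted_um = report.predicted_width_um
        measured_um = run.measured_width_mean
        rows.append(
            ComparisonRow(
                gauge=cond.nozzle.gauge,
                speed_m_s=cond.stage_speed,
                pressure_Pa=cond.gauge_pressure,
                status=run.status,
                measured_um=measured_um,
                predicted_um=predicted_um,
                relative_error=(predicted_um - measured_um) / measured_um,
                abscissa=cond.abscissa,
            )
        )
    if not rows:
        raise DomainError("no runs with a measured width to compare")
    return ComparisonResult(rows, ink)


def enumerate_design(
    nozzles: Sequence[NozzleSpec],
    pressures: Sequence[float],
    speeds: Sequence[float],
) -> list[PrintCondition]:
    """Full-factorial design grid, ordered by (nozzle, speed, pressure)."""
    if not nozzles or not len(pressures) or not len(speeds):
        raise DomainError("design grid requires non-empty nozzle/pressure/speed lists")
    return [
        PrintCondition(nozzle=nozzle, gauge_pressure=float(p), stage_speed=float(v))
        for nozzle in nozzles
        for v in speeds
        for p in pressures
    ]
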