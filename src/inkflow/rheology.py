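"""Power-law (Ostwald–de Waele) rheology: flow curves and log-log fitting.

A shear-thinning hydrogel ink is characterised by the power-law viscosity
model

    η(γ̇) = η₀ · γ̇^(n−1),

with γ̇ the shear rate (1/s), η the apparent viscosity (Pa·s), n the
dimensionless power-law index (n < 1 ⇒ shear thinning) and η₀ the viscosity
at the reference shear rate γ₀ = 1 s⁻¹ (numerically the consistency index in
Pa·sⁿ). Taking logarithms linearises the model,

    log η = (n − 1)·log γ̇ + log η₀,

so n and η₀ are recovered by ordinary least squares of log₁₀ η on log₁₀ γ̇
over a user-chosen shear-rate window. Rheometer exports of apparent
viscosity vs shear rate are the expected input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateFitError, DomainError, ValidationError

__all__ = [
    "FlowCurve",
    "PowerLawFit",
    "InkParams",
    "PowerLawModel",
    "fit_power_law",
    "apparent_viscosity",
    "read_flow_curve",
    "write_fit_report",
]

#: shear-rate column name in delimited flow-curve files
SHEAR_RATE_COLUMN = "shear_rate_1/s"
#: viscosity column name in delimited flow-curve files
VISCOSITY_COLUMN = "viscosity_Pa_s"


@dataclass(frozen=True)
class FlowCurve:
    """Paired shear-rate / apparent-viscosity measurements from a rheometer.

    Measurements are canonically sorted by increasing shear rate on
    construction. Duplicate shear rates are permitted and treated as
    replicate points by the regression.

    Parameters
    ----------
    shear_rate : sequence of float
        Shear rates in 1/s; strictly positive, at least two values.
    viscosity : sequence of float
        Apparent viscosities in Pa·s; strictly positive, same length.
    label : str
        Free-text identifier (ink name, concentration, ...).
    """

    shear_rate: np.ndarray
    viscosity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        gamma = np.asarray(self.shear_rate, dtype=float)
        eta = np.asarray(self.viscosity, dtype=float)
        if gamma.ndim != 1 or eta.ndim != 1:
            raise ValidationError("flow-curve arrays must be one-dimensional")
        if gamma.size != eta.size:
            raise ValidationError(
                f"shear_rate and viscosity lengths differ "
                f"({gamma.size} vs {eta.size})"
            )
        if gamma.size < 2:
            raise ValidationError("a flow curve needs at least two points")
        if not np.all(np.isfinite(gamma)) or not np.all(np.isfinite(eta)):
            raise DomainError("flow-curve values must be finite")
        if np.any(gamma <= 0):
            raise DomainError("all shear rates must be strictly positive")
        if np.any(eta <= 0):
            raise DomainError("all viscosities must be strictly positive")
        order = np.argsort(gamma, kind="stable")
        object.__setattr__(self, "shear_rate", gamma[order])
        object.__setattr__(self, "viscosity", eta[order])

    def __len__(self) -> int:
        return self.shear_rate.size

    def window(self, lo: float, hi: float) -> "FlowCurve":
        """Return the sub-curve with shear rates in the closed interval [lo, hi]."""
        if not (0 < lo < hi):
            raise DomainError(f"window bounds must satisfy 0 < lo < hi, got ({lo}, {hi})")
        mask = (self.shear_rate >= lo) & (self.shear_rate <= hi)
        if mask.sum() < 2:
            raise DegenerateFitError(
                f"window [{lo}, {hi}] leaves {int(mask.sum())} point(s); "
                "at least 2 required"
            )
        return FlowCurve(self.shear_rate[mask], self.viscosity[mask], self.label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {SHEAR_RATE_COLUMN: self.shear_rate, VISCOSITY_COLUMN: self.viscosity}
        )


@dataclass(frozen=True)
class InkParams:
    """The two rheological constants the width prediction consumes.

    ``eta`` is the apparent viscosity (Pa·s) used as a constant in the
    capillary model; under the reference shear rate γ₀ = 1 s⁻¹ it coincides
    with the power-law coefficient η₀.
    """

    n: float
    eta: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.n) and self.n > 0):
            raise DomainError(f"power-law index n must be positive, got {self.n}")
        if not (np.isfinite(self.eta) and self.eta > 0):
            raise DomainError(f"apparent viscosity must be positive, got {self.eta}")

    def viscosity_cp(self) -> float:
        """Apparent viscosity in centipoise."""
        from .units import pa_s_to_cp

        return pa_s_to_cp(self.eta)


@dataclass(frozen=True)
class PowerLawFit:
    """Results object of the log-log power-law regression.

    Attributes
    ----------
    n : float
        Power-law index (slope + 1).
    eta0 : float
        Viscosity at the reference shear rate, Pa·sⁿ (back-transformed
        intercept).
    reference_shear_rate : float
        Fixed to 1 s⁻¹.
    r_squared : float
        Coefficient of determination of the log-log regression.
    window : tuple of float
        (min, max) shear rate actually used.
    n_points : int
        Number of regression points inside the window.
    se_n, se_log10_eta0 : float
        Standard errors of the slope-derived index and of the intercept
        (NaN for a two-point fit).
    label : str
        Carried over from the flow curve.
    """

    n: float
    eta0: float
    r_squared: float
    window: tuple[float, float]
    n_points: int
    reference_shear_rate: float = 1.0
    se_n: float = float("nan")
    se_log10_eta0: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise DomainError(
                f"fitted power-law index n = {self.n} is non-positive; the "
                "capillary model requires n > 0"
            )
        if not self.eta0 > 0:
            raise DomainError(f"fitted eta0 = {self.eta0} is non-positive")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise DomainError(f"R² = {self.r_squared} outside [0, 1]")
        lo, hi = self.window
        if not (0 < lo < hi):
            raise DomainError(f"invalid fit window {self.window}")

    def apparent_viscosity(self, shear_rate: float) -> float:
        """η(γ̇) = η₀ · γ̇^(n−1) at the given shear rate (1/s)."""
        return apparent_viscosity(self, shear_rate)

    def to_ink(self, label: Optional[str] = None) -> InkParams:
        """Collapse the fit into the (n, η) constants the flow model uses."""
        return InkParams(n=self.n, eta=self.eta0, label=label or self.label)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "eta0": self.eta0,
            "reference_shear_rate": self.reference_shear_rate,
            "r_squared": self.r_squared,
            "window": list(self.window),
            "n_points": self.n_points,
        }

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = [
            "Power-law (Ostwald-de Waele) fit" + (f": {self.label}" if self.label else ""),
            "-" * 48,
            f"  model                eta = eta0 * gamma^(n-1)",
            f"  power-law index n    {self.n:.6g}"
            + ("" if math.isnan(self.se_n) else f"  (se {self.se_n:.2g})"),
            f"  eta0 [Pa s^n]        {self.eta0:.6g}",
            f"  reference gamma      {self.reference_shear_rate:g} 1/s",
            f"  R^2 (log-log OLS)    {self.r_squared:.6f}",
            f"  window [1/s]         [{self.window[0]:g}, {self.window[1]:g}]",
            f"  points used          {self.n_points}",
            f"  behaviour            "
            + ("shear-thinning" if self.n < 1 else "Newtonian" if self.n == 1 else "shear-thickening"),
        ]
        return "\n".join(lines)


class PowerLawModel:
    """Power-law viscosity model bound to flow-curve data.

    Mirrors the model/results split common in statistical packages: the
    model holds the data, :meth:`fit` performs the log-log OLS and returns a
    :class:`PowerLawFit`.

    Examples
    --------
    >>> model = PowerLawModel.from_csv("flow_curve.csv")   # doctest: +SKIP
    >>> fit = model.fit(window=(None, 1500.0))             # doctest: +SKIP
    >>> print(fit.summary())                               # doctest: +SKIP
    """

    def __init__(self, curve: FlowCurve):
        self.curve = curve

    @classmethod
    def from_arrays(
        cls, shear_rate: Sequence[float], viscosity: Sequence[float], label: str = ""
    ) -> "PowerLawModel":
        return cls(FlowCurve(np.asarray(shear_rate), np.asarray(viscosity), label))

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label: str = "") -> "PowerLawModel":
        """Build from a DataFrame with the canonical flow-curve columns."""
        missing = {SHEAR_RATE_COLUMN, VISCOSITY_COLUMN} - set(frame.columns)
        if missing:
            raise ValidationError(f"flow-curve frame missing columns: {sorted(missing)}")
        return cls.from_arrays(
            frame[SHEAR_RATE_COLUMN].to_numpy(float),
            frame[VISCOSITY_COLUMN].to_numpy(float),
            label,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PowerLawModel":
        return cls(read_flow_curve(path))

    def fit(self, window: Optional[tuple[Optional[float], Optional[float]]] = None) -> PowerLawFit:
        return fit_power_law(self.curve, window=window)


def fit_power_law(
    curve: FlowCurve,
    window: Optional[tuple[Optional[float], Optional[float]]] = None,
) -> PowerLawFit:
    """Fit η = η₀·γ̇^(n−1) by unweighted OLS of log₁₀ η on log₁₀ γ̇.

    Parameters
    ----------
    curve : FlowCurve
        The measurements.
    window : (lo, hi), optional
        Closed shear-rate interval to fit over; either bound may be None
        (open side). Defaults to the full curve. A window of
        ``(None, 1500.0)`` restricts the fit to the quasi-linear low-to-mid
        shear region typical of cone-plate flow sweeps.

    Returns
    -------
    PowerLawFit
        Slope + 1 is the power-law index n; the back-transformed intercept
        is η₀; ``r_squared`` is the regression R².

    Raises
    ------
    DegenerateFitError
        If fewer than two distinct shear rates remain inside the window.
    """
    gamma = curve.shear_rate
    eta = curve.viscosity
    if window is not None:
        lo = curve.shear_rate[0] if window[0] is None else float(window[0])
        hi = curve.shear_rate[-1] if window[1] is None else float(window[1])
        if not (0 < lo <= hi):
            raise DomainError(f"invalid fit window ({lo}, {hi})")
        mask = (gamma >= lo) & (gamma <= hi)
        gamma, eta = gamma[mask], eta[mask]
    if gamma.size < 2 or np.unique(gamma).size < 2:
        raise DegenerateFitError(
            f"{gamma.size} in-window point(s) with "
            f"{np.unique(gamma).size if gamma.size else 0} distinct shear rate(s); "
            "need at least 2 distinct shear rates"
        )

    x = np.log10(gamma)
    y = np.log10(eta)
    res = stats.linregress(x, y)
    n = res.slope + 1.0
    eta0 = 10.0 ** res.intercept
    # R^2 is undefined for a zero-variance response (Newtonian curve):
    # report 0 by convention; otherwise clamp roundoff into [0, 1]
    rvalue = 0.0 if math.isnan(res.rvalue) else res.rvalue
    r_squared = float(min(max(rvalue**2, 0.0), 1.0))
    return PowerLawFit(
        n=float(n),
        eta0=float(eta0),
        r_squared=r_squared,
        window=(float(gamma[0]), float(gamma[-1])),
        n_points=int(gamma.size),
        se_n=float(res.stderr) if gamma.size > 2 else float("nan"),
        se_log10_eta0=float(res.intercept_stderr) if gamma.size > 2 else float("nan"),
        label=curve.label,
    )


def apparent_viscosity(fit_or_ink: PowerLawFit | InkParams, shear_rate: float) -> float:
    """Evaluate η = η₀ · γ̇^(n−1) for a fit or an ink-parameter set.

    At γ̇ = 1 s⁻¹ this returns η₀ exactly; for a Newtonian fluid (n = 1) it
    is shear-rate independent.
    """
    if not (np.isfinite(shear_rate) and shear_rate > 0):
        raise DomainError(f"shear rate must be positive, got {shear_rate}")
    n = fit_or_ink.n
    eta0 = getattr(fit_or_ink, "eta0", None)
    if eta0 is None:
        eta0 = fit_or_ink.eta
    return float(eta0 * shear_rate ** (n - 1.0))


def read_flow_curve(path: str | Path, label: Optional[str] = None) -> FlowCurve:
    """Read a delimited flow-curve file (comma or tab, auto-sniffed).

    Expects header columns ``shear_rate_1/s`` and ``viscosity_Pa_s``; lines
    starting with ``#`` are ignored.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty flow-curve file") from exc
    missing = {SHEAR_RATE_COLUMN, VISCOSITY_COLUMN} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return FlowCurve(
        frame[SHEAR_RATE_COLUMN].to_numpy(float),
        frame[VISCOSITY_COLUMN].to_numpy(float),
        label if label is not None else path.stem,
    )


def write_fit_report(fit: PowerLawFit, destination: str | Path | IO[str]) -> None:
    """Write a fit report as JSON (fields n, eta0, reference_shear_rate,
    r_squared, window, n_points)."""
    payload = json.dumps(fit.to_dict(), indent=2, sort_keys=True) + "\n"
    if hasattr(destination, "write"):
        destination.write(payload)
    else:
        Path(destination).write_text(payload)
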