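"""Width-vs-D²√ΔP comparison plots.

The capillary model predicts d = k(v̇)·D²√ΔP with slope
k = sqrt((4n/(3n+1))/(32ηLv̇)) per stage speed, so measured and predicted
widths plotted against the collapse abscissa D²√ΔP fall on one straight
line per speed. That is the standard visual check of the model.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .experiment import ComparisonResult
from .flow import rabinowitsch_factor
from .rheology import InkParams
from .units import UM_PER_M


def model_slope(ink: InkParams, nozzle_length: float, stage_speed: float) -> float:
    """Slope k of d = k·(D²√ΔP) at one stage speed, SI units."""
    return math.sqrt(
        1.0 / (32.0 * ink.eta * nozzle_length * stage_speed * rabinowitsch_factor(ink.n))
    )


def plot_comparison(
    result: ComparisonResult,
    nozzle_length: float = 0.005,
    ax: Optional["object"] = None,
):
    """Scatter measured and predicted widths against D²√ΔP, one model line
    per stage speed. Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    frame = result.to_frame()
    for speed, group in frame.groupby("speed_m_s"):
        x = group["abscissa"].to_numpy()
        pts = ax.scatter(x, group["measured_um"], label=f"measured, v = {speed:g} m/s")
        grid = np.linspace(0, frame["abscissa"].max() * 1.05, 50)
        slope = model_slope(result.ink, nozzle_length, speed) * UM_PER_M
        ax.plot(grid, slope * grid, "--", color=pts.get_facecolor()[0],
                label=f"model, v = {speed:g} m/s")
    ax.set_xlabel(r"$D^2\sqrt{\Delta P}$  [m$^2$ Pa$^{1/2}$]")
    ax.set_ylabel(r"line width $d$  [$\mu$m]")
    ax.set_title(result.ink.label or "model vs measurement")
    ax.legend(fontsize=8)
    return ax
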