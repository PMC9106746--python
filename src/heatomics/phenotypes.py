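"""Physiology calculators: turbidostat growth rates, pigment equations,
relative qPCR expression, ROS background subtraction/normalization, and
the shared Welch-t + Benjamini-Hochberg testing utility.

Pigments follow the methanol-extract equations (concentrations in
ug mL-1 from absorbances at 470, 652 and 665 nm):

    chl_total   = 22.12*A652 + 2.71*A665
    chl_a       = 16.29*A665 - 8.54*A652
    chl_b       = 30.66*A652 - 13.58*A665
    carotenoids = (1000*A470 - 2.86*chl_a - 129.2*chl_b) / 221

The coefficients are exactly additive: chl_a + chl_b == chl_total for
every input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, welch_ttest
from .matrices import KineticTrace

__all__ = [
    "GrowthSegment",
    "detect_cycles",
    "PigmentResult",
    "pigments",
    "ddct_fold",
    "ros_fold",
    "welch_bh",
]


@dataclass
class GrowthSegment:
    """One inter-dilution growth segment of a turbidostat OD680 trace."""

    start_h: float
    end_h: float
    slope_per_h: float  # slope of log2(OD680): relative growth rate
    r_squared: float

    @property
    def doubling_time_h(self) -> float | None:
        return 1.0 / self.slope_per_h if self.slope_per_h > 0 else None


def detect_cycles(
    trace: KineticTrace, band: float = 0.08, min_points: int = 3
) -> list[GrowthSegment]:
    """Split an OD680 trace at dilution events and fit log2(OD) per
    segment by least squares.

    A dilution event is a relative drop exceeding half the turbidostat
    band within one sampling step. Returns the fitted segments in time
    order; a trace without a complete segment yields an empty list.
    """
    if np.any(trace.y <= 0):
        raise ValueError("OD trace must be strictly positive")
    rel_drop = 1.0 - trace.y[1:] / trace.y[:-1]
    cut = np.where(rel_drop > band / 2.0)[0] + 1
    bounds = np.concatenate([[0], cut, [trace.y.size]])
    segments = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo < min_points:
            continue
        t = trace.x[lo:hi]
        logod = np.log2(trace.y[lo:hi])
        res = stats.linregress(t, logod)
        segments.append(
            GrowthSegment(
                start_h=float(t[0]),
                end_h=float(t[-1]),
                slope_per_h=float(res.slope),
                r_squared=float(res.rvalue**2),
            )
        )
    if not segments:
        warnings.warn("no complete growth segment in trace")
    return segments


@dataclass
class PigmentResult:
    chl_a: float
    chl_b: float
    chl_total: float
    carotenoids: float
    chl_a_b_ratio: float
    chl_car_ratio: float
    out_of_range: bool
    per_cell: dict | None = None  # pg/cell when a cell density is given


def pigments(
    a470: float, a652: float, a665: float, cells_per_ml: float | None = None
) -> PigmentResult:
    """Evaluate the pigment equations (module docstring) at the measured
    absorbances. Negative concentrations are returned as-is with
    ``out_of_range`` set rather than clipped. With ``cells_per_ml`` the
    per-cell values are reported in pg/cell."""
    chl_a = 16.29 * a665 - 8.54 * a652
    chl_b = 30.66 * a652 - 13.58 * a665
    chl_total = 22.12 * a652 + 2.71 * a665
    car = (1000.0 * a470 - 2.86 * chl_a - 129.2 * chl_b) / 221.0
    per_cell = None
    if cells_per_ml:
        scale = 1e6 / cells_per_ml  # ug/mL -> pg/cell
        per_cell = {
            "chl_a": chl_a * scale,
            "chl_b": chl_b * scale,
            "chl_total": chl_total * scale,
            "carotenoids": car * scale,
        }
    return PigmentResult(
        chl_a=chl_a,
        chl_b=chl_b,
        chl_total=chl_total,
        carotenoids=car,
        chl_a_b_ratio=chl_a / chl_b if chl_b != 0 else float("nan"),
        chl_car_ratio=chl_total / car if car != 0 else float("nan"),
        out_of_range=bool(min(chl_a, chl_b, car) < 0),
        per_cell=per_cell,
    )


def ddct_fold(ct_target: float, ct_ref: float, calibrator_dct: float) -> float:
    """Relative expression by the 2^-ddCT method: the target/reference CT
    difference versus a calibrator sample's dCT."""
    return float(2.0 ** (-((ct_target - ct_ref) - calibrator_dct)))


def ros_fold(
    signal: float,
    ascorbate_signal: float,
    cells_per_ml: float,
    mean_cell_volume: float,
    baseline_per_cell: float,
    baseline_per_volume: float | None = None,
) -> dict:
    """Ascorbate-background-corrected ROS signal normalized per cell and
    per summed cell volume, as fold-change over the (already corrected
    and normalized) baseline."""
    corrected = signal - ascorbate_signal
    per_cell = corrected / cells_per_ml
    per_volume = corrected / (cells_per_ml * mean_cell_volume)
    if baseline_per_cell <= 0:
        raise ValueError("baseline corrected signal must be positive")
    if baseline_per_volume is None:
        baseline_per_volume = baseline_per_cell / mean_cell_volume
    return {
        "corrected": corrected,
        "per_cell": per_cell,
        "per_volume": per_volume,
        "fold_per_cell": per_cell / baseline_per_cell,
        "fold_per_volume": per_volume / baseline_per_volume,
        "negative_corrected": corrected < 0,
    }


def welch_bh(groups_a, groups_b, labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """Two-tailed Welch t-test per measurement with BH correction across
    the family; both raw and adjusted p are reported and the significance
    flag uses the adjusted value."""
    if labels is None:
        labels = [f"m{i}" for i in range(len(groups_a))]
    rows = []
    for lab, a, b in zip(labels, groups_a, groups_b):
        t, p = welch_ttest(a, b)
        rows.append({"measurement": lab, "t": t, "p": p})
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["fdr"] < alpha
    return table
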