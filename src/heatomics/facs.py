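"""FACS DNA-content histogram analysis with cell-size-dependent
background correction and power-of-two ploidy assignment.

Chlamydomonas divides by multiple fission, so DNA-content histograms show
peaks at 1C, 2C, 4C, ... The raw fluorescence of a peak is background +
ploidy * unit_signal, where the background staining scales with cell
size; subtracting it restores the doubling series (e.g. raw peaks at
3, 5.5 and 10 x 1e5 with background 0.5 x 1e5 correct to 2.5, 5 and
9.5 x 1e5 for 1C/2C/4C).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy.signal import find_peaks as _scipy_find_peaks

from .matrices import KineticTrace

__all__ = [
    "find_peaks",
    "correct_background",
    "assign_ploidy",
    "estimate_background",
    "calibrate_background_coefficient",
    "PloidyCall",
    "call_ploidy",
]

RATIO_WINDOW = (1.7, 2.3)


def find_peaks(
    trace: KineticTrace,
    min_prominence: float | None = None,
    smooth_window: int = 5,
) -> np.ndarray:
    """Histogram modes after moving-average smoothing, ranked by
    prominence and returned in increasing signal order.

    ``trace`` is a ``facs_hist`` histogram (x = bin centers on log-spaced
    bins, y = cell counts). Default prominence is 2% of the maximum
    smoothed count. Raises when no peak is found (e.g. flat histogram).
    """
    kernel = np.ones(smooth_window)
    # edge-corrected moving average: a flat histogram stays flat
    y = np.convolve(trace.y, kernel, mode="same") / np.convolve(
        np.ones_like(trace.y), kernel, mode="same"
    )
    if min_prominence is None:
        min_prominence = 0.02 * y.max()
    idx, props = _scipy_find_peaks(y, prominence=min_prominence)
    if idx.size == 0:
        raise ValueError("no peaks found in histogram")
    order = np.argsort(props["prominences"])[::-1]
    return np.sort(trace.x[idx[order]])


def correct_background(raw_peaks, background: float) -> np.ndarray:
    """Subtract the (cell-size-dependent) background staining signal from
    every raw peak position; a background exceeding a peak is an error."""
    if background < 0:
        raise ValueError("background must be non-negative")
    raw = np.asarray(raw_peaks, dtype=float)
    corrected = raw - background
    if (corrected < 0).any():
        raise ValueError("background exceeds a peak position")
    return corrected


def assign_ploidy(corrected_positions) -> list[str | None]:
    """Label corrected peaks as 1C, 2C, 4C, ... by nearest power-of-two
    ratio to the smallest (1C) peak.

    A peak whose ratio to the previous power-of-two class falls outside
    [1.7, 2.3] stays unlabeled (None).
    """
    pos = np.sort(np.asarray(corrected_positions, dtype=float))
    if pos.size == 0:
        raise ValueError("need at least one corrected peak")
    labels: list[str | None] = ["1C"]
    base = pos[0]
    for p in pos[1:]:
        ratio = p / base
        k = int(round(np.log2(ratio))) if ratio > 0 else 0
        if k < 1:
            labels.append(None)
            continue
        step = ratio / 2 ** (k - 1)  # ratio to the previous doubling class
        if RATIO_WINDOW[0] <= step <= RATIO_WINDOW[1]:
            labels.append(f"{2**k}C")
        else:
            labels.append(None)
    return labels


def calibrate_background_coefficient(
    reference_volume: float, reference_background: float
) -> float:
    """kappa such that background = kappa * mean cell volume, calibrated
    on a reference (pre-heat) sample with known background."""
    if reference_volume <= 0:
        raise ValueError("reference volume must be positive")
    return reference_background / reference_volume


def estimate_background(mean_cell_volume: float, kappa: float) -> float:
    """Volume-proportional background staining model."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if mean_cell_volume < 0:
        raise ValueError("volume must be non-negative")
    return kappa * mean_cell_volume


@dataclass
class PloidyCall:
    raw_peaks: np.ndarray = field(repr=False)
    background: float = 0.0
    corrected_peaks: np.ndarray = field(repr=False, default=None)
    labels: list = field(default_factory=list)
    fractions: pd.Series = field(repr=False, default=None)


def call_ploidy(
    trace: KineticTrace,
    background: float,
    min_prominence: float | None = None,
) -> PloidyCall:
    """End-to-end histogram call: peak finding, background correction,
    ploidy labels, and per-label population fractions.

    Fractions assign every histogram bin to the nearest raw peak in log
    space, so they sum to 1 over the labeled plus unlabeled peaks.
    """
    raw = find_peaks(trace, min_prominence=min_prominence)
    corrected = correct_background(raw, background)
    labels = assign_ploidy(corrected)
    logx = np.log(trace.x)
    logp = np.log(raw)
    nearest = np.argmin(np.abs(logx[:, None] - logp[None, :]), axis=1)
    total = trace.y.sum()
    frac = pd.Series(
        [trace.y[nearest == i].sum() / total for i in range(raw.size)],
        index=[lab if lab is not None else f"peak{i}" for i, lab in enumerate(labels)],
    )
    return PloidyCall(
        raw_peaks=raw,
        background=background,
        corrected_peaks=corrected,
        labels=labels,
        fractions=frac,
    )
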