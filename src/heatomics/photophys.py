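"""Photophysiology calculators: chlorophyll-fluorescence parameters,
electrochromic-shift (ECS) dark-interval relaxation, P700 re-reduction
kinetics, 77 K emission-spectrum antenna fractions, and oxygen-electrode
rates.

Fluorescence parameters use the standard pulse-amplitude definitions:
Fv/Fm = (Fm - Fo)/Fm, PhiPSII = (Fm' - Fs)/Fm', NPQ = (Fm - Fm')/Fm',
qL = ((Fm' - Fs)/(Fm' - Fo')) * (Fo'/Fs), QA redox (fraction reduced)
= 1 - qL, and a relative linear electron flow LEF = I * PhiPSII *
psii_fraction (no absorptance calibration; units follow the light
intensity I in umol photons m-2 s-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .matrices import KineticTrace

__all__ = [
    "FluorescenceLevels",
    "fluorescence_params",
    "ExpFit",
    "fit_exponential_decay",
    "dirk_ecs",
    "p700_tau",
    "psii_fraction_77k",
    "o2_rates",
]


@dataclass
class FluorescenceLevels:
    """Dark-adapted (Fo, Fm) and light-adapted (Fs, Fm', Fo') levels at
    actinic intensity ``light`` (umol photons m-2 s-1)."""

    fo: float
    fm: float
    fs: float | None = None
    fm_prime: float | None = None
    fo_prime: float | None = None
    light: float | None = None

    def __post_init__(self):
        if not (self.fm >= self.fo > 0):
            raise ValueError("need Fm >= Fo > 0")
        if self.fs is not None and self.fm_prime is not None:
            if not (self.fm_prime >= self.fs > 0):
                raise ValueError("need Fm' >= Fs > 0")


def fluorescence_params(levels: FluorescenceLevels, psii_fraction: float = 1.0) -> dict:
    """Compute Fv/Fm, PhiPSII, NPQ, qL, QA redox state and relative LEF.

    An Fm' exceeding the dark-adapted Fm is a measurement anomaly; the
    values are still computed and ``anomaly`` is flagged.
    """
    out = {
        "fv_fm": (levels.fm - levels.fo) / levels.fm,
        "phi_psii": np.nan,
        "npq": np.nan,
        "qL": np.nan,
        "qa_redox": np.nan,
        "lef": np.nan,
        "anomaly": False,
    }
    if levels.fs is None or levels.fm_prime is None:
        return out
    if levels.fm_prime > levels.fm:
        warnings.warn("Fm' exceeds dark-adapted Fm; flagged as anomaly")
        out["anomaly"] = True
    out["phi_psii"] = (levels.fm_prime - levels.fs) / levels.fm_prime
    out["npq"] = (levels.fm - levels.fm_prime) / levels.fm_prime
    if levels.fo_prime is not None and levels.fm_prime != levels.fo_prime:
        out["qL"] = (
            (levels.fm_prime - levels.fs)
            / (levels.fm_prime - levels.fo_prime)
            * (levels.fo_prime / levels.fs)
        )
        out["qa_redox"] = 1.0 - out["qL"]
    if levels.light is not None:
        out["lef"] = levels.light * out["phi_psii"] * psii_fraction
    return out


@dataclass
class ExpFit:
    amplitude: float
    tau_s: float
    offset: float
    residual_rms: float
    at_bound: bool = False
    misfit: bool = False


_TAU_BOUNDS = (1e-5, 100.0)


def fit_exponential_decay(
    t: np.ndarray, y: np.ndarray, noise_floor: float | None = None
) -> ExpFit:
    """Least-squares fit of A*exp(-t/tau) + c with log-linear
    initialization and tau bounded to (1e-5, 100) s.

    ``noise_floor`` (estimated from first differences when omitted) sets
    the misfit flag when the residual rms exceeds three times it, e.g.
    for multi-exponential input forced through a single exponential.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    t0 = t - t[0]
    c0 = y[-1]
    a0 = y[0] - c0
    if abs(a0) < 1e-12 or np.allclose(y, y[0]):
        raise ValueError("trace does not decay; cannot fit an exponential")
    # log-linear initial tau from the early part of the decay
    z = (y - c0) / a0
    ok = z > 0.05
    tau0 = max(
        -1.0
        / np.polyfit(t0[ok], np.log(z[ok]), 1)[0]
        if ok.sum() >= 2
        else (t0[-1] - t0[0]) / 3.0,
        _TAU_BOUNDS[0] * 10,
    )

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    popt, _ = curve_fit(
        model,
        t0,
        y,
        p0=[a0, min(tau0, _TAU_BOUNDS[1] / 2), c0],
        bounds=([-np.inf, _TAU_BOUNDS[0], -np.inf], [np.inf, _TAU_BOUNDS[1], np.inf]),
        maxfev=20000,
    )
    resid = y - model(t0, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if noise_floor is None:
        noise_floor = float(np.std(np.diff(y)) / np.sqrt(2.0))
    tau = float(popt[1])
    at_bound = bool(
        np.isclose(tau, _TAU_BOUNDS[0], rtol=1e-3)
        or np.isclose(tau, _TAU_BOUNDS[1], rtol=1e-3)
    )
    if at_bound:
        warnings.warn("fitted tau hit an optimizer bound")
    return ExpFit(
        amplitude=float(popt[0]),
        tau_s=tau,
        offset=float(popt[2]),
        residual_rms=rms,
        at_bound=at_bound,
        misfit=bool(rms > 3.0 * max(noise_floor, 1e-12)),
    )


def dirk_ecs(trace: KineticTrace, dark_start_s: float | None = None) -> dict:
    """ECS dark-interval relaxation: fit the post light-off decay with a
    first-order exponential. Returns ECSt (amplitude, a proxy for the
    proton motive force) and the proton conductivity 1/tau (s-1)."""
    if dark_start_s is None:
        dark_start_s = trace.meta.get("dark_start_s")
    if dark_start_s is None:
        raise ValueError("light->dark transition not marked in trace")
    sel = trace.x >= dark_start_s
    fit = fit_exponential_decay(trace.x[sel], trace.y[sel])
    return {
        "ecst": abs(fit.amplitude),
        "tau_s": fit.tau_s,
        "proton_conductivity": 1.0 / fit.tau_s,
        "fit": fit,
    }


def p700_tau(traces, far_red_off_s: float | None = None) -> ExpFit:
    """P700+ dark re-reduction time constant (cyclic electron flow
    proxy; smaller tau = faster reduction).

    ``traces`` is one KineticTrace or a sequence of replicate traces on a
    common time base, which are averaged before fitting the reduction
    phase (t >= far-red off) with A*exp(-t/tau) + c.
    """
    if isinstance(traces, KineticTrace):
        traces = [traces]
    x = traces[0].x
    for tr in traces[1:]:
        if not np.array_equal(tr.x, x):
            raise ValueError("replicate traces need a common time base")
    y = np.mean([tr.y for tr in traces], axis=0)
    if far_red_off_s is None:
        far_red_off_s = traces[0].meta.get("far_red_off_s", x[0])
    sel = x >= far_red_off_s
    return fit_exponential_decay(x[sel], y[sel])


def psii_fraction_77k(
    trace: KineticTrace,
    psii_nm: float = 686.0,
    psi_window_nm: tuple = (705.0, 725.0),
) -> dict:
    """Relative PSII antenna fraction from a 77 K emission spectrum.

    The spectrum is normalized to its value at 686 nm (PSII peak); the
    PSI peak is the maximum in the 705-725 nm search window (nominally
    714 nm, allowing for the blue shift seen in heat-treated cells).
    PSII% = P686 / (P686 + P_PSI) with P686 = 1 after normalization.
    """
    if trace.x.min() > 650.0 or trace.x.max() < 750.0:
        raise ValueError("spectrum must cover 650-750 nm")
    p686 = float(np.interp(psii_nm, trace.x, trace.y))
    if p686 <= 0:
        raise ValueError("non-positive signal at 686 nm")
    norm = trace.y / p686
    sel = (trace.x >= psi_window_nm[0]) & (trace.x <= psi_window_nm[1])
    p_psi = float(np.max(norm[sel]))
    psi_nm = float(trace.x[sel][np.argmax(norm[sel])])
    return {
        "psii_percent": 100.0 / (1.0 + p_psi),
        "psi_peak_nm": psi_nm,
        "psi_peak_norm": p_psi,
    }


def o2_rates(net_light_slope: float, dark_slope: float) -> dict:
    """Oxygen-electrode rates: respiration is the magnitude of the dark
    slope and gross evolution is net + respiration (same units as the
    inputs, e.g. umol O2 mL-1 h-1)."""
    respiration = abs(dark_slope)
    return {
        "net": net_light_slope,
        "respiration": respiration,
        "gross": net_light_slope + respiration,
    }
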