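"""Transcript-protein coupling: fold-changes versus pre-heat, phase
windows, per-functional-term Pearson correlation, and kernel-density
summaries of the correlation distribution.

The heat (HS) and recovery (RE) periods are split into three windows
each: HS1 = heat 0-1 h, HS2 = 2-8 h, HS3 = 16-24 h; RE1 = recovery
0-2 h, RE2 = 4-8 h, RE3 = 24-48 h. Per window every gene with both a
transcript and a protein measurement contributes one fold-change pair;
collecting the pairs of a functional term gives that term's Pearson r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import TimeCourseDesign

__all__ = [
    "WindowSpec",
    "DEFAULT_WINDOWS",
    "log2fc_vs_preheat",
    "window_average",
    "term_correlations",
    "correlation_density",
    "silverman_bandwidth",
    "global_scatter",
]


@dataclass(frozen=True)
class WindowSpec:
    window_id: str
    phase: str
    times_h: tuple

    def keys(self):
        return [(self.phase, t) for t in self.times_h]


DEFAULT_WINDOWS = (
    WindowSpec("HS1", "heat", (0.0, 0.5, 1.0)),
    WindowSpec("HS2", "heat", (2.0, 4.0, 8.0)),
    WindowSpec("HS3", "heat", (16.0, 24.0)),
    WindowSpec("RE1", "recovery", (0.0, 2.0)),
    WindowSpec("RE2", "recovery", (4.0, 8.0)),
    WindowSpec("RE3", "recovery", (24.0, 48.0)),
)


def log2fc_vs_preheat(
    values: pd.DataFrame,
    design: TimeCourseDesign,
    treatment: str,
    offset: float = 0.0,
) -> pd.DataFrame:
    """Per-entity log2(group mean / pre-heat mean) for every time point.

    ``values`` is entities x samples on the measurement scale (TPM or
    normalized intensity); ``offset`` is added to both means before the
    ratio (use 0.01 for TPM so zero pre-heat means stay defined).
    """
    pre_cols = [
        s for s in design.samples_for(treatment, "pre_heat", 0.0) if s in values.columns
    ]
    if not pre_cols:
        raise ValueError(f"no pre-heat samples for {treatment}")
    base = values[pre_cols].mean(axis=1) + offset
    if (base <= 0).any():
        bad = base.index[base <= 0][:5].tolist()
        raise ValueError(
            f"non-positive pre-heat means (e.g. {bad}); supply a positive offset"
        )
    out = {}
    for tr, ph, t in design.group_keys(treatment):
        if ph == "pre_heat":
            continue
        cols = [s for s in design.samples_for(tr, ph, t) if s in values.columns]
        if not cols:
            continue
        out[(ph, t)] = np.log2((values[cols].mean(axis=1) + offset) / base)
    fc = pd.DataFrame(out)
    fc.columns = pd.MultiIndex.from_tuples(fc.columns, names=["phase", "time_h"])
    return fc


def window_average(fcs: pd.DataFrame, windows=DEFAULT_WINDOWS) -> pd.DataFrame:
    """Arithmetic mean fold-change per entity per window; windows with no
    matching time point are dropped with a warning."""
    cols = {}
    for w in windows:
        present = [k for k in w.keys() if k in fcs.columns]
        if not present:
            warnings.warn(f"window {w.window_id} has no data; dropped")
            continue
        cols[w.window_id] = fcs[present].mean(axis=1)
    return pd.DataFrame(cols)


def _pairs(transcript_windows, protein_windows, entities=None):
    shared = transcript_windows.index.intersection(protein_windows.index)
    if entities is not None:
        shared = shared.intersection(pd.Index(list(entities)))
    return shared


def term_correlations(
    transcript_windows: pd.DataFrame,
    protein_windows: pd.DataFrame,
    ontology,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson r between transcript and protein window fold-changes for
    every tree-expanded functional term and window; terms with fewer than
    ``min_pairs`` pairs are suppressed."""
    shared = _pairs(transcript_windows, protein_windows)
    term_members: dict[str, list] = {}
    for ent in shared:
        for term in ontology.expanded(ent):
            term_members.setdefault(term, []).append(ent)
    windows = [w for w in transcript_windows.columns if w in protein_windows.columns]
    rows = []
    for term in sorted(term_members):
        members = term_members[term]
        if len(members) < min_pairs:
            continue
        tw = transcript_windows.loc[members]
        pw = protein_windows.loc[members]
        for w in windows:
            x, y = tw[w].to_numpy(float), pw[w].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_pairs or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            rows.append({"term_id": term, "window": w, "r": r, "n_pairs": int(ok.sum())})
    return pd.DataFrame(rows, columns=["term_id", "window", "r", "n_pairs"])


def silverman_bandwidth(values) -> float:
    """Silverman's rule of thumb: h = 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need >= 2 values for a density estimate")
    sd = np.std(v, ddof=1)
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-0.2)
    if h <= 0:
        warnings.warn("zero spread; bandwidth floored at 1e-3")
        h = 1e-3
    return float(h)


def correlation_density(
    r_values, grid=None, bandwidth: float | None = None
) -> pd.DataFrame:
    """Gaussian KDE of term correlation coefficients with Silverman
    bandwidth, evaluated on ``grid`` (default 513 points on [-1, 1])."""
    v = np.asarray(r_values, dtype=float)
    h = silverman_bandwidth(v) if bandwidth is None else float(bandwidth)
    if grid is None:
        grid = np.linspace(-1.0, 1.0, 513)
    grid = np.asarray(grid, dtype=float)
    dens = np.mean(
        stats.norm.pdf((grid[:, None] - v[None, :]) / h), axis=1
    ) / h
    return pd.DataFrame({"r": grid, "density": dens})


def global_scatter(
    transcript_windows: pd.DataFrame,
    protein_windows: pd.DataFrame,
    window: str,
    term_table: pd.DataFrame | None = None,
) -> dict:
    """All-pairs Pearson r, OLS fit (protein fc on transcript fc) and the
    top-correlated functional term for one window."""
    shared = _pairs(transcript_windows, protein_windows)
    x = transcript_windows.loc[shared, window].to_numpy(float)
    y = protein_windows.loc[shared, window].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 transcript-protein pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance in fold-change pairs")
    res = stats.linregress(x, y)
    out = {
        "window": window,
        "r": float(res.rvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "n_pairs": int(x.size),
        "top_term": None,
        "top_term_r": float("nan"),
    }
    if term_table is not None and len(term_table):
        sub = term_table[term_table["window"] == window]
        if len(sub):
            best = sub.loc[sub["r"].idxmax()]
            out["top_term"] = str(best["term_id"])
            out["top_term_r"] = float(best["r"])
    return out
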