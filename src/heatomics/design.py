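"""Sample design for photobioreactor heat time courses.

Every sample maps to a treatment (constant 25 degC control, moderate 35 degC
heat, or acute 40 degC heat), an experimental phase (pre_heat, heat,
recovery), a time in hours within the phase, and a biological replicate.
The default grid is one pre-heat point, eight heat points (reaching
temperature = 0 h, then 0.5, 1, 2, 4, 8, 16, 24 h) and six recovery points
(reaching 25 degC = 0 h, then 2, 4, 8, 24, 48 h), with three biological
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TREATMENTS = ("ctrl25", "heat35", "heat40")
PHASES = ("pre_heat", "heat", "recovery")
PHASE_ORDER = {"pre_heat": 0, "heat": 1, "recovery": 2}

HEAT_TIMES_H = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0)
RECOVERY_TIMES_H = (0.0, 2.0, 4.0, 8.0, 24.0, 48.0)

DESIGN_COLUMNS = ("sample_id", "treatment", "phase", "time_h", "replicate")


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class TimeCourseDesign:
    """Validated sample sheet; ``table`` has the DESIGN_COLUMNS layout."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        t = self.table
        missing = set(DESIGN_COLUMNS) - set(t.columns)
        if missing:
            raise DesignError(f"design table missing columns: {sorted(missing)}")
        if len(t) == 0:
            raise DesignError("design table is empty")
        bad_tr = set(t["treatment"]) - set(TREATMENTS)
        if bad_tr:
            raise DesignError(f"unknown treatment labels: {sorted(bad_tr)}")
        bad_ph = set(t["phase"]) - set(PHASES)
        if bad_ph:
            raise DesignError(f"unknown phase labels: {sorted(bad_ph)}")
        if (t["time_h"] < 0).any():
            bad = t.loc[t["time_h"] < 0, "sample_id"].tolist()
            raise DesignError(f"negative time_h for samples: {bad}")
        if (t["replicate"] < 1).any():
            raise DesignError("replicate indices must be positive integers")
        key = t[["treatment", "phase", "time_h", "replicate"]]
        if key.duplicated().any():
            dup = t.loc[key.duplicated(), "sample_id"].tolist()
            raise DesignError(f"duplicate (treatment, phase, time, replicate): {dup}")
        if t["sample_id"].duplicated().any():
            raise DesignError("duplicate sample ids")
        for tr, sub in t.groupby("treatment"):
            if "pre_heat" not in set(sub["phase"]):
                raise DesignError(f"treatment {tr} has no pre_heat entry")
            for ph in ("heat", "recovery"):
                times = sorted(set(sub.loc[sub["phase"] == ph, "time_h"]))
                if times != sorted(times):
                    raise DesignError(f"{tr}/{ph} time grid is not increasing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def groups(self) -> pd.core.groupby.DataFrameGroupBy:
        """Replicate groups keyed by (treatment, phase, time_h)."""
        return self.table.groupby(["treatment", "phase", "time_h"], sort=True)

    def group_keys(self, treatment: str | None = None) -> list[tuple]:
        keys = []
        for (tr, ph, t), _ in self.groups():
            if treatment is None or tr == treatment:
                keys.append((tr, ph, t))
        keys.sort(key=lambda k: (k[0], PHASE_ORDER[k[1]], k[2]))
        return keys

    def samples_for(self, treatment: str, phase: str, time_h: float) -> list[str]:
        t = self.table
        sel = (
            (t["treatment"] == treatment)
            & (t["phase"] == phase)
            & (t["time_h"] == time_h)
        )
        return list(t.loc[sel, "sample_id"])

    def subset(self, sample_ids) -> "TimeCourseDesign":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return TimeCourseDesign(keep.reset_index(drop=True))

    def treatment_subset(self, treatments) -> "TimeCourseDesign":
        keep = self.table[self.table["treatment"].isin(set(treatments))]
        return TimeCourseDesign(keep.reset_index(drop=True))


def default_design(
    treatments=TREATMENTS,
    n_replicates: int = 3,
    heat_times=HEAT_TIMES_H,
    recovery_times=RECOVERY_TIMES_H,
) -> TimeCourseDesign:
    """The built-in photobioreactor grid: 15 time points per treatment
    (1 pre-heat + 8 heat + 6 recovery), three replicates by default.

    The 25 degC control is sampled on the same grid (its "heat" phase is a
    mock shift at constant temperature) so that every time point has a
    contemporaneous control.
    """
    rows = []
    for tr in treatments:
        points = [("pre_heat", 0.0)]
        points += [("heat", t) for t in heat_times]
        points += [("recovery", t) for t in recovery_times]
        for ph, t in points:
            for r in range(1, n_replicates + 1):
                sid = f"{tr}_{ph}_{t:g}h_r{r}"
                rows.append((sid, tr, ph, float(t), r))
    return TimeCourseDesign(pd.DataFrame(rows, columns=list(DESIGN_COLUMNS)))


def read_design(path) -> TimeCourseDesign:
    """Read a TSV sample sheet with DESIGN_COLUMNS and validate it."""
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise DesignError(f"design file {path} is empty") from exc
    if len(table) == 0:
        raise DesignError(f"design file {path} contains no samples")
    table["time_h"] = table["time_h"].astype(float)
    table["replicate"] = table["replicate"].astype(int)
    table["sample_id"] = table["sample_id"].astype(str)
    return TimeCourseDesign(table.reset_index(drop=True))


def write_design(design: TimeCourseDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)
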