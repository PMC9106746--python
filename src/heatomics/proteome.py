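"""Proteome stage: median-of-ratios normalization, replicate-support
filtering, kNN + Gaussian missing-value imputation, and Dunnett testing
of each time point against the pre-heat control.

Imputation operates on log2 intensities and distinguishes three cases per
protein and replicate group:

1. the group has at least one observed value: missing replicates are drawn
   from Normal(group mean, global sd);
2. the group is wholly missing but an adjacent time point (previous/next
   grid point, pre-heat adjacent to heat 0 h) has values: the group mean is
   borrowed by k-nearest-neighbour matching on protein time profiles, then
   replicates are sampled as in (1);
3. the group and both adjacent groups are empty: the cells stay missing.

The "global sd" is the pooled within-group standard deviation of log2
intensities across all proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, dunnett_adjusted_pvalues, dunnett_adjusted_pvalues_mc
from .design import PHASE_ORDER, TimeCourseDesign
from .matrices import ProteomeMatrix

__all__ = [
    "normalize_median_of_ratios",
    "filter_replicate_support",
    "impute",
    "dunnett_test",
    "ImputationReport",
]


def normalize_median_of_ratios(matrix: ProteomeMatrix):
    """DESeq-style size factors from rows observed in every sample.

    The reference is the per-protein geometric mean over samples; each
    sample's factor is the median ratio of its intensities to the
    reference over complete rows, and every column is divided by its
    factor. Returns (normalized matrix, size factor Series).
    """
    vals = matrix.intensities
    complete = vals.dropna(axis=0)
    if complete.empty:
        raise ValueError(
            "median-of-ratios needs at least one protein observed in all "
            "samples; filter the matrix first"
        )
    ref = np.exp(np.log(complete).mean(axis=1))
    factors = (complete.div(ref, axis=0)).median(axis=0)
    normalized = vals.div(factors, axis=1)
    out = ProteomeMatrix(
        normalized, matrix.proteotypic.copy(), matrix.imputed_mask.copy()
    )
    return out, factors.rename("size_factor")


def filter_replicate_support(
    matrix: ProteomeMatrix, design: TimeCourseDesign
) -> ProteomeMatrix:
    """Drop proteins for which no (treatment, phase, time) replicate group
    has more than one observed value."""
    observed = ~matrix.intensities.isna()
    support = pd.Series(False, index=matrix.intensities.index)
    for (_, _, _), sub in design.groups():
        cols = [s for s in sub["sample_id"] if s in observed.columns]
        if cols:
            support |= observed[cols].sum(axis=1) >= 2
    keep = support[support].index
    return ProteomeMatrix(
        matrix.intensities.loc[keep],
        matrix.proteotypic.loc[keep],
        matrix.imputed_mask.loc[keep],
    )


@dataclass
class ImputationReport:
    """Per-protein per-group imputation bookkeeping.

    ``status`` holds 'observed', 'partial_imputed', 'knn_imputed' or
    'left_missing' per (protein, group); ``neighbors`` lists donor protein
    ids for kNN-imputed groups; ``global_sd`` is the pooled log2 sd used
    for sampling.
    """

    status: pd.DataFrame = field(repr=False)
    neighbors: dict = field(repr=False)
    global_sd: float = float("nan")

    def counts(self) -> pd.Series:
        return self.status.stack().value_counts()


def _group_columns(design: TimeCourseDesign, sample_ids) -> dict[tuple, list[str]]:
    cols = {}
    universe = set(sample_ids)
    for (tr, ph, t), sub in design.groups():
        members = [s for s in sub["sample_id"] if s in universe]
        if members:
            cols[(tr, ph, t)] = members
    return cols


def _ordered_groups(group_cols) -> dict[str, list[tuple]]:
    """Groups per treatment in phase/time order (pre_heat, heat, recovery)."""
    per_tr: dict[str, list[tuple]] = {}
    for key in group_cols:
        per_tr.setdefault(key[0], []).append(key)
    for tr in per_tr:
        per_tr[tr].sort(key=lambda k: (PHASE_ORDER[k[1]], k[2]))
    return per_tr


def pooled_group_sd(log2_vals: pd.DataFrame, group_cols) -> float:
    """Pooled within-group sd of log2 intensities across all proteins."""
    ss, dof = 0.0, 0
    for cols in group_cols.values():
        sub = log2_vals[cols]
        n = sub.notna().sum(axis=1)
        dev = sub.sub(sub.mean(axis=1), axis=0) ** 2
        ss += dev.sum(axis=1).sum()
        dof += int((n - 1).clip(lower=0).sum())
    return float(np.sqrt(ss / dof)) if dof > 0 else float("nan")


def impute(
    matrix: ProteomeMatrix,
    design: TimeCourseDesign,
    k: int = 3,
    seed: int = 0,
    global_sd: float | None = None,
):
    """Impute missing intensities; see the module docstring for the rules.

    Returns (ProteomeMatrix with imputed cells flagged, ImputationReport).
    Observed cells are never altered. Neighbour search for rule (2) is a
    Euclidean match on shared observed group-mean profiles, restricted to
    proteins observed at the query group.
    """
    rng = np.random.default_rng(seed)
    vals = matrix.intensities.copy()
    log2v = np.log2(vals)
    group_cols = _group_columns(design, vals.columns)
    keys = list(group_cols)
    means = pd.DataFrame(
        {key: log2v[cols].mean(axis=1) for key, cols in group_cols.items()}
    )
    sd = pooled_group_sd(log2v, group_cols) if global_sd is None else float(global_sd)
    per_tr = _ordered_groups(group_cols)

    status = pd.DataFrame("observed", index=vals.index, columns=pd.Index(keys))
    neighbors: dict = {}
    imputed_mask = matrix.imputed_mask.copy()
    n_obs = pd.DataFrame(
        {key: log2v[cols].notna().sum(axis=1) for key, cols in group_cols.items()}
    )

    filled_means = means.copy()
    for tr, ordered in per_tr.items():
        for gi, key in enumerate(ordered):
            cols = group_cols[key]
            empty = n_obs[key] == 0
            partial = (~empty) & (n_obs[key] < len(cols))
            status.loc[partial, key] = "partial_imputed"
            adjacent = []
            if gi > 0:
                adjacent.append(ordered[gi - 1])
            if gi + 1 < len(ordered):
                adjacent.append(ordered[gi + 1])
            adj_has = pd.Series(False, index=vals.index)
            for akey in adjacent:
                adj_has |= n_obs[akey] > 0
            status.loc[empty & adj_has, key] = "knn_imputed"
            status.loc[empty & ~adj_has, key] = "left_missing"

            # rule (2): borrow the group mean from profile neighbours.
            # Distances and the borrowed value are offset-adjusted (each
            # profile centred on the shared groups) so a neighbour's
            # abundance level does not leak into the imputed mean.
            queries = vals.index[empty & adj_has]
            if len(queries):
                donors = vals.index[n_obs[key] > 0]
                donor_prof = means.loc[donors]
                for prot in queries:
                    prof = means.loc[prot]
                    shared = prof.notna() & donor_prof.notna()
                    offset = (donor_prof - prof).where(shared).mean(axis=1)
                    centered = (donor_prof.sub(offset, axis=0) - prof).where(shared)
                    dist = (centered**2).mean(axis=1).dropna()
                    kk = min(k, len(dist))
                    if kk == 0:
                        status.loc[prot, key] = "left_missing"
                        continue
                    if kk < k:
                        warnings.warn(
                            f"kNN pool for {prot} at {key} reduced to {kk}",
                            stacklevel=2,
                        )
                    best = dist.nsmallest(kk).index
                    neighbors[(prot, key)] = list(best)
                    filled_means.loc[prot, key] = (
                        means.loc[best, key] - offset.loc[best]
                    ).mean()

    # sample missing replicates from Normal(group mean, global sd)
    for key in keys:
        cols = group_cols[key]
        gmean = filled_means[key]
        for col in cols:
            missing = vals[col].isna() & gmean.notna()
            if missing.any():
                draw = rng.normal(gmean[missing], 0.0 if np.isnan(sd) else sd)
                vals.loc[missing, col] = np.exp2(draw)
                imputed_mask.loc[missing, col] = True

    report = ImputationReport(status=status, neighbors=neighbors, global_sd=sd)
    out = ProteomeMatrix(vals, matrix.proteotypic.copy(), imputed_mask)
    return out, report


def dunnett_test(
    matrix: ProteomeMatrix,
    design: TimeCourseDesign,
    treatment: str,
    alphas=(0.05, 0.01),
    require_proteotypic: bool = True,
    exclude_imputed: bool = True,
    mc_seed: int = 0,
) -> pd.DataFrame:
    """Dunnett many-to-one comparisons of each time point against the
    pre-heat control on log2 intensities.

    Proteins from ambiguous (non-proteotypic) peptides or with any missing
    replicate in the tested groups are excluded. Balanced designs use the
    exact equicorrelated multivariate-t adjustment; unbalanced ones fall
    back to a seeded Monte-Carlo evaluation.
    """
    group_cols = _group_columns(design, matrix.intensities.columns)
    ordered = _ordered_groups(group_cols).get(treatment, [])
    ctrl_key = next((kk for kk in ordered if kk[1] == "pre_heat"), None)
    if ctrl_key is None:
        raise ValueError(f"no pre-heat control group for treatment {treatment}")
    ctrl_cols = group_cols[ctrl_key]
    if len(ctrl_cols) < 2:
        raise ValueError("Dunnett test needs >= 2 control replicates")
    test_keys = [kk for kk in ordered if kk != ctrl_key]

    vals = np.log2(matrix.intensities)
    keep = matrix.proteotypic if require_proteotypic else pd.Series(
        True, index=vals.index
    )
    used_cols = ctrl_cols + [c for kk in test_keys for c in group_cols[kk]]
    keep = keep & vals[used_cols].notna().all(axis=1)
    if exclude_imputed:
        # cells filled during imputation still count as originally missing
        keep = keep & ~matrix.imputed_mask[used_cols].any(axis=1)
    vals = vals.loc[keep]

    n_groups = len(test_keys) + 1
    sizes = [len(ctrl_cols)] + [len(group_cols[kk]) for kk in test_keys]
    df_resid = sum(sizes) - n_groups
    balanced = len(set(sizes[1:])) == 1

    ctrl = vals[ctrl_cols].to_numpy()
    ctrl_mean = ctrl.mean(axis=1)
    ss = ((ctrl - ctrl_mean[:, None]) ** 2).sum(axis=1)
    group_means, group_ns = [], []
    for kk in test_keys:
        g = vals[group_cols[kk]].to_numpy()
        gm = g.mean(axis=1)
        ss += ((g - gm[:, None]) ** 2).sum(axis=1)
        group_means.append(gm)
        group_ns.append(g.shape[1])
    s2 = ss / max(df_resid, 1)

    rows = []
    tstats = np.empty((len(vals), len(test_keys)))
    for j, (kk, gm, ng) in enumerate(zip(test_keys, group_means, group_ns)):
        with np.errstate(invalid="ignore", divide="ignore"):
            tstats[:, j] = (gm - ctrl_mean) / np.sqrt(
                s2 * (1.0 / ng + 1.0 / len(ctrl_cols))
            )
    if balanced and len(test_keys) > 0:
        lam = np.sqrt(group_ns[0] / (group_ns[0] + len(ctrl_cols)))
        flat = dunnett_adjusted_pvalues(
            tstats.ravel(), len(test_keys), df_resid, lam
        ).reshape(tstats.shape)
    else:
        lams = np.sqrt(np.array(group_ns) / (np.array(group_ns) + len(ctrl_cols)))
        flat = np.column_stack(
            [
                dunnett_adjusted_pvalues_mc(tstats[:, j], lams, df_resid, seed=mc_seed)
                for j in range(len(test_keys))
            ]
        )
    raw = 2.0 * stats.t.sf(np.abs(tstats), df_resid)
    for j, kk in enumerate(test_keys):
        chunk = pd.DataFrame(
            {
                "protein_id": vals.index,
                "treatment": treatment,
                "phase": kk[1],
                "time_h": kk[2],
                "log2fc": group_means[j] - ctrl_mean,
                "t": tstats[:, j],
                "p_raw": raw[:, j],
                "p_adj": flat[:, j],
            }
        )
        rows.append(chunk)
    table = pd.concat(rows, ignore_index=True)
    for a in alphas:
        table[f"sig_{a:g}"] = table["p_adj"] < a
    return table
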