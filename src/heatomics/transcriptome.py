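"""Transcriptome stage: count filtering, TPM, differential expression,
DEG set algebra and the SVD (surprisal-style) decomposition.

Differential expression follows a three-criterion call per gene and time
point versus the pre-heat control of the same treatment:

* |log2 fold-change| > 1 (from the model coefficient),
* Benjamini-Hochberg FDR < 0.05 within the contrast,
* absolute difference of group mean TPM >= 1.

The count model is a negative-binomial regression with a log link, a
log-library-size offset and a single group factor (contrast time point vs
pre-heat). The fold-change is tested with a Wald statistic referred to a
t distribution on the residual degrees of freedom; gene-wise quadratic
mean-variance dispersions are moderated toward the experiment-wide median
to stabilise the small-replicate fits. Fits are iteratively reweighted
least squares vectorised over genes, cross-checked against statsmodels'
scalar GLM in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .design import PHASE_ORDER, TimeCourseDesign
from .matrices import ExpressionMatrix, TpmMatrix

__all__ = [
    "filter_genes",
    "compute_tpm",
    "differential_expression",
    "deg_sets",
    "surprisal_analysis",
    "SurprisalDecomposition",
]

DEG_COLUMNS = (
    "gene_id",
    "treatment",
    "phase",
    "time_h",
    "log2fc",
    "p",
    "fdr",
    "tpm_ctrl",
    "tpm_trt",
    "significant",
)


def filter_genes(
    matrix: ExpressionMatrix, min_reads: int = 10, min_fraction: float = 0.10
) -> ExpressionMatrix:
    """Keep genes with >= min_reads counts in >= ceil(min_fraction * n)
    of the n samples (default: at least 10 reads in at least 10%)."""
    n = len(matrix.sample_ids)
    need = math.ceil(min_fraction * n)
    hits = (matrix.counts >= min_reads).sum(axis=1)
    keep = matrix.counts.index[hits >= need]
    if len(keep) == 0:
        warnings.warn("count filter removed every gene", stacklevel=2)
    return ExpressionMatrix(matrix.counts.loc[keep], matrix.gene_length_bp.loc[keep])


def compute_tpm(matrix: ExpressionMatrix) -> TpmMatrix:
    """Transcripts per million: length-normalised count rates scaled so
    every sample column sums to 1e6."""
    rates = matrix.counts.div(matrix.gene_length_bp / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    dead = totals.index[totals == 0]
    if len(dead):
        raise ValueError(f"all-zero sample columns: {list(dead)}")
    return TpmMatrix(rates.div(totals, axis=1) * 1e6)


# ---------------------------------------------------------------------------
# negative-binomial two-group Wald fit, vectorised over genes


def _nb_dispersion_mom(y: np.ndarray, mu: np.ndarray, p_params: int) -> np.ndarray:
    """Method-of-moments dispersion phi in Var = mu + phi*mu^2, per gene."""
    resid2 = (y - mu) ** 2 - mu
    denom = np.sum(mu**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.sum(resid2, axis=1) / np.maximum(denom, 1e-12)
    return np.clip(phi, 1e-8, 100.0)


def nb_wald_two_group(
    counts: np.ndarray,
    offset: np.ndarray,
    is_trt: np.ndarray,
    dispersion: np.ndarray | None = None,
    n_iter: int = 50,
    tol: float = 1e-10,
):
    """Vectorised NB GLM ``log mu = offset + b0 + b1*treat`` per gene.

    Returns (b1, se1, p, phi): natural-log fold-change coefficient, its
    standard error, two-sided Wald p (normal reference, the standard GLM
    Wald test), and the dispersion used. Dispersions are moderated: the
    gene-wise method-of-moments estimate is averaged with the across-gene
    median using the residual degrees of freedom as the data weight, which
    guards the small-replicate fits against underdispersed flukes.
    """
    y = np.asarray(counts, dtype=float)
    n_genes, n_samples = y.shape
    x = np.asarray(is_trt, dtype=float)
    o = np.asarray(offset, dtype=float)

    # initial group means on the rate scale
    r = y / np.exp(o)
    m0 = np.maximum(r[:, x == 0].mean(axis=1), 1e-8)
    m1 = np.maximum(r[:, x == 1].mean(axis=1), 1e-8)
    b0 = np.log(m0)
    b1 = np.log(m1) - np.log(m0)

    mu = np.exp(o[None, :] + b0[:, None] + b1[:, None] * x[None, :])
    if dispersion is None:
        phi_gene = _nb_dispersion_mom(y, mu, 2)
        med = np.median(phi_gene)
        df_data = n_samples - 2
        prior_weight = 10.0
        phi = (df_data * phi_gene + prior_weight * med) / (df_data + prior_weight)
    else:
        phi = np.broadcast_to(np.asarray(dispersion, float), (n_genes,)).copy()

    for _ in range(n_iter):
        mu = np.exp(np.clip(o[None, :] + b0[:, None] + b1[:, None] * x[None, :], -700, 700))
        w = mu / (1.0 + phi[:, None] * mu)
        z = (b0[:, None] + b1[:, None] * x[None, :]) + (y - mu) / np.maximum(mu, 1e-12)
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swxx = (w * x * x).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x * z).sum(axis=1)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        nb0 = (swxx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        shift = np.nanmax(np.abs(nb0 - b0) + np.abs(nb1 - b1))
        b0, b1 = nb0, nb1
        if not np.isfinite(shift) or shift < tol:
            break

    mu = np.exp(np.clip(o[None, :] + b0[:, None] + b1[:, None] * x[None, :], -700, 700))
    w = mu / (1.0 + phi[:, None] * mu)
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    swxx = (w * x * x).sum(axis=1)
    det = sw * swxx - swx**2
    with np.errstate(invalid="ignore", divide="ignore"):
        se1 = np.sqrt(sw / det)
        tstat = b1 / se1
    p = 2.0 * stats.norm.sf(np.abs(tstat))
    return b1, se1, p, phi


def differential_expression(
    matrix: ExpressionMatrix,
    design: TimeCourseDesign,
    treatments=("heat35", "heat40"),
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    tpm_delta: float = 1.0,
    pool_fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene differential expression of every (treatment, time point)
    against the same treatment's pre-heat group.

    Returns a tidy table with DEG_COLUMNS. ``pool_fdr`` switches the BH
    family from per-contrast (default) to all contrasts pooled.
    """
    tpm = compute_tpm(matrix).tpm
    lib = matrix.counts.sum(axis=0).astype(float)
    records = []
    for tr in treatments:
        ctrl_samples = design.samples_for(tr, "pre_heat", 0.0)
        ctrl_samples = [s for s in ctrl_samples if s in matrix.counts.columns]
        if len(ctrl_samples) == 0:
            warnings.warn(f"no pre-heat samples for {tr}; treatment skipped")
            continue
        for ph, t in [
            (p, x) for (trr, p, x) in design.group_keys(tr) if p != "pre_heat"
        ]:
            trt_samples = [
                s for s in design.samples_for(tr, ph, t) if s in matrix.counts.columns
            ]
            if len(trt_samples) == 0:
                warnings.warn(f"contrast {tr}/{ph}/{t} has no samples; skipped")
                continue
            cols = ctrl_samples + trt_samples
            y = matrix.counts[cols].to_numpy(float)
            offset = np.log(lib[cols].to_numpy())
            is_trt = np.array([0] * len(ctrl_samples) + [1] * len(trt_samples))
            b1, _, p, _ = nb_wald_two_group(y, offset, is_trt)
            log2fc = b1 / np.log(2.0)
            mean_ctrl = tpm[ctrl_samples].mean(axis=1).to_numpy()
            mean_trt = tpm[trt_samples].mean(axis=1).to_numpy()
            chunk = pd.DataFrame(
                {
                    "gene_id": matrix.gene_ids,
                    "treatment": tr,
                    "phase": ph,
                    "time_h": t,
                    "log2fc": log2fc,
                    "p": p,
                    "tpm_ctrl": mean_ctrl,
                    "tpm_trt": mean_trt,
                }
            )
            records.append(chunk)
    if not records:
        return pd.DataFrame(columns=list(DEG_COLUMNS))
    table = pd.concat(records, ignore_index=True)
    if pool_fdr:
        table["fdr"] = bh_adjust(table["p"].to_numpy())
    else:
        table["fdr"] = np.nan
        for _, idx in table.groupby(["treatment", "phase", "time_h"]).groups.items():
            table.loc[idx, "fdr"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    table["significant"] = (
        (np.abs(table["log2fc"]) > lfc_threshold)
        & (table["fdr"] < alpha)
        & (np.abs(table["tpm_ctrl"] - table["tpm_trt"]) >= tpm_delta)
    )
    return table[list(DEG_COLUMNS)]


def deg_sets(degs_a: pd.DataFrame, degs_b: pd.DataFrame) -> pd.DataFrame:
    """Per time point, counts of up/down-regulated genes that overlap
    between the two treatments or are unique to either."""
    rows = []
    keys = sorted(
        set(map(tuple, degs_a[["phase", "time_h"]].drop_duplicates().to_numpy()))
        | set(map(tuple, degs_b[["phase", "time_h"]].drop_duplicates().to_numpy())),
        key=lambda k: (PHASE_ORDER[k[0]], k[1]),
    )

    def sig_ids(df, ph, t, sign):
        sel = df[(df["phase"] == ph) & (df["time_h"] == t) & df["significant"]]
        if sign > 0:
            sel = sel[sel["log2fc"] > 0]
        else:
            sel = sel[sel["log2fc"] < 0]
        return set(sel["gene_id"])

    for ph, t in keys:
        for sign, label in ((1, "up"), (-1, "down")):
            a = sig_ids(degs_a, ph, t, sign)
            b = sig_ids(degs_b, ph, t, sign)
            rows.append(
                {
                    "phase": ph,
                    "time_h": t,
                    "direction": label,
                    "overlap": len(a & b),
                    "unique_a": len(a - b),
                    "unique_b": len(b - a),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SurprisalDecomposition:
    """SVD decomposition of replicate-averaged log expression.

    Component 0 is the baseline (largest singular value); components 1..k
    are time-dependent constraint patterns with potentials
    ``lambda_a(t) = s_a * v_a(t)`` and gene weights ``G[:, a]``.
    """

    potentials: pd.DataFrame = field(repr=False)  # components x time points
    gene_weights: pd.DataFrame = field(repr=False)  # genes x components
    singular_values: np.ndarray
    variance_fraction: np.ndarray
    n_retained: int = 3

    def reconstruction(self, k: int) -> np.ndarray:
        """ln-scale reconstruction using the baseline plus k constraints."""
        G = self.gene_weights.to_numpy()[:, : k + 1]
        lam = self.potentials.to_numpy()[: k + 1]
        return G @ lam


def surprisal_analysis(
    tpm: TpmMatrix | pd.DataFrame,
    design: TimeCourseDesign | None = None,
    treatment: str | None = None,
    n_constraints: int = 3,
) -> SurprisalDecomposition:
    """Decompose ln(TPM + 1) (genes x time points) by SVD.

    When a design is given, replicates are averaged per (phase, time)
    group first; otherwise columns are taken as already being time points.
    The leading component (index 0) is the steady-state baseline; the
    following ``n_constraints`` components are the retained constraints.
    """
    mat = tpm.tpm if isinstance(tpm, TpmMatrix) else tpm
    if design is not None:
        cols = {}
        keys = design.group_keys(treatment)
        for tr, ph, t in keys:
            samples = [s for s in design.samples_for(tr, ph, t) if s in mat.columns]
            if samples:
                cols[f"{tr}:{ph}:{t:g}"] = mat[samples].mean(axis=1)
        mat = pd.DataFrame(cols)
    if mat.shape[1] < 4:
        raise ValueError("surprisal analysis needs at least 4 time points")
    ln = np.log(mat.to_numpy(float) + 1.0)
    U, s, Vt = np.linalg.svd(ln, full_matrices=False)
    # sign convention: time profile of each component has positive mean
    flip = np.where(Vt.sum(axis=1) < 0, -1.0, 1.0)
    U = U * flip[None, :]
    Vt = Vt * flip[:, None]
    k = min(n_constraints + 1, s.size)
    potentials = pd.DataFrame(
        s[:k, None] * Vt[:k], index=[f"lambda_{a}" for a in range(k)], columns=mat.columns
    )
    weights = pd.DataFrame(
        U[:, :k], index=mat.index, columns=[f"G_{a}" for a in range(k)]
    )
    var_frac = s**2 / np.sum(s**2)
    return SurprisalDecomposition(
        potentials, weights, s[:k], var_frac[:k], n_retained=k - 1
    )
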