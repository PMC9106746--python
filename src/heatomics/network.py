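"""Correlation-network stage thresholded by random matrix theory.

The absolute-correlation threshold is chosen by scanning candidate values
and watching the nearest-neighbour spacing distribution (NNSD) of the
unfolded eigenvalue spectrum of the thresholded matrix. A dense noisy
correlation matrix behaves like a Gaussian orthogonal ensemble and shows
Wigner-Dyson spacings; once the threshold strips the noise and leaves
modular signal, the spectrum decouples into independent blocks and the
spacings become Poissonian. The chosen threshold rho* is the first scan
value at which the NNSD is closer (chi-square distance over fixed bins)
to the Poisson law exp(-s) than to the Wigner surmise
(pi s / 2) exp(-pi s^2 / 4).

Modules on the thresholded graph come from greedy modularity
maximization; each module is summarised by its eigenvector (leading
principal component of the z-scored member time series, zero mean and
unit variance), with anti-correlated members carrying sign -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from ._stats import bh_adjust, hypergeom_sf

# |r| cutoffs reported for a published Chlamydomonas heat time course
# (moderate/acute arms); sensible defaults when rerunning comparable real
# data with a user-supplied threshold instead of the NNSD scan.
REFERENCE_THRESHOLDS = {"heat35": 0.8194, "heat40": 0.8675}

__all__ = [
    "REFERENCE_THRESHOLDS",
    "anova_prefilter",
    "rmt_threshold",
    "RmtScan",
    "build_modules",
    "NetworkModule",
    "assign_by_anova",
    "enrich",
]


def duplicate_ambiguous_groups(
    profiles: pd.DataFrame, proteotypic: pd.Series
) -> pd.DataFrame:
    """Split ';'-joined ambiguous protein groups into singleton rows."""
    rows, index = [], []
    for pid, row in profiles.iterrows():
        if not proteotypic.get(pid, True) and ";" in str(pid):
            for member in str(pid).split(";"):
                rows.append(row)
                index.append(member)
        else:
            rows.append(row)
            index.append(pid)
    out = pd.DataFrame(rows, index=pd.Index(index))
    return out[~out.index.duplicated(keep="first")]


def anova_prefilter(
    log_intensities: pd.DataFrame,
    design,
    treatment: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Keep entities whose profile varies across time-point groups
    (one-way ANOVA p < alpha). Columns are sample ids from the design."""
    groups = []
    for (tr, _, _), sub in design.groups():
        if treatment is not None and tr != treatment:
            continue
        cols = [s for s in sub["sample_id"] if s in log_intensities.columns]
        if len(cols) >= 2:
            groups.append(log_intensities[cols].to_numpy(float))
    if len(groups) < 2:
        raise ValueError("ANOVA prefilter needs >= 2 groups with >= 2 replicates")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    return log_intensities.loc[p < alpha]


_POISSON = lambda a, b: np.exp(-a) - np.exp(-b)
_WIGNER = lambda a, b: np.exp(-np.pi * a**2 / 4) - np.exp(-np.pi * b**2 / 4)


def _nnsd(eigenvalues: np.ndarray, spline_frac: float = 0.5):
    """Unfolded nearest-neighbour spacings of a (deduplicated) spectrum."""
    ev = np.unique(np.round(np.sort(eigenvalues), 8))
    n = ev.size
    if n < 6:
        return None
    cumulative = np.arange(1, n + 1, dtype=float)
    s = max(n * spline_frac, 1.0)
    spline = UnivariateSpline(ev, cumulative, k=3, s=s)
    unfolded = spline(ev)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if spacings.size < 5:
        return None
    return spacings / spacings.mean()


def _nnsd_distances(spacings: np.ndarray, bin_width: float = 0.25, smax: float = 3.0):
    edges = np.arange(0.0, smax + bin_width / 2, bin_width)
    obs, _ = np.histogram(spacings, bins=edges)
    obs = obs / spacings.size
    a, b = edges[:-1], edges[1:]
    exp_p = _POISSON(a, b)
    exp_w = _WIGNER(a, b)
    d_p = float(np.sum((obs - exp_p) ** 2 / np.maximum(exp_p, 1e-12)))
    d_w = float(np.sum((obs - exp_w) ** 2 / np.maximum(exp_w, 1e-12)))
    return d_p, d_w


@dataclass
class RmtScan:
    """Result of the threshold scan; ``transitioned`` is False when the
    NNSD never turned Poissonian within the scan range (or the spectrum
    was degenerate throughout), in which case ``threshold`` is the scan
    maximum."""

    threshold: float
    transitioned: bool
    table: pd.DataFrame = field(repr=False)  # threshold, d_poisson, d_wigner


def rmt_threshold(
    corr: pd.DataFrame | np.ndarray,
    scan=None,
) -> RmtScan:
    """Scan absolute-correlation thresholds and pick the Wigner->Poisson
    transition of the unfolded NNSD (see module docstring)."""
    C = corr.to_numpy(float) if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    if C.shape[0] < 50:
        warnings.warn("fewer than 50 entities; NNSD statistics are unreliable")
    if scan is None:
        scan = np.round(np.arange(0.50, 0.991, 0.01), 2)
    rows = []
    chosen, transitioned = None, False
    for thr in scan:
        M = np.where(np.abs(C) >= thr, C, 0.0)
        np.fill_diagonal(M, 1.0)
        ev = np.linalg.eigvalsh(M)
        spac = _nnsd(ev)
        if spac is None:
            rows.append((thr, np.nan, np.nan))
            continue
        d_p, d_w = _nnsd_distances(spac)
        rows.append((thr, d_p, d_w))
        if chosen is None and d_p < d_w:
            chosen, transitioned = float(thr), True
    table = pd.DataFrame(rows, columns=["threshold", "d_poisson", "d_wigner"])
    if chosen is None:
        chosen = float(scan[-1])
        warnings.warn("NNSD never transitioned to Poisson within the scan range")
    return RmtScan(chosen, transitioned, table)


@dataclass
class NetworkModule:
    """A correlation-network community with its aggregate signal shape."""

    module_id: int
    members: pd.Series = field(repr=False)  # entity id -> sign (+1/-1)
    eigenvector: pd.Series = field(repr=False)  # time point -> value (z-scored)
    variance_explained: float = float("nan")

    @property
    def member_ids(self) -> list:
        return list(self.members.index)


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0).replace(0.0, 1.0)
    return df.sub(mu, axis=0).div(sd, axis=0)


def build_modules(
    profiles: pd.DataFrame,
    corr: pd.DataFrame,
    rho: float,
    min_size: int = 2,
    seed: int = 0,
) -> list[NetworkModule]:
    """Communities of the |r| >= rho graph by greedy modularity
    maximization; singletons are discarded.

    ``profiles`` holds entity time series (entities x time points) used to
    compute each module's eigenvector: the leading principal component of
    the z-scored member series, scaled to zero mean and unit variance over
    time points. Members negatively correlated with the eigenvector get
    sign -1; the global sign is fixed so the mean member correlation is
    positive.
    """
    A = corr.to_numpy(float)
    ids = list(corr.index)
    G = nx.Graph()
    G.add_nodes_from(ids)
    iu, ju = np.triu_indices(len(ids), k=1)
    strong = np.abs(A[iu, ju]) >= rho
    G.add_weighted_edges_from(
        (ids[i], ids[j], abs(A[i, j])) for i, j in zip(iu[strong], ju[strong])
    )
    G.remove_nodes_from(list(nx.isolates(G)))
    if G.number_of_edges() == 0:
        warnings.warn("thresholded graph has no edges; no modules built")
        return []
    communities = nx.community.greedy_modularity_communities(G, weight="weight")
    modules = []
    mid = 0
    for comm in communities:
        members = sorted(comm)
        if len(members) < min_size:
            continue
        mid += 1
        Z = _zscore_rows(profiles.loc[members])
        X = Z.to_numpy(float)
        # leading right-singular vector of the z-scored member matrix is
        # the module's representative time course (WGCNA-style eigengene)
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        eig = Vt[0]
        eig = (eig - eig.mean()) / eig.std(ddof=0)
        cors = np.array([np.corrcoef(row, eig)[0, 1] for row in X])
        if np.nanmean(cors) < 0:
            eig, cors = -eig, -cors
        signs = np.where(cors >= 0, 1, -1)
        var_expl = float(s[0] ** 2 / np.sum(s**2)) if s.size else float("nan")
        modules.append(
            NetworkModule(
                module_id=mid,
                members=pd.Series(signs, index=pd.Index(members)),
                eigenvector=pd.Series(eig, index=profiles.columns),
                variance_explained=var_expl,
            )
        )
    return modules


def assign_by_anova(
    profiles: pd.DataFrame,
    modules: list[NetworkModule],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Assign each entity to the module whose eigenvector best explains
    its profile (linear-model F-test, BH over all entity x module tests,
    winner = minimum FDR below the cutoff; ties break to the lower
    module id). Unassigned entities get module_id 0."""
    if not modules:
        return pd.DataFrame(columns=["entity_id", "module_id", "fdr"])
    n = profiles.shape[1]
    pmat = np.empty((len(profiles), len(modules)))
    X = profiles.to_numpy(float)
    for j, mod in enumerate(modules):
        e = mod.eigenvector.reindex(profiles.columns).to_numpy(float)
        ez = (e - e.mean()) / e.std(ddof=0)
        xz = (X - X.mean(axis=1, keepdims=True)) / np.maximum(
            X.std(axis=1, ddof=0, keepdims=True), 1e-300
        )
        r = (xz * ez).mean(axis=1)
        r2 = np.clip(r**2, 0.0, 1.0 - 1e-15)
        f = r2 / (1 - r2) * (n - 2)
        pmat[:, j] = stats.f.sf(f, 1, n - 2)
    qmat = bh_adjust(pmat.ravel()).reshape(pmat.shape)
    best = np.argmin(qmat, axis=1)
    best_q = qmat[np.arange(len(profiles)), best]
    assigned = np.where(best_q < fdr, best + 1, 0)
    module_ids = {j + 1: modules[j].module_id for j in range(len(modules))}
    module_ids[0] = 0
    return pd.DataFrame(
        {
            "entity_id": profiles.index,
            "module_id": [module_ids[a] for a in assigned],
            "fdr": best_q,
        }
    )


def enrich(
    member_ids,
    ontology,
    universe,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Tree-expanded hypergeometric enrichment of a module against a
    universe of entities.

    Every entity counts once at each ancestor level of its assigned
    terms. For each term with K annotated universe entities and k of the
    n module members, p is the exact upper hypergeometric tail
    P(X >= k); BH correction runs across terms within the module.
    """
    universe = list(universe)
    members = set(member_ids)
    if not members <= set(universe):
        raise ValueError("module members must be contained in the universe")
    term_universe: dict[str, int] = {}
    term_module: dict[str, int] = {}
    for ent in universe:
        for term in ontology.expanded(ent):
            term_universe[term] = term_universe.get(term, 0) + 1
            if ent in members:
                term_module[term] = term_module.get(term, 0) + 1
    N, n = len(universe), len(members)
    rows = []
    for term in sorted(term_universe):
        K = term_universe[term]
        k = term_module.get(term, 0)
        rows.append(
            {
                "term_id": term,
                "overlap": k,
                "module_size": n,
                "term_size": K,
                "universe": N,
                "p": hypergeom_sf(k, N, K, n),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["fdr"] < fdr_alpha
    return table
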