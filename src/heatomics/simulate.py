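"""Synthetic inputs with the statistical structure the pipeline assumes.

The omics generator emulates a paired photobioreactor heat time course:
negative-binomial RNA-seq counts over the default grid (pre-heat; heat 0,
0.5, 1, 2, 4, 8, 16, 24 h; recovery 0, 2, 4, 8, 24, 48 h; three
replicates; 25/35/40 degC arms), log-normal label-free protein
intensities for a gene subset with structured missingness (random plus
intensity-dependent dropout), and phase-dependent transcript-protein
coupling (high during heat, low during recovery). Truth tables record
every planted effect so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import TimeCourseDesign, default_design
from .matrices import (
    ExpressionMatrix,
    KineticTrace,
    OntologyAnnotation,
    ProteomeMatrix,
)

__all__ = [
    "Archetype",
    "SimRecipe",
    "simulate_omics",
    "simulate_od_trace",
    "simulate_kinetics",
    "simulate_facs",
    "PigmentAbsorbance",
    "simulate_absorbance",
]


@dataclass(frozen=True)
class Archetype:
    """A temporal log2 fold-change program shared by a block of genes.

    ``profile`` maps (treatment, phase, time_h) to the planted log2FC
    versus pre-heat; unlisted groups default to 0. ``scale40`` multiplies
    the profile for the acute (40 degC) arm.
    """

    name: str
    n_genes: int
    profile: dict = field(default_factory=dict)
    scale40: float = 1.5


def _default_archetypes() -> tuple:
    heat_t = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0)
    rec_t = (0.0, 2.0, 4.0, 8.0, 24.0, 48.0)

    def prof(heat_vals, rec_vals):
        out = {}
        for tr in ("heat35", "heat40"):
            for t, v in zip(heat_t, heat_vals):
                out[(tr, "heat", t)] = v
            for t, v in zip(rec_t, rec_vals):
                out[(tr, "recovery", t)] = v
        return out

    return (
        # canonical heat-shock burst: sharp early induction, fast decay
        Archetype("early_heat", 60, prof((1, 3, 2.5, 1.5, 1, 0.5, 0.3, 0.2), (0, 0, 0, 0, 0, 0))),
        # sustained heat program (e.g. carbon metabolism)
        Archetype("sustained_heat", 60, prof((0.5, 1, 1.5, 2, 2, 2, 2, 1.8), (1, 0.5, 0.2, 0, 0, 0))),
        # DNA-synthesis style recovery peak
        Archetype("recovery_peak", 60, prof((0, 0, 0, -0.3, -0.5, -0.5, -0.3, 0), (0.5, 2, 2.5, 1.5, 0.3, 0))),
        # photosynthesis light reactions: early-recovery dip
        Archetype("recovery_dip", 60, prof((0, 0.3, 0.3, 0.2, 0, 0, 0, 0), (-1, -2, -1.5, -1, -0.3, 0))),
    )


@dataclass(frozen=True)
class SimRecipe:
    """Generator settings; defaults are the study conditions emulated.

    Negative-binomial counts use Var = mu + phi mu^2 with phi = 0.1 (a
    typical bulk RNA-seq scale); protein replicate noise is Gaussian on
    log2 scale with sd 0.3; missingness combines a 5% random rate with a
    logistic intensity-dependent dropout; the transcript-protein coupling
    is rho = 0.8 during heat and 0.2 during recovery.
    """

    seed: int = 0
    n_genes: int = 2000
    n_proteins: int = 600
    archetypes: tuple = field(default_factory=_default_archetypes)
    nb_dispersion: float = 0.1
    library_size_range: tuple = (8e5, 1.2e6)
    rho_heat: float = 0.8
    rho_recovery: float = 0.2
    protein_noise_sd: float = 0.3
    protein_smoothness: float = 0.9  # AR(1) of group-level protein noise
    mcar_rate: float = 0.05
    mnar_scale: float = 1.0
    mnar_quantile: float = 0.05
    n_terms: int = 20
    genes_per_term: int = 25
    ontology_depth: int = 2
    base_log2_tpm_mean: float = 4.0
    base_log2_tpm_sd: float = 2.0

    def __post_init__(self):
        for r in (self.mcar_rate,):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        for rho in (self.rho_heat, self.rho_recovery):
            if abs(rho) > 1:
                raise ValueError("|coupling rho| must be <= 1")
        total = sum(a.n_genes for a in self.archetypes)
        if total > self.n_genes:
            raise ValueError("archetypes assign more genes than n_genes")

    def null(self) -> "SimRecipe":
        """A copy with every planted effect removed (for calibration)."""
        return replace(self, archetypes=(), mcar_rate=0.0, mnar_scale=0.0)


def _group_lfc_table(recipe: SimRecipe, design: TimeCourseDesign, gene_ids):
    keys = design.group_keys()
    present_treatments = set(design.table["treatment"])
    for arch in recipe.archetypes:
        for key in arch.profile:
            if key[0] not in present_treatments:
                continue  # treatment arm not simulated in this design
            if key not in keys:
                raise ValueError(
                    f"archetype {arch.name} references absent group {key}"
                )
    lfc = pd.DataFrame(0.0, index=gene_ids, columns=pd.Index(keys))
    membership = pd.Series("null", index=gene_ids, name="archetype")
    cursor = 0
    for arch in recipe.archetypes:
        genes = gene_ids[cursor : cursor + arch.n_genes]
        cursor += arch.n_genes
        membership[genes] = arch.name
        for key, v in arch.profile.items():
            if key not in lfc.columns:
                continue
            val = v * (arch.scale40 if key[0] == "heat40" else 1.0)
            lfc.loc[genes, [key]] = val
    return lfc, membership


def simulate_omics(recipe: SimRecipe, design: TimeCourseDesign | None = None):
    """Generate (ExpressionMatrix, ProteomeMatrix, OntologyAnnotation,
    truth) for a design (default: the built-in grid).

    truth is a dict of DataFrames: 'transcript_lfc' and 'protein_lfc'
    (gene/protein x replicate group), 'archetype' membership,
    'missing_mechanism' per proteome cell ('observed'/'mcar'/'mnar').
    """
    if design is None:
        design = default_design()
    rng = np.random.default_rng(recipe.seed)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(recipe.n_genes)])
    lengths = pd.Series(
        np.round(rng.lognormal(np.log(1500), 0.5, recipe.n_genes)).clip(200, 20000),
        index=gene_ids,
        name="length_bp",
    )
    base = rng.normal(recipe.base_log2_tpm_mean, recipe.base_log2_tpm_sd, recipe.n_genes)
    lfc, membership = _group_lfc_table(recipe, design, gene_ids)

    # counts: library- and length-scaled NB draws around 2^(base + lfc)
    sample_rows = design.table
    libs = rng.uniform(*recipe.library_size_range, len(sample_rows))
    counts = np.empty((recipe.n_genes, len(sample_rows)), dtype=np.int64)
    phi = recipe.nb_dispersion
    len_kb = lengths.to_numpy() / 1000.0
    for j, (_, row) in enumerate(sample_rows.iterrows()):
        key = (row["treatment"], row["phase"], row["time_h"])
        rel = np.exp2(base + lfc[[key]].to_numpy()[:, 0]) * len_kb
        mu = libs[j] * rel / rel.sum()
        if phi > 0:
            n_param = 1.0 / phi
            p_param = n_param / (n_param + mu)
            counts[:, j] = rng.negative_binomial(n_param, p_param)
        else:
            counts[:, j] = rng.poisson(mu)
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=list(sample_rows["sample_id"])),
        lengths,
    )

    # proteins: phase-coupled group-level log2 fold-changes + replicate
    # noise. The decoupling noise is an AR(1) process along each arm's
    # time grid (protein abundances drift slowly), with amplitude set so
    # that the across-gene correlation with transcript log2FC is ~rho.
    prot_genes = gene_ids[: recipe.n_proteins]
    keys = list(lfc.columns)
    prot_lfc = pd.DataFrame(0.0, index=prot_genes, columns=pd.Index(keys))
    sigma_t = float(lfc.loc[prot_genes].to_numpy().std()) or 1.0
    phi_ar = recipe.protein_smoothness
    from .design import PHASE_ORDER

    for tr in sorted({k[0] for k in keys}):
        ordered = sorted(
            (k for k in keys if k[0] == tr), key=lambda k: (PHASE_ORDER[k[1]], k[2])
        )
        u = np.empty((len(prot_genes), len(ordered)))
        u[:, 0] = rng.standard_normal(len(prot_genes))
        for g in range(1, len(ordered)):
            u[:, g] = phi_ar * u[:, g - 1] + np.sqrt(
                max(1 - phi_ar**2, 0.0)
            ) * rng.standard_normal(len(prot_genes))
        for g, key in enumerate(ordered):
            ph = key[1]
            if ph == "pre_heat":
                continue
            rho = recipe.rho_heat if ph == "heat" else recipe.rho_recovery
            t_lfc = lfc.loc[prot_genes, [key]].to_numpy()[:, 0]
            sigma = sigma_t * np.sqrt(max(1 - rho**2, 0.0))
            prot_lfc[[key]] = (rho * t_lfc + sigma * u[:, g])[:, None]
    prot_base = rng.normal(20.0, 2.0, len(prot_genes))  # log2 intensity scale
    inten = np.empty((len(prot_genes), len(sample_rows)))
    for j, (_, row) in enumerate(sample_rows.iterrows()):
        key = (row["treatment"], row["phase"], row["time_h"])
        mean_log2 = prot_base + prot_lfc[[key]].to_numpy()[:, 0]
        inten[:, j] = np.exp2(mean_log2 + rng.normal(0, recipe.protein_noise_sd, len(prot_genes)))

    log2i = np.log2(inten)
    mech = np.full(inten.shape, "observed", dtype=object)
    if recipe.mnar_scale > 0:
        thresh = np.quantile(log2i, recipe.mnar_quantile)
        p_mnar = 1.0 / (1.0 + np.exp((log2i - thresh) / recipe.mnar_scale))
        mech[rng.random(inten.shape) < p_mnar] = "mnar"
    if recipe.mcar_rate > 0:
        mech[rng.random(inten.shape) < recipe.mcar_rate] = "mcar"
    vals = pd.DataFrame(
        np.where(mech == "observed", inten, np.nan),
        index=prot_genes,
        columns=list(sample_rows["sample_id"]),
    )
    proteome = ProteomeMatrix(vals)

    ontology = _simulate_ontology(recipe, rng, gene_ids, membership)
    truth = {
        "transcript_lfc": lfc,
        "protein_lfc": prot_lfc,
        "archetype": membership.to_frame(),
        "missing_mechanism": pd.DataFrame(
            mech, index=prot_genes, columns=list(sample_rows["sample_id"])
        ),
    }
    return expr, proteome, ontology, truth


def _simulate_ontology(recipe, rng, gene_ids, membership) -> OntologyAnnotation:
    """A small MapMan-style forest: one bin per archetype (so planted
    blocks are coherent functional terms) plus random filler bins, all
    nested under top-level roots."""
    terms = [("root_metabolism", "metabolism", ""), ("root_stress", "stress", "")]
    assignments: dict[str, set] = {}
    for arch in sorted(set(membership) - {"null"}):
        tid = f"bin_{arch}"
        terms.append((tid, arch.replace("_", " "), "root_stress"))
        for g in membership.index[membership == arch]:
            assignments.setdefault(g, set()).add(tid)
    n_filler = max(recipe.n_terms - len(terms), 0)
    for i in range(n_filler):
        parent = "root_metabolism" if i % 2 == 0 else "root_stress"
        tid = f"bin_rand{i:02d}"
        if recipe.ontology_depth > 1 and i % 3 == 2:
            parent = f"bin_rand{i - 1:02d}"
        terms.append((tid, f"random bin {i}", parent))
        for g in rng.choice(gene_ids, size=min(recipe.genes_per_term, len(gene_ids)), replace=False):
            assignments.setdefault(str(g), set()).add(tid)
    table = pd.DataFrame(terms, columns=["term_id", "name", "parent"])
    return OntologyAnnotation(table, assignments)


def simulate_od_trace(
    doubling_time_h: float,
    target_od: float,
    band: float = 0.08,
    duration_h: float = 24.0,
    noise_sd: float = 0.0,
    dt_h: float = 0.01,
    seed: int = 0,
) -> KineticTrace:
    """Turbidostat OD680 sawtooth: exponential growth from target*(1-band)
    to target*(1+band), instantaneous dilution, repeat; plus additive
    Gaussian noise. The inter-dilution interval is
    doubling_time * log2((1+band)/(1-band))."""
    if doubling_time_h <= 0:
        raise ValueError("doubling time must be positive")
    if not 0 < band < 1:
        raise ValueError("band must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h, dt_h)
    cycle_h = doubling_time_h * np.log2((1 + band) / (1 - band))
    od = target_od * (1 - band) * np.exp2((t % cycle_h) / doubling_time_h)
    if noise_sd > 0:
        od = od + rng.normal(0, noise_sd, od.size)
    return KineticTrace(
        "od680",
        t,
        od,
        {"doubling_time_h": doubling_time_h, "band": band, "target_od": target_od,
         "cycle_h": cycle_h},
    )


def simulate_kinetics(kind: str, params: dict, noise_sd: float = 0.0, seed: int = 0) -> KineticTrace:
    """Model traces for the spectroscopy calculators.

    kinds/params:
      * 'p700': amplitude, tau_s, offset [, duration_s, dt_s] — dark
        re-reduction decay starting at t = 0 (far-red just switched off);
      * 'ecs': ecst, tau_s, offset [, light_s, dt_s] — a flat light phase
        followed by the dark-interval relaxation (meta marks dark onset);
      * 'fluorescence': fo, fm, fs, fm_prime, fo_prime — piecewise level
        trace echoing the pulse protocol;
      * 'spectrum77k': peak686, peak714 [, width_nm] — two Gaussian
        emission bands on a 650-750 nm grid.
    """
    rng = np.random.default_rng(seed)
    p = dict(params)
    if kind == "p700":
        tau = p["tau_s"]
        if tau <= 0:
            raise ValueError("tau must be positive")
        dt = p.get("dt_s", 0.01)
        t = np.arange(0.0, p.get("duration_s", 5.0), dt)
        y = p["offset"] + p["amplitude"] * np.exp(-t / tau)
        meta = {**p, "far_red_off_s": 0.0}
    elif kind == "ecs":
        tau = p["tau_s"]
        if tau <= 0:
            raise ValueError("tau must be positive")
        dt = p.get("dt_s", 0.001)
        light_s = p.get("light_s", 0.3)
        t = np.arange(0.0, light_s + p.get("dark_s", 0.3), dt)
        y = np.where(
            t < light_s,
            p["offset"] + p["ecst"],
            p["offset"] + p["ecst"] * np.exp(-(t - light_s) / tau),
        )
        meta = {**p, "dark_start_s": light_s}
    elif kind == "fluorescence":
        levels = [p["fo"], p["fm"], p["fo"], p["fs"], p["fm_prime"], p["fo_prime"]]
        seg = p.get("segment_s", 0.5)
        dt = p.get("dt_s", 0.01)
        t = np.arange(0.0, seg * len(levels), dt)
        idx = np.minimum((t // seg).astype(int), len(levels) - 1)
        y = np.asarray(levels, dtype=float)[idx]
        meta = dict(p)
    elif kind == "spectrum77k":
        width = p.get("width_nm", 8.0)
        t = np.arange(650.0, 750.5, 0.5)
        y = p["peak686"] * np.exp(-((t - 686.0) ** 2) / (2 * width**2)) + p[
            "peak714"
        ] * np.exp(-((t - 714.0) ** 2) / (2 * width**2))
        meta = dict(p)
    else:
        raise ValueError(f"unknown kinetic kind {kind!r}")
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, y.size)
    kind_out = "spectrum77k" if kind == "spectrum77k" else (
        "fluorescence" if kind == "fluorescence" else kind
    )
    return KineticTrace(kind_out, t, y, meta)


def simulate_facs(
    ploidy_fractions: dict,
    unit_signal: float,
    background: float,
    n: int = 20000,
    cv: float = 0.08,
    seed: int = 0,
    n_bins: int = 256,
) -> KineticTrace:
    """DNA-content histogram of n cells: per-cell signal = (background +
    ploidy * unit_signal) with multiplicative log-normal spread cv,
    binned on log-spaced bins (histogram x = geometric bin centers)."""
    if background < 0:
        raise ValueError("background must be non-negative")
    ploidies = np.array(sorted(ploidy_fractions))
    if not set(ploidies) <= {1, 2, 4, 8, 16}:
        raise ValueError("ploidies must be in {1, 2, 4, 8, 16}")
    fracs = np.array([ploidy_fractions[p] for p in ploidies], dtype=float)
    if not np.isclose(fracs.sum(), 1.0):
        raise ValueError("ploidy fractions must sum to 1")
    rng = np.random.default_rng(seed)
    draw = rng.choice(ploidies, size=n, p=fracs)
    center = background + draw * unit_signal
    sigma = np.sqrt(np.log1p(cv**2))
    signal = center * np.exp(rng.normal(0.0, sigma, n))
    lo, hi = signal.min() * 0.9, signal.max() * 1.1
    edges = np.geomspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(signal, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return KineticTrace(
        "facs_hist",
        centers,
        counts.astype(float),
        {"unit_signal": unit_signal, "background": background, "cv": cv, "n": n,
         "fractions": dict(ploidy_fractions)},
    )


@dataclass(frozen=True)
class PigmentAbsorbance:
    a470: float
    a652: float
    a665: float


def simulate_absorbance(chl_a: float, chl_b: float, carotenoids: float) -> PigmentAbsorbance:
    """Invert the pigment equations: absorbances whose forward evaluation
    returns the given concentrations (the 2x2 chlorophyll system is
    always invertible)."""
    det = 16.29 * 30.66 - 8.54 * 13.58
    a665 = (30.66 * chl_a + 8.54 * chl_b) / det
    a652 = (13.58 * chl_a + 16.29 * chl_b) / det
    a470 = (221.0 * carotenoids + 2.86 * chl_a + 129.2 * chl_b) / 1000.0
    return PigmentAbsorbance(a470=a470, a652=a652, a665=a665)
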