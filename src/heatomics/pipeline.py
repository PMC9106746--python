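"""Stage orchestration: chain the analysis stages over files on disk.

A run is configured by a YAML mapping (see ``example_config``) naming
either a synthetic recipe or input files, an output directory and a seed.
Stages execute in dependency order and write TSV tables plus a run log
with package version, seed and parameters; numeric outputs are a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import TimeCourseDesign, default_design, read_design, write_design
from .matrices import ExpressionMatrix, ProteomeMatrix, read_counts, read_ontology
from . import facs as facs_mod
from . import integration as integ
from . import network as net
from . import phenotypes as pheno
from . import photophys as photo
from . import proteome as prot
from . import simulate as sim
from . import transcriptome as tx

log = logging.getLogger("heatomics")

STAGES = (
    "simulate",
    "transcriptome",
    "proteome",
    "network",
    "integrate",
    "phenotype",
    "photophys",
    "facs",
)


class StageError(RuntimeError):
    pass


def example_config(seed: int = 1) -> dict:
    return {
        "seed": seed,
        "synthetic": {"n_genes": 400, "n_proteins": 150},
        "stages": ["simulate", "transcriptome", "proteome", "network", "integrate"],
    }


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


def _recipe_from_config(cfg: dict, seed: int) -> sim.SimRecipe:
    syn = dict(cfg.get("synthetic") or {})
    syn.setdefault("seed", seed)
    if syn.pop("null", False):
        return sim.SimRecipe(**syn).null()
    return sim.SimRecipe(**syn)


class PipelineRun:
    """Holds in-memory state while stages execute and writes outputs."""

    def __init__(self, config: dict, out_dir, seed: int | None = None):
        self.config = config
        self.seed = int(config.get("seed", 0) if seed is None else seed)
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.design: TimeCourseDesign | None = None
        self.expr: ExpressionMatrix | None = None
        self.proteome_raw: ProteomeMatrix | None = None
        self.proteome: ProteomeMatrix | None = None
        self.ontology = None
        self.deg_table: pd.DataFrame | None = None
        self.tpm = None
        self.results: dict = {}
        self._log_path = self.out / "run_log.txt"
        self._log(f"heatomics {__version__} seed={self.seed}")
        self._log(f"config: {json.dumps(config, default=str, sort_keys=True)}")

    def _log(self, msg: str):
        with open(self._log_path, "a") as fh:
            fh.write(msg + "\n")
        log.info(msg)

    # -- input/simulation -------------------------------------------------
    def stage_simulate(self):
        recipe = _recipe_from_config(self.config, self.seed)
        self.design = _design_from_config(self.config)
        expr, proteome, onto, truth = sim.simulate_omics(recipe, self.design)
        self.expr, self.proteome_raw, self.ontology = expr, proteome, onto
        write_design(self.design, self.out / "design.tsv")
        expr.write(self.out / "counts.tsv")
        proteome.write(self.out / "proteome_raw.tsv")
        onto.write(self.out / "ontology_terms.tsv", self.out / "ontology_assignments.tsv")
        for name, df in truth.items():
            flat = df.copy()
            if isinstance(flat.columns, pd.MultiIndex) or flat.columns.dtype == object:
                flat.columns = [str(c) for c in flat.columns]
            flat.to_csv(self.out / f"truth_{name}.tsv", sep="\t")
        self._log(f"simulate: {recipe.n_genes} genes, {recipe.n_proteins} proteins")

    def _require(self, attr, stage, needed_by):
        if getattr(self, attr) is None:
            raise StageError(
                f"stage '{needed_by}' requires output of stage '{stage}' "
                f"(missing {attr}); add it to the stage list or config inputs"
            )

    def load_inputs(self):
        inputs = self.config.get("inputs") or {}
        if "design" in inputs:
            self.design = read_design(inputs["design"])
        if "counts" in inputs:
            if "lengths" not in inputs:
                raise StageError("counts input requires a 'lengths' file")
            self.expr = read_counts(inputs["counts"], inputs["lengths"])
        if "proteome" in inputs:
            self.proteome_raw = ProteomeMatrix.read(inputs["proteome"])
        if "ontology_terms" in inputs:
            self.ontology = read_ontology(
                inputs["ontology_terms"], inputs["ontology_assignments"]
            )

    # -- analysis stages ---------------------------------------------------
    def stage_transcriptome(self):
        self._require("expr", "simulate/inputs", "transcriptome")
        self._require("design", "simulate/inputs", "transcriptome")
        params = self.config.get("transcriptome") or {}
        filtered = tx.filter_genes(
            self.expr,
            min_reads=params.get("min_reads", 10),
            min_fraction=params.get("min_fraction", 0.10),
        )
        self.tpm = tx.compute_tpm(filtered)
        self.tpm.write(self.out / "tpm.tsv")
        treatments = [
            t
            for t in ("heat35", "heat40")
            if t in set(self.design.table["treatment"])
        ]
        self.deg_table = tx.differential_expression(
            filtered, self.design, treatments=treatments
        )
        self.deg_table.to_csv(self.out / "deg_table.tsv", sep="\t", index=False)
        if len(treatments) == 2:
            sets = tx.deg_sets(
                self.deg_table[self.deg_table["treatment"] == treatments[0]],
                self.deg_table[self.deg_table["treatment"] == treatments[1]],
            )
            sets.to_csv(self.out / "deg_sets.tsv", sep="\t", index=False)
        for tr in treatments:
            try:
                dec = tx.surprisal_analysis(self.tpm, self.design, treatment=tr)
                dec.potentials.to_csv(self.out / f"surprisal_potentials_{tr}.tsv", sep="\t")
            except ValueError as exc:
                warnings.warn(f"surprisal skipped for {tr}: {exc}")
        self.expr_filtered = filtered
        self._log(
            f"transcriptome: {len(filtered.gene_ids)} genes kept, "
            f"{int(self.deg_table['significant'].sum()) if len(self.deg_table) else 0} DEG calls"
        )

    def stage_proteome(self):
        # normalization and imputation run independently per treatment arm
        self._require("proteome_raw", "simulate/inputs", "proteome")
        self._require("design", "simulate/inputs", "proteome")
        params = self.config.get("proteome") or {}
        arms, factors_all, daps = [], [], []
        for tr in sorted(set(self.design.table["treatment"])):
            arm_design = self.design.treatment_subset([tr])
            cols = [
                s
                for s in arm_design.sample_ids
                if s in self.proteome_raw.intensities.columns
            ]
            if not cols:
                continue
            arm = ProteomeMatrix(
                self.proteome_raw.intensities[cols],
                self.proteome_raw.proteotypic,
            )
            arm = prot.filter_replicate_support(arm, arm_design)
            arm, factors = prot.normalize_median_of_ratios(arm)
            arm, report = prot.impute(
                arm, arm_design, k=params.get("knn_k", 3), seed=self.seed
            )
            arms.append(arm)
            factors_all.append(factors)
            report.status.to_csv(self.out / f"imputation_report_{tr}.tsv", sep="\t")
            if tr in ("heat35", "heat40"):
                daps.append(prot.dunnett_test(arm, arm_design, tr, mc_seed=self.seed))
        if not arms:
            raise StageError("proteome stage found no samples matching the design")
        merged = pd.concat([a.intensities for a in arms], axis=1)
        imputed_mask = pd.concat([a.imputed_mask for a in arms], axis=1).fillna(False)
        self.proteome = ProteomeMatrix(
            merged, self.proteome_raw.proteotypic, imputed_mask
        )
        self.proteome.write(self.out / "proteome_imputed.tsv")
        pd.concat(factors_all).to_csv(self.out / "size_factors.tsv", sep="\t")
        if daps:
            self.dap_table = pd.concat(daps, ignore_index=True)
            self.dap_table.to_csv(self.out / "dap_table.tsv", sep="\t", index=False)
        self._log(f"proteome: {len(self.proteome.protein_ids)} protein groups merged")

    def stage_network(self):
        self._require("proteome", "proteome", "network")
        params = self.config.get("network") or {}
        rows = []
        for tr in ("heat35", "heat40"):
            if tr not in set(self.design.table["treatment"]):
                continue
            log2i = np.log2(self.proteome.intensities)
            log2i = net.duplicate_ambiguous_groups(log2i, self.proteome.proteotypic)
            kept = net.anova_prefilter(log2i.dropna(), self.design, treatment=tr)
            if len(kept) < 10:
                warnings.warn(f"network for {tr} skipped: too few variable proteins")
                continue
            profiles = _group_mean_profiles(kept, self.design, tr)
            corr = profiles.T.corr()
            user_rho = params.get("rho")
            if user_rho is None:
                scanres = net.rmt_threshold(corr)
                rho = scanres.threshold
            else:
                rho = float(user_rho)
            modules = net.build_modules(profiles, corr, rho, seed=self.seed)
            assign = net.assign_by_anova(profiles, modules)
            assign.to_csv(self.out / f"module_assignment_{tr}.tsv", sep="\t", index=False)
            for mod in modules:
                if self.ontology is not None:
                    enr = net.enrich(mod.member_ids, self.ontology, list(profiles.index))
                    enr.insert(0, "module_id", mod.module_id)
                    rows.append(enr)
            pd.DataFrame(
                {f"module_{m.module_id}": m.eigenvector for m in modules}
            ).to_csv(self.out / f"module_eigenvectors_{tr}.tsv", sep="\t")
            self._log(f"network[{tr}]: rho={rho:.3f}, {len(modules)} modules")
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(
                self.out / "module_enrichment.tsv", sep="\t", index=False
            )

    def stage_integrate(self):
        self._require("tpm", "transcriptome", "integrate")
        self._require("proteome", "proteome", "integrate")
        self._require("ontology", "simulate/inputs", "integrate")
        all_rows, dens_rows, scatter_rows = [], [], []
        for tr in ("heat35", "heat40"):
            if tr not in set(self.design.table["treatment"]):
                continue
            tfc = integ.log2fc_vs_preheat(self.tpm.tpm, self.design, tr, offset=0.01)
            pfc = integ.log2fc_vs_preheat(self.proteome.intensities, self.design, tr)
            tw = integ.window_average(tfc)
            pw = integ.window_average(pfc)
            terms = integ.term_correlations(tw, pw, self.ontology)
            terms.insert(0, "treatment", tr)
            all_rows.append(terms)
            for w in tw.columns.intersection(pw.columns):
                sub = terms[terms["window"] == w]
                if len(sub) >= 2:
                    dens = integ.correlation_density(sub["r"].to_numpy())
                    dens.insert(0, "window", w)
                    dens.insert(0, "treatment", tr)
                    dens_rows.append(dens)
                try:
                    scatter_rows.append(
                        {"treatment": tr, **integ.global_scatter(tw, pw, w, terms)}
                    )
                except ValueError as exc:
                    warnings.warn(f"scatter skipped for {tr}/{w}: {exc}")
        if all_rows:
            pd.concat(all_rows, ignore_index=True).to_csv(
                self.out / "term_correlations.tsv", sep="\t", index=False
            )
        if dens_rows:
            pd.concat(dens_rows, ignore_index=True).to_csv(
                self.out / "correlation_density.tsv", sep="\t", index=False
            )
        if scatter_rows:
            pd.DataFrame(scatter_rows).to_csv(
                self.out / "global_scatter.tsv", sep="\t", index=False
            )
        self._log("integrate: transcript-protein window correlations written")

    # -- trace stages ------------------------------------------------------
    def stage_phenotype(self):
        cfg = self.config.get("phenotype") or {}
        rows = []
        from .matrices import read_trace_csv

        for item in cfg.get("od_traces", []):
            trace = read_trace_csv(item["path"], "od680")
            for seg in pheno.detect_cycles(trace, band=item.get("band", 0.08)):
                rows.append(
                    {
                        "trace": item["path"],
                        "start_h": seg.start_h,
                        "end_h": seg.end_h,
                        "growth_rate_per_h": seg.slope_per_h,
                        "doubling_time_h": seg.doubling_time_h,
                        "r2": seg.r_squared,
                    }
                )
        if rows:
            pd.DataFrame(rows).to_csv(self.out / "growth_segments.tsv", sep="\t", index=False)
        pig_rows = []
        for item in cfg.get("pigments", []):
            res = pheno.pigments(item["a470"], item["a652"], item["a665"], item.get("cells_per_ml"))
            pig_rows.append({"sample": item.get("sample", ""), **res.__dict__})
        if pig_rows:
            pd.DataFrame(pig_rows).drop(columns=["per_cell"]).to_csv(
                self.out / "pigments.tsv", sep="\t", index=False
            )
        self._log("phenotype: growth/pigment tables written")

    def stage_photophys(self):
        cfg = self.config.get("photophys") or {}
        from .matrices import read_trace_csv

        rows = []
        for item in cfg.get("ecs_traces", []):
            trace = read_trace_csv(item["path"], "ecs", {"dark_start_s": item["dark_start_s"]})
            res = photo.dirk_ecs(trace)
            rows.append(
                {"trace": item["path"], "kind": "ecs", "ecst": res["ecst"],
                 "tau_s": res["tau_s"], "conductivity": res["proton_conductivity"]}
            )
        for item in cfg.get("p700_traces", []):
            trace = read_trace_csv(item["path"], "p700", {"far_red_off_s": item.get("far_red_off_s", 0.0)})
            fit = photo.p700_tau(trace)
            rows.append({"trace": item["path"], "kind": "p700", "tau_s": fit.tau_s,
                         "amplitude": fit.amplitude, "misfit": fit.misfit})
        for item in cfg.get("spectra_77k", []):
            trace = read_trace_csv(item["path"], "spectrum77k")
            res = photo.psii_fraction_77k(trace)
            rows.append({"trace": item["path"], "kind": "77k",
                         "psii_percent": res["psii_percent"]})
        if rows:
            pd.DataFrame(rows).to_csv(self.out / "photophys.tsv", sep="\t", index=False)
        self._log("photophys: kinetic fits written")

    def stage_facs(self):
        cfg = self.config.get("facs") or {}
        from .matrices import read_trace_csv

        rows = []
        for item in cfg.get("histograms", []):
            trace = read_trace_csv(item["path"], "facs_hist")
            call = facs_mod.call_ploidy(trace, background=item.get("background", 0.0))
            for raw, corr_p, lab in zip(call.raw_peaks, call.corrected_peaks, call.labels):
                rows.append(
                    {"trace": item["path"], "raw_peak": raw, "corrected": corr_p,
                     "label": lab if lab else "unassigned",
                     "fraction": call.fractions.get(lab, np.nan) if lab else np.nan}
                )
        if rows:
            pd.DataFrame(rows).to_csv(self.out / "ploidy_calls.tsv", sep="\t", index=False)
        self._log("facs: ploidy calls written")

    def run(self, stages=None):
        stages = list(stages or self.config.get("stages") or STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise StageError(f"unknown stages: {sorted(unknown)}")
        self.load_inputs()
        for st in STAGES:  # dependency order
            if st not in stages:
                continue
            if st == "simulate" and "synthetic" not in self.config:
                continue  # real inputs supplied; nothing to simulate
            getattr(self, f"stage_{st}")()
        return self


def _design_from_config(config: dict) -> TimeCourseDesign:
    inputs = config.get("inputs") or {}
    if "design" in inputs:
        return read_design(inputs["design"])
    dcfg = config.get("design") or {}
    return default_design(
        treatments=tuple(dcfg.get("treatments", ("ctrl25", "heat35", "heat40"))),
        n_replicates=dcfg.get("n_replicates", 3),
    )


def _group_mean_profiles(values: pd.DataFrame, design, treatment: str) -> pd.DataFrame:
    cols = {}
    for tr, ph, t in design.group_keys(treatment):
        samples = [s for s in design.samples_for(tr, ph, t) if s in values.columns]
        if samples:
            cols[f"{ph}:{t:g}"] = values[samples].mean(axis=1)
    return pd.DataFrame(cols)


def run_pipeline(config, out_dir, seed: int | None = None, stages=None) -> PipelineRun:
    """Execute the configured stages; see module docstring."""
    cfg = load_config(config)
    run = PipelineRun(cfg, out_dir, seed=seed)
    return run.run(stages)
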