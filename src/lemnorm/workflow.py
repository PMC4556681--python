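"""Config-driven three-arm comparison: raw vs geNorm vs error-model normalization.

A single structured config (dict or YAML) drives the full pipeline --
load or simulate, quality-flag, impute for the reference-gene arms, run each
requested normalization, then evaluate: per-(gene, condition) sd reduction,
mean displacement, differential expression, variance decomposition and a
Student-t fit of the model residuals. Output is a machine-readable report
(plus CSV tables when an output directory is configured); identical config
and seed reproduce identical numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataio, model, refnorm, simgen, stats
from .errors import ParameterError

logger = logging.getLogger(__name__)

_METHODS = ("lem", "genorm", "ddct_single")


@dataclass
class WorkflowConfig:
    ct_path: str | None = None
    design_path: str | None = None
    simulate: dict | None = None          # SimConfig fields
    reference_group: str = "control"
    candidate_rgs: tuple = ()
    methods: tuple = ("lem", "genorm")
    batch_factors: tuple = ()
    use_ssdna: bool = False
    ct_max: float = 40.0
    knn_k: int = 10
    genorm_cutoff: float = 0.15
    single_rg: str | None = None          # default: most stable candidate
    tests: tuple = ("welch",)
    correction: str = "bonferroni"
    bonferroni_n: int | None = None
    residual_fit: bool = True
    residual_boot: int = 199
    variance_factors: tuple = ()
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.methods:
            raise ParameterError("at least one method is required")
        unknown = set(self.methods) - set(_METHODS)
        if unknown:
            raise ParameterError(f"unknown methods: {sorted(unknown)}")
        if self.simulate is None and (self.ct_path is None or self.design_path is None):
            raise ParameterError("either a simulate block or ct/design paths are required")
        for name in ("candidate_rgs", "methods", "batch_factors", "tests",
                     "variance_factors"):
            setattr(self, name, tuple(getattr(self, name)))

    @classmethod
    def from_dict(cls, d: dict) -> "WorkflowConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_inputs(config: WorkflowConfig):
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        table, design, truth = simgen.simulate(simgen.SimConfig(**sim))
        design = dataio.StudyDesign(table=design.table,
                                    reference_group=design.reference_group,
                                    batch_factors=config.batch_factors
                                    or design.batch_factors)
        return table, design, truth
    table = dataio.read_ct_long(config.ct_path)
    design = dataio.read_design(config.design_path, config.reference_group,
                                batch_factors=config.batch_factors)
    return table, design, None


def run(config: WorkflowConfig) -> dict:
    """Execute the configured comparison; returns the report dictionary.

    Every configured method contributes every configured evaluation, or an
    explicit ``{"skipped": reason}`` entry. Any stage failure aborts with the
    stage name; partial results gathered so far are attached to the raised
    error as ``partial_report``.
    """
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in dataclasses.asdict(config).items()},
                    "stages": {}, "arms": {}}
    stage = "load"
    try:
        table, design, truth = _load_inputs(config)
        ref = design.reference_group
        stage = "flag"
        table = dataio.flag_invalid(table, ct_max=config.ct_max)
        raw_matrix = table.mean_ct_matrix(include_imputed=False)
        report["stages"]["load"] = {
            "n_genes": len(table.genes), "n_samples": len(table.samples),
            "n_valid_records": table.n_valid(), "dropped": len(table.dropped)}

        arm_matrices: dict[str, pd.DataFrame] = {}
        norm_exprs: dict[str, model.NormalizedExpression] = {}
        lem_fit = None

        if "lem" in config.methods:
            stage = "lem"
            opts = model.LemOptions(reference_group=ref,
                                    batch_factors=config.batch_factors,
                                    use_ssdna_covariate=config.use_ssdna)
            lem_fit = model.fit_lem(table, design, opts)
            norm_exprs["lem"] = model.minus_delta_ct(lem_fit)
            arm_matrices["lem"] = lem_fit.yhat_matrix()
            report["arms"]["lem"] = {
                "conservation_error_cycles": lem_fit.conservation_error(),
                "global_treatment_contrast":
                    lem_fit.global_treatment_contrast().to_dict(),
                "warnings": lem_fit.warnings}

        needs_complete = {"genorm", "ddct_single"} & set(config.methods)
        imputed = None
        if needs_complete:
            stage = "impute"
            m = table.mean_ct_matrix(include_imputed=False)
            if m.isna().any().any():
                k = min(config.knn_k, len(table.genes) - 1)
                imputed = dataio.knn_impute(table, k=k)
            else:
                imputed = table

        genorm_res = None
        if "genorm" in config.methods or config.single_rg is None:
            candidates = list(config.candidate_rgs) or list(table.genes)
            if len(candidates) >= 3 and imputed is not None:
                stage = "genorm_ranking"
                q = refnorm.relative_quantities(
                    imputed.mean_ct_matrix().loc[candidates])
                genorm_res = refnorm.genorm(q, cutoff=config.genorm_cutoff)

        if "genorm" in config.methods:
            stage = "genorm"
            if genorm_res is None:
                report["arms"]["genorm"] = {
                    "skipped": "needs >= 3 candidate reference genes"}
            else:
                rgs = genorm_res.ranking[:genorm_res.selected_n]
                norm_table, nexpr = refnorm.genorm_normalize(
                    imputed, rgs, design=design)
                norm_exprs["genorm"] = nexpr
                arm_matrices["genorm"] = norm_table.mean_ct_matrix()
                report["arms"]["genorm"] = {
                    "selected_rgs": rgs,
                    "selected_n": genorm_res.selected_n,
                    "m_values": {g: float(v)
                                 for g, v in genorm_res.m_values.items()},
                    "v_ladder": {int(n): float(v)
                                 for n, v in genorm_res.v_ladder.items()},
                    "warnings": genorm_res.warnings}

        if "ddct_single" in config.methods:
            stage = "ddct_single"
            rg = config.single_rg or (genorm_res.ranking[0] if genorm_res
                                      else None)
            if rg is None:
                report["arms"]["ddct_single"] = {
                    "skipped": "no reference gene configured or rankable"}
            else:
                nexpr = model.single_rg_normalize(imputed or table, design, rg)
                norm_exprs["ddct_single"] = nexpr
                arm_matrices["ddct_single"] = nexpr.minus_delta_ct
                report["arms"]["ddct_single"] = {"reference_gene": rg}

        # evaluations per arm
        stage = "evaluate"
        for arm, mat in arm_matrices.items():
            entry = report["arms"].setdefault(arm, {})
            sdc = stats.sd_reduction(raw_matrix, mat, design)
            entry["sd_reduction"] = {
                grp: {"mean_pct": float(row["mean"]),
                      "sd_pct": float(row["std"]) if np.isfinite(row["std"]) else None}
                for grp, row in sdc.summary.iterrows()}
            entry["mean_reduction_pct_overall"] = (
                float(sdc.per_cell["reduction_pct"].mean())
                if len(sdc.per_cell) else None)
            _, med = stats.mean_displacement(raw_matrix, mat, design)
            entry["mean_displacement_median"] = {g: float(v)
                                                 for g, v in med.items()}
            if arm in norm_exprs:
                for test in config.tests:
                    de = stats.diff_expression(
                        norm_exprs[arm].minus_delta_ct, design, method=test,
                        correction=config.correction,
                        bonferroni_n=config.bonferroni_n)
                    entry[f"diff_expression_{test}"] = {
                        "n_tests": int(de["p"].notna().sum()),
                        "n_significant": int((de["p_adj"] < 0.05).sum()),
                        "min_p": float(de["p"].min()) if de["p"].notna().any()
                        else None}

        if config.variance_factors:
            stage = "variance_decomposition"
            vd = stats.variance_decomposition(table, design,
                                              list(config.variance_factors))
            report["variance_decomposition_median"] = {
                c: float(vd.proportions[c].median()) for c in vd.proportions}

        if config.residual_fit and lem_fit is not None:
            stage = "residual_fit"
            tfit = stats.fit_residual_t(
                lem_fit.residual_vector(), n_boot=config.residual_boot,
                p_method="bootstrap" if config.residual_boot else "asymptotic",
                seed=config.seed, with_qq=False)
            report["residual_t"] = {
                "df": tfit.df, "location": tfit.location, "scale": tfit.scale,
                "ks_stat": tfit.ks_stat, "ks_p": tfit.ks_p,
                "kuiper_stat": tfit.kuiper_stat, "kuiper_p": tfit.kuiper_p}

        if truth is not None and lem_fit is not None:
            stage = "recovery"
            rec = simgen.recovery_report(lem_fit, truth)
            report["recovery"] = {
                comp: {"bias": float(row["bias"]), "rmse": float(row["rmse"])}
                for comp, row in rec.iterrows()}

        if config.out_dir:
            stage = "write"
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for arm, mat in arm_matrices.items():
                dataio.write_results(mat.rename_axis("gene"),
                                     out / f"{arm}_matrix.csv")
            for arm, nexpr in norm_exprs.items():
                dataio.write_results(nexpr.minus_delta_ct.rename_axis("gene"),
                                     out / f"{arm}_minus_delta_ct.csv")
            with open(out / "summary.json", "w") as fh:
                json.dump(report, fh, indent=2, default=_jsonable)
            logger.info("workflow outputs written to %s", out)
    except Exception as exc:
        exc.partial_report = report          # type: ignore[attr-defined]
        raise RuntimeError(f"workflow stage {stage!r} failed: {exc}") from exc
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, pd.Series)):
        return list(obj)
    return str(obj)
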