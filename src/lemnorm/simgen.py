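"""Synthetic parallel-qPCR data with known ground truth.

The generator draws every component of the additive Ct error decomposition
(probe-per-array, batch/cDNA-conversion, sample, global and per-gene
treatment effects, Student-t residuals with variance increasing in mean Ct)
and emits a Ct table, its study design and the realized truth, so that
estimator-recovery and method-comparison claims can be tested without any
external data.

The default configuration mirrors a two-condition cell-culture experiment on
a 48x48 microfluidic chip: 2 groups x 4 biological replicates, 3 independent
cDNA conversions per biological sample, each run in 2 qPCR replicates (48
loaded samples), 48 assays on one array. Noise scales follow the variance
budget such experiments show: the cDNA-conversion (reverse transcription)
step dominates the technical error, with smaller per-sample and probe
pipetting terms and a heteroscedastic qPCR residual whose sd grows with Ct.
Residuals are Student-t with 5 degrees of freedom (heavier-tailed than
normal, as observed in chip residuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import CtTable, StudyDesign
from .errors import IntegrityError, ParameterError
from .model import LemFit

#: Residual sd never drops below this fraction of ``residual_scale``.
_SCALE_FLOOR_FRACTION = 0.1


@dataclass
class SimConfig:
    """Generative settings; all Ct-scale quantities in cycles."""

    n_genes: int = 48
    n_groups: int = 2
    n_bio_reps: int = 4
    n_cdna_reps: int = 3
    n_pcr_reps: int = 2
    n_arrays: int = 1
    baseline_ct: float = 22.0
    sd_probe_array: float = 0.3
    sd_sample: float = 0.2
    sd_batch: float = 0.5
    global_shift: Sequence[float] | None = None     # per group, cycles
    de_fraction: float = 0.25
    de_effect_sd: float = 1.0
    residual_df: float = 5.0
    residual_scale: float = 0.3
    heteroscedastic_slope: float = 0.02
    rg_genes: tuple = ()            # indices of designated stable genes
    rg_group_shift: Sequence[float] | None = None   # shared shift of rg genes per group
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_groups", "n_bio_reps", "n_cdna_reps",
                     "n_pcr_reps", "n_arrays"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        for name in ("sd_probe_array", "sd_sample", "sd_batch",
                     "residual_scale", "heteroscedastic_slope"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ParameterError("de_fraction must be in [0, 1]")
        if self.residual_df <= 2:
            raise ParameterError("residual_df must be > 2 (finite variance)")
        if self.global_shift is not None and len(self.global_shift) != self.n_groups:
            raise ParameterError("global_shift must have one entry per group")
        if self.rg_group_shift is not None and len(self.rg_group_shift) != self.n_groups:
            raise ParameterError("rg_group_shift must have one entry per group")
        bad = [i for i in self.rg_genes if not (0 <= i < self.n_genes)]
        if bad:
            raise ParameterError(f"rg_genes indices out of range: {bad}")
        self.rg_genes = tuple(self.rg_genes)


@dataclass
class SimTruth:
    """Realized effects behind a simulated table, keyed like the model fit."""

    gene_level: pd.Series               # gene -> cycles above/below baseline
    probe_array: pd.Series              # (gene, array) -> cycles
    batch: pd.Series                    # cdna_batch -> cycles
    sample: pd.Series                   # sample -> cycles
    global_treatment: pd.Series         # group -> cycles
    gene_treatment: pd.Series           # (gene, group) -> cycles
    residual: pd.Series                 # record index -> cycles
    noiseless_ct: pd.Series             # record index -> cycles
    de_flags: pd.Series                 # gene -> bool
    baseline_ct: float = 22.0
    config: SimConfig | None = None


def simulate(config: SimConfig) -> tuple[CtTable, StudyDesign, SimTruth]:
    """Draw one dataset from the additive error model.

    Ct(record) = baseline + gene_level + probe_array + batch + global_shift
               + gene_treatment + sample + residual

    with zero-mean normal effects at the configured sds, per-gene treatment
    effects only for the DE genes (never the designated stable genes), and
    Student-t residuals whose scale grows linearly with the gene's mean Ct.
    The same seed reproduces the table bit for bit.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    genes = [f"g{i:03d}" for i in range(c.n_genes)]
    groups = ["control"] + [f"treat{j}" for j in range(1, c.n_groups)]

    # design: samples are cDNA units nested in biological replicates
    rows = []
    for gi, grp in enumerate(groups):
        for b in range(1, c.n_bio_reps + 1):
            bio = f"{grp}_b{b}"
            for cd in range(1, c.n_cdna_reps + 1):
                rows.append({"sample": f"{bio}_c{cd}", "group": grp,
                             "bio_rep": bio, "cdna_batch": f"{bio}_c{cd}"})
    design_df = pd.DataFrame(rows).set_index("sample")
    design_df["array"] = [f"chip{i % c.n_arrays + 1}"
                          for i in range(len(design_df))]
    design = StudyDesign(table=design_df, reference_group="control",
                         batch_factors=("cdna_batch",) if c.n_cdna_reps > 1 else ())
    samples = list(design_df.index)
    arrays = sorted(design_df["array"].unique())

    gene_level = pd.Series(rng.uniform(-4.0, 8.0, c.n_genes), index=genes)
    pa = pd.Series(
        rng.normal(0.0, c.sd_probe_array, c.n_genes * len(arrays)),
        index=pd.MultiIndex.from_product([genes, arrays], names=["gene", "array"]))
    batch = pd.Series(rng.normal(0.0, c.sd_batch, len(samples)),
                      index=design_df["cdna_batch"].values)
    sample_eff = pd.Series(rng.normal(0.0, c.sd_sample, len(samples)),
                           index=samples)
    shifts = c.global_shift if c.global_shift is not None else [0.0] * c.n_groups
    dt = pd.Series(list(shifts), index=groups, dtype=float)

    rg_set = {genes[i] for i in c.rg_genes}
    candidates = [g for g in genes if g not in rg_set]
    n_de = int(round(c.de_fraction * len(candidates)))
    de_genes = set(rng.choice(candidates, size=n_de, replace=False)) if n_de else set()
    de_flags = pd.Series([g in de_genes for g in genes], index=genes)
    dtg_idx = pd.MultiIndex.from_product([genes, groups], names=["gene", "group"])
    dtg = pd.Series(0.0, index=dtg_idx)
    for g in sorted(de_genes):
        for grp in groups[1:]:
            dtg.loc[(g, grp)] = rng.normal(0.0, c.de_effect_sd)
    if c.rg_group_shift is not None:
        # coexpressed "reference" genes sharing one group-dependent factor
        for g in sorted(rg_set):
            for grp, s in zip(groups, c.rg_group_shift):
                dtg.loc[(g, grp)] = dtg.loc[(g, grp)] + s

    # records: gene x sample x pcr_rep
    rec = pd.DataFrame(
        [(g, s, r) for g in genes for s in samples
         for r in range(1, c.n_pcr_reps + 1)],
        columns=["gene", "sample", "pcr_rep"])
    rec["array"] = rec["sample"].map(design_df["array"])
    rec["assay_rep"] = 1
    grp_of = rec["sample"].map(design_df["group"])
    noiseless = (c.baseline_ct
                 + rec["gene"].map(gene_level).to_numpy()
                 + pa.reindex(pd.MultiIndex.from_arrays(
                     [rec["gene"], rec["array"]])).to_numpy()
                 + rec["sample"].map(design_df["cdna_batch"]).map(batch).to_numpy()
                 + grp_of.map(dt).to_numpy()
                 + dtg.reindex(pd.MultiIndex.from_arrays(
                     [rec["gene"], grp_of])).to_numpy()
                 + rec["sample"].map(sample_eff).to_numpy())
    gene_mean = c.baseline_ct + rec["gene"].map(gene_level).to_numpy()
    scale = np.maximum(c.residual_scale
                       + c.heteroscedastic_slope * (gene_mean - c.baseline_ct),
                       _SCALE_FLOOR_FRACTION * c.residual_scale)
    resid = rng.standard_t(c.residual_df, len(rec)) * scale
    rec["ct"] = noiseless + resid
    rec["valid"] = True
    rec["imputed"] = False

    table = CtTable.from_records(rec, provenance=f"simulated(seed={c.seed})")
    truth = SimTruth(gene_level=gene_level, probe_array=pa,
                     batch=batch.groupby(level=0).first(),
                     sample=sample_eff, global_treatment=dt, gene_treatment=dtg,
                     residual=pd.Series(resid, index=table.records.index),
                     noiseless_ct=pd.Series(noiseless, index=table.records.index),
                     de_flags=de_flags, baseline_ct=c.baseline_ct, config=c)
    return table, design, truth


# ---------------------------------------------------------------------------


def recovery_report(fit: LemFit, truth: SimTruth) -> pd.DataFrame:
    """Bias/RMSE of estimated effects against the simulated truth.

    Absolute effect levels are not identified (any constant moves freely
    between components), so each family is compared on identifiable
    contrasts: global and per-gene treatment effects against the reference
    group, sample effects centred within their treatment group. Rows:
    component, bias, rmse, n, plus an empirical-coverage column for the
    per-gene treatment contrasts (nominal 95% intervals from the residual
    spread).
    """
    ref = fit.options.reference_group
    if not set(fit.global_treatment.index) <= set(truth.global_treatment.index):
        raise IntegrityError("fit and truth use different group labels")
    rows = []

    # the global shift and the all-gene mean of the per-gene effects move
    # freely between the two components, so the global contrast is compared
    # against truth Delta_T plus the gene-average of the true Delta_TG
    est_dt = fit.global_treatment - fit.global_treatment[ref]
    tru_dtg_mean = truth.gene_treatment.groupby(level="group").mean()
    tru_dt = (truth.global_treatment + tru_dtg_mean)
    tru_dt = tru_dt - tru_dt[ref]
    err = (est_dt - tru_dt.reindex(est_dt.index)).drop(index=ref)
    rows.append({"component": "global_treatment_contrast",
                 "bias": err.mean(), "rmse": np.sqrt((err ** 2).mean()),
                 "n": len(err), "coverage": np.nan})

    # per-gene treatment contrasts are identified as the *total* shift
    # Delta_T + Delta_TG relative to the reference group
    est = (fit.gene_treatment + fit.global_treatment.reindex(
        fit.gene_treatment.index.get_level_values("group")).values
    ).unstack("group")
    tru = (truth.gene_treatment + truth.global_treatment.reindex(
        truth.gene_treatment.index.get_level_values("group")).values
    ).unstack("group").reindex(est.index)
    est_c = est.sub(est[ref], axis=0).drop(columns=ref)
    tru_c = tru.sub(tru[ref], axis=0).drop(columns=ref)
    err = (est_c - tru_c).to_numpy().ravel()
    err = err[np.isfinite(err)]
    # nominal SE of a contrast of two cell means from the residual spread
    resid_sd = float(fit.records["eps"].std(ddof=1))
    counts = fit.records.groupby(["gene", "group"])["ct"].size()
    n_cell = float(counts.median())
    se = resid_sd * np.sqrt(2.0 / n_cell)
    coverage = float(np.mean(np.abs(err) <= 1.96 * se)) if len(err) else np.nan
    rows.append({"component": "gene_treatment_contrast",
                 "bias": err.mean(), "rmse": np.sqrt(np.mean(err ** 2)),
                 "n": len(err), "coverage": coverage})

    # batch and sample offsets are only identified jointly (and only up to
    # within-group centring), so compare their sum
    per_sample = fit.records.groupby("sample")[["eps_batch", "eps_s"]].mean().sum(axis=1)
    grp = fit.design.table["group"].reindex(per_sample.index)
    tru_s = (truth.sample
             + fit.design.table["cdna_batch"].map(truth.batch)).reindex(per_sample.index)
    est_cent = per_sample - per_sample.groupby(grp).transform("mean")
    tru_cent = tru_s - tru_s.groupby(grp).transform("mean")
    err = (est_cent - tru_cent).dropna()
    rows.append({"component": "sample_plus_batch_centred",
                 "bias": err.mean(), "rmse": np.sqrt((err ** 2).mean()),
                 "n": len(err), "coverage": np.nan})

    return pd.DataFrame(rows).set_index("component")
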