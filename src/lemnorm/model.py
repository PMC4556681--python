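"""Sequential linear error model for parallel qPCR Ct data.

Every chamber measurement is decomposed additively (cycles) as

    Ct = eps_PA + eps_batch + eps_S  +  Delta_T + Delta_TG + eps
         `------- technical -------'   `------- retained --------'

where ``eps_PA`` is the probe-per-array effect (mean of a gene's measurements
on one chip), ``eps_batch`` collects systematic batch offsets (e.g. cDNA
conversion runs), ``eps_S`` the per-sample effect (mean of a sample over all
genes), ``Delta_T`` the global treatment shift of the all-gene average,
``Delta_TG`` the per-gene treatment effect (the biology of interest) and
``eps`` the residual holding biological variation plus non-systematic
technical noise.

The effects are estimated as plain (or optionally median) group means in a
fixed order -- probe-per-array, batch, global treatment, sample, per-gene
treatment -- and the order matters: estimating the sample effect before the
global treatment shift would absorb the shift into the sample effects and
silently remove it from the retained values. ``fit_lem`` enforces the correct
order; a diagnostic flag exposes the wrong one so its failure mode can be
demonstrated.

Retained values ``Yhat = Delta_T + Delta_TG + eps`` feed the -dCt contrast

    -dCt = -(Yhat - mean[Yhat over reference-group records])     per gene,

and fold changes ``base ** (-dCt)`` with base 2 (assay efficiencies are taken
as 100%, i.e. a doubling per cycle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import CtTable, StudyDesign
from .errors import IntegrityError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class LemOptions:
    """Fitting options for the linear error model.

    ``batch_factors`` overrides the design's factor list when given.
    ``use_ssdna_covariate`` turns on the single-stranded-cDNA regression
    that identifies sample-level systematic errors which would otherwise be
    confounded with the treatment. ``efficiency_base`` is the fold change per
    cycle (default 2, i.e. 100% PCR efficiency). ``robust`` switches every
    mean to a median.
    """

    reference_group: str
    batch_factors: tuple = ()
    use_ssdna_covariate: bool = False
    efficiency_base: float = 2.0
    robust: bool = False

    def __post_init__(self):
        if self.efficiency_base <= 1:
            raise ParameterError("efficiency_base must be > 1")
        self.batch_factors = tuple(self.batch_factors)


@dataclass
class LemFit:
    """Estimated decomposition of a Ct table.

    ``records`` holds one row per valid measurement with the raw ``ct``, every
    per-record effect column (``eps_pa``, ``eps_batch``, ``delta_t``,
    ``eps_s``, ``delta_tg``), the residual ``eps`` and the retained value
    ``yhat``. Level tables give each effect at its natural granularity.
    The identity ``ct == eps_pa + eps_batch + eps_s + yhat`` holds to machine
    precision for every record.
    """

    records: pd.DataFrame
    probe_array_effect: pd.Series          # (gene, array) -> cycles
    batch_effect: dict                     # factor -> level Series
    global_treatment: pd.Series            # group -> cycles
    sample_effect: pd.Series               # sample -> cycles
    gene_treatment: pd.Series              # (gene, group) -> cycles
    options: LemOptions
    design: StudyDesign
    warnings: list = field(default_factory=list)

    @property
    def residual(self) -> pd.Series:
        return self.records["eps"]

    @property
    def retained(self) -> pd.Series:
        return self.records["yhat"]

    def conservation_error(self) -> float:
        """Largest |Ct - sum of components| over all records (cycles)."""
        r = self.records
        recon = r["eps_pa"] + r["eps_batch"] + r["eps_s"] + r["yhat"]
        return float((r["ct"] - recon).abs().max())

    def global_treatment_contrast(self) -> pd.Series:
        """Global treatment shift relative to the reference group (zero there)."""
        ref = self.global_treatment.get(self.options.reference_group, np.nan)
        return self.global_treatment - ref

    def yhat_matrix(self) -> pd.DataFrame:
        """Gene x sample matrix of per-cell mean retained values."""
        return self.records.pivot_table(index="gene", columns="sample",
                                        values="yhat", aggfunc="mean")

    def residual_vector(self) -> np.ndarray:
        return self.records["eps"].to_numpy()


@dataclass
class NormalizedExpression:
    """Per-(gene, sample) -dCt values and fold changes against a reference group."""

    minus_delta_ct: pd.DataFrame
    reference_group: str
    base: float = 2.0
    per_record: pd.DataFrame | None = None
    dropped_genes: list = field(default_factory=list)
    dropped_samples: list = field(default_factory=list)

    @property
    def fold_change(self) -> pd.DataFrame:
        return self.base ** self.minus_delta_ct


# ---------------------------------------------------------------------------


def estimate_group_mean_effect(values: pd.Series, grouping: pd.Series,
                               robust: bool = False):
    """Per-level mean (or median) effect and the centred residuals.

    Missing values are ignored, never imputed. Levels whose values are all
    missing get an undefined (NaN) effect and are reported; the caller decides
    whether to drop or abort.

    Returns ``(effects, residuals, empty_levels)``.
    """
    agg = "median" if robust else "mean"
    effects = values.groupby(grouping).agg(agg)
    fitted = grouping.map(effects)
    residuals = values - fitted
    empty = effects.index[effects.isna()].tolist()
    if empty:
        logger.warning("levels without valid values: %s", empty)
    return effects, residuals, empty


def _transform(df: pd.DataFrame, by, values: pd.Series, robust: bool) -> pd.Series:
    agg = "median" if robust else "mean"
    return values.groupby([df[b] for b in by] if isinstance(by, list) else df[by]) \
                 .transform(agg)


def fit_lem(table: CtTable, design: StudyDesign,
            options: LemOptions | None = None, *,
            sample_error_first: bool = False) -> LemFit:
    """Fit the sequential linear error model.

    Estimation order (each step works on the previous step's residuals):

    1. probe-per-array effect: per-(gene, array) mean of Ct;
    2. systematic batch effects: for each configured batch factor, level
       means estimated only from variation orthogonal to the treatment
       (within-biological-replicate level means for nested factors,
       group-centred level means for crossed ones); optionally a regression
       of per-sample residual means on centred log2 ssDNA quantity;
       a batch factor whose levels coincide with treatment groups is
       indistinguishable from the treatment itself and is skipped with a
       warning unless the ssDNA covariate is used;
    3. global treatment shift: per-group mean over all genes and records;
    4. sample effect: per-sample mean of the step-2 residuals minus the
       sample's group shift;
    5. per-gene treatment effect: per-(gene, group) mean of what remains.

    Only measured values participate (no imputation; invalid and imputed
    records are excluded). ``sample_error_first=True`` deliberately runs step
    4 before step 3 -- a diagnostic that demonstrates how the global
    treatment shift is then absorbed into the sample effects.
    """
    if options is None:
        options = LemOptions(reference_group=design.reference_group,
                             batch_factors=design.batch_factors)
    factors = options.batch_factors or design.batch_factors
    robust = options.robust
    warnings: list = []

    df = table.records
    df = df[df["valid"] & ~df["imputed"]].copy().reset_index(drop=True)
    if not len(df):
        raise IntegrityError("no valid records to fit")
    design.require_covers(df["sample"].unique())
    d = design.table
    df["group"] = df["sample"].map(d["group"])
    df["bio_rep"] = df["sample"].map(d["bio_rep"])
    for f in factors:
        df[f] = df["sample"].map(d[f])
    if options.reference_group not in set(df["group"]):
        raise ParameterError(
            f"reference group {options.reference_group!r} has no samples")

    # step 1: probe error per array
    pa_fit = _transform(df, ["gene", "array"], df["ct"], robust)
    df["eps_pa"] = pa_fit
    r = df["ct"] - pa_fit
    pa_levels = df.groupby(["gene", "array"])["ct"].agg(
        "median" if robust else "mean")

    # step 2: systematic batch effects
    df["eps_batch"] = 0.0
    batch_levels: dict = {}
    if options.use_ssdna_covariate:
        if not design.has_ssdna():
            raise ParameterError("use_ssdna_covariate requires ssdna for all samples")
        x = np.log2(d["ssdna"].astype(float))
        x = x - x.mean()
        ybar = r.groupby(df["sample"]).mean()
        xs = x.reindex(ybar.index)
        denom = float(((xs - xs.mean()) ** 2).sum())
        if denom <= 0:
            raise ParameterError("ssdna covariate has no variance")
        slope = float(((xs - xs.mean()) * (ybar - ybar.mean())).sum() / denom)
        eff = df["sample"].map(slope * x)
        df["eps_batch"] = df["eps_batch"] + eff
        r = r - eff
        batch_levels["ssdna"] = slope * x
        logger.info("ssdna covariate slope: %.4f cycles per log2 unit", slope)
    for f in factors:
        level_to_bio = d.groupby(f)["bio_rep"].nunique()
        level_to_group = d.groupby(f)["group"].nunique()
        nested_in_bio = (level_to_bio <= 1).all()
        within_group = (level_to_group <= 1).all()
        if nested_in_bio:
            t_level = _transform(df, f, r, robust)
            t_parent = _transform(df, "bio_rep", r, robust)
            eff = t_level - t_parent
        elif within_group and len(design.groups) > 1:
            msg = (f"batch factor {f!r} is confounded with the treatment "
                   f"groups; its group-wise component is indistinguishable "
                   f"from the treatment and is skipped (use the ssDNA "
                   f"covariate to identify it)")
            warnings.append(msg)
            logger.warning(msg)
            continue
        else:
            rc = r - _transform(df, "group", r, robust)
            eff = _transform(df, f, rc, robust)
        df["eps_batch"] = df["eps_batch"] + eff
        r = r - eff
        batch_levels[f] = eff.groupby(df[f]).first()

    agg = "median" if robust else "mean"
    if not sample_error_first:
        # step 3: global treatment shift (record-weighted)
        dt_fit = _transform(df, "group", r, robust)
        df["delta_t"] = dt_fit
        # step 4: sample effect on the *step-2* residuals, treatment removed
        ms = _transform(df, "sample", r, robust)
        df["eps_s"] = ms - dt_fit
        r4 = r - ms
    else:
        # wrong order, kept as a diagnostic: the per-sample means soak up the
        # treatment shift, leaving a near-zero "global" effect afterwards
        ms = _transform(df, "sample", r, robust)
        df["eps_s"] = ms
        r_after = r - ms
        dt_fit = _transform(df, "group", r_after, robust)
        df["delta_t"] = dt_fit
        r4 = r_after - dt_fit
    # step 5: per-gene treatment effect
    dtg_fit = _transform(df, ["gene", "group"], r4, robust)
    df["delta_tg"] = dtg_fit
    df["eps"] = r4 - dtg_fit
    df["yhat"] = df["delta_t"] + df["delta_tg"] + df["eps"]

    dt_levels = df.groupby("group")["delta_t"].first()
    s_levels = df.groupby("sample")["eps_s"].first()
    dtg_levels = df.groupby(["gene", "group"])["delta_tg"].first()

    fit = LemFit(records=df,
                 probe_array_effect=pa_levels,
                 batch_effect=batch_levels,
                 global_treatment=dt_levels,
                 sample_effect=s_levels,
                 gene_treatment=dtg_levels,
                 options=options, design=design, warnings=warnings)
    logger.info("fit_lem: %d records, conservation error %.2e cycles",
                len(df), fit.conservation_error())
    return fit


def minus_delta_ct(fit: LemFit) -> NormalizedExpression:
    """Per-gene contrast of retained values against the reference group.

    -dCt(g, record) = -(Yhat - mean over reference-group records of Yhat(g)).
    Reference-group gene means are exactly zero; the per-(gene, sample) matrix
    averages records within each cell. Genes without any valid
    reference-group record are excluded and reported.
    """
    df = fit.records
    ref = fit.options.reference_group
    is_ref = df["group"] == ref
    ref_mean = df.loc[is_ref].groupby("gene")["yhat"].mean()
    dropped = sorted(set(df["gene"]) - set(ref_mean.index))
    if dropped:
        logger.warning("genes without reference-group records excluded: %s", dropped)
    sub = df[df["gene"].isin(ref_mean.index)].copy()
    sub["minus_delta_ct"] = -(sub["yhat"] - sub["gene"].map(ref_mean))
    mat = sub.pivot_table(index="gene", columns="sample",
                          values="minus_delta_ct", aggfunc="mean")
    return NormalizedExpression(minus_delta_ct=mat, reference_group=ref,
                                base=fit.options.efficiency_base,
                                per_record=sub, dropped_genes=dropped)


def single_rg_normalize(table: CtTable, design: StudyDesign, rg: str,
                        base: float = 2.0) -> NormalizedExpression:
    """Classical single-reference-gene relative quantification.

    For target gene *g* and sample *s*, with reference-group (control) Ct
    taken as the mean over control samples and both efficiencies equal to
    ``base``::

        -ddCt(g, s) = (mean_c Ct(g) - Ct(g, s)) - (mean_c Ct(rg) - Ct(rg, s))
        ratio       = base ** (-ddCt)

    Samples where the reference gene is not measured are excluded with a
    report.
    """
    m = table.mean_ct_matrix(include_imputed=True)
    if rg not in m.index:
        raise ParameterError(f"reference gene {rg!r} not in table")
    design.require_covers(m.columns)
    rg_row = m.loc[rg]
    bad = rg_row.index[rg_row.isna()].tolist()
    if bad:
        logger.warning("samples without reference-gene measurement excluded: %s", bad)
        m = m.drop(columns=bad)
        rg_row = rg_row.drop(index=bad)
    groups = m.columns.map(design.table["group"])
    ref_cols = m.columns[groups == design.reference_group]
    if not len(ref_cols):
        raise ParameterError("no reference-group samples with data")
    dct_t = m[ref_cols].mean(axis=1).values[:, None] - m.values
    dct_r = rg_row[ref_cols].mean() - rg_row.values[None, :]
    mdd = pd.DataFrame(dct_t - dct_r, index=m.index, columns=m.columns)
    return NormalizedExpression(minus_delta_ct=mdd,
                                reference_group=design.reference_group,
                                base=base, dropped_samples=bad)
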