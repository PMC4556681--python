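"""Evaluation statistics for qPCR normalization methods.

Covers: per-(gene, condition) standard-deviation reduction; mean-displacement
diagnostics (does a normalization shift a gene's condition mean relative to
raw data?); sequential nested ANOVA decomposing each gene's variance into the
replicate hierarchy (treatment, biological, cDNA conversion, qPCR, ...);
heteroscedasticity regression of replicate sd on mean Ct; Welch and
empirical-Bayes moderated t-tests for differential expression; paired
nonparametric tests for comparing sd vectors; and a Student-t fit of model
residuals with Kolmogorov-Smirnov and Kuiper goodness-of-fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.special import digamma, polygamma

from .dataio import CtTable, StudyDesign
from .errors import ParameterError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sd reduction and mean displacement


@dataclass
class SdComparison:
    """Per-(gene, group) sd of raw vs processed values and percent reduction."""

    per_cell: pd.DataFrame          # gene, group, sd_raw, sd_processed, reduction_pct
    summary: pd.DataFrame           # per group: mean and sd of reduction_pct
    n_excluded: int = 0


def _group_cols(matrix: pd.DataFrame, design: StudyDesign) -> pd.Series:
    design.require_covers(matrix.columns)
    return matrix.columns.map(design.table["group"])


def sd_reduction(raw: pd.DataFrame, processed: pd.DataFrame,
                 design: StudyDesign) -> SdComparison:
    """Percent reduction of per-(gene, group) sd from raw to processed.

    Both inputs are gene x sample matrices on the same keys; the sample sd
    (n-1 denominator) is taken over samples within each treatment group.
    Cells with fewer than two observations or zero raw sd are excluded and
    counted.
    """
    processed = processed.reindex(index=raw.index, columns=raw.columns)
    groups = _group_cols(raw, design)
    rows = []
    n_excluded = 0
    for grp in pd.unique(groups):
        cols = raw.columns[groups == grp]
        sr = raw[cols].std(axis=1, ddof=1)
        sp = processed[cols].std(axis=1, ddof=1)
        counts = raw[cols].notna().sum(axis=1)
        for g in raw.index:
            if counts[g] < 2 or not np.isfinite(sr[g]) or sr[g] == 0 \
                    or not np.isfinite(sp[g]):
                n_excluded += 1
                continue
            rows.append({"gene": g, "group": grp, "sd_raw": sr[g],
                         "sd_processed": sp[g],
                         "reduction_pct": 100.0 * (1.0 - sp[g] / sr[g])})
    per_cell = pd.DataFrame(rows)
    if n_excluded:
        logger.info("sd_reduction: %d cells excluded", n_excluded)
    summary = per_cell.groupby("group")["reduction_pct"].agg(["mean", "std"]) \
        if len(per_cell) else pd.DataFrame(columns=["mean", "std"])
    return SdComparison(per_cell=per_cell, summary=summary, n_excluded=n_excluded)


def mean_displacement(raw: pd.DataFrame, processed: pd.DataFrame,
                      design: StudyDesign):
    """Shift of per-(gene, group) means introduced by a normalization.

    shift(g, grp) = [mean processed - mean raw](g, grp)
                  - [mean processed - mean raw](g, reference group)

    i.e. displacement relative to the same contrast in the reference group,
    so per-gene constants cancel. Returns ``(per-gene DataFrame, per-group
    median Series)``.
    """
    processed = processed.reindex(index=raw.index, columns=raw.columns)
    groups = _group_cols(raw, design)
    diff = processed - raw
    shifts = {}
    for grp in pd.unique(groups):
        cols = raw.columns[groups == grp]
        shifts[grp] = diff[cols].mean(axis=1)
    shifts = pd.DataFrame(shifts)
    rel = shifts.sub(shifts[design.reference_group], axis=0)
    medians = rel.median(axis=0)
    return rel, medians


# ---------------------------------------------------------------------------
# variance decomposition


@dataclass
class VarianceDecomposition:
    """Per-gene proportions of sequential sums of squares, residual last."""

    proportions: pd.DataFrame       # genes x (factors + "residual"), sums to 1
    ss: pd.DataFrame
    factors: list


def _sequential_ss(y: np.ndarray, factor_codes: list) -> list:
    """Type-I sums of squares for an ordered list of categorical factors.

    Each step adds the factor's dummies to the cumulative design matrix and
    charges it the drop in residual sum of squares. Returns
    ``[ss_f1, ..., ss_fk, ss_residual]``.
    """
    n = len(y)
    X = np.ones((n, 1))
    resid = y - y.mean()
    rss_prev = float(resid @ resid)
    out = []
    for codes in factor_codes:
        dummies = pd.get_dummies(pd.Categorical(codes), dtype=float).values
        X = np.hstack([X, dummies])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        out.append(max(rss_prev - rss, 0.0))
        rss_prev = rss
    out.append(rss_prev)
    return out


def variance_decomposition(table: CtTable, design: StudyDesign,
                           factors: list, values: pd.Series | None = None
                           ) -> VarianceDecomposition:
    """Per-gene sequential (nested) ANOVA over the replicate hierarchy.

    ``factors`` are record-level columns: design columns (``group``,
    ``bio_rep``, ``cdna_batch``, ...) or record fields (``pcr_rep``,
    ``assay_rep``), ordered coarse to fine; the residual (charged to the
    finest step, qPCR) is appended. ``values`` optionally overrides the raw
    Ct per record (e.g. with error-model residual-plus-effects), aligned to
    ``table.records.index``. Proportions per gene sum to one; sample order
    never changes the result. Factors with a single level contribute zero.
    """
    df = table.records[table.records["valid"]].copy()
    design.require_covers(df["sample"].unique())
    for f in factors:
        if f in df.columns:
            continue
        if f in design.table.columns:
            df[f] = df["sample"].map(design.table[f])
        else:
            raise ParameterError(f"unknown factor {f!r}")
    y_all = df["ct"] if values is None else values.reindex(df.index)

    props, sss = {}, {}
    labels = list(factors) + ["residual"]
    for g, sub in df.groupby("gene", sort=False):
        y = y_all.loc[sub.index].to_numpy(dtype=float)
        if len(y) < 2:
            continue
        ss = _sequential_ss(y, [sub[f].to_numpy() for f in factors])
        total = sum(ss)
        sss[g] = ss
        props[g] = [s / total if total > 0 else 0.0 for s in ss]
    proportions = pd.DataFrame.from_dict(props, orient="index", columns=labels)
    ss = pd.DataFrame.from_dict(sss, orient="index", columns=labels)
    return VarianceDecomposition(proportions=proportions, ss=ss, factors=labels)


# ---------------------------------------------------------------------------
# heteroscedasticity


@dataclass
class SdMeanRegression:
    slope: float
    intercept: float
    rvalue: float
    pvalue: float
    positive_slope: bool
    points: pd.DataFrame


def sd_vs_mean_regression(table: CtTable, design: StudyDesign | None = None,
                          level: str = "technical") -> SdMeanRegression:
    """OLS of replicate sd on mean Ct, diagnosing heteroscedasticity.

    ``level="technical"``: one point per (gene, biological replicate), sd and
    mean over its technical replicate records. ``level="biological"``: one
    point per (gene, group), sd over the per-biological-replicate means.
    Needs at least 3 points and non-degenerate x variance.
    """
    df = table.records[table.records["valid"]].copy()
    if design is not None:
        df["bio_rep"] = df["sample"].map(design.table["bio_rep"])
        df["group"] = df["sample"].map(design.table["group"])
    else:
        # without a design every record of a gene counts as one technical set
        df["bio_rep"] = "all"
        df["group"] = "all"
    if level == "technical":
        agg = df.groupby(["gene", "bio_rep"])["ct"].agg(["mean", "std", "count"])
    elif level == "biological":
        per_bio = df.groupby(["gene", "group", "bio_rep"])["ct"].mean()
        agg = per_bio.groupby(["gene", "group"]).agg(["mean", "std", "count"])
    else:
        raise ParameterError(f"unknown level {level!r}")
    pts = agg[(agg["count"] >= 2) & agg["std"].notna()].reset_index()
    if len(pts) < 3:
        raise ParameterError("need at least 3 (mean, sd) points")
    if np.isclose(pts["mean"].var(), 0.0):
        raise ParameterError("degenerate x variance in sd-vs-mean regression")
    res = st.linregress(pts["mean"], pts["std"])
    return SdMeanRegression(slope=float(res.slope), intercept=float(res.intercept),
                            rvalue=float(res.rvalue), pvalue=float(res.pvalue),
                            positive_slope=res.slope > 0, points=pts)


# ---------------------------------------------------------------------------
# differential expression


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on trigamma; standard moment-matching helper.
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderated_t_prior(s2: np.ndarray, df: np.ndarray,
                      robust: bool = True) -> tuple:
    """Empirical-Bayes prior (d0, s0^2) for gene-wise variances.

    Moment matching on log variances: with z = log s2,
    E[z] = log s0^2 + digamma(d/2) - log(d/2) - (digamma(d0/2) - log(d0/2))
    and Var[z] = trigamma(d/2) + trigamma(d0/2). ``robust`` winsorizes the
    variances at the 1st/99th percentile before estimation so single outlier
    genes do not inflate the prior (an approximation to the published robust
    variant).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2u, dfu = s2[ok], df[ok]
    if robust and len(s2u) >= 10:
        lo, hi = np.percentile(s2u, [1, 99])
        s2u = np.clip(s2u, lo, hi)
    z = np.log(s2u)
    e = z - digamma(dfu / 2.0) + np.log(dfu / 2.0)
    emean = e.mean()
    n = len(e)
    evar = e.var(ddof=1) * 1.0 if n > 1 else 0.0
    target = evar - np.mean(polygamma(1, dfu / 2.0))
    if target > 0:
        d0 = 2.0 * _trigamma_inverse(target)
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def diff_expression(matrix: pd.DataFrame, design: StudyDesign,
                    method: str = "welch", correction: str = "bonferroni",
                    bonferroni_n: int | None = None,
                    robust: bool = True) -> pd.DataFrame:
    """Per-gene tests of each treatment group against the reference group.

    ``method="welch"``: unequal-variance t with Welch-Satterthwaite degrees
    of freedom. ``method="moderated"``: empirical-Bayes variance shrinkage --
    the posterior variance (d0*s0^2 + d_g*s_g^2)/(d0 + d_g) with the prior
    estimated by moment matching of log variances -- and a t statistic on
    d0 + d_g degrees of freedom. Bonferroni multiplies p by the number of
    tests performed (or ``bonferroni_n`` when the study defines a fixed
    denominator), capped at 1.

    Returns a tidy frame: gene, contrast, statistic, df, p, p_adj.
    Genes with zero within-group variance in both groups are reported as
    undefined (NaN statistic).
    """
    if method not in ("welch", "moderated"):
        raise ParameterError(f"unknown method {method!r}")
    if correction not in ("bonferroni", "none"):
        raise ParameterError(f"unknown correction {correction!r}")
    groups = _group_cols(matrix, design)
    ref_cols = matrix.columns[groups == design.reference_group]
    rows = []
    other = [g for g in pd.unique(groups) if g != design.reference_group]
    for grp in other:
        cols = matrix.columns[groups == grp]
        A = matrix[cols].to_numpy(dtype=float)
        B = matrix[ref_cols].to_numpy(dtype=float)
        nA = np.sum(np.isfinite(A), axis=1)
        nB = np.sum(np.isfinite(B), axis=1)
        mA, mB = np.nanmean(A, axis=1), np.nanmean(B, axis=1)
        vA = np.nanvar(A, axis=1, ddof=1)
        vB = np.nanvar(B, axis=1, ddof=1)
        if method == "welch":
            se2 = vA / nA + vB / nB
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = (mA - mB) / np.sqrt(se2)
                dof = se2 ** 2 / ((vA / nA) ** 2 / (nA - 1)
                                  + (vB / nB) ** 2 / (nB - 1))
            p = 2.0 * st.t.sf(np.abs(tstat), dof)
        else:
            dg = nA + nB - 2
            sp2 = ((nA - 1) * vA + (nB - 1) * vB) / dg
            d0, s02 = moderated_t_prior(sp2, dg, robust=robust)
            if np.isinf(d0):
                s2post = np.full_like(sp2, s02)
                dof = np.full_like(sp2, 1e6)
            else:
                s2post = (d0 * s02 + dg * sp2) / (d0 + dg)
                dof = d0 + dg
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = (mA - mB) / np.sqrt(s2post * (1.0 / nA + 1.0 / nB))
            p = 2.0 * st.t.sf(np.abs(tstat), dof)
        undef = (vA == 0) & (vB == 0)
        tstat = np.where(undef, np.nan, tstat)
        p = np.where(undef, np.nan, p)
        dof = np.broadcast_to(np.asarray(dof, dtype=float), tstat.shape)
        if np.any(undef):
            logger.warning("%d genes with zero variance in both groups (%s)",
                           int(np.sum(undef)), grp)
        contrast = f"{grp} vs {design.reference_group}"
        for i, g in enumerate(matrix.index):
            rows.append({"gene": g, "contrast": contrast,
                         "statistic": tstat[i], "df": dof[i], "p": p[i]})
    out = pd.DataFrame(rows)
    n_tests = bonferroni_n if bonferroni_n is not None else out["p"].notna().sum()
    if correction == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * n_tests, 1.0)
    else:
        out["p_adj"] = out["p"]
    return out


# ---------------------------------------------------------------------------
# paired nonparametric tests on sd vectors


@dataclass
class PairedTestResult:
    statistic: float
    p: float
    n_used: int
    n_zero_dropped: int
    method: str


def paired_sd_tests(sd_a, sd_b, method: str = "wilcoxon_signed_rank"
                    ) -> PairedTestResult:
    """Paired test of equality between two sd vectors (paired by gene/group).

    ``wilcoxon_signed_rank`` uses the exact null distribution for n <= 25 and
    the normal approximation with continuity correction above; ``sign`` is the
    exact binomial sign test. Zero differences are dropped (and counted); if
    every difference is zero the p-value is 1 by convention.
    """
    a = np.asarray(sd_a, dtype=float)
    b = np.asarray(sd_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("sd vectors must have equal length")
    if len(a) < 5:
        raise ParameterError("need at least 5 pairs")
    d = a - b
    nz = d != 0
    n_dropped = int(np.sum(~nz))
    d = d[nz]
    if n_dropped:
        logger.info("paired_sd_tests: %d zero differences dropped", n_dropped)
    if len(d) == 0:
        return PairedTestResult(statistic=np.nan, p=1.0, n_used=0,
                                n_zero_dropped=n_dropped, method=method)
    if method == "wilcoxon_signed_rank":
        mode = "exact" if len(d) <= 25 else "approx"
        res = st.wilcoxon(d, zero_method="wilcox", correction=(mode == "approx"),
                          method=mode)
        return PairedTestResult(float(res.statistic), float(res.pvalue),
                                len(d), n_dropped, method)
    if method == "sign":
        k = int(np.sum(d > 0))
        res = st.binomtest(k, len(d), 0.5)
        return PairedTestResult(float(k), float(res.pvalue), len(d),
                                n_dropped, method)
    raise ParameterError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# residual distribution


@dataclass
class TDistFit:
    """Maximum-likelihood Student-t fit of residuals plus goodness-of-fit."""

    df: float
    location: float
    scale: float
    ks_stat: float
    ks_p: float
    kuiper_stat: float
    kuiper_p: float
    qq: pd.DataFrame | None = None
    p_method: str = "bootstrap"


def kuiper_statistic(x, cdf) -> float:
    """Kuiper statistic V = D+ + D- of a sample against a continuous CDF.

    Unlike Kolmogorov-Smirnov, V is invariant under cyclic shifts of a
    circular sample, weighting both tails equally.
    """
    u = np.sort(np.asarray(cdf(np.asarray(x, dtype=float))))
    n = len(u)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    return float(d_plus + d_minus)


def kuiper_p_asymptotic(v: float, n: int) -> float:
    lam = v * (np.sqrt(n) + 0.155 + 0.24 / np.sqrt(n))
    if lam < 0.4:
        return 1.0
    k = np.arange(1, 101)
    terms = (4.0 * k ** 2 * lam ** 2 - 1.0) * np.exp(-2.0 * k ** 2 * lam ** 2)
    return float(np.clip(2.0 * terms.sum(), 0.0, 1.0))


def fit_residual_t(residuals, n_boot: int = 999, p_method: str = "bootstrap",
                   seed: int | None = None, with_qq: bool = True) -> TDistFit:
    """Fit a location-scale Student-t to residuals and test the fit.

    Parameters are maximum-likelihood (df, location, scale). Because the
    parameters are estimated from the same data, the default p-values come
    from a parametric bootstrap (the fit is re-estimated on every replicate,
    avoiding the Lilliefors bias); ``p_method="asymptotic"`` uses the
    classical large-sample formulas instead, which are fast but
    anti-conservative here.
    """
    x = np.asarray(residuals, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 30:
        raise ParameterError("need at least 30 residuals")
    df_, loc, scale = st.t.fit(x)
    cdf = st.t(df_, loc=loc, scale=scale).cdf
    ks_stat = float(st.kstest(x, cdf).statistic)
    v_stat = kuiper_statistic(x, cdf)

    if p_method == "asymptotic":
        ks_p = float(st.kstest(x, cdf).pvalue)
        kuiper_p = kuiper_p_asymptotic(v_stat, len(x))
    elif p_method == "bootstrap":
        rng = np.random.default_rng(seed)
        ks_ge = ku_ge = 0
        for _ in range(n_boot):
            sim = st.t.rvs(df_, loc=loc, scale=scale, size=len(x),
                           random_state=rng)
            bdf, bloc, bscale = st.t.fit(sim)
            bcdf = st.t(bdf, loc=bloc, scale=bscale).cdf
            if st.kstest(sim, bcdf).statistic >= ks_stat:
                ks_ge += 1
            if kuiper_statistic(sim, bcdf) >= v_stat:
                ku_ge += 1
        ks_p = (1 + ks_ge) / (n_boot + 1)
        kuiper_p = (1 + ku_ge) / (n_boot + 1)
    else:
        raise ParameterError(f"unknown p_method {p_method!r}")

    qq = None
    if with_qq:
        xs = np.sort(x)
        probs = (np.arange(1, len(x) + 1) - 0.5) / len(x)
        qq = pd.DataFrame({"theoretical": st.t.ppf(probs, df_, loc=loc, scale=scale),
                           "empirical": xs})
    return TDistFit(df=float(df_), location=float(loc), scale=float(scale),
                    ks_stat=ks_stat, ks_p=float(ks_p),
                    kuiper_stat=v_stat, kuiper_p=float(kuiper_p),
                    qq=qq, p_method=p_method)
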