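"""Reference-gene based comparator methods: delta-delta-Ct and geNorm.

geNorm ranks candidate reference genes (RGs) by the stability measure M --
the mean standard deviation, across samples, of a gene's pairwise log2
expression ratios with every other candidate -- iteratively removing the
least stable gene. The per-sample normalization factor NF_n is the geometric
mean of the n most stable genes' relative quantities; the pairwise variation
V(n, n+1) = sd of log2(NF_n / NF_{n+1}) decides how many RGs to use (the
conventional cutoff is 0.15).

``genorm_normalize`` maps the normalization back onto the Ct scale so that
geNorm output is directly comparable with raw and error-model-processed
values: NF is rescaled to geometric mean 1 over samples (which preserves each
gene's all-sample average Ct) and added as ``log_base NF`` cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CtTable, StudyDesign
from .errors import MissingDataError, ParameterError
from .model import NormalizedExpression

logger = logging.getLogger(__name__)


@dataclass
class DdctParams:
    """Efficiencies and control label for the delta-delta-Ct ratio."""

    e_tg: float = 2.0
    e_rg: float = 2.0
    control_group: str = "control"

    def __post_init__(self):
        for name, e in (("e_tg", self.e_tg), ("e_rg", self.e_rg)):
            if not (1.0 < e <= 2.2):
                raise ParameterError(f"{name} must be in (1, 2.2], got {e}")


@dataclass
class GeNormResult:
    """Stability ranking, normalization factors and pairwise-variation ladder."""

    m_values: pd.Series                 # gene -> M at its elimination round
    ranking: list                       # most stable first
    m_history: list = field(default_factory=list)   # per-round M Series
    nf: pd.DataFrame | None = None      # samples x n
    v_ladder: pd.Series | None = None   # n -> V(n, n+1)
    selected_n: int | None = None
    cutoff: float = 0.15
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------


def ddct_ratio(params: DdctParams, ct_tg_c, ct_tg_s, ct_rg_c, ct_rg_s):
    """Relative expression ratio of a target gene versus a reference gene.

    ratio = e_tg ** (Ct_tg,control - Ct_tg,sample)
          / e_rg ** (Ct_rg,control - Ct_rg,sample)

    Accepts scalars or arrays; non-finite inputs propagate as NaN with a
    report.
    """
    args = [np.asarray(a, dtype=float) for a in (ct_tg_c, ct_tg_s, ct_rg_c, ct_rg_s)]
    bad = ~np.isfinite(sum(args))
    if np.any(bad):
        logger.warning("ddct_ratio: %d non-finite inputs propagated as missing",
                       int(np.sum(bad)))
    out = params.e_tg ** (args[0] - args[1]) / params.e_rg ** (args[2] - args[3])
    out = np.where(bad, np.nan, out)
    return float(out) if out.ndim == 0 else out


def relative_quantities(table, base: float = 2.0) -> pd.DataFrame:
    """Per-gene relative quantities Q for geNorm.

    Q(g, s) = base ** (min_s' Ct(g, s') - Ct(g, s)); the per-gene maximum is 1.
    Anchoring at the per-gene minimum Ct is the standard convention and
    cancels in every ratio geNorm forms. Requires a complete matrix -- impute
    first (see :func:`lemnorm.dataio.knn_impute`).
    """
    m = table.mean_ct_matrix(include_imputed=True) if isinstance(table, CtTable) \
        else pd.DataFrame(table)
    if m.isna().any().any():
        raise MissingDataError(
            "relative_quantities requires a complete matrix; run knn_impute first")
    return pd.DataFrame(base ** (m.min(axis=1).values[:, None] - m.values),
                        index=m.index, columns=m.columns)


def _m_values(q: pd.DataFrame) -> pd.Series:
    """Stability M for every gene: mean over partners of sd(log2 ratio)."""
    logq = np.log2(q.values)
    genes = q.index
    n = len(genes)
    m = np.empty(n)
    for i in range(n):
        diffs = logq[i][None, :] - logq      # partners x samples
        sds = np.std(np.delete(diffs, i, axis=0), axis=1, ddof=1)
        m[i] = sds.mean()
    return pd.Series(m, index=genes)


def genorm_stability(q: pd.DataFrame) -> GeNormResult:
    """Rank candidate reference genes by iterative elimination on M.

    Needs at least 3 candidate genes and 2 samples; quantities must be
    strictly positive. The gene with the highest M is removed and M
    recomputed until two genes remain; those two are tied best (the returned
    order breaks the tie lexicographically for determinism).
    """
    q = pd.DataFrame(q)
    if q.index.duplicated().any():
        raise ParameterError("duplicate gene names among candidates")
    if len(q.index) < 3:
        raise ParameterError("genorm_stability needs >= 3 candidate genes")
    if len(q.columns) < 2:
        raise ParameterError("genorm_stability needs >= 2 samples")
    if (q.values <= 0).any():
        raise ParameterError("quantities must be strictly positive")

    remaining = q.copy()
    history = []
    eliminated = []
    final_m = {}
    while len(remaining) > 2:
        m = _m_values(remaining)
        history.append(m)
        # ties broken toward the lexicographically last name, deterministically
        worst_m = m.max()
        worst = sorted(m.index[m == worst_m])[-1]
        final_m[worst] = float(m[worst])
        eliminated.append(worst)
        remaining = remaining.drop(index=worst)
    # M of the final pair: sd of their mutual log ratio (same for both)
    pair = sorted(remaining.index)
    sd_pair = float(np.std(np.log2(remaining.loc[pair[0]].values
                                   / remaining.loc[pair[1]].values), ddof=1))
    for g in pair:
        final_m[g] = sd_pair
    ranking = pair + list(reversed(eliminated))
    m_values = pd.Series({g: final_m[g] for g in ranking})
    return GeNormResult(m_values=m_values, ranking=ranking, m_history=history)


def genorm_select(q: pd.DataFrame, ranking: list,
                  cutoff: float = 0.15) -> GeNormResult:
    """Build NF_n factors and the pairwise-variation ladder; pick n.

    ``selected_n`` is the smallest n >= 2 with V(n, n+1) strictly below the
    cutoff; if no V passes, the n minimizing V is used with a warning. With
    fewer than 3 candidates the ladder is undefined and n = 2 is returned
    with a warning.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    q = pd.DataFrame(q).loc[ranking]
    warnings = []
    logq = np.log2(q.values)
    n_genes = len(ranking)
    nf_log = {n: logq[:n].mean(axis=0) for n in range(2, n_genes + 1)}
    nf = pd.DataFrame({n: 2.0 ** v for n, v in nf_log.items()}, index=q.columns)
    if n_genes < 3:
        warnings.append("fewer than 3 candidates: V ladder undefined, n = 2 used")
        logger.warning(warnings[-1])
        return GeNormResult(m_values=pd.Series(dtype=float), ranking=list(ranking),
                            nf=nf, v_ladder=pd.Series(dtype=float),
                            selected_n=2, cutoff=cutoff, warnings=warnings)
    v = {}
    for n in range(2, n_genes):
        v[n] = float(np.std(nf_log[n] - nf_log[n + 1], ddof=1))
    v_ladder = pd.Series(v)
    below = [n for n, val in v.items() if val < cutoff]
    if below:
        selected_n = min(below)
    else:
        selected_n = int(v_ladder.idxmin())
        warnings.append(
            f"no pairwise variation below cutoff {cutoff}; "
            f"using n = {selected_n} (minimum V = {v_ladder.min():.3f})")
        logger.warning(warnings[-1])
    return GeNormResult(m_values=pd.Series(dtype=float), ranking=list(ranking),
                        nf=nf, v_ladder=v_ladder, selected_n=selected_n,
                        cutoff=cutoff, warnings=warnings)


def genorm(q: pd.DataFrame, cutoff: float = 0.15) -> GeNormResult:
    """Convenience wrapper: stability ranking followed by NF/V selection."""
    stab = genorm_stability(q)
    sel = genorm_select(q, stab.ranking, cutoff=cutoff)
    sel.m_values = stab.m_values
    sel.m_history = stab.m_history
    return sel


def genorm_normalize(table: CtTable, rgs: list, base: float = 2.0,
                     design: StudyDesign | None = None):
    """Normalize a Ct table with a chosen set of reference genes.

    The per-sample NF (geometric mean of the RGs' relative quantities) is
    rescaled to geometric mean 1 across samples and applied on the Ct scale:
    ``Ct'(g, s) = Ct(g, s) + log_base NF_scaled(s)``. The rescaling keeps
    every gene's all-sample average Ct unchanged, making the output directly
    comparable with raw data. If a design is given, -dCt/fold changes against
    its reference group are computed from the normalized table as well.

    Returns ``(normalized CtTable, NormalizedExpression | None)``.
    """
    rgs = list(rgs)
    missing = sorted(set(rgs) - set(table.genes))
    if missing:
        raise ParameterError(f"reference genes not in table: {missing}")
    m = table.mean_ct_matrix(include_imputed=True)
    if m.loc[rgs].isna().any().any():
        raise MissingDataError("reference genes have missing cells; impute first")
    q_rg = base ** (m.loc[rgs].min(axis=1).values[:, None] - m.loc[rgs].values)
    log_nf = np.log2(q_rg).mean(axis=0) / np.log2(base)   # log_base NF
    log_nf_scaled = log_nf - log_nf.mean()
    shift = pd.Series(log_nf_scaled, index=m.columns)

    df = table.records.copy()
    usable = df["valid"] | df["imputed"]
    df.loc[usable, "ct"] = df.loc[usable, "ct"] + df.loc[usable, "sample"].map(shift)
    norm_table = CtTable.from_records(
        df, provenance=(table.provenance + "|genorm").lstrip("|"))

    norm_expr = None
    if design is not None:
        design.require_covers(m.columns)
        nm = norm_table.mean_ct_matrix(include_imputed=True)
        groups = nm.columns.map(design.table["group"])
        ref_cols = nm.columns[groups == design.reference_group]
        mdct = pd.DataFrame(nm[ref_cols].mean(axis=1).values[:, None] - nm.values,
                            index=nm.index, columns=nm.columns)
        norm_expr = NormalizedExpression(minus_delta_ct=mdct,
                                         reference_group=design.reference_group,
                                         base=base)
    return norm_table, norm_expr
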