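"""Shared builders and independent oracles for the test suite.

Oracles here are deliberately naive (explicit loops, brute force) and must
stay independent of the library code paths they check.
"""

import itertools

import numpy as np
import pandas as pd

from lemnorm import CtTable, StudyDesign


def build_table(matrix: pd.DataFrame, n_pcr: int = 1, array: str = "1",
                noise=None) -> CtTable:
    """CtTable from a gene x sample matrix; optional per-replicate noise."""
    rows = []
    for g in matrix.index:
        for s in matrix.columns:
            for r in range(1, n_pcr + 1):
                ct = matrix.at[g, s]
                if noise is not None:
                    ct = ct + noise(g, s, r)
                rows.append({"gene": g, "sample": s, "array": array,
                             "pcr_rep": r, "assay_rep": 1, "ct": ct})
    return CtTable.from_records(pd.DataFrame(rows))


def build_design(samples, groups, reference_group, bio_reps=None,
                 cdna_batches=None, ssdna=None, batch_factors=()) -> StudyDesign:
    df = pd.DataFrame({"sample": list(samples), "group": list(groups)})
    df["bio_rep"] = list(bio_reps) if bio_reps is not None else df["sample"]
    df["cdna_batch"] = list(cdna_batches) if cdna_batches is not None \
        else df["sample"]
    if ssdna is not None:
        df["ssdna"] = list(ssdna)
    return StudyDesign(table=df.set_index("sample"),
                       reference_group=reference_group,
                       batch_factors=tuple(batch_factors))


# ---------------------------------------------------------------------------
# oracles


def knn_impute_oracle(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Exhaustive-search KNN imputation on a gene x sample matrix.

    Distance between genes: Euclidean over mutually observed samples,
    rescaled by sqrt(n_total / n_observed); a donor must be observed in the
    target sample.
    """
    m = matrix.copy()
    vals = matrix.values.astype(float)
    n_total = vals.shape[1]
    for i, g in enumerate(matrix.index):
        for j, s in enumerate(matrix.columns):
            if not np.isnan(vals[i, j]):
                continue
            dists = []
            for i2 in range(len(matrix.index)):
                if i2 == i or np.isnan(vals[i2, j]):
                    continue
                both = ~np.isnan(vals[i]) & ~np.isnan(vals[i2])
                if not both.any():
                    continue
                d = np.sqrt(np.sum((vals[i][both] - vals[i2][both]) ** 2)
                            * n_total / both.sum())
                dists.append((d, i2))
            dists.sort()
            donors = [vals[i2, j] for _, i2 in dists[:k]]
            m.iloc[i, j] = np.mean(donors)
    return m


def sequential_means_oracle(ct: pd.DataFrame, groups: dict) -> dict:
    """Spreadsheet-style five-step decomposition of a one-array matrix.

    ``ct`` is gene x sample (one record per cell, single array, no batch
    factors); ``groups`` maps sample -> group. Returns the effect tables and
    per-cell residuals computed with explicit loops.
    """
    genes, samples = list(ct.index), list(ct.columns)
    pa = {g: np.mean([ct.at[g, s] for s in samples]) for g in genes}
    r1 = {(g, s): ct.at[g, s] - pa[g] for g in genes for s in samples}
    glevels = sorted(set(groups.values()))
    dt = {}
    for grp in glevels:
        vals = [r1[(g, s)] for g in genes for s in samples if groups[s] == grp]
        dt[grp] = np.mean(vals)
    es = {}
    for s in samples:
        vals = [r1[(g, s)] for g in genes]
        es[s] = np.mean(vals) - dt[groups[s]]
    r4 = {(g, s): r1[(g, s)] - dt[groups[s]] - es[s] for g in genes for s in samples}
    dtg = {}
    for g in genes:
        for grp in glevels:
            vals = [r4[(g, s)] for s in samples if groups[s] == grp]
            dtg[(g, grp)] = np.mean(vals)
    eps = {(g, s): r4[(g, s)] - dtg[(g, groups[s])] for g in genes for s in samples}
    return {"pa": pa, "dt": dt, "es": es, "dtg": dtg, "eps": eps}


def genorm_oracle(q: pd.DataFrame):
    """Brute-force geNorm: all-pairs log2-ratio sds, iterative elimination.

    Returns (list of per-round M dicts, elimination order).
    """
    remaining = list(q.index)
    rounds, elim = [], []
    while len(remaining) > 2:
        M = {}
        for j in remaining:
            sds = []
            for k2 in remaining:
                if k2 == j:
                    continue
                ratios = [np.log2(q.at[j, s] / q.at[k2, s]) for s in q.columns]
                sds.append(np.std(ratios, ddof=1))
            M[j] = np.mean(sds)
        rounds.append(M)
        worst_val = max(M.values())
        worst = sorted([g for g, v in M.items() if v == worst_val])[-1]
        elim.append(worst)
        remaining.remove(worst)
    return rounds, elim


def signed_rank_exact_p(diffs: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating all 2^n signs."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        w = min(w_plus, ranks.sum() - w_plus)
        if w <= w_obs:
            count += 1
    return count / 2 ** n


def nested_ss_oracle(y: np.ndarray, levels: list) -> list:
    """Explicit group-mean sequential SS for a nesting chain of factors.

    ``levels`` is a list of label arrays ordered coarse to fine. Returns
    [ss per factor..., residual ss] using cumulative-grouping cell means.
    """
    y = np.asarray(y, dtype=float)
    fits = [np.full(len(y), y.mean())]
    cum = None
    for lab in levels:
        lab = np.asarray(lab).astype(str)
        cum = lab if cum is None else np.char.add(cum, np.char.add("|", lab))
        fit = np.empty(len(y))
        for lv in np.unique(cum):
            mask = cum == lv
            fit[mask] = y[mask].mean()
        fits.append(fit)
    out = []
    for a, b in zip(fits, fits[1:]):
        out.append(float(np.sum((b - a) ** 2)))
    out.append(float(np.sum((y - fits[-1]) ** 2)))
    return out
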