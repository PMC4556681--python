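"""Reading, validation, flagging, imputation and writing of parallel qPCR Ct tables.

The canonical interchange format is a long ("tidy") CSV with one row per
reaction chamber and the header::

    gene,sample,array,pcr_rep,assay_rep,ct

``gene`` is the assay/probe identifier, ``sample`` the loaded cDNA identifier,
``array`` the chip, ``pcr_rep``/``assay_rep`` the qPCR and primer duplicate
indices. Instrument no-calls may appear as ``999``, ``No Call``, ``NA`` or an
empty cell; they are kept as records with ``valid = False`` so that downstream
methods can decide how to treat them (the linear error model ignores them,
the reference-gene comparators impute them).

Study metadata (treatment group, biological replicate, cDNA-conversion batch,
optional single-stranded cDNA quantity) lives in a separate design CSV with
header ``sample,group,bio_rep,cdna_batch[,array][,ssdna]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .errors import FormatError, IntegrityError, ParameterError

logger = logging.getLogger(__name__)

#: Columns that uniquely identify a reaction chamber.
KEY_COLUMNS = ["gene", "sample", "array", "pcr_rep", "assay_rep"]
#: Full canonical record schema (flags included).
RECORD_COLUMNS = KEY_COLUMNS + ["ct", "valid", "imputed"]

#: Case-insensitive sentinels treated as instrument no-calls.
DEFAULT_MISSING_SENTINELS = frozenset({"999", "999.0", "no call", "nocall", "", "na", "nan"})


def _ordered_unique(values: Iterable) -> list:
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


@dataclass
class CtTable:
    """Long-format reaction-chamber measurements with validity flags.

    ``records`` is a DataFrame with columns :data:`RECORD_COLUMNS`. ``genes``
    and ``samples`` preserve input order and exclude entities that ended up
    without any usable (valid or imputed) record; such entities are listed in
    ``dropped`` with a reason.
    """

    records: pd.DataFrame
    genes: list
    samples: list
    provenance: str = ""
    dropped: dict = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: pd.DataFrame, provenance: str = "") -> "CtTable":
        df = records.copy()
        for col, default in (("array", "1"), ("pcr_rep", 1), ("assay_rep", 1)):
            if col not in df.columns:
                df[col] = default
        for col in ("valid",):
            if col not in df.columns:
                df[col] = df["ct"].notna()
        if "imputed" not in df.columns:
            df["imputed"] = False
        df["gene"] = df["gene"].astype(str)
        df["sample"] = df["sample"].astype(str)
        df["array"] = df["array"].astype(str)
        df["pcr_rep"] = df["pcr_rep"].astype(int)
        df["assay_rep"] = df["assay_rep"].astype(int)
        df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
        df["valid"] = df["valid"].astype(bool) & df["ct"].notna()
        df["imputed"] = df["imputed"].astype(bool)

        dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            offending = df.loc[dup, KEY_COLUMNS].drop_duplicates().values.tolist()
            raise IntegrityError(f"duplicate record keys: {offending[:10]}")

        usable = df["valid"] | df["imputed"]
        genes = _ordered_unique(df["gene"])
        samples = _ordered_unique(df["sample"])
        dropped = {}
        ok_genes = set(df.loc[usable, "gene"])
        ok_samples = set(df.loc[usable, "sample"])
        for g in genes:
            if g not in ok_genes:
                dropped[("gene", g)] = "no valid record"
        for s in samples:
            if s not in ok_samples:
                dropped[("sample", s)] = "no valid record"
        if dropped:
            logger.warning("dropping %d entities without valid records: %s",
                           len(dropped), sorted(dropped))
            keep = df["gene"].isin(ok_genes) & df["sample"].isin(ok_samples)
            df = df[keep].reset_index(drop=True)
            genes = [g for g in genes if g in ok_genes]
            samples = [s for s in samples if s in ok_samples]

        return cls(records=df[RECORD_COLUMNS].reset_index(drop=True),
                   genes=genes, samples=samples,
                   provenance=provenance, dropped=dropped)

    def copy(self) -> "CtTable":
        return replace(self, records=self.records.copy(),
                       genes=list(self.genes), samples=list(self.samples),
                       dropped=dict(self.dropped))

    # -- views -------------------------------------------------------------

    def mean_ct_matrix(self, include_imputed: bool = True) -> pd.DataFrame:
        """Gene x sample matrix of per-cell mean Ct over usable records."""
        mask = self.records["valid"]
        if include_imputed:
            mask = mask | self.records["imputed"]
        sub = self.records[mask]
        mat = sub.pivot_table(index="gene", columns="sample", values="ct",
                              aggfunc="mean")
        return mat.reindex(index=self.genes, columns=self.samples)

    def n_valid(self) -> int:
        return int(self.records["valid"].sum())

    def equals(self, other: "CtTable") -> bool:
        """Order-insensitive equality of records and entity sets."""
        a = self.records.sort_values(KEY_COLUMNS).reset_index(drop=True)
        b = other.records.sort_values(KEY_COLUMNS).reset_index(drop=True)
        if sorted(self.genes) != sorted(other.genes):
            return False
        if sorted(self.samples) != sorted(other.samples):
            return False
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True


@dataclass
class StudyDesign:
    """Maps each sample to its experimental structure.

    ``table`` is indexed by sample with columns ``group``, ``bio_rep``,
    ``cdna_batch`` and optionally ``array`` and ``ssdna`` (single-stranded
    cDNA quantity in arbitrary linear units). ``batch_factors`` names the
    design columns to treat as systematic batch effects when fitting the
    linear error model.
    """

    table: pd.DataFrame
    reference_group: str
    batch_factors: tuple = ()

    def __post_init__(self):
        t = self.table
        required = {"group", "bio_rep", "cdna_batch"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"design is missing columns: {sorted(missing)}")
        if self.reference_group not in set(t["group"]):
            raise ParameterError(
                f"reference_group {self.reference_group!r} not among groups "
                f"{sorted(set(t['group']))}")
        nest = t.groupby("cdna_batch")["bio_rep"].nunique()
        bad = nest[nest > 1]
        if len(bad):
            raise IntegrityError(
                f"cdna_batch levels spanning several bio_reps: {list(bad.index)}")
        for f in self.batch_factors:
            if f not in t.columns:
                raise ParameterError(f"batch factor {f!r} not a design column")
        self.batch_factors = tuple(self.batch_factors)

    @property
    def samples(self) -> list:
        return list(self.table.index)

    @property
    def groups(self) -> list:
        return _ordered_unique(self.table["group"])

    def require_covers(self, samples: Iterable) -> None:
        missing = sorted(set(samples) - set(self.table.index))
        if missing:
            raise IntegrityError(f"samples without design entry: {missing}")

    def column_for_records(self, records: pd.DataFrame, col: str) -> pd.Series:
        return records["sample"].map(self.table[col])

    def has_ssdna(self) -> bool:
        return "ssdna" in self.table.columns and self.table["ssdna"].notna().all()


# ---------------------------------------------------------------------------
# reading


def _normalize_ct_column(raw: pd.Series, sentinels: frozenset) -> pd.Series:
    txt = raw.astype(str).str.strip().str.lower()
    is_missing = txt.isin(sentinels)
    ct = pd.to_numeric(raw, errors="coerce")
    ct[is_missing] = np.nan
    n_nonnum = int((ct.isna() & ~is_missing).sum())
    if n_nonnum:
        logger.warning("%d non-numeric Ct entries treated as missing", n_nonnum)
    return ct


_FLUIDIGM_ALIASES = {
    "gene": ("fam-mgb name", "assay", "assay name", "detector name", "gene"),
    "sample": ("sample name", "sample"),
    "ct": ("value", "ct value", "ct"),
    "call": ("ct call", "call"),
    "array": ("chip", "array", "chip id"),
}


def read_ct_long(path, dialect: str = "generic_csv",
                 sentinels: Iterable[str] | None = None) -> CtTable:
    """Read a Ct table from ``path``.

    ``dialect`` is ``generic_csv`` (canonical long format; columns ``gene``,
    ``sample``, ``ct`` required, replicate/array columns optional) or
    ``fluidigm_export`` (BioMark Real-Time PCR Analysis software CSV export,
    column names sniffed case-insensitively, the ``Call``/``Ct Call`` column
    honoured as a validity flag). ``.xlsx`` files are accepted for either
    dialect.

    Missing-value sentinels (``999``, ``No Call``, empty, ``NA``; configurable)
    and non-numeric entries become records with ``valid = False``. Row order in
    the file never affects downstream results.
    """
    path = Path(path)
    sent = frozenset(s.strip().lower() for s in sentinels) if sentinels is not None \
        else DEFAULT_MISSING_SENTINELS
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, dtype=str)
    else:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)

    if dialect == "generic_csv":
        raw.columns = [c.strip().lower() for c in raw.columns]
        for col in ("gene", "sample", "ct"):
            if col not in raw.columns:
                raise FormatError(f"required column {col!r} missing from {path.name}")
        df = raw.copy()
    elif dialect == "fluidigm_export":
        lower = {c.strip().lower(): c for c in raw.columns}
        mapping = {}
        for target, aliases in _FLUIDIGM_ALIASES.items():
            for a in aliases:
                if a in lower:
                    mapping[target] = lower[a]
                    break
        for col in ("gene", "sample", "ct"):
            if col not in mapping:
                raise FormatError(
                    f"could not locate a {col!r} column in Fluidigm export "
                    f"{path.name}; saw {list(raw.columns)}")
        df = pd.DataFrame({t: raw[c] for t, c in mapping.items() if t != "call"})
        if "call" in mapping:
            call = raw[mapping["call"]].astype(str).str.strip().str.lower()
            df["valid"] = ~call.isin({"fail", "no call", "nocall", "flag"})
            n_nc = int((~df["valid"]).sum())
            if n_nc:
                logger.info("Fluidigm export: %d chambers flagged by call column", n_nc)
        # replicate indices: successive occurrences of the same gene/sample pair
        df["pcr_rep"] = df.groupby(["gene", "sample"]).cumcount() + 1
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")

    df["ct"] = _normalize_ct_column(df["ct"], sent)
    if "valid" in df.columns:
        df["valid"] = df["valid"].astype(bool) & df["ct"].notna()
    table = CtTable.from_records(df, provenance=f"{dialect}:{path.name}")
    logger.info("read %s: %d genes x %d samples, %d/%d valid records",
                path.name, len(table.genes), len(table.samples),
                table.n_valid(), len(table.records))
    return table


def read_design(path, reference_group: str,
                batch_factors: Sequence[str] = ()) -> StudyDesign:
    """Read a study-design CSV (``sample,group,bio_rep,cdna_batch[,array][,ssdna]``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample" not in df.columns:
        raise FormatError(f"required column 'sample' missing from {path.name}")
    df["sample"] = df["sample"].astype(str)
    if df["sample"].duplicated().any():
        raise IntegrityError("duplicate sample rows in design")
    if "ssdna" in df.columns:
        df["ssdna"] = pd.to_numeric(df["ssdna"], errors="coerce")
    return StudyDesign(table=df.set_index("sample"),
                       reference_group=reference_group,
                       batch_factors=tuple(batch_factors))


# ---------------------------------------------------------------------------
# flagging and imputation


def flag_invalid(table: CtTable, ct_max: float = 40.0) -> CtTable:
    """Mark records with Ct above ``ct_max`` (cycles) as invalid.

    Idempotent; lowering ``ct_max`` never un-flags a record. Returns a new
    table (entities left without any valid record are reported as dropped).
    """
    if ct_max <= 0:
        raise ParameterError("ct_max must be > 0")
    df = table.records.copy()
    newly = df["valid"] & (df["ct"] > ct_max)
    if newly.any():
        logger.info("flag_invalid: %d records newly flagged (ct > %g)",
                    int(newly.sum()), ct_max)
    df.loc[newly, "valid"] = False
    return CtTable.from_records(df, provenance=table.provenance)


def knn_impute(table: CtTable, k: int = 10) -> CtTable:
    """Fill missing gene-by-sample cells by K-nearest-neighbour imputation.

    Works on the gene x sample matrix of per-cell mean Ct (technical
    replicates averaged first): a missing cell is replaced by the average of
    the ``k`` nearest genes (Euclidean distance over mutually observed
    samples, rescaled by ``sqrt(n_total / n_observed)``) that are observed in
    that sample, and the value is broadcast back into the record table with an
    ``imputed`` provenance flag. Observed cells are never altered. The default
    ``k = 10`` follows common practice for expression matrices.

    Genes missing everywhere cannot be imputed; they are reported and left
    missing.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    m = table.mean_ct_matrix(include_imputed=False)
    if not m.isna().any().any():
        return table.copy()
    all_missing = m.index[m.isna().all(axis=1)].tolist()
    work = m.drop(index=all_missing)
    if all_missing:
        logger.warning("knn_impute: genes with no observed values left missing: %s",
                       all_missing)
    if k > len(work) - 1:
        raise ParameterError(
            f"k={k} but only {len(work)} genes with observations are available")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = pd.DataFrame(imputer.fit_transform(work.values),
                          index=work.index, columns=work.columns)

    df = table.records.copy()
    cells = [(g, s) for g in work.index for s in work.columns
             if pd.isna(m.at[g, s])]
    new_rows = []
    for g, s in cells:
        value = filled.at[g, s]
        sel = (df["gene"] == g) & (df["sample"] == s)
        if sel.any():
            idx = df.index[sel][0]
            df.loc[idx, ["ct", "imputed"]] = [value, True]
        else:
            arr = df.loc[df["sample"] == s, "array"]
            new_rows.append({"gene": g, "sample": s,
                             "array": arr.iloc[0] if len(arr) else "1",
                             "pcr_rep": 1, "assay_rep": 1,
                             "ct": value, "valid": False, "imputed": True})
    if new_rows:
        df = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    logger.info("knn_impute: filled %d cells with k=%d", len(cells), k)
    return CtTable.from_records(df, provenance=table.provenance)


# ---------------------------------------------------------------------------
# writing


def write_results(result, path, format: str = "csv") -> None:
    """Write a result table (DataFrame or :class:`CtTable`) deterministically.

    Rows are ordered by gene then sample (lexicographically where applicable),
    columns keep their canonical order, and values are stored at full
    precision so a read-back reproduces them.
    """
    if format not in ("csv", "tsv"):
        raise ParameterError(f"unknown format {format!r}")
    sep = "," if format == "csv" else "\t"
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(result, CtTable):
        df = result.records.sort_values(KEY_COLUMNS).reset_index(drop=True)
        trivial_flags = (df["valid"] == df["ct"].notna()).all() and not df["imputed"].any()
        if trivial_flags:
            df = df[KEY_COLUMNS + ["ct"]]
    elif isinstance(result, pd.DataFrame):
        df = result.copy()
        sort_cols = [c for c in ("gene", "sample") if c in df.columns]
        if sort_cols:
            df = df.sort_values(sort_cols).reset_index(drop=True)
        elif df.index.name is not None:
            df = df.sort_index()
            df = df.reset_index()
    else:
        df = pd.DataFrame(result)
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def write_ct(table: CtTable, path, format: str = "csv") -> None:
    """Alias of :func:`write_results` restricted to Ct tables."""
    write_results(table, path, format=format)
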