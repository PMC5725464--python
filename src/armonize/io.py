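"""Reading per-method DE tables, expression matrices, manifests; building the
gene x method log2 fold-change matrix; the expression inclusion filter.

Per-method differential-expression callers export tables with different
column layouts; :func:`read_method_table` adapts any delimited layout through
a column map, so DESeq/CuffDiff/limma style exports need no code changes.
The merged :class:`ProfileMatrix` — genes as rows, methods as columns, with
an explicit missing mask — is the substrate for the ensemble regression and
PCA selections.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

CANONICAL_COLUMNS = ("gene_id", "log2fc", "pvalue", "qvalue")

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def strip_gene_version(gene_id: str) -> str:
    """Drop an Ensembl-style trailing version suffix (``ENSG...17.3`` -> ``ENSG...17``)."""
    return _VERSION_SUFFIX.sub("", gene_id)


@dataclass
class MethodCallTable:
    """One DE caller's output: per-gene log2FC with p- and FDR-adjusted q-values.

    ``records`` is a DataFrame indexed by gene_id with columns
    ``log2fc``, ``pvalue``, ``qvalue``; p/q may be NaN (absent), log2fc may not.
    Genes lacking a q-value are ineligible for significance calls downstream.
    """

    method_name: str
    records: pd.DataFrame
    parse_report: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.records
        missing_cols = [c for c in ("log2fc", "pvalue", "qvalue") if c not in df.columns]
        if missing_cols:
            raise ConfigError(f"method table '{self.method_name}' lacks columns: {missing_cols}")
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            raise DataError(
                f"method table '{self.method_name}' has duplicate gene_ids: {dup}"
            )
        lfc = df["log2fc"].to_numpy(float)
        if not np.all(np.isfinite(lfc)):
            bad = df.index[~np.isfinite(lfc)].tolist()
            raise DataError(
                f"method table '{self.method_name}' has non-finite log2fc for: {bad[:10]}"
            )
        for col in ("pvalue", "qvalue"):
            vals = df[col].to_numpy(float)
            present = ~np.isnan(vals)
            if np.any((vals[present] < 0) | (vals[present] > 1)):
                raise DataError(
                    f"method table '{self.method_name}': {col} outside [0, 1]"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.records.index)

    def __len__(self) -> int:
        return len(self.records)


def read_method_table(
    path,
    method_name: str,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
    strip_versions: bool = False,
) -> MethodCallTable:
    """Parse one caller's delimited export into a :class:`MethodCallTable`.

    ``column_map`` maps canonical names (gene_id, log2fc, pvalue, qvalue) to
    the file's own header names. Missing mapped columns raise
    :class:`ConfigError`; duplicate genes or non-numeric values raise
    :class:`DataError`. Absent ("NA"/empty) p/q values are kept as NaN and
    counted in ``parse_report``.
    """
    cmap = dict(zip(CANONICAL_COLUMNS, CANONICAL_COLUMNS))
    if column_map:
        unknown = set(column_map) - set(CANONICAL_COLUMNS)
        if unknown:
            raise ConfigError(f"unknown canonical column names in map: {sorted(unknown)}")
        cmap.update(column_map)

    try:
        raw = pd.read_csv(path, sep=sep, dtype=str)
    except FileNotFoundError:
        raise ConfigError(f"method table not found: {path}") from None

    for canon, src in cmap.items():
        if src not in raw.columns:
            raise ConfigError(
                f"column '{src}' (mapped from '{canon}') absent from {path}; "
                f"available: {list(raw.columns)}"
            )

    genes = raw[cmap["gene_id"]].astype(str)
    if genes.isna().any():
        raise DataError(f"{path}: missing gene_id values")
    if strip_versions:
        genes = genes.map(strip_gene_version)
    dup = genes[genes.duplicated()].unique().tolist()
    if dup:
        raise DataError(f"{path}: duplicate gene_ids: {dup}")

    def _numeric(canon: str, required: bool) -> pd.Series:
        col = raw[cmap[canon]]
        num = pd.to_numeric(col, errors="coerce")
        bad = num.isna() & col.notna()
        if bad.any():
            offenders = col[bad].unique().tolist()
            raise DataError(f"{path}: non-numeric {canon} values: {offenders[:10]}")
        if required and num.isna().any():
            raise DataError(f"{path}: missing {canon} values")
        return num

    lfc = _numeric("log2fc", required=True)
    pval = _numeric("pvalue", required=False)
    qval = _numeric("qvalue", required=False)

    records = pd.DataFrame(
        {"log2fc": lfc.values, "pvalue": pval.values, "qvalue": qval.values},
        index=pd.Index(genes.values, name="gene_id"),
    )
    report = {
        "n_records": len(records),
        "n_missing_pvalue": int(records["pvalue"].isna().sum()),
        "n_missing_qvalue": int(records["qvalue"].isna().sum()),
    }
    return MethodCallTable(method_name=method_name, records=records, parse_report=report)


def write_method_table(table: MethodCallTable, path, sep: str = "\t") -> None:
    """Write a table back to delimited text (round-trips with read_method_table)."""
    table.records.to_csv(path, sep=sep, na_rep="NA")


@dataclass
class ProfileMatrix:
    """Gene x method log2FC matrix; NaN cells are missing (not called by that method).

    Invariants: unique genes, every row observed by at least one method.
    """

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"profile matrix has duplicate genes: {dup}")
        if len(self.data) and self.data.isna().all(axis=1).any():
            bad = self.data.index[self.data.isna().all(axis=1)].tolist()
            raise DataError(f"genes with zero observed values: {bad[:10]}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def methods(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed-indicator, True where a value is present."""
        return self.data.notna()

    def missing_fraction(self) -> pd.Series:
        """Per-method fraction of genes the method did not call."""
        return self.data.isna().mean(axis=0)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)


def build_profile_matrix(tables: Sequence[MethodCallTable]) -> ProfileMatrix:
    """Merge per-method tables into the gene x method log2FC matrix.

    Gene set is the union across tables (first-seen order); a cell is observed
    iff the gene appears in that method's table. Rows with zero observations
    are impossible by construction.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ConfigError("build_profile_matrix requires at least 2 method tables")
    names = [t.method_name for t in tables]
    if len(set(names)) != len(names):
        raise ConfigError(f"method names must be distinct, got {names}")

    gene_order: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for g in t.records.index:
            if g not in seen:
                seen.add(g)
                gene_order.append(g)

    data = pd.DataFrame(
        np.nan, index=pd.Index(gene_order, name="gene_id"), columns=names, dtype=float
    )
    for t in tables:
        data.loc[t.records.index, t.method_name] = t.records["log2fc"].to_numpy(float)
    return ProfileMatrix(data)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values in one unit (fpkm or read_count)."""

    data: pd.DataFrame  # genes x samples, non-negative
    unit: str  # "fpkm" | "read_count"
    groups: pd.Series  # sample -> condition label

    def __post_init__(self):
        if self.unit not in ("fpkm", "read_count"):
            raise ConfigError(f"unit must be 'fpkm' or 'read_count', got {self.unit!r}")
        vals = self.data.to_numpy(float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise DataError(f"{self.unit} matrix contains negative or non-finite values")
        if self.unit == "read_count" and not np.allclose(vals, np.rint(vals)):
            raise DataError("read_count matrix contains non-integer values")
        missing = [s for s in self.data.columns if s not in self.groups.index]
        if missing:
            raise DataError(f"samples without group label: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class FilterConfig:
    """Expression inclusion rule: FPKM > fpkm_min and reads > count_min in at
    least ``sample_frac`` of samples, evaluated per condition group by default.

    Threshold comparisons are strict (>); the sample-fraction quota is
    inclusive (>=), with the quota as the ceiling of sample_frac * n.
    """

    fpkm_min: float = 1.0
    count_min: float = 10.0
    sample_frac: float = 0.10
    per_group: bool = True

    def __post_init__(self):
        if self.fpkm_min < 0 or self.count_min < 0:
            raise ConfigError("thresholds must be >= 0")
        if not (0 < self.sample_frac <= 1):
            raise ConfigError("sample_frac must be in (0, 1]")


def _quota(frac: float, n: int) -> int:
    # guard against float artifacts like 0.1 * 30 = 3.0000000000000004
    return max(1, math.ceil(frac * n - 1e-9))


def expression_filter(
    fpkm: ExpressionMatrix,
    counts: ExpressionMatrix,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[str], pd.DataFrame]:
    """Apply the inclusion filter to a paired (FPKM, read-count) matrix.

    A gene is retained iff it exceeds ``fpkm_min`` (strictly) in at least the
    quota of samples AND exceeds ``count_min`` (strictly) in at least the
    quota, where the quota is ceil(sample_frac * n_samples). With
    ``per_group`` the conjunction must hold within every condition group.
    Returns (retained gene list, per-gene report of passing-sample counts).
    """
    if fpkm.unit != "fpkm" or counts.unit != "read_count":
        raise ConfigError("expression_filter expects (fpkm, read_count) matrices in that order")
    if set(fpkm.data.index) != set(counts.data.index):
        raise DataError("fpkm and count matrices have different gene sets")
    if set(fpkm.samples) != set(counts.samples):
        raise DataError("fpkm and count matrices have different sample sets")
    counts_aligned = counts.data.loc[fpkm.data.index, fpkm.data.columns]

    if cfg.per_group:
        group_of = fpkm.groups.loc[fpkm.data.columns]
        groups = {g: list(group_of.index[group_of == g]) for g in group_of.unique()}
    else:
        groups = {"all": list(fpkm.data.columns)}

    report = pd.DataFrame(index=fpkm.data.index)
    ok_all = pd.Series(True, index=fpkm.data.index)
    for gname, samples in groups.items():
        q = _quota(cfg.sample_frac, len(samples))
        fp_pass = (fpkm.data[samples] > cfg.fpkm_min).sum(axis=1)
        ct_pass = (counts_aligned[samples] > cfg.count_min).sum(axis=1)
        ok = (fp_pass >= q) & (ct_pass >= q)
        report[f"{gname}_fpkm_pass"] = fp_pass
        report[f"{gname}_count_pass"] = ct_pass
        report[f"{gname}_quota"] = q
        ok_all &= ok
    report["retained"] = ok_all
    retained = list(fpkm.data.index[ok_all])
    return retained, report


@dataclass
class SampleManifest:
    """Per-sample QC accounting: group label, pass/fail flag and reason."""

    records: pd.DataFrame  # columns: sample_id, group, qc_flag (bool), flag_reason

    def __post_init__(self):
        df = self.records
        for col in ("sample_id", "group", "qc_flag"):
            if col not in df.columns:
                raise ConfigError(f"manifest lacks column '{col}'")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise DataError(f"duplicate sample_ids in manifest: {dup}")


def read_manifest(path, sep: str = "\t") -> SampleManifest:
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "qc_flag" in df.columns:
        df["qc_flag"] = df["qc_flag"].str.lower().map({"pass": True, "fail": False})
        if df["qc_flag"].isna().any():
            raise DataError(f"{path}: qc_flag values must be 'pass' or 'fail'")
    if "flag_reason" not in df.columns:
        df["flag_reason"] = ""
    return SampleManifest(df)


def count_retained(manifest: SampleManifest | pd.DataFrame | Iterable[bool],
                   by_group: bool = False):
    """Count records with a passing retention flag; optionally per group.

    Accepts a :class:`SampleManifest`, a DataFrame with ``qc_flag`` (and
    ``group``), or a bare iterable of booleans. Empty input yields 0.
    """
    if isinstance(manifest, SampleManifest):
        df = manifest.records
    elif isinstance(manifest, pd.DataFrame):
        df = manifest
    else:
        flags = list(manifest)
        if by_group:
            raise ConfigError("grouped counts need a manifest with a 'group' column")
        return int(sum(bool(f) for f in flags))
    if len(df) == 0:
        return {} if by_group else 0
    flags = df["qc_flag"].astype(bool)
    if by_group:
        return flags.groupby(df["group"]).sum().astype(int).to_dict()
    return int(flags.sum())
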