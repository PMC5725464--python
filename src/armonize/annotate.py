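"""Biotype and gene-family decomposition of gene selections, and
annotation-version set comparison.

Biotypes partition a selection (each gene counts once, unknowns fall into
an "unclassified" bucket); gene families overlap, so a gene with k family
labels contributes to k rows. Parental genes are additionally reported
both as an overlapping roll-up row (alongside the true biotype counts) and
as a strict partition where parental genes replace their biotype row.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigError, DataError

UNCLASSIFIED = "unclassified"
PARENTAL = "parental_gene"


@dataclass
class BiotypeCatalog:
    """Per-gene biotype, optional overlapping family labels, parental flag."""

    biotypes: dict[str, str]
    families: dict[str, set[str]] = field(default_factory=dict)
    parental: set[str] = field(default_factory=set)


def read_catalog(path, sep: str = "\t") -> BiotypeCatalog:
    """Read a catalog TSV: gene_id, biotype, families (semicolon-separated),
    is_parental (true/false/1/0; optional columns may be absent)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("gene_id", "biotype"):
        if col not in df.columns:
            raise ConfigError(f"catalog lacks column '{col}'")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise DataError(f"duplicate gene_ids in catalog: {dup[:10]}")
    biotypes = dict(zip(df["gene_id"], df["biotype"]))
    families: dict[str, set[str]] = {}
    if "families" in df.columns:
        for g, fam in zip(df["gene_id"], df["families"]):
            if isinstance(fam, str) and fam.strip():
                families[g] = {f.strip() for f in fam.split(";") if f.strip()}
    parental: set[str] = set()
    if "is_parental" in df.columns:
        truthy = {"true", "1", "yes"}
        parental = {
            g for g, flag in zip(df["gene_id"], df["is_parental"])
            if isinstance(flag, str) and flag.strip().lower() in truthy
        }
    return BiotypeCatalog(biotypes=biotypes, families=families, parental=parental)


@dataclass
class BiotypeBreakdown:
    """Counts per biotype (strict partition by true biotype), a parental
    roll-up that overlaps the biotype rows, and a strict-partition variant
    where parental genes occupy their own row instead of their biotype's."""

    biotype_counts: dict[str, int]
    parental_rollup: int
    strict_counts: dict[str, int]
    total: int

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(set(self.biotype_counts) | set(self.strict_counts))
        return pd.DataFrame(
            {
                "biotype": rows,
                "count": [self.biotype_counts.get(b, 0) for b in rows],
                "strict_count": [self.strict_counts.get(b, 0) for b in rows],
            }
        )


def biotype_decompose(selection: Iterable[str], catalog: BiotypeCatalog) -> BiotypeBreakdown:
    """Count a selection per biotype; every gene counted exactly once, with
    genes absent from the catalog bucketed as unclassified."""
    genes = set(selection)
    counts: Counter = Counter()
    strict: Counter = Counter()
    rollup = 0
    for g in genes:
        bt = catalog.biotypes.get(g, UNCLASSIFIED)
        counts[bt] += 1
        if g in catalog.parental:
            rollup += 1
            strict[PARENTAL] += 1
        else:
            strict[bt] += 1
    return BiotypeBreakdown(
        biotype_counts=dict(counts),
        parental_rollup=rollup,
        strict_counts=dict(strict),
        total=len(genes),
    )


def family_decompose(selection: Iterable[str], catalog: BiotypeCatalog) -> dict[str, int]:
    """Count a selection per gene-family label; families overlap, so a gene
    with k labels contributes to k rows and the column sum may exceed the
    selection size."""
    genes = set(selection)
    counts: Counter = Counter()
    for g in genes:
        for fam in catalog.families.get(g, ()):
            counts[fam] += 1
    return dict(counts)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VersionComparison:
    shared: int
    pct_shared: float  # of A, rounded half-up to 2 decimals
    pct_absent: float  # of A, likewise


def compare_annotation_versions(set_a: Iterable[str], set_b: Iterable[str]) -> VersionComparison:
    """How much of annotation set A survives into set B.

    Returns the shared count, the percentage of A contained in B and the
    percentage of A absent from B, each rounded half-up to two decimals
    (e.g. 51,858 of 62,893 genes -> 82.45% shared, 17.55% absent).
    """
    a, b = set(set_a), set(set_b)
    if not a:
        raise DataError("set A is empty: percentages undefined")
    shared = len(a & b)
    return VersionComparison(
        shared=shared,
        pct_shared=_round2(100.0 * shared / len(a)),
        pct_absent=_round2(100.0 * (len(a) - shared) / len(a)),
    )
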