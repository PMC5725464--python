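"""Pseudogene -> parental-gene association from tabular alignment hits.

A pseudogene's parental gene is the functional coding gene with the highest
sequence similarity; it is assigned as the best overall alignment hit by
e-value (ties broken by bitscore, then subject id, for determinism). Hits
with winning identity below 90% are flagged low-similarity, preserving the
caveat that read-level evidence for such pairs is weaker. Correlation
patterns between pseudogene and parent DE profiles are summarized per
expression-level stratum.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigError, DataError

HIT_FIELDS = (
    "query_id", "subject_id", "identity_pct", "align_len", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
)


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column blast-tabular alignment file."""

    query_id: str
    subject_id: str
    identity_pct: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not (0 <= self.identity_pct <= 100):
            raise DataError(f"identity_pct {self.identity_pct} outside [0, 100]")
        if self.evalue < 0:
            raise DataError(f"negative e-value {self.evalue}")


@dataclass(frozen=True)
class ParentAssociation:
    """Pseudogene linked to its best-hit parental gene."""

    pseudogene_id: str
    parent_gene_id: str
    evalue: float
    bitscore: float
    identity_pct: float
    high_similarity: bool  # identity_pct >= 90


def parse_hits(path) -> list[AlignmentHit]:
    """Parse a whitespace/tab-delimited 12-column alignment-hit file.

    Rows with the wrong column count or untypable fields raise
    :class:`DataError` naming the offending line.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 12:
                raise DataError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}: {line!r}"
                )
            try:
                hit = AlignmentHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    identity_pct=float(parts[2]),
                    align_len=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            except ValueError as e:
                raise DataError(f"{path}:{lineno}: malformed field ({e})") from None
            hits.append(hit)
    return hits


def write_hits(hits: Iterable[AlignmentHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:.2f}\t{h.align_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}\t"
                f"{h.s_start}\t{h.s_end}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def best_hit(
    hits: Iterable[AlignmentHit],
    tx2gene: Mapping[str, str] | None = None,
) -> list[ParentAssociation]:
    """Select each pseudogene's parental gene: the overall best hit by
    minimum e-value, ties broken by maximum bitscore then lexicographically
    smallest subject (gene) id.

    ``tx2gene`` optionally collapses transcript-level subjects to genes
    before selection. The winning hit's identity sets the high-similarity
    flag (>= 90%). Output is invariant under input row order.
    """
    gene_of = (lambda s: tx2gene.get(s, s)) if tx2gene else (lambda s: s)
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)

    associations = []
    for query in sorted(by_query):
        winner = min(
            by_query[query],
            key=lambda h: (h.evalue, -h.bitscore, gene_of(h.subject_id)),
        )
        associations.append(
            ParentAssociation(
                pseudogene_id=query,
                parent_gene_id=gene_of(winner.subject_id),
                evalue=winner.evalue,
                bitscore=winner.bitscore,
                identity_pct=winner.identity_pct,
                high_similarity=winner.identity_pct >= 90.0,
            )
        )
    return associations


def unique_parents(
    associations: Sequence[ParentAssociation],
) -> tuple[set[str], dict[str, int]]:
    """Distinct parental genes and per-parent pseudogene multiplicity
    (some parental genes collect multiple associated pseudogenes)."""
    counts = Counter(a.parent_gene_id for a in associations)
    return set(counts), dict(counts)


def read_tx2gene(path, sep: str = "\t") -> dict[str, str]:
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: transcript->gene map needs 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def pair_correlation(
    pairs: pd.DataFrame,
    method: str = "pearson",
    strata: int | None = None,
) -> pd.DataFrame:
    """Correlation and least-squares slope between pseudogene and parent
    log2FC, optionally within expression-level strata.

    ``pairs`` needs columns ``pseudo_lfc`` and ``parent_lfc`` (and
    ``expression_level`` when ``strata`` is given, in which case quantile
    bins are formed). Strata with fewer than 3 pairs or a constant vector
    are flagged degenerate rather than computed.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigError("method must be 'pearson' or 'spearman'")
    for col in ("pseudo_lfc", "parent_lfc"):
        if col not in pairs.columns:
            raise ConfigError(f"pairs table lacks column '{col}'")
    if strata is not None:
        if "expression_level" not in pairs.columns:
            raise ConfigError("strata require an 'expression_level' column")
        labels = pd.qcut(pairs["expression_level"], strata, duplicates="drop")
        grouped = pairs.groupby(labels, observed=True)
    else:
        grouped = [("all", pairs)]

    rows = []
    for name, grp in grouped:
        x = grp["pseudo_lfc"].to_numpy(float)
        y = grp["parent_lfc"].to_numpy(float)
        degenerate = len(grp) < 3 or np.var(x) == 0 or np.var(y) == 0
        if degenerate:
            rows.append({"stratum": str(name), "n": len(grp), "r": np.nan,
                         "slope": np.nan, "degenerate": True})
            continue
        if method == "pearson":
            r = scipy.stats.pearsonr(x, y).statistic
        else:
            r = scipy.stats.spearmanr(x, y).statistic
        slope = scipy.stats.linregress(x, y).slope
        rows.append({"stratum": str(name), "n": len(grp), "r": float(r),
                     "slope": float(slope), "degenerate": False})
    return pd.DataFrame(rows)


def pair_sign_concordance(pairs: pd.DataFrame) -> float:
    """Fraction of pairs whose pseudogene and parent log2FC share a strict
    sign (zeros count as discordant); NaN when the table is empty."""
    if len(pairs) == 0:
        return float("nan")
    x = pairs["pseudo_lfc"].to_numpy(float)
    y = pairs["parent_lfc"].to_numpy(float)
    concordant = (np.sign(x) == np.sign(y)) & (x != 0) & (y != 0)
    return float(concordant.mean())
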