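"""Consensus set algebra over per-method DE calls.

Each caller contributes a significant gene set; the union (the "DE-space")
is decomposed into Venn regions keyed by which subset of methods made each
call. Fold changes of multiply-detected genes are averaged over the
detecting methods, and direction agreement (sign concordance) is flagged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io import MethodCallTable, ProfileMatrix


@dataclass(frozen=True)
class SignificanceRule:
    """FDR and effect-size cutoff: q <= q_max and |log2FC| > lfc_min.

    The q threshold is inclusive and the fold-change threshold strict,
    matching the conventional "q-value <= 5% and log(FC) > 1.2" reading.
    """

    q_max: float = 0.05
    lfc_min: float = 0.0

    def __post_init__(self):
        if not (0 < self.q_max <= 1):
            raise ConfigError("q_max must be in (0, 1]")
        if self.lfc_min < 0:
            raise ConfigError("lfc_min must be >= 0")


def significant_set(table: MethodCallTable, rule: SignificanceRule = SignificanceRule()) -> set[str]:
    """Genes called significant by one method under ``rule``.

    Genes lacking a q-value are excluded.
    """
    df = table.records
    ok = df["qvalue"].notna() & (df["qvalue"] <= rule.q_max)
    if rule.lfc_min > 0:
        ok &= df["log2fc"].abs() > rule.lfc_min
    return set(df.index[ok])


class Concordance(enum.Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    NOT_APPLICABLE = "na"


def mean_lfc(matrix: ProfileMatrix, gene: str) -> float:
    """Arithmetic mean of a gene's observed log2FC over the methods that call it."""
    if gene not in matrix.data.index:
        raise KeyError(f"gene '{gene}' absent from profile matrix")
    row = matrix.data.loc[gene]
    return float(row.dropna().mean())


def sign_concordance(
    matrix: ProfileMatrix, gene: str, methods: Sequence[str] | None = None
) -> Concordance:
    """Do all detecting methods agree on the direction of change?

    Evaluated over ``methods`` (default: all methods with an observed value).
    A log2FC of exactly 0 carries no direction and renders the gene
    discordant. Fewer than two observed calls -> NOT_APPLICABLE.
    """
    if gene not in matrix.data.index:
        raise KeyError(f"gene '{gene}' absent from profile matrix")
    row = matrix.data.loc[gene]
    if methods is not None:
        row = row.loc[list(methods)]
    vals = row.dropna().to_numpy(float)
    if len(vals) < 2:
        return Concordance.NOT_APPLICABLE
    if np.any(vals == 0):
        return Concordance.DISCORDANT
    signs = np.sign(vals)
    return Concordance.CONCORDANT if np.all(signs == signs[0]) else Concordance.DISCORDANT


@dataclass
class ConsensusResult:
    """Venn decomposition of the DE-space union.

    ``membership`` maps each union gene to the ordered tuple of methods that
    called it; ``region_counts`` counts genes per non-empty method subset.
    When built with a profile matrix, ``mean_lfc`` and ``concordant`` carry
    the averaged fold change and direction agreement per gene.
    """

    methods: list[str]
    membership: dict[str, tuple[str, ...]]
    region_counts: dict[tuple[str, ...], int]
    core: set[str]
    union_size: int
    mean_lfc: pd.Series | None = None
    concordant: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.membership)
        sig = ["|".join(self.membership[g]) for g in genes]
        df = pd.DataFrame(
            {
                "signature": sig,
                "n_methods": [len(self.membership[g]) for g in genes],
            },
            index=pd.Index(genes, name="gene_id"),
        )
        if self.mean_lfc is not None:
            df["mean_lfc"] = self.mean_lfc.reindex(df.index)
        if self.concordant is not None:
            df["concordant"] = self.concordant.reindex(df.index)
        return df

    def region_frame(self) -> pd.DataFrame:
        rows = [
            {"signature": "|".join(sig), "n_methods": len(sig), "count": n}
            for sig, n in sorted(
                self.region_counts.items(), key=lambda kv: (-len(kv[0]), kv[0])
            )
        ]
        return pd.DataFrame(rows)


def venn_decompose(
    sets: Mapping[str, set[str]], matrix: ProfileMatrix | None = None
) -> ConsensusResult:
    """Assign every union gene to exactly one method-subset region.

    Region counts conserve the union size by construction. With a profile
    matrix, per-gene averaged log2FC (over detecting methods with observed
    values) and sign concordance are attached.
    """
    if len(sets) < 2:
        raise ConfigError("venn_decompose requires at least 2 sets")
    methods = list(sets)
    union: set[str] = set().union(*sets.values())
    membership: dict[str, tuple[str, ...]] = {}
    region_counts: dict[tuple[str, ...], int] = {}
    for g in union:
        sig = tuple(m for m in methods if g in sets[m])
        membership[g] = sig
        region_counts[sig] = region_counts.get(sig, 0) + 1
    all_sig = tuple(methods)
    core = {g for g, sig in membership.items() if sig == all_sig}

    mlfc = conc = None
    if matrix is not None:
        absent = union - set(matrix.data.index)
        if absent:
            raise DataError(
                f"{len(absent)} consensus genes absent from profile matrix, "
                f"e.g. {sorted(absent)[:5]}"
            )
        mlfc_vals, conc_vals = {}, {}
        for g, sig in membership.items():
            row = matrix.data.loc[g, list(sig)].dropna()
            mlfc_vals[g] = float(row.mean()) if len(row) else np.nan
            conc_vals[g] = sign_concordance(matrix, g, sig).value if len(sig) >= 2 else Concordance.NOT_APPLICABLE.value
        mlfc = pd.Series(mlfc_vals, name="mean_lfc")
        conc = pd.Series(conc_vals, name="concordant")

    return ConsensusResult(
        methods=methods,
        membership=membership,
        region_counts=region_counts,
        core=core,
        union_size=len(union),
        mean_lfc=mlfc,
        concordant=conc,
    )
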