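"""Ground-truth generators for every pipeline input.

The profile generator emulates the statistical structure the alternating
regression assumes: a shared per-gene log2FC signal theta observed through
method-specific channels y_gm = a_m + b_m * theta_g + eps_gm, with
per-method noise and dropout, plus one optional *outlier method* whose
profile is independent noise — reproducing the behavior of a caller that
covers gene-space regions unexplored by the others and therefore cannot be
predicted from them. Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigError
from .io import MethodCallTable, ProfileMatrix
from .pseudogene import AlignmentHit, write_hits
from .stats import bh_adjust


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic log2FC matrix.

    Defaults: 5,000 genes x 5 methods, 10% true DE genes with signed effect
    magnitudes uniform on [2, 4], per-method noise sd uniform on [0.3, 0.8],
    15% per-cell dropout, and the last method an outlier emitting
    independent Normal(0, 2^2) noise.
    """

    n_genes: int = 5000
    n_methods: int = 5
    pi_de: float = 0.10
    effect_range: tuple[float, float] = (2.0, 4.0)
    bias: tuple[float, ...] | None = None  # a_m, default all 0
    gain: tuple[float, ...] | None = None  # b_m, default all 1
    noise_sd_range: tuple[float, float] = (0.3, 0.8)
    dropout: float = 0.15
    outlier_method: int | None = 4
    outlier_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_methods < 2:
            raise ConfigError("need n_genes >= 1 and n_methods >= 2")
        if not (0 <= self.pi_de <= 1):
            raise ConfigError("pi_de must be in [0, 1]")
        if not (0 < self.noise_sd_range[0] <= self.noise_sd_range[1]):
            raise ConfigError("noise sd bounds must be positive and ordered")
        if not (0 <= self.dropout < 1):
            raise ConfigError("dropout must be in [0, 1)")
        if self.outlier_method is not None and not (
            0 <= self.outlier_method < self.n_methods
        ):
            raise ConfigError("outlier_method index out of range")
        for name in ("bias", "gain"):
            vec = getattr(self, name)
            if vec is not None and len(vec) != self.n_methods:
                raise ConfigError(f"{name} must have one entry per method")
        if self.outlier_sd <= 0:
            raise ConfigError("outlier_sd must be > 0")

    @property
    def method_names(self) -> list[str]:
        return [f"method{j + 1}" for j in range(self.n_methods)]


@dataclass
class SimTruth:
    """Ground truth stored alongside every generated dataset."""

    theta: pd.Series  # true per-gene effect, 0 for nulls
    de_labels: pd.Series  # bool, theta != 0
    dropout_mask: pd.DataFrame  # True where the cell was masked missing
    sigma: pd.Series  # realized per-method noise sd (outlier_sd for the outlier)
    bias: pd.Series
    gain: pd.Series
    outlier_method: str | None
    config: SimConfig


def gen_profile_matrix(cfg: SimConfig = SimConfig()) -> tuple[ProfileMatrix, SimTruth]:
    """Generate a gene x method log2FC matrix with known truth.

    Rows that the dropout mask would leave fully missing get one uniformly
    chosen cell re-exposed, so the matrix invariant (every gene observed at
    least once) holds by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_genes, cfg.n_methods
    genes = [f"g{i:05d}" for i in range(n)]
    methods = cfg.method_names

    de = rng.random(n) < cfg.pi_de
    theta = np.zeros(n)
    k = int(de.sum())
    lo, hi = cfg.effect_range
    theta[de] = rng.choice([-1.0, 1.0], size=k) * rng.uniform(lo, hi, size=k)

    sigma = rng.uniform(*cfg.noise_sd_range, size=m)
    a = np.asarray(cfg.bias if cfg.bias is not None else np.zeros(m), float)
    b = np.asarray(cfg.gain if cfg.gain is not None else np.ones(m), float)

    values = a[None, :] + b[None, :] * theta[:, None] + rng.normal(0.0, sigma, size=(n, m))
    outlier_name = None
    if cfg.outlier_method is not None:
        j = cfg.outlier_method
        outlier_name = methods[j]
        values[:, j] = rng.normal(0.0, cfg.outlier_sd, size=n)
        sigma[j] = cfg.outlier_sd

    drop = rng.random((n, m)) < cfg.dropout
    all_missing = drop.all(axis=1)
    for i in np.flatnonzero(all_missing):
        drop[i, rng.integers(m)] = False
    values = values.copy()
    values[drop] = np.nan

    data = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=methods)
    truth = SimTruth(
        theta=pd.Series(theta, index=data.index, name="theta"),
        de_labels=pd.Series(de, index=data.index, name="de"),
        dropout_mask=pd.DataFrame(drop, index=data.index, columns=methods),
        sigma=pd.Series(sigma, index=methods, name="sigma"),
        bias=pd.Series(a, index=methods, name="bias"),
        gain=pd.Series(b, index=methods, name="gain"),
        outlier_method=outlier_name,
        config=cfg,
    )
    return ProfileMatrix(data), truth


def gen_method_tables(cfg: SimConfig = SimConfig()) -> tuple[list[MethodCallTable], SimTruth]:
    """Per-method DE tables derived from the generated matrix.

    Each observed cell yields a z-statistic y/sigma_m, a two-sided normal
    p-value, and a Benjamini-Hochberg q-value adjusted within that method's
    table. Tables round-trip through the profile-matrix builder.
    """
    matrix, truth = gen_profile_matrix(cfg)
    tables = []
    for method in matrix.methods:
        col = matrix.data[method].dropna()
        scale = float(truth.sigma[method])
        z = col.to_numpy(float) / scale
        p = 2.0 * scipy.stats.norm.sf(np.abs(z))
        q = bh_adjust(p)
        records = pd.DataFrame(
            {"log2fc": col.to_numpy(float), "pvalue": p, "qvalue": q},
            index=col.index,
        )
        tables.append(MethodCallTable(method_name=method, records=records))
    return tables, truth


def gen_hit_table(
    n_pseudogenes: int,
    n_parents: int,
    n_decoys: int,
    seed: int = 0,
    path=None,
) -> tuple[list[AlignmentHit], dict[str, str]]:
    """Alignment-hit fixture with known pseudogene -> parent truth.

    Each pseudogene gets one true-parent hit with an e-value (<= 1e-120)
    strictly smaller than every decoy hit (>= 1e-100), so best-hit
    selection provably recovers the truth. Winning identities are drawn on
    [80, 100) to straddle the 90% similarity flag. With ``path`` the table
    is also written as 12-column text (deterministic bytes for a seed).
    """
    if n_pseudogenes < 1 or n_parents < 1 or n_decoys < 0:
        raise ConfigError("counts must be positive (decoys >= 0)")
    rng = np.random.default_rng(seed)
    parents = [f"PARENT{j:04d}" for j in range(n_parents)]
    hits: list[AlignmentHit] = []
    truth: dict[str, str] = {}

    def _hit(query, subject, evalue, identity, bitscore):
        alen = int(rng.integers(200, 1200))
        mism = int(round(alen * (100.0 - identity) / 100.0))
        return AlignmentHit(
            query_id=query,
            subject_id=subject,
            identity_pct=round(identity, 2),
            align_len=alen,
            mismatches=mism,
            gap_opens=int(rng.integers(0, 5)),
            q_start=1,
            q_end=alen,
            s_start=1,
            s_end=alen,
            evalue=evalue,
            bitscore=round(bitscore, 1),
        )

    for i in range(n_pseudogenes):
        pg = f"PSG{i:04d}"
        true_parent = parents[int(rng.integers(n_parents))]
        truth[pg] = true_parent
        hits.append(
            _hit(
                pg,
                true_parent,
                evalue=10.0 ** -float(rng.uniform(120, 180)),
                identity=float(rng.uniform(80, 100)),
                bitscore=float(rng.uniform(500, 900)),
            )
        )
        for _ in range(n_decoys):
            decoy = parents[int(rng.integers(n_parents))]
            hits.append(
                _hit(
                    pg,
                    decoy,
                    evalue=10.0 ** -float(rng.uniform(10, 100)),
                    identity=float(rng.uniform(60, 95)),
                    bitscore=float(rng.uniform(50, 400)),
                )
            )
    if path is not None:
        write_hits(hits, path)
    return hits, truth


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Same study conditions, different random seed."""
    return replace(cfg, seed=seed)
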