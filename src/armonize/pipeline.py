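"""End-to-end workflow: import -> consensus -> ARM -> PCA -> selections ->
annotation decomposition, with a machine-readable run summary.

The summary carries every stage's counts (the flow-accounting numbers for a
run) and echoes every configuration value actually used, so a run is fully
auditable from its JSON alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import annotate as annotate_mod
from .arm import ArmConfig, ensemble_average, fits_frame, iqr_select, rotate
from .consensus import SignificanceRule, significant_set, venn_decompose
from .errors import ConfigError
from .io import MethodCallTable, build_profile_matrix, read_method_table
from .pca import pc1_select

log = logging.getLogger("armonize")


@dataclass
class TableSpec:
    path: str
    method_name: str
    column_map: dict | None = None
    sep: str = "\t"


@dataclass
class RunConfig:
    """Everything a pipeline run needs, in one audited surface."""

    tables: list[TableSpec] = field(default_factory=list)
    rule: SignificanceRule = field(default_factory=SignificanceRule)
    arm: ArmConfig = field(default_factory=ArmConfig)
    pca_k: float = 1.5
    pca_scale: bool = False
    catalog_path: str | None = None
    out_dir: str = "armonize_out"


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, set) else [
            _jsonable(v) for v in obj
        ]
    return obj


def run_pipeline(
    cfg: RunConfig, tables: Sequence[MethodCallTable] | None = None
) -> dict:
    """Execute the full workflow and write stage outputs under ``out_dir``.

    ``tables`` may be passed in-memory (e.g. from the simulator); otherwise
    they are read from ``cfg.tables``. Returns the run summary dict, also
    written to ``summary.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if tables is None:
        if len(cfg.tables) < 2:
            raise ConfigError("run needs at least 2 method tables")
        for spec in cfg.tables:
            if not Path(spec.path).exists():
                raise ConfigError(f"method table path does not exist: {spec.path}")
        tables = [
            read_method_table(s.path, s.method_name, s.column_map, sep=s.sep)
            for s in cfg.tables
        ]
    log.info("imported %d method tables: %s", len(tables),
             [t.method_name for t in tables])
    log.info("config: rule=%s arm=%s pca_k=%s pca_scale=%s",
             cfg.rule, cfg.arm, cfg.pca_k, cfg.pca_scale)

    matrix = build_profile_matrix(tables)
    matrix.to_tsv(out / "profile_matrix.tsv")

    sets = {t.method_name: significant_set(t, cfg.rule) for t in tables}
    cons = venn_decompose(sets, matrix=matrix)
    cons.to_frame().to_csv(out / "consensus.tsv", sep="\t")
    cons.region_frame().to_csv(out / "region_counts.tsv", sep="\t", index=False)
    log.info("consensus: union=%d core=%d", cons.union_size, len(cons.core))

    fits = rotate(matrix, cfg.arm)
    fits_frame(fits).to_csv(out / "arm_fits.tsv", sep="\t", index=False)
    profile = ensemble_average(fits, cfg.arm)
    profile.table.to_csv(out / "ensemble_profile.tsv", sep="\t")
    arm_sel = iqr_select(
        profile.summary(cfg.arm.summary_stat), cfg.arm.iqr_k,
        statistic_name=f"ensemble_{cfg.arm.summary_stat}",
    )
    arm_sel.to_frame().to_csv(out / "arm_selection.tsv", sep="\t")
    log.info("ARM: %d rotations, %d excluded, selection=%d",
             len(fits), len(profile.excluded_responses), len(arm_sel.selected))

    pca = pc1_select(matrix, k=cfg.pca_k, scale=cfg.pca_scale)
    pca_frame = pca.pc1_scores.to_frame()
    pca_frame["selected"] = pca_frame.index.isin(pca.selection.selected)
    pca_frame["direction"] = pca.selection.direction.reindex(pca_frame.index)
    pca_frame.to_csv(out / "pca_scores.tsv", sep="\t")
    log.info("PCA: explained=%.3f selection=%d", pca.explained_frac,
             len(pca.selection.selected))

    overlap = arm_sel.selected & pca.selection.selected

    summary = {
        "config": {
            "rule": _jsonable(cfg.rule),
            "arm": _jsonable(cfg.arm),
            "pca_k": cfg.pca_k,
            "pca_scale": cfg.pca_scale,
        },
        "methods": [t.method_name for t in tables],
        "table_sizes": {t.method_name: len(t) for t in tables},
        "matrix_genes": len(matrix.genes),
        "significant_per_method": {m: len(s) for m, s in sets.items()},
        "consensus_union": cons.union_size,
        "consensus_core": len(cons.core),
        "arm_excluded_responses": _jsonable(profile.excluded_responses),
        "arm_fences": {
            "lower": arm_sel.lower_fence, "upper": arm_sel.upper_fence,
            "k": arm_sel.k, "statistic": arm_sel.statistic_name,
        },
        "arm_selection": len(arm_sel.selected),
        "pca_explained_frac": pca.explained_frac,
        "pca_fences": {
            "lower": pca.selection.lower_fence, "upper": pca.selection.upper_fence,
            "k": pca.selection.k,
        },
        "pca_selection": len(pca.selection.selected),
        "arm_pca_overlap": len(overlap),
    }

    if cfg.catalog_path:
        catalog = annotate_mod.read_catalog(cfg.catalog_path)
        breakdown = annotate_mod.biotype_decompose(arm_sel.selected, catalog)
        breakdown.to_frame().to_csv(out / "arm_biotypes.tsv", sep="\t", index=False)
        fam = annotate_mod.family_decompose(arm_sel.selected, catalog)
        summary["arm_biotypes"] = breakdown.biotype_counts
        summary["arm_parental_rollup"] = breakdown.parental_rollup
        summary["arm_families"] = fam

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
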