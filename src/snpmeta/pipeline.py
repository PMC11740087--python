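"""Orchestration: filter -> contrast -> pool -> diagnose, across subgroups.

Produces a stratified grid with one "Total" row plus one row per subgroup
level, each crossed with the five genetic models in canonical order
(allelic, homozygote, heterozygote, dominant, recessive).  Publication-bias
tests are attached whenever a cell pools at least three studies.
"""

from __future__ import annotations

import json
import logging
import math
import sys
from dataclasses import dataclass, field
from typing import Sequence

from .bias_diagnostics import BiasTestResult, begg_test, egger_test
from .errors import EstimationError, InsufficientStudiesError
from .genetic_models import MODELS, contrast_table
from .meta_core import EffectEstimate, PooledResult, meta_analyse, study_log_or
from .study_io import SUBGROUP_FACTORS, StudyRecord, filter_studies

logger = logging.getLogger("snpmeta")

#: Small pooled p-values are printed as "0.000", matching the reporting
#: convention of stratified association tables.
_P_PRINT_FLOOR = 5e-4

TSV_COLUMNS = ("polymorphism", "subgroup", "model", "k", "n_case",
               "n_control", "model_used", "or", "ci_low", "ci_high", "z",
               "p", "q", "p_h", "i2", "tau2", "begg_p", "egger_p")


@dataclass(frozen=True)
class GridRow:
    """Pooled result for one (polymorphism, subgroup, model) cell."""

    polymorphism: str
    subgroup: str             # "Total" or "factor=level"
    model: str
    pooled: PooledResult
    begg: BiasTestResult | None
    egger: BiasTestResult | None
    effects: tuple[EffectEstimate, ...] = field(default=(), repr=False)


@dataclass(frozen=True)
class MetaGrid:
    rows: tuple[GridRow, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def subgroups(self) -> list[str]:
        seen: list[str] = []
        for row in self.rows:
            if row.subgroup not in seen:
                seen.append(row.subgroup)
        return seen


def _pool_cell(studies: Sequence[StudyRecord], polymorphism: str,
               subgroup: str, model: str, correction: float,
               het_threshold: float) -> GridRow:
    effects, skipped = [], []
    n_case = n_control = 0
    for r in studies:
        t = contrast_table(r.cases, r.controls, model)
        try:
            effects.append(study_log_or(t, correction=correction,
                                        study_id=r.study_id))
        except EstimationError:
            skipped.append(r.study_id)
            continue
        n_case += r.cases.total
        n_control += r.controls.total
    if skipped:
        logger.info("%s/%s/%s: %d study(ies) not estimable: %s",
                    polymorphism, subgroup, model, len(skipped),
                    ", ".join(skipped))
    pooled = meta_analyse(effects, het_threshold=het_threshold,
                          n_case=n_case, n_control=n_control)
    begg = egger = None
    if len(effects) >= 3:
        try:
            begg = begg_test(effects)
        except InsufficientStudiesError:
            pass
        try:
            egger = egger_test(effects)
        except InsufficientStudiesError:
            pass
    return GridRow(polymorphism=polymorphism, subgroup=subgroup, model=model,
                   pooled=pooled, begg=begg, egger=egger,
                   effects=tuple(effects))


def run_meta(studies: Sequence[StudyRecord], polymorphism: str,
             subgroup_plan: Sequence[str] = (),
             het_threshold: float = 0.05,
             hwe_threshold: float | None = None,
             correction: float = 0.5) -> MetaGrid:
    """Build the stratified meta-analysis grid for one polymorphism.

    ``subgroup_plan`` names stratification factors (any of ethnicity,
    cancer_type, source_of_control); each observed level with at least one
    study contributes a row.  ``hwe_threshold`` optionally excludes studies
    whose controls violate Hardy-Weinberg equilibrium at that p-value.
    """
    for factor in subgroup_plan:
        if factor not in SUBGROUP_FACTORS:
            raise InsufficientStudiesError(
                f"unknown subgroup factor {factor!r}")
    total = filter_studies(studies, polymorphism=polymorphism,
                           hwe_threshold=hwe_threshold)
    if not total:
        raise InsufficientStudiesError(
            f"no studies available for polymorphism {polymorphism!r}")
    rows: list[GridRow] = []
    for model in MODELS:
        rows.append(_pool_cell(total, polymorphism, "Total", model,
                               correction, het_threshold))
    for factor in subgroup_plan:
        levels: list[str] = []
        for r in total:
            level = getattr(r, factor)
            if level not in levels:
                levels.append(level)
        for level in levels:
            subset = [r for r in total if getattr(r, factor) == level]
            if not subset:
                logger.info("%s: subgroup %s=%s empty, omitted",
                            polymorphism, factor, level)
                continue
            label = f"{factor}={level}"
            for model in MODELS:
                rows.append(_pool_cell(subset, polymorphism, label, model,
                                       correction, het_threshold))
    return MetaGrid(rows=tuple(rows))


def format_or_ci(odds_ratio: float, ci_low: float, ci_high: float) -> str:
    """Render "OR (low-high)" with 3 decimals and an en-dash separator,
    e.g. ``1.078 (1.020–1.140)``."""
    return f"{odds_ratio:.3f} ({ci_low:.3f}–{ci_high:.3f})"


def _fmt_p(p: float) -> str:
    if math.isnan(p):
        return "NA"
    if p < _P_PRINT_FLOOR:
        return "0.000"
    return f"{p:.3f}"


def _fmt(x: float, digits: int = 3) -> str:
    return "NA" if (x is None or math.isnan(x)) else f"{x:.{digits}f}"


def _row_dict(row: GridRow, full_precision: bool) -> dict:
    p = row.pooled
    if full_precision:
        return {
            "polymorphism": row.polymorphism, "subgroup": row.subgroup,
            "model": row.model, "k": p.k, "n_case": p.n_case,
            "n_control": p.n_control, "model_used": p.model_used,
            "or": p.odds_ratio, "ci_low": p.ci_low, "ci_high": p.ci_high,
            "log_or": p.log_or, "se": p.se, "z": p.z, "p": p.p,
            "q": p.q, "p_h": p.p_h, "i2": p.i2, "tau2": p.tau2,
            "begg_p": row.begg.p if row.begg else None,
            "egger_p": row.egger.p if row.egger else None,
        }
    return {
        "polymorphism": row.polymorphism, "subgroup": row.subgroup,
        "model": row.model, "k": str(p.k), "n_case": str(p.n_case),
        "n_control": str(p.n_control), "model_used": p.model_used,
        "or": _fmt(p.odds_ratio), "ci_low": _fmt(p.ci_low),
        "ci_high": _fmt(p.ci_high), "z": _fmt(p.z), "p": _fmt_p(p.p),
        "q": _fmt(p.q), "p_h": _fmt_p(p.p_h), "i2": _fmt(p.i2),
        "tau2": _fmt(p.tau2, 4),
        "begg_p": _fmt_p(row.begg.p) if row.begg else "NA",
        "egger_p": _fmt_p(row.egger.p) if row.egger else "NA",
    }


def write_grid(grid: MetaGrid, path, format: str = "tsv") -> None:
    """Serialize a grid: TSV rounded for reporting, JSON at full precision."""
    if len(grid) == 0:
        raise InsufficientStudiesError("cannot write an empty grid")
    if format == "tsv":
        lines = ["\t".join(TSV_COLUMNS)]
        for row in grid.rows:
            d = _row_dict(row, full_precision=False)
            lines.append("\t".join(d[c] for c in TSV_COLUMNS))
        text = "\n".join(lines) + "\n"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    elif format == "json":
        payload = [_row_dict(row, full_precision=True) for row in grid.rows]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, allow_nan=True)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_grid_json(path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def export_forest(row: GridRow, path) -> None:
    """Write forest-plot data: per-study OR/CI/weight plus summary diamond.

    Weights are the pooling weights of the model actually used, normalized
    to percentages.
    """
    if not row.effects:
        raise InsufficientStudiesError("grid row retains no per-study effects")
    p = row.pooled
    tau2 = p.tau2 if (p.model_used == "random" and not math.isnan(p.tau2)) else 0.0
    raw = [1.0 / (e.variance + tau2) for e in row.effects]
    total = sum(raw)
    lines = ["study_id\tor\tci_low\tci_high\tweight_pct"]
    for e, w in zip(row.effects, raw):
        lines.append(f"{e.study_id}\t{e.odds_ratio:.6g}\t{e.ci_low:.6g}"
                     f"\t{e.ci_high:.6g}\t{100 * w / total:.10f}")
    lines.append(f"SUMMARY\t{p.odds_ratio:.6g}\t{p.ci_low:.6g}"
                 f"\t{p.ci_high:.6g}\t100.0000000000")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
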