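"""Pearson chi-square tests of r x c frequency tables, with Yates correction.

Used to relate a binary expression split (low/high) to clinicopathological
covariates.  2x2 tables take the Yates continuity correction, in which each
absolute deviation |o - e| is reduced by 0.5 (floored at zero) before
squaring; larger tables take the plain Pearson statistic.  The packaged
fixture ``data/table2_counts.tsv`` holds seven covariate blocks (age,
gender, histologic grade, stage, and the T/M/N classification) from a
gastric-cancer expression cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, ValidationError


@dataclass(frozen=True)
class FrequencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray            # shape (r, c), nonnegative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValidationError("frequency table must be at least 2x2")
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValidationError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", counts.astype(int))


@dataclass(frozen=True)
class Chi2Result:
    covariate: str
    chi2: float
    df: int
    p: float
    yates: bool


def pearson_chi2(table: FrequencyTable | np.ndarray,
                 yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square statistic, degrees of freedom and p-value.

    ``yates`` applies the continuity correction and is permitted only on
    2x2 tables.  Tables with a zero marginal row or column are degenerate.
    """
    counts = table.counts if isinstance(table, FrequencyTable) else np.asarray(table)
    counts = counts.astype(float)
    r, c = counts.shape
    if yates and (r != 2 or c != 2):
        raise ValidationError("Yates correction applies only to 2x2 tables")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = counts.sum()
    if n < 1 or np.any(row_sums == 0) or np.any(col_sums == 0):
        raise DegenerateTableError("table has an all-zero row or column")
    expected = np.outer(row_sums, col_sums) / n
    dev = np.abs(counts - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)   # floor guards tiny deviations
    chi2 = float(np.sum(dev ** 2 / expected))
    df = (r - 1) * (c - 1)
    return chi2, df, float(stats.chi2.sf(chi2, df=df))


def _packaged_table2_path():
    return resources.files("snpmeta").joinpath("data/table2_counts.tsv")


def read_count_blocks(path=None) -> list[tuple[str, FrequencyTable]]:
    """Read covariate blocks from a TSV of (covariate, level, low, high).

    Each covariate becomes one (name, FrequencyTable) pair with levels as
    rows and the low/high expression groups as columns.  Defaults to the
    packaged gastric-cancer fixture.
    """
    if path is None:
        path = _packaged_table2_path()
    df = pd.read_csv(path, sep="\t", dtype={"covariate": str, "level": str})
    required = {"covariate", "level", "low_count", "high_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"count file missing column(s): {sorted(missing)}")
    tables = []
    for covariate, block in df.groupby("covariate", sort=False):
        counts = block[["low_count", "high_count"]].to_numpy()
        try:
            tables.append((str(covariate), FrequencyTable(
                row_labels=tuple(block["level"]),
                col_labels=("Low", "High"),
                counts=counts)))
        except ValidationError as exc:
            raise ValidationError(f"covariate {covariate!r}: {exc}") from exc
    return tables


def reproduce_table2(counts_path=None) -> list[Chi2Result]:
    """Chi-square statistic per covariate block of the packaged count grids.

    2x2 blocks take the Yates correction, larger blocks plain Pearson —
    the convention the source statistics follow.
    """
    results = []
    for covariate, table in read_count_blocks(counts_path):
        yates = table.counts.shape == (2, 2)
        try:
            chi2, df, p = pearson_chi2(table, yates=yates)
        except DegenerateTableError as exc:
            raise DegenerateTableError(f"covariate {covariate!r}: {exc}") from exc
        results.append(Chi2Result(covariate=covariate, chi2=chi2, df=df, p=p,
                                  yates=yates))
    return results
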