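"""Reading, validation and filtering of per-study genotype-count tables.

The study table is UTF-8 delimited text (tab by default) with one header row
and exactly these columns::

    study_id, author, year, country, ethnicity, cancer_type,
    source_of_control, genotyping_method, polymorphism,
    case_MM, case_MW, case_WW, ctrl_MM, ctrl_MW, ctrl_WW

Genotype classes follow the M/W convention: M is the variant allele, W the
wild type, so MM are variant homozygotes, MW heterozygotes and WW wild-type
homozygotes.  Which physical allele plays M for a given polymorphism is the
input provider's responsibility (for IL-8 -251, M = A and W = T).
"""

from __future__ import annotations

import operator
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

ETHNICITIES = ("Asian", "Caucasian", "African", "Mixed")
CONTROL_SOURCES = ("HB", "PB")
POLYMORPHISMS = ("-251", "-353", "+678", "+1633", "+2767", "+781")
SUBGROUP_FACTORS = ("ethnicity", "cancer_type", "source_of_control")

COLUMNS = (
    "study_id", "author", "year", "country", "ethnicity", "cancer_type",
    "source_of_control", "genotyping_method", "polymorphism",
    "case_MM", "case_MW", "case_WW", "ctrl_MM", "ctrl_MW", "ctrl_WW",
)
_COUNT_COLUMNS = COLUMNS[9:]


def canonical_polymorphism(label: str) -> str:
    """Normalize a polymorphism label to its canonical spelling.

    Unicode minus signs are mapped to ASCII hyphens, and the site that the
    literature labels both "+781" and "-781" is canonicalized to "+781".
    """
    label = str(label).strip().replace("−", "-").replace("‐", "-")
    if label == "-781":
        return "+781"
    return label


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm (cases or controls) of one study."""

    n_MM: int
    n_MW: int
    n_WW: int

    def __post_init__(self) -> None:
        for name in ("n_MM", "n_MW", "n_WW"):
            v = getattr(self, name)
            try:
                iv = operator.index(v)  # ints and numpy ints, not floats
            except TypeError:
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            if iv < 0:
                raise ValidationError(f"{name} must be >= 0, got {iv}")
            object.__setattr__(self, name, int(iv))

    @property
    def total(self) -> int:
        return self.n_MM + self.n_MW + self.n_WW

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_MM, self.n_MW, self.n_WW)


@dataclass(frozen=True)
class StudyRecord:
    """One study's metadata plus case and control genotype counts."""

    study_id: str
    author: str
    year: int
    country: str
    ethnicity: str
    cancer_type: str
    source_of_control: str
    genotyping_method: str
    polymorphism: str
    cases: GenotypeCounts
    controls: GenotypeCounts

    def __post_init__(self) -> None:
        sid = self.study_id
        if self.ethnicity not in ETHNICITIES:
            raise ValidationError(
                f"study {sid!r}: unknown ethnicity {self.ethnicity!r} "
                f"(expected one of {ETHNICITIES})")
        if self.source_of_control not in CONTROL_SOURCES:
            raise ValidationError(
                f"study {sid!r}: unknown source_of_control "
                f"{self.source_of_control!r} (expected one of {CONTROL_SOURCES})")
        poly = canonical_polymorphism(self.polymorphism)
        if poly not in POLYMORPHISMS:
            raise ValidationError(
                f"study {sid!r}: unknown polymorphism {self.polymorphism!r} "
                f"(expected one of {POLYMORPHISMS})")
        object.__setattr__(self, "polymorphism", poly)
        # an all-zero arm would silently corrupt study counts downstream
        if self.cases.total < 1:
            raise ValidationError(f"study {sid!r}: case arm has zero total")
        if self.controls.total < 1:
            raise ValidationError(f"study {sid!r}: control arm has zero total")


def read_studies(path, delimiter: str = "\t") -> list[StudyRecord]:
    """Read a study table; one :class:`StudyRecord` per row, order preserved.

    Raises :class:`SchemaError` naming any missing column and
    :class:`ValidationError` (with the study_id) for bad rows.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    for _, row in df.iterrows():
        sid = row["study_id"]
        counts: dict[str, int] = {}
        for col in _COUNT_COLUMNS:
            raw = str(row[col]).strip()
            try:
                value = int(raw)
            except ValueError:
                raise ValidationError(
                    f"study {sid!r}: column {col} has non-integer value {raw!r}")
            if value < 0:
                raise ValidationError(
                    f"study {sid!r}: column {col} is negative ({value})")
            counts[col] = value
        try:
            year = int(str(row["year"]).strip())
        except ValueError:
            raise ValidationError(
                f"study {sid!r}: year {row['year']!r} is not an integer")
        records.append(StudyRecord(
            study_id=sid,
            author=row["author"],
            year=year,
            country=row["country"],
            ethnicity=row["ethnicity"],
            cancer_type=row["cancer_type"],
            source_of_control=row["source_of_control"],
            genotyping_method=row["genotyping_method"],
            polymorphism=row["polymorphism"],
            cases=GenotypeCounts(counts["case_MM"], counts["case_MW"],
                                 counts["case_WW"]),
            controls=GenotypeCounts(counts["ctrl_MM"], counts["ctrl_MW"],
                                    counts["ctrl_WW"]),
        ))
    return records


def write_studies(records: Iterable[StudyRecord], path,
                  delimiter: str = "\t") -> None:
    """Write records in the table format :func:`read_studies` accepts."""
    rows = []
    for r in records:
        rows.append({
            "study_id": r.study_id, "author": r.author, "year": r.year,
            "country": r.country, "ethnicity": r.ethnicity,
            "cancer_type": r.cancer_type,
            "source_of_control": r.source_of_control,
            "genotyping_method": r.genotyping_method,
            "polymorphism": r.polymorphism,
            "case_MM": r.cases.n_MM, "case_MW": r.cases.n_MW,
            "case_WW": r.cases.n_WW,
            "ctrl_MM": r.controls.n_MM, "ctrl_MW": r.controls.n_MW,
            "ctrl_WW": r.controls.n_WW,
        })
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(
        path, sep=delimiter, index=False)


def filter_studies(records: Sequence[StudyRecord],
                   polymorphism: str | None = None,
                   subgroup_factor: str | None = None,
                   subgroup_level: str | None = None,
                   hwe_threshold: float | None = None) -> list[StudyRecord]:
    """Select the studies entering one pooled analysis.

    ``hwe_threshold``, when given, drops studies whose control-arm
    Hardy-Weinberg chi-square p-value falls below it (a sensitivity switch:
    the primary analysis retains HWE-violating studies, so the default is
    no filtering).
    """
    if subgroup_factor is not None and subgroup_factor not in SUBGROUP_FACTORS:
        raise ValidationError(
            f"unknown subgroup factor {subgroup_factor!r} "
            f"(expected one of {SUBGROUP_FACTORS})")
    out = list(records)
    if polymorphism is not None:
        target = canonical_polymorphism(polymorphism)
        out = [r for r in out if r.polymorphism == target]
    if subgroup_factor is not None and subgroup_level is not None:
        out = [r for r in out if getattr(r, subgroup_factor) == subgroup_level]
    if hwe_threshold is not None and hwe_threshold > 0:
        from .genetic_models import hwe_chi_square
        out = [r for r in out if hwe_chi_square(r.controls).p >= hwe_threshold]
    return out
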