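"""Study-level data model for two-arm mean platelet volume (MPV) comparisons.

Each study contributes per-arm summary statistics (sample size, mean and SD of
MPV in femtolitres) for a patient group with a psychiatric diagnosis and a
healthy control group, plus optional moderators (mean age per arm, male
fraction, recent antipsychotic exposure, Newcastle-Ottawa quality score).

The canonical on-disk format is UTF-8 CSV with a documented header; ``NA`` and
the empty string both denote a missing moderator.  The 24-study table of the
source meta-analysis ships with the package and is returned by
:func:`builtin_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "StudyRecord",
    "StudyTable",
    "SchemaError",
    "StudyValidationError",
    "CSV_COLUMNS",
    "DIAGNOSES",
    "DESIGNS",
    "INSTRUMENTS",
    "read_study_table",
    "write_study_table",
    "builtin_table",
    "filter_studies",
    "min_total_n",
    "diagnosis_is",
    "apd_recent_is",
    "nos_between",
    "all_of",
]

DIAGNOSES = ("depression", "anxiety", "bipolar", "schizophrenia")
DESIGNS = ("case-control", "cross-sectional", "prospective-cohort")
INSTRUMENTS = ("DSM-4", "DSM-5", "ICD-10")

#: Documented CSV header, in order.
CSV_COLUMNS = [
    "study_id", "diagnosis", "region", "design", "instrument",
    "n_case", "mean_case", "sd_case", "n_control", "mean_control",
    "sd_control", "age_case", "age_control", "male_fraction",
    "apd_recent", "nos_score",
]

_MANDATORY = CSV_COLUMNS[:11]
_OPTIONAL = CSV_COLUMNS[11:]


class SchemaError(ValueError):
    """The on-disk table does not match the documented column schema."""


class StudyValidationError(ValueError):
    """One or more study records violate a data invariant."""


@dataclass(frozen=True)
class StudyRecord:
    """Two-arm summary statistics and moderators for one study.

    ``mean_*``/``sd_*`` are MPV in femtolitres; ``age_*`` are mean ages in
    years; ``male_fraction`` is the male proportion of the total sample;
    ``apd_recent`` flags antipsychotic intake within one month before blood
    sampling; ``nos_score`` is the Newcastle-Ottawa quality score (0-9).
    """

    study_id: str
    diagnosis: str
    region: str
    design: str
    instrument: str
    n_case: int
    mean_case: float
    sd_case: float
    n_control: int
    mean_control: float
    sd_control: float
    age_case: Optional[float] = None
    age_control: Optional[float] = None
    male_fraction: Optional[float] = None
    apd_recent: Optional[bool] = None
    nos_score: Optional[int] = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.diagnosis not in DIAGNOSES:
            problems.append(f"diagnosis {self.diagnosis!r} not in {DIAGNOSES}")
        if self.design not in DESIGNS:
            problems.append(f"design {self.design!r} not in {DESIGNS}")
        if self.instrument not in INSTRUMENTS:
            problems.append(f"instrument {self.instrument!r} not in {INSTRUMENTS}")
        if self.n_case < 2:
            problems.append(f"n_case = {self.n_case} < 2")
        if self.n_control < 2:
            problems.append(f"n_control = {self.n_control} < 2")
        if not self.sd_case > 0:
            problems.append(f"sd_case = {self.sd_case} not > 0")
        if not self.sd_control > 0:
            problems.append(f"sd_control = {self.sd_control} not > 0")
        if self.age_case is not None and self.age_case < 0:
            problems.append("age_case < 0")
        if self.age_control is not None and self.age_control < 0:
            problems.append("age_control < 0")
        if self.male_fraction is not None and not 0 <= self.male_fraction <= 1:
            problems.append(f"male_fraction = {self.male_fraction} outside [0,1]")
        if self.nos_score is not None and not 0 <= self.nos_score <= 9:
            problems.append(f"nos_score = {self.nos_score} outside [0,9]")
        return problems

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control


@dataclass(frozen=True)
class StudyTable:
    """An ordered, uniquely-labelled collection of :class:`StudyRecord`.

    Order is part of the contract: leave-one-out rows are labelled by position.
    """

    records: tuple[StudyRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.study_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise StudyValidationError(f"duplicate study_id values: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, key: Union[int, str]) -> StudyRecord:
        if isinstance(key, str):
            for r in self.records:
                if r.study_id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    @property
    def study_ids(self) -> list[str]:
        return [r.study_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Render the table as a DataFrame with the documented columns."""
        rows = []
        for r in self.records:
            rows.append({f.name: getattr(r, f.name) for f in fields(StudyRecord)})
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        return df


def _parse_optional_float(value, row: int, col: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "NA", "NaN", "nan"):
        return None
    try:
        return float(s)
    except ValueError:
        raise SchemaError(f"row {row}: non-numeric value {s!r} in column {col!r}")


def _parse_optional_bool(value, row: int, col: str) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "NA", "NaN", "nan"):
        return None
    if s.lower() in ("true", "1", "yes"):
        return True
    if s.lower() in ("false", "0", "no"):
        return False
    raise SchemaError(f"row {row}: non-boolean value {s!r} in column {col!r}")


def read_study_table(path: Union[str, Path], provenance: Optional[str] = None) -> StudyTable:
    """Read a study table from CSV, validating the schema and all invariants.

    Parameters
    ----------
    path : str or Path
        CSV file with the documented header (see :data:`CSV_COLUMNS`).
    provenance : str, optional
        Free-text source description; defaults to the file path.

    Raises
    ------
    SchemaError
        Missing mandatory column, or a non-parseable cell (reported with row
        and column).
    StudyValidationError
        Invariant violations, reported with row numbers; duplicate study ids.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    records = []
    problems = []
    for i, row in raw.iterrows():
        rownum = i + 2  # header is line 1
        try:
            rec = StudyRecord(
                study_id=row["study_id"].strip(),
                diagnosis=row["diagnosis"].strip(),
                region=row["region"].strip(),
                design=row["design"].strip(),
                instrument=row["instrument"].strip(),
                n_case=_parse_mandatory_int(row["n_case"], rownum, "n_case"),
                mean_case=_parse_mandatory_float(row["mean_case"], rownum, "mean_case"),
                sd_case=_parse_mandatory_float(row["sd_case"], rownum, "sd_case"),
                n_control=_parse_mandatory_int(row["n_control"], rownum, "n_control"),
                mean_control=_parse_mandatory_float(row["mean_control"], rownum, "mean_control"),
                sd_control=_parse_mandatory_float(row["sd_control"], rownum, "sd_control"),
                age_case=_parse_optional_float(row.get("age_case"), rownum, "age_case"),
                age_control=_parse_optional_float(row.get("age_control"), rownum, "age_control"),
                male_fraction=_parse_optional_float(row.get("male_fraction"), rownum, "male_fraction"),
                apd_recent=_parse_optional_bool(row.get("apd_recent"), rownum, "apd_recent"),
                nos_score=_parse_optional_int(row.get("nos_score"), rownum, "nos_score"),
            )
        except SchemaError:
            raise
        bad = rec.validate()
        if bad:
            problems.append(f"row {rownum} ({rec.study_id}): " + "; ".join(bad))
        records.append(rec)
    if problems:
        raise StudyValidationError("\n".join(problems))
    return StudyTable(tuple(records), provenance or str(path))


def _parse_mandatory_float(value, row: int, col: str) -> float:
    out = _parse_optional_float(value, row, col)
    if out is None:
        raise SchemaError(f"row {row}: missing mandatory value in column {col!r}")
    return out


def _parse_mandatory_int(value, row: int, col: str) -> int:
    out = _parse_mandatory_float(value, row, col)
    if out != int(out):
        raise SchemaError(f"row {row}: non-integer value {value!r} in column {col!r}")
    return int(out)


def _parse_optional_int(value, row: int, col: str) -> Optional[int]:
    out = _parse_optional_float(value, row, col)
    if out is None:
        return None
    if out != int(out):
        raise SchemaError(f"row {row}: non-integer value {value!r} in column {col!r}")
    return int(out)


def write_study_table(table: StudyTable, path: Union[str, Path]) -> None:
    """Write a study table to CSV; missing moderators become ``NA``."""
    df = table.to_frame()
    df["apd_recent"] = df["apd_recent"].map(
        lambda v: "NA" if v is None or (isinstance(v, float) and math.isnan(v)) else str(bool(v)).lower()
    )
    df.to_csv(path, index=False, na_rep="NA")


def builtin_table() -> StudyTable:
    """The packaged 24-study MPV table, in its published row order.

    Per-arm medication history, sex ratio and quality score were not published
    per study, so ``apd_recent``, ``male_fraction`` and ``nos_score`` are
    missing throughout; analyses over those moderators need user-supplied
    annotation.  One study (Mukta) has no age data.
    """
    src = resources.files("mpvmeta").joinpath("data/table1.csv")
    with resources.as_file(src) as p:
        table = read_study_table(p, provenance="packaged 24-study MPV table")
    return table


# ---------------------------------------------------------------------------
# Selection predicates


def min_total_n(threshold: int) -> Callable[[StudyRecord], bool]:
    """Keep studies with total sample size (both arms) >= ``threshold``."""
    def rule(r: StudyRecord) -> bool:
        return r.n_total >= threshold
    rule.__name__ = f"min_total_n_{threshold}"
    return rule


def diagnosis_is(diagnosis: str) -> Callable[[StudyRecord], bool]:
    def rule(r: StudyRecord) -> bool:
        return r.diagnosis == diagnosis
    rule.__name__ = f"diagnosis_is_{diagnosis}"
    rule._moderator = None
    return rule


def apd_recent_is(flag: bool) -> Callable[[StudyRecord], bool]:
    def rule(r: StudyRecord) -> bool:
        return r.apd_recent is flag
    rule.__name__ = f"apd_recent_is_{flag}"
    rule._moderator = "apd_recent"
    return rule


def nos_between(low: int, high: int) -> Callable[[StudyRecord], bool]:
    def rule(r: StudyRecord) -> bool:
        return r.nos_score is not None and low <= r.nos_score <= high
    rule.__name__ = f"nos_between_{low}_{high}"
    rule._moderator = "nos_score"
    return rule


def all_of(*rules: Callable[[StudyRecord], bool]) -> Callable[[StudyRecord], bool]:
    """Composite predicate: conjunction of the given rules."""
    def rule(r: StudyRecord) -> bool:
        return all(f(r) for f in rules)
    rule.__name__ = "all_of_" + "_".join(getattr(f, "__name__", "rule") for f in rules)
    return rule


def filter_studies(table: StudyTable, predicate: Callable[[StudyRecord], bool]) -> StudyTable:
    """Return the sub-table of records satisfying ``predicate``, order kept.

    Raises
    ------
    StudyValidationError
        If the predicate depends on a moderator that is missing in every
        record (the selection would be vacuous rather than meaningful).
    """
    moderator = getattr(predicate, "_moderator", False)
    if moderator:
        if all(getattr(r, moderator) is None for r in table):
            raise StudyValidationError(
                f"moderator {moderator!r} is missing in every record; "
                "supply per-study annotation before filtering on it"
            )
    kept = tuple(r for r in table if predicate(r))
    name = getattr(predicate, "__name__", "predicate")
    return StudyTable(kept, provenance=f"{table.provenance} | filter: {name}")
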