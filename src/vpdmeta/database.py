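"""Study-level data model and CSV I/O.

One :class:`StudyRecord` is a single extracted observation: a trait measured
on one species in one experiment, under a control and a high vapor-pressure-
deficit (VPD) treatment, with arm means, SDs and sample sizes, the VPD levels,
environmental moderators and plant-grouping labels.  A :class:`StudyDatabase`
is an ordered collection of records validated against a trait catalog.

The CSV dialect is UTF-8, comma-separated, header required; an empty cell is
an explicit missing value.  Floats are written at full repr precision so a
write/read round-trip is exact.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .catalog import TraitCatalog, default_catalog

IRRIGATION_LEVELS = ("hydroponic_or_daily", "less_than_daily_or_unreported")
SOIL_LEVELS = ("artificial", "hydroponic", "native", "topsoil_mix", "unspecified")
EVOLUTIONARY_LEVELS = ("dicot", "fern", "gymnosperm", "monocot")
HABIT_LEVELS = ("forb", "grass", "woody")
DURATION_LEVELS = ("annual_biennial", "perennial")
END_USE_LEVELS = ("crop", "non_crop")
CONDITION_LEVELS = ("SC", "DC", "NA")

#: canonical column order of the study table CSV
COLUMNS = [
    "paper_id", "study_id", "species", "family", "trait",
    "mean_control", "mean_high", "sd_control", "sd_high",
    "n_control", "n_high", "vpd_control", "vpd_high", "day_temp",
    "irrigation", "soil_type", "treatment_duration", "plant_age",
    "evolutionary_history", "growth_habit", "growth_duration", "end_use",
    "measurement_condition",
]

_FLOAT_FIELDS = {"mean_control", "mean_high", "sd_control", "sd_high",
                 "vpd_control", "vpd_high", "day_temp", "treatment_duration",
                 "plant_age"}
_INT_FIELDS = {"n_control", "n_high"}


class ValidationError(ValueError):
    pass


@dataclass
class StudyRecord:
    paper_id: str
    study_id: str
    species: str
    family: str
    trait: str
    mean_control: float
    mean_high: float
    sd_control: Optional[float] = None
    sd_high: Optional[float] = None
    n_control: Optional[int] = None
    n_high: Optional[int] = None
    vpd_control: Optional[float] = None
    vpd_high: Optional[float] = None
    day_temp: Optional[float] = None
    irrigation: Optional[str] = None
    soil_type: Optional[str] = None
    treatment_duration: Optional[float] = None
    plant_age: Optional[float] = None
    evolutionary_history: Optional[str] = None
    growth_habit: Optional[str] = None
    growth_duration: Optional[str] = None
    end_use: Optional[str] = None
    measurement_condition: str = "NA"


@dataclass
class Violation:
    row: int          # 1-based data-row index in the source file
    study_id: str
    reason: str


@dataclass
class ValidationReport:
    accepted: int = 0
    rejected: int = 0
    violations: list[Violation] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "accepted": self.accepted,
                "rejected": self.rejected,
                "violations": [
                    {"row": v.row, "study_id": v.study_id, "reason": v.reason}
                    for v in self.violations
                ],
            },
            indent=2,
        )


def _record_violations(rec: StudyRecord, catalog: TraitCatalog) -> list[str]:
    """Reasons this record cannot enter the database (empty list if valid)."""
    out = []
    if rec.trait not in catalog:
        out.append(f"unknown trait {rec.trait!r}")
    if not (rec.mean_control > 0) or not (rec.mean_high > 0):
        out.append("non-positive mean")  # log ratio undefined
    for name in ("sd_control", "sd_high"):
        v = getattr(rec, name)
        if v is not None and v < 0:
            out.append(f"negative {name}")
    for name in ("n_control", "n_high"):
        v = getattr(rec, name)
        if v is not None and v < 1:
            out.append(f"{name} < 1")
    for name in ("vpd_control", "vpd_high"):
        v = getattr(rec, name)
        if v is not None and v <= 0:
            out.append(f"non-positive {name}")
    if (rec.vpd_control is not None and rec.vpd_high is not None
            and not rec.vpd_high > rec.vpd_control):
        out.append("vpd_high not greater than vpd_control")
    if rec.treatment_duration is not None and rec.treatment_duration < 2:
        out.append("treatment_duration < 2 days")
    if rec.measurement_condition not in CONDITION_LEVELS:
        out.append(f"invalid measurement_condition {rec.measurement_condition!r}")
    for name, levels in (("irrigation", IRRIGATION_LEVELS),
                         ("soil_type", SOIL_LEVELS),
                         ("evolutionary_history", EVOLUTIONARY_LEVELS),
                         ("growth_habit", HABIT_LEVELS),
                         ("growth_duration", DURATION_LEVELS),
                         ("end_use", END_USE_LEVELS)):
        v = getattr(rec, name)
        if v is not None and v not in levels:
            out.append(f"invalid {name} level {v!r}")
    return out


class StudyDatabase:
    """Ordered collection of validated :class:`StudyRecord` objects."""

    def __init__(self, records: Iterable[StudyRecord],
                 catalog: Optional[TraitCatalog] = None,
                 provenance: str = "",
                 report: Optional[ValidationReport] = None,
                 validate: bool = True):
        self.catalog = catalog if catalog is not None else default_catalog()
        self.records = list(records)
        self.provenance = provenance
        self.report = report if report is not None else ValidationReport(
            accepted=len(self.records))
        if validate:
            seen: set[str] = set()
            for i, rec in enumerate(self.records):
                probs = _record_violations(rec, self.catalog)
                if rec.study_id in seen:
                    probs.append("duplicate study_id")
                seen.add(rec.study_id)
                if probs:
                    raise ValidationError(f"record {i} ({rec.study_id}): "
                                          + "; ".join(probs))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def traits(self) -> list[str]:
        """Distinct traits present, in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.trait, None)
        return list(seen)

    def filter_trait(self, trait: str, condition: str = "any") -> list[StudyRecord]:
        """Records of ``trait`` matching a measurement condition.

        ``condition`` is one of ``"SC"``, ``"DC"``, ``"NA"`` or ``"any"``;
        ``"any"`` ignores the flag.
        """
        if trait not in self.catalog:
            raise KeyError(f"unknown trait {trait!r}")
        if condition not in ("any", *CONDITION_LEVELS):
            raise ValueError(f"invalid condition {condition!r}")
        recs = [r for r in self.records if r.trait == trait]
        if condition == "any":
            return recs
        return [r for r in recs if r.measurement_condition == condition]

    def copy(self) -> "StudyDatabase":
        return StudyDatabase([replace(r) for r in self.records],
                             catalog=self.catalog,
                             provenance=self.provenance,
                             report=self.report, validate=False)

    def write_csv(self, path: str | Path) -> None:
        write_study_table(self, path)


def count_species(records: Iterable[StudyRecord]) -> int:
    """Number of distinct species among records (N), case/whitespace normalized."""
    return len({r.species.strip().casefold() for r in records})


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(value)
    return str(value)


def _parse_cell(name: str, raw: str):
    if raw.strip() == "":
        return None
    if name in _FLOAT_FIELDS:
        return float(raw.strip())
    if name in _INT_FIELDS:
        return int(float(raw.strip()))
    # string fields round-trip verbatim (normalization is the consumer's job,
    # e.g. count_species casefolds and trims)
    return raw


def read_study_table(path: str | Path,
                     catalog: Optional[TraitCatalog] = None) -> StudyDatabase:
    """Read and validate a study-table CSV.

    Every row is either accepted into the database or recorded in the
    attached :class:`ValidationReport` with a reason; rows never vanish
    silently.  Missing cells (empty strings) become ``None``.
    """
    catalog = catalog if catalog is not None else default_catalog()
    path = Path(path)
    report = ValidationReport()
    records: list[StudyRecord] = []
    seen_ids: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, header required")
        missing_cols = set(COLUMNS) - set(reader.fieldnames)
        if missing_cols:
            raise ValidationError(
                f"{path}: missing columns {sorted(missing_cols)}")
        for i, row in enumerate(reader, start=1):
            sid = (row.get("study_id") or "").strip()
            try:
                kwargs = {name: _parse_cell(name, row.get(name) or "")
                          for name in COLUMNS}
            except ValueError as exc:
                report.violations.append(Violation(i, sid, f"unparseable cell: {exc}"))
                report.rejected += 1
                continue
            if kwargs["measurement_condition"] is None:
                kwargs["measurement_condition"] = "NA"
            required = [k for k in ("paper_id", "study_id", "species", "family",
                                    "trait", "mean_control", "mean_high")
                        if kwargs[k] is None]
            if required:
                report.violations.append(
                    Violation(i, sid, f"missing required fields {required}"))
                report.rejected += 1
                continue
            rec = StudyRecord(**kwargs)
            probs = _record_violations(rec, catalog)
            if rec.study_id in seen_ids:
                probs.append("duplicate study_id")
            if probs:
                report.violations.append(Violation(i, sid, "; ".join(probs)))
                report.rejected += 1
                continue
            seen_ids.add(rec.study_id)
            records.append(rec)
            report.accepted += 1
    return StudyDatabase(records, catalog=catalog, provenance=str(path),
                         report=report, validate=False)


def write_study_table(db: StudyDatabase, path: str | Path) -> None:
    """Write the database back to the identical-schema CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for rec in db.records:
            writer.writerow([_fmt(getattr(rec, name)) for name in COLUMNS])
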