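"""Surface-contamination survey tables: parsing, summary, assessment.

Wipe-sampling surveys report drug mass per surface area for facility
areas (pharmacy, drug administration, patient care, operating room),
usually as a range, a mean/median, or a 75th percentile, in units that
span pg/cm² to μg/cm².  This module reads such tables from CSV,
normalizes everything to ng/cm², handles left-censored lower bounds
("ND", "<LOD", "< x"), summarizes maxima, and classifies each entry
against an acceptable surface contamination level (ASCL).

A transcription of a published review of 27 wipe-sampling studies is
bundled as ``data/surface_survey_review.csv`` and available through
:func:`load_reference_survey`.

Platinum-compound entries are retained but flagged: inorganic/metal
analytes fall outside the TTC approach, so they are excluded from ASCL
verdict counts unless explicitly included.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

from .units import to_ng_per_cm2, canonical_surface_unit, UnitError

__all__ = [
    "FacilityArea",
    "StatKind",
    "RecordVerdict",
    "SurveyRecord",
    "SurveyParseResult",
    "SurveyAssessment",
    "ANALYTE_CODES",
    "normalize_to_ng_per_cm2",
    "parse_survey_csv",
    "load_reference_survey",
    "summarize",
    "assess_against_ascl",
]

logger = logging.getLogger(__name__)

#: Analyte codes: 5-fluorouracil, cyclophosphamide, docetaxel,
#: gemcitabine, ifosfamide, methotrexate, paclitaxel, platinum compounds.
ANALYTE_CODES = frozenset({"5-FU", "CP", "DX", "GM", "IF", "MT", "PX", "Pt"})


class FacilityArea(str, Enum):
    PHARMACY = "pharmacy"
    ADMINISTRATION = "administration"
    PATIENT_CARE = "patient_care"
    OPERATING_ROOM = "operating_room"


class StatKind(str, Enum):
    RANGE = "range"
    MEDIAN = "median"
    MEAN = "mean"
    P75 = "p75"


#: Statistic kinds whose value_high is a summary value, not a raw maximum.
SUMMARY_KINDS = (StatKind.MEDIAN, StatKind.MEAN, StatKind.P75)


class RecordVerdict(str, Enum):
    BELOW = "below"
    EXCEEDS_AT_HIGH = "exceeds_at_high"
    EXCEEDS_AT_SUMMARY = "exceeds_at_summary"


@dataclass(frozen=True)
class SurveyRecord:
    """One wipe-sampling survey entry, values canonical in ng/cm²."""

    facility_area: FacilityArea
    analytes: tuple[str, ...]
    n_samples: int
    value_low: float  # ng/cm²
    value_high: float  # ng/cm²
    stat_kind: StatKind
    low_censored: bool = False
    source_ref: str = ""

    def __post_init__(self) -> None:
        if not self.analytes:
            raise ValueError("analytes must be non-empty")
        unknown = set(self.analytes) - ANALYTE_CODES
        if unknown:
            raise ValueError(f"unknown analyte codes: {sorted(unknown)}")
        if not self.n_samples > 0:
            raise ValueError("n_samples must be > 0")
        if not 0 <= self.value_low <= self.value_high:
            raise ValueError(
                f"need 0 <= value_low <= value_high, got "
                f"[{self.value_low}, {self.value_high}]"
            )

    @property
    def has_platinum(self) -> bool:
        return "Pt" in self.analytes


@dataclass
class SurveyParseResult:
    records: list[SurveyRecord]
    rejected: list[tuple[int, str]]  # (row number, reason)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def normalize_to_ng_per_cm2(value: float, unit: str) -> float:
    """Exact power-of-ten conversion of a surface density to ng/cm²."""
    return to_ng_per_cm2(value, unit)


def _parse_low_value(token: str, censored_field: str) -> tuple[float, bool]:
    """Interpret a printed lower bound.

    "ND"/"<LOD" → 0.0, censored; "< x" → x, censored; a plain number is
    censored only if the low_censored column says so.
    """
    token = token.strip()
    upper = token.upper()
    if upper in ("ND", "<LOD", "< LOD", "N.D."):
        return 0.0, True
    if token.startswith("<"):
        return float(token[1:].strip()), True
    censored = censored_field.strip().lower() in ("true", "1", "yes")
    return float(token), censored


def parse_survey_csv(path: str | Path) -> SurveyParseResult:
    """Parse a survey CSV into records plus per-row rejections.

    Expected header: ``area, analytes, n_samples, value_low, value_high,
    stat_kind, unit, low_censored, source`` with analytes ;-separated
    and values in the stated unit (converted to ng/cm² on load).
    Malformed rows are rejected individually — with their row number and
    a reason — rather than aborting the whole file.
    """
    path = Path(path)
    records: list[SurveyRecord] = []
    rejected: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {
            "area", "analytes", "n_samples", "value_low",
            "value_high", "stat_kind", "unit",
        }
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row_no, row in enumerate(reader, start=2):
            try:
                unit = canonical_surface_unit(row["unit"])
                low, censored = _parse_low_value(
                    row["value_low"], row.get("low_censored") or ""
                )
                record = SurveyRecord(
                    facility_area=FacilityArea(row["area"].strip()),
                    analytes=tuple(
                        a.strip() for a in row["analytes"].split(";") if a.strip()
                    ),
                    n_samples=int(row["n_samples"]),
                    value_low=normalize_to_ng_per_cm2(low, unit),
                    value_high=normalize_to_ng_per_cm2(
                        float(row["value_high"]), unit
                    ),
                    stat_kind=StatKind(row["stat_kind"].strip()),
                    low_censored=censored,
                    source_ref=(row.get("source") or "").strip(),
                )
            except (ValueError, KeyError, UnitError) as exc:
                logger.warning("%s row %d rejected: %s", path, row_no, exc)
                rejected.append((row_no, str(exc)))
                continue
            records.append(record)
    return SurveyParseResult(records=records, rejected=rejected)


def load_reference_survey() -> SurveyParseResult:
    """The bundled transcription of the published wipe-sampling review."""
    with resources.as_file(
        resources.files("ttcrisk.data") / "surface_survey_review.csv"
    ) as p:
        return parse_survey_csv(p)


def summarize(records: list[SurveyRecord]) -> dict:
    """Maxima over a set of survey records (all in ng/cm²).

    ``max_mean``/``max_median``/``max_p75`` are the largest value_high
    among records of that statistic kind (None when absent);
    ``max_overall`` spans every record; ``per_area`` maps facility area
    to its maximum.  Censored lower bounds never enter any maximum.
    """
    if not records:
        raise ValueError("records must be non-empty")

    def _max_of(kind: StatKind) -> float | None:
        values = [r.value_high for r in records if r.stat_kind is kind]
        return max(values) if values else None

    per_area: dict[str, float] = {}
    for rec in records:
        key = rec.facility_area.value
        per_area[key] = max(per_area.get(key, 0.0), rec.value_high)
    return {
        "max_overall": max(r.value_high for r in records),
        "max_mean": _max_of(StatKind.MEAN),
        "max_median": _max_of(StatKind.MEDIAN),
        "max_p75": _max_of(StatKind.P75),
        "per_area": per_area,
        "n_records": len(records),
    }


@dataclass
class SurveyAssessment:
    """Classification of survey records against an ASCL (ng/cm²)."""

    ascl_used: float
    verdicts: list[tuple[SurveyRecord, RecordVerdict]]
    counts_by_area: dict
    max_mean: float | None
    max_overall: float
    excluded_records: list[tuple[SurveyRecord, str]] = field(default_factory=list)

    @property
    def n_below(self) -> int:
        return sum(1 for _, v in self.verdicts if v is RecordVerdict.BELOW)

    @property
    def n_exceeds(self) -> int:
        return len(self.verdicts) - self.n_below


def _classify(record: SurveyRecord, ascl: float) -> RecordVerdict:
    # boundary inclusive: value_high == ascl is "below", mirroring DDI/ADI <= 1
    if record.value_high <= ascl:
        return RecordVerdict.BELOW
    if record.stat_kind in SUMMARY_KINDS:
        return RecordVerdict.EXCEEDS_AT_SUMMARY
    return RecordVerdict.EXCEEDS_AT_HIGH


def assess_against_ascl(
    records: list[SurveyRecord],
    ascl: float,
    include_pt: bool = False,
) -> SurveyAssessment:
    """Classify each record's value_high against the ASCL.

    Records whose analytes include platinum compounds are excluded by
    default (metals fall outside the TTC approach); pass
    ``include_pt=True`` to assess them anyway.  For summary statistics
    (mean/median/p75) the stored value_high *is* the summary value — the
    upper end of the printed summary range — which is the conservative
    end to compare.
    """
    if not ascl > 0:
        raise ValueError("ascl must be > 0")
    if not records:
        raise ValueError("records must be non-empty")

    assessed: list[SurveyRecord] = []
    excluded: list[tuple[SurveyRecord, str]] = []
    for rec in records:
        if rec.has_platinum and not include_pt:
            excluded.append((rec, "Pt analyte not TTC-assessable"))
        else:
            assessed.append(rec)

    verdicts = [(rec, _classify(rec, ascl)) for rec in assessed]
    counts_by_area: dict[str, dict[str, int]] = {}
    for rec, verdict in verdicts:
        area = counts_by_area.setdefault(
            rec.facility_area.value, {v.value: 0 for v in RecordVerdict}
        )
        area[verdict.value] += 1

    stats = summarize(assessed) if assessed else {"max_mean": None, "max_overall": 0.0}
    return SurveyAssessment(
        ascl_used=ascl,
        verdicts=verdicts,
        counts_by_area=counts_by_area,
        max_mean=stats["max_mean"],
        max_overall=stats["max_overall"],
        excluded_records=excluded,
    )
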