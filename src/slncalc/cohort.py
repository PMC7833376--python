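"""Patient data model, factor schemes, cohort CSV I/O and summary tables.

A cohort is a list of :class:`PatientRecord` — one clinically node-negative
breast-cancer patient each, carrying the prognostic factors the risk model
uses (age, tumor diameter in mm, histologic type, ER, PR, Ki67, HER2,
histological grade) and the sentinel-lymph-node label established at surgery.

A :class:`FactorScheme` declares which prognostic factors enter the model and
how raw record values map onto discrete factor levels; the per-level
multipliers of the risk model are indexed by (factor, level) pairs of the
scheme. Missing values map to the reserved level ``"unknown"``, which the
model treats as a neutral multiplier of 1.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import CohortSchemaError, ConfigurationError, RecordValidationError

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"

#: CSV column order; unknowns are encoded as the literal string "unknown".
CSV_COLUMNS = (
    "patient_id",
    "age",
    "diameter_mm",
    "histology",
    "er",
    "pr",
    "ki67",
    "her2",
    "grading",
    "node_status",
)

_HISTOLOGY_VALUES = frozenset({"ductal", "lobular", UNKNOWN})
_POSNEG_VALUES = frozenset({"pos", "neg"})
_HER2_VALUES = frozenset({"pos", "neg", UNKNOWN})
_GRADING_VALUES = frozenset({"1", "2", "3", UNKNOWN})


@dataclass(frozen=True)
class PatientRecord:
    """One clinically node-negative patient.

    ``ki67`` is dichotomized at the 20% cut-off upstream (``pos`` means ≥20%);
    ``node_status`` is 1 when the sentinel lymph node was positive.
    """

    patient_id: str
    age: int
    diameter: float
    histology: str
    er: str
    pr: str
    ki67: str
    her2: str
    grading: str
    node_status: int

    def __post_init__(self) -> None:
        if not (isinstance(self.age, int) and self.age >= 18):
            raise RecordValidationError(
                f"age must be an integer >= 18, got {self.age!r}", field="age"
            )
        if not self.diameter > 0:
            raise RecordValidationError(
                f"diameter must be > 0 mm, got {self.diameter!r}", field="diameter"
            )
        for name, allowed in (
            ("histology", _HISTOLOGY_VALUES),
            ("er", _POSNEG_VALUES),
            ("pr", _POSNEG_VALUES),
            ("ki67", _POSNEG_VALUES),
            ("her2", _HER2_VALUES),
            ("grading", _GRADING_VALUES),
        ):
            if getattr(self, name) not in allowed:
                raise RecordValidationError(
                    f"{name} must be one of {sorted(allowed)}, got {getattr(self, name)!r}",
                    field=name,
                )
        if self.node_status not in (0, 1):
            raise RecordValidationError(
                f"node_status must be 0 or 1, got {self.node_status!r}",
                field="node_status",
            )


class Subtype(Enum):
    """St. Gallen intrinsic molecular subtype from ER/PR/HER2/Ki67 status."""

    LUMINAL_A = "LuminalA"
    LUMINAL_B = "LuminalB"
    HER2_POS = "HER2pos"
    TRIPLE_NEGATIVE = "TripleNegative"
    UNKNOWN = "unknown"


def assign_subtype(record: PatientRecord) -> Subtype:
    """St. Gallen surrogate subtype.

    Hormone-receptor positive (ER+ or PR+) tumors are Luminal A when HER2−
    and Ki67 low, Luminal B when HER2+ or Ki67 high; receptor-negative tumors
    split into HER2-positive and triple-negative. HER2 unknown yields
    ``Subtype.UNKNOWN`` (the only missingness that blocks the call).
    """
    if record.her2 == UNKNOWN:
        return Subtype.UNKNOWN
    hr_pos = record.er == "pos" or record.pr == "pos"
    if hr_pos:
        if record.her2 == "pos" or record.ki67 == "pos":
            return Subtype.LUMINAL_B
        return Subtype.LUMINAL_A
    return Subtype.HER2_POS if record.her2 == "pos" else Subtype.TRIPLE_NEGATIVE


# --------------------------------------------------------------------------
# Factor schemes
# --------------------------------------------------------------------------

#: (low, high, label) half-open intervals [low, high) covering [18, 120).
DEFAULT_AGE_BINS: tuple[tuple[int, int, str], ...] = (
    (18, 31, "21-30"),
    (31, 41, "31-40"),
    (41, 51, "41-50"),
    (51, 61, "51-60"),
    (61, 71, "61-70"),
    (71, 81, "71-80"),
    (81, 91, "81-90"),
    (91, 120, ">90"),
)

#: Coarser bins used for clinical subgroup stratification, independent of the
#: model's decade bins.
STRATIFICATION_AGE_BINS: tuple[tuple[int, int, str], ...] = (
    (18, 46, "<=45"),
    (46, 61, "46-60"),
    (61, 120, ">60"),
)

#: Tumor-size categories; the upper bound is inclusive (T1 means D <= 20 mm).
TUMOR_SIZE_BINS: tuple[tuple[float, str], ...] = ((20.0, "T1"), (50.0, "T2"), (float("inf"), "T3"))

_FIXED_LEVELS: dict[str, tuple[str, ...]] = {
    "histology": ("ductal", "lobular"),
    "er": ("pos", "neg"),
    "pr": ("pos", "neg"),
    "ki67": ("pos", "neg"),
    "her2": ("pos", "neg"),
    "grading": ("G1", "G2", "G3"),
    "tumor_size": tuple(label for _, label in TUMOR_SIZE_BINS),
}

_KNOWN_FACTORS = ("age", "histology", "er", "pr", "ki67", "her2", "grading", "tumor_size")

#: Factors of the base model, matching the covariates the original web
#: calculator conditions on (diameter enters the model directly, not as a factor).
BASE_FACTORS = ("age", "histology", "er", "pr", "grading")


@dataclass(frozen=True)
class FactorScheme:
    """Ordered declaration of model factors and their level mappings."""

    factors: tuple[str, ...]
    age_bins: tuple[tuple[int, int, str], ...] = DEFAULT_AGE_BINS

    def __post_init__(self) -> None:
        for f in self.factors:
            if f not in _KNOWN_FACTORS:
                raise ConfigurationError(f"unknown factor {f!r}")
        if len(set(self.factors)) != len(self.factors):
            raise ConfigurationError("duplicate factor in scheme")
        bins = sorted(self.age_bins)
        labels = [lab for _, _, lab in bins]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate age-bin label")
        lo = 18
        for b_lo, b_hi, _ in bins:
            if b_lo != lo or b_hi <= b_lo:
                raise ConfigurationError("age bins must be disjoint and cover [18, 120)")
            lo = b_hi
        if lo != 120:
            raise ConfigurationError("age bins must cover [18, 120)")

    def levels(self, factor: str) -> tuple[str, ...]:
        """Non-unknown level labels of ``factor``, in declaration order."""
        if factor == "age":
            return tuple(lab for _, _, lab in self.age_bins)
        return _FIXED_LEVELS[factor]

    def map_record(self, record: PatientRecord) -> dict[str, str]:
        return map_to_levels(record, self)

    def to_dict(self) -> dict:
        return {"factors": list(self.factors), "age_bins": [list(b) for b in self.age_bins]}

    @classmethod
    def from_dict(cls, d: dict) -> "FactorScheme":
        return cls(
            factors=tuple(d["factors"]),
            age_bins=tuple((int(lo), int(hi), str(lab)) for lo, hi, lab in d["age_bins"]),
        )

    def fingerprint(self) -> str:
        """Stable hex digest identifying the factor/level structure."""
        payload = json.dumps(
            {"factors": list(self.factors),
             "levels": {f: list(self.levels(f)) for f in self.factors},
             "age_bins": [list(b) for b in self.age_bins]},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


#: Model variants: A = base covariates, B adds HER2, C adds Ki67, D adds both.
VARIANT_FACTORS: dict[str, tuple[str, ...]] = {
    "A": BASE_FACTORS,
    "B": BASE_FACTORS + ("her2",),
    "C": BASE_FACTORS + ("ki67",),
    "D": BASE_FACTORS + ("her2", "ki67"),
}


def build_scheme(
    variant: str = "A", age_bins: tuple[tuple[int, int, str], ...] = DEFAULT_AGE_BINS
) -> FactorScheme:
    """Scheme for a named model variant (A/B/C/D)."""
    try:
        factors = VARIANT_FACTORS[variant.upper()]
    except KeyError:
        raise ConfigurationError(f"unknown variant {variant!r}; expected one of A, B, C, D")
    return FactorScheme(factors=factors, age_bins=age_bins)


def summary_scheme() -> FactorScheme:
    """Scheme covering every factor plus tumor-size category, for Table-1-style summaries."""
    return FactorScheme(factors=("age", "tumor_size", "histology", "er", "pr", "ki67", "her2", "grading"))


def map_to_levels(record: PatientRecord, scheme: FactorScheme) -> dict[str, str]:
    """Map a record to exactly one level label per scheme factor.

    Raw unknowns pass through as the level ``"unknown"``. An age outside
    every declared bin is a configuration error (bins should cover [18, 120)).
    """
    out: dict[str, str] = {}
    for factor in scheme.factors:
        if factor == "age":
            for lo, hi, lab in scheme.age_bins:
                if lo <= record.age < hi:
                    out[factor] = lab
                    break
            else:
                raise ConfigurationError(
                    f"age {record.age} falls outside all age bins of the scheme"
                )
        elif factor == "tumor_size":
            for upper, lab in TUMOR_SIZE_BINS:
                if record.diameter <= upper:
                    out[factor] = lab
                    break
        elif factor == "grading":
            out[factor] = UNKNOWN if record.grading == UNKNOWN else f"G{record.grading}"
        else:
            out[factor] = getattr(record, factor)
    return out


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

def _parse_row(row: dict[str, str], idx: int) -> PatientRecord:
    try:
        age = int(row["age"])
        diameter = float(row["diameter_mm"])
        node = int(row["node_status"])
    except (TypeError, ValueError) as exc:
        raise RecordValidationError(f"row {idx}: unparseable numeric field ({exc})", row=idx)
    try:
        return PatientRecord(
            patient_id=str(row["patient_id"]),
            age=age,
            diameter=diameter,
            histology=row["histology"].strip(),
            er=row["er"].strip(),
            pr=row["pr"].strip(),
            ki67=row["ki67"].strip(),
            her2=row["her2"].strip(),
            grading=row["grading"].strip(),
            node_status=node,
        )
    except RecordValidationError as exc:
        raise RecordValidationError(f"row {idx}: {exc}", row=idx, field=exc.field)


def read_cohort(path: str | Path, strict: bool = True) -> list[PatientRecord]:
    """Read a cohort CSV.

    In strict mode any invalid row aborts with a :class:`RecordValidationError`
    naming the row; in lenient mode invalid rows are skipped and counted.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortSchemaError(f"{path}: empty file, header expected")
        missing = set(CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CohortSchemaError(f"{path}: missing required columns {sorted(missing)}")
        records: list[PatientRecord] = []
        skipped = 0
        for idx, row in enumerate(reader):
            try:
                records.append(_parse_row(row, idx))
            except RecordValidationError:
                if strict:
                    raise
                skipped += 1
    if skipped:
        logger.info("read_cohort(%s): kept %d records, skipped %d invalid rows",
                    path, len(records), skipped)
    return records


def write_cohort(cohort: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical column order."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in cohort:
            writer.writerow(
                [r.patient_id, r.age, repr(r.diameter), r.histology, r.er, r.pr,
                 r.ki67, r.her2, r.grading, r.node_status]
            )


# --------------------------------------------------------------------------
# Summary tables
# --------------------------------------------------------------------------

def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    scale = 10 ** ndigits
    import math

    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def cohort_summary(cohort: Sequence[PatientRecord], scheme: FactorScheme) -> pd.DataFrame:
    """Per-factor, per-level counts and positivity, mirroring a clinical
    characteristics table.

    Columns: factor, level, n, pct (share of cohort), n_pos, pct_pos
    (positivity within the level). Percentages are rounded to 2 decimals,
    half away from zero; an empty level reports pct_pos as NaN.
    """
    if not cohort:
        raise ValueError("cohort_summary requires a non-empty cohort")
    n_total = len(cohort)
    n_pos_total = sum(r.node_status for r in cohort)
    rows: list[dict] = [
        {
            "factor": "overall",
            "level": "all",
            "n": n_total,
            "pct": 100.0,
            "n_pos": n_pos_total,
            "pct_pos": round_half_away(100.0 * n_pos_total / n_total),
        }
    ]
    mapped = [map_to_levels(r, scheme) for r in cohort]
    for factor in scheme.factors:
        level_order = list(scheme.levels(factor)) + [UNKNOWN]
        counts = {lev: 0 for lev in level_order}
        pos = {lev: 0 for lev in level_order}
        for rec, m in zip(cohort, mapped):
            counts[m[factor]] += 1
            pos[m[factor]] += rec.node_status
        for lev in level_order:
            if lev == UNKNOWN and counts[lev] == 0:
                continue
            n = counts[lev]
            rows.append(
                {
                    "factor": factor,
                    "level": lev,
                    "n": n,
                    "pct": round_half_away(100.0 * n / n_total),
                    "n_pos": pos[lev],
                    "pct_pos": round_half_away(100.0 * pos[lev] / n) if n else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["factor", "level", "n", "pct", "n_pos", "pct_pos"])
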