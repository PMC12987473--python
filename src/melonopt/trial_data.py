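"""Field-trial tables for the two-factor melon cultivation experiment.

A trial crosses plant spacing (cm) with a pruning / fruit-retention method
(1V1F, 2V2F, 3V3F, 3V2F: vines kept x fruits kept per plant).  This module
holds the domain types, phenology (stage-date) arithmetic, CSV reading and
writing for the four table kinds, dataset validation, and the built-in
treatment tables of the 2023 Tumushuke field trial that the rest of the
package analyses.
"""

from __future__ import annotations

import datetime as _dt
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PRUNING_LABELS",
    "PRUNING_CODES",
    "VINES_PER_CODE",
    "SPACING_MIN_CM",
    "SPACING_MAX_CM",
    "SPACING_STEP_CM",
    "INDICATOR_NAMES",
    "TreatmentSpec",
    "PhenologyRecord",
    "TrialDataset",
    "ValidationIssue",
    "ValidationReport",
    "stage_duration",
    "compute_phenology_durations",
    "parse_value_cell",
    "parse_date_cell",
    "load_trial_table",
    "write_trial_table",
    "validate_dataset",
    "builtin_fixture",
    "FIXTURE_NAMES",
]

# ---------------------------------------------------------------------------
# Design-space constants
# ---------------------------------------------------------------------------

#: Pruning / fruit-retention codes as used in the optimization encoding.
PRUNING_LABELS: dict[int, str] = {1: "1V1F", 2: "2V2F", 3: "3V3F", 4: "3V2F"}
PRUNING_CODES: dict[str, int] = {v: k for k, v in PRUNING_LABELS.items()}
#: Number of vines retained for each pruning code (fruit count differs).
VINES_PER_CODE: dict[int, int] = {1: 1, 2: 2, 3: 3, 4: 3}

SPACING_MIN_CM = 30
SPACING_MAX_CM = 80
SPACING_STEP_CM = 5

#: The nine fruit-quality indicators, in table column order.
INDICATOR_NAMES: tuple[str, ...] = (
    "single_fruit_weight_kg",
    "fruit_shape_index",
    "flesh_moisture_pct",
    "hardness_N",
    "flesh_thickness_mm",
    "soluble_solids_pct",
    "soluble_sugar_mg_g",
    "soluble_sugar_pct",
    "vitamin_c_mg_kg",
)

_PHENOLOGY_STAGES: tuple[str, ...] = (
    "sowing_date",
    "emergence_date",
    "vine_elongation_date",
    "female_flower_date",
    "fruit_set_date",
    "enlargement_date",
    "maturity_date",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreatmentSpec:
    """One cultivation configuration: a label plus the two design factors."""

    label: str
    spacing_cm: int
    pruning_code: int

    @property
    def pruning_label(self) -> str:
        return PRUNING_LABELS[self.pruning_code]

    def check(self) -> list[str]:
        """Return invariant violations (empty list when valid)."""
        problems = []
        if not SPACING_MIN_CM <= self.spacing_cm <= SPACING_MAX_CM:
            problems.append(
                f"spacing {self.spacing_cm} cm outside "
                f"[{SPACING_MIN_CM}, {SPACING_MAX_CM}]"
            )
        if self.spacing_cm % SPACING_STEP_CM != 0:
            problems.append(
                f"spacing {self.spacing_cm} not divisible by {SPACING_STEP_CM}"
            )
        if self.pruning_code not in PRUNING_LABELS:
            problems.append(f"unknown pruning code {self.pruning_code}")
        return problems


@dataclass(frozen=True)
class PhenologyRecord:
    """Calendar dates of the tracked developmental stages for one treatment.

    Stage order (non-decreasing): sowing, emergence, vine elongation, female
    flower blooming, fruit set, fruit enlargement, maturity.
    """

    treatment: TreatmentSpec
    sowing_date: _dt.date
    emergence_date: _dt.date
    vine_elongation_date: _dt.date
    female_flower_date: _dt.date
    fruit_set_date: _dt.date
    enlargement_date: _dt.date
    maturity_date: _dt.date

    def dates_in_order(self) -> tuple[_dt.date, ...]:
        return tuple(getattr(self, s) for s in _PHENOLOGY_STAGES)

    def check(self) -> list[str]:
        problems = []
        dates = self.dates_in_order()
        for (na, a), (nb, b) in zip(
            zip(_PHENOLOGY_STAGES, dates), list(zip(_PHENOLOGY_STAGES, dates))[1:]
        ):
            if b < a:
                problems.append(
                    f"{self.treatment.label}: {nb} ({b.isoformat()}) precedes "
                    f"{na} ({a.isoformat()})"
                )
        if dates[-1] > dates[0] + _dt.timedelta(days=366):
            problems.append(
                f"{self.treatment.label}: maturity more than one year after sowing"
            )
        return problems


@dataclass
class TrialDataset:
    """Treatments with design factors, stage dates, responses and indicators.

    ``indicators`` holds the per-treatment means of the nine quality
    indicators (rows indexed by treatment label); ``indicator_sds`` the
    replicate standard deviations when the source table printed mean ± sd.
    ``responses`` has columns ``duration_days``, ``yield_t_hm2`` and ``ci``
    with NaN for values not (yet) available.
    """

    treatments: list[TreatmentSpec] = field(default_factory=list)
    phenology: dict[str, PhenologyRecord] = field(default_factory=dict)
    indicators: pd.DataFrame | None = None
    indicator_sds: pd.DataFrame | None = None
    responses: pd.DataFrame | None = None

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.treatments]

    def treatment(self, label: str) -> TreatmentSpec:
        for t in self.treatments:
            if t.label == label:
                return t
        raise KeyError(f"no treatment labelled {label!r}")

    def ensure_responses(self) -> pd.DataFrame:
        if self.responses is None:
            self.responses = pd.DataFrame(
                np.nan,
                index=pd.Index(self.labels, name="treatment"),
                columns=["duration_days", "yield_t_hm2", "ci"],
            )
        return self.responses

    def merge(self, other: "TrialDataset") -> "TrialDataset":
        """Fold another dataset's tables into this one (labels must agree
        where both are present); returns self for chaining."""
        if not self.treatments:
            self.treatments = list(other.treatments)
        if other.phenology:
            self.phenology.update(other.phenology)
        if other.indicators is not None:
            self.indicators = other.indicators.copy()
        if other.indicator_sds is not None:
            self.indicator_sds = other.indicator_sds.copy()
        if other.responses is not None:
            resp = self.ensure_responses()
            for col in other.responses.columns:
                for lab, v in other.responses[col].items():
                    if pd.notna(v):
                        resp.loc[lab, col] = v
        return self


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str
    location: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def to_json_dict(self) -> dict:
        return {
            "ok": self.ok,
            "issues": [
                {"severity": i.severity, "message": i.message, "location": i.location}
                for i in self.issues
            ],
        }


# ---------------------------------------------------------------------------
# Phenology arithmetic
# ---------------------------------------------------------------------------


def stage_duration(start_date: _dt.date, end_date: _dt.date) -> int:
    """Inclusive day count between two stage dates.

    Both endpoints are counted, so a stage starting and ending on the same
    day lasts 1 day.  This is the unique convention under which the printed
    duration columns of the trial's growth-period table follow from its
    printed stage dates.
    """
    if end_date < start_date:
        raise ValueError(
            f"end date {end_date.isoformat()} precedes start date "
            f"{start_date.isoformat()}"
        )
    return (end_date - start_date).days + 1


def compute_phenology_durations(record: PhenologyRecord) -> tuple[int, int]:
    """(fruit development days, total growth days) for one treatment.

    Fruit development runs from fruit set to maturity; the total growth
    period from sowing to maturity; both are inclusive day counts.
    """
    for name in ("sowing_date", "fruit_set_date", "maturity_date"):
        if getattr(record, name, None) is None:
            raise ValueError(f"{record.treatment.label}: missing {name}")
    fruit = stage_duration(record.fruit_set_date, record.maturity_date)
    total = stage_duration(record.sowing_date, record.maturity_date)
    return fruit, total


# ---------------------------------------------------------------------------
# Cell parsing
# ---------------------------------------------------------------------------

_MEAN_SD_RE = re.compile(
    r"^\s*([-+]?\d+(?:\.\d+)?)\s*(?:±|\+/-|\+-)\s*(\d+(?:\.\d+)?)\s*[A-Za-z ]*\s*$"
)
_PLAIN_RE = re.compile(r"^\s*([-+]?\d+(?:\.\d+)?)\s*[A-Za-z ]*\s*$")


def parse_value_cell(cell: object) -> tuple[float, float | None]:
    """Parse a numeric table cell into (mean, sd).

    Accepts plain numbers and "mean ± sd" strings; trailing significance
    letters (a, ab, cd ...) are stripped.  sd is None when absent.
    """
    if isinstance(cell, (int, float)) and not isinstance(cell, bool):
        if isinstance(cell, float) and math.isnan(cell):
            raise ValueError("empty numeric cell")
        return float(cell), None
    text = str(cell)
    m = _MEAN_SD_RE.match(text)
    if m:
        return float(m.group(1)), float(m.group(2))
    m = _PLAIN_RE.match(text)
    if m:
        return float(m.group(1)), None
    raise ValueError(f"unparseable numeric cell {text!r}")


def parse_date_cell(cell: object) -> _dt.date:
    """Parse a date cell from ISO 8601 (YYYY-MM-DD) or the YYYY/M/D dialect."""
    if isinstance(cell, _dt.date):
        return cell
    text = str(cell).strip()
    for pattern in ("%Y-%m-%d", "%Y/%m/%d"):
        try:
            return _dt.datetime.strptime(text, pattern).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date cell {text!r}")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_TABLE_KINDS = ("design", "phenology", "indicators", "responses")

_DESIGN_COLUMNS = ("treatment", "spacing_cm", "pruning")
_PHENOLOGY_COLUMNS = ("treatment",) + _PHENOLOGY_STAGES
_RESPONSE_COLUMNS = ("treatment", "duration_days", "yield_t_hm2", "ci")


def _read_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.columns.size == 0 or (df.columns.size == 1 and df.empty):
        raise ValueError(f"{path}: empty table")
    df.columns = [c.strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    unknown = [c for c in df.columns if c not in expected]
    if missing or unknown:
        raise ValueError(
            f"{path}: schema mismatch; expected columns {list(expected)}, "
            f"missing {missing}, unknown {unknown}"
        )


def _parse_pruning(cell: str) -> int:
    text = str(cell).strip()
    if text in PRUNING_CODES:
        return PRUNING_CODES[text]
    try:
        code = int(text)
    except ValueError:
        raise ValueError(f"unparseable pruning cell {cell!r}") from None
    if code not in PRUNING_LABELS:
        raise ValueError(f"pruning code {code} not in 1..4")
    return code


def load_trial_table(path: str | Path, schema: str) -> TrialDataset:
    """Read one CSV table of the given kind into a :class:`TrialDataset`.

    ``schema`` is one of ``design``, ``phenology``, ``indicators``,
    ``responses``.  Dates are accepted in ISO 8601 and YYYY/M/D; numeric
    cells may carry "± sd" and significance letters.
    """
    if schema not in _TABLE_KINDS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {_TABLE_KINDS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_csv(path)
    ds = TrialDataset()

    if schema == "design":
        _require_columns(df, _DESIGN_COLUMNS, path)
        for idx, row in df.iterrows():
            try:
                ds.treatments.append(
                    TreatmentSpec(
                        label=str(row["treatment"]).strip(),
                        spacing_cm=int(float(row["spacing_cm"])),
                        pruning_code=_parse_pruning(row["pruning"]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} row {idx}: {exc}") from None
        return ds

    if schema == "phenology":
        _require_columns(df, _PHENOLOGY_COLUMNS, path)
        for idx, row in df.iterrows():
            label = str(row["treatment"]).strip()
            try:
                dates = {s: parse_date_cell(row[s]) for s in _PHENOLOGY_STAGES}
            except ValueError as exc:
                raise ValueError(f"{path} row {idx} ({label}): {exc}") from None
            spec = TreatmentSpec(label=label, spacing_cm=SPACING_MIN_CM, pruning_code=1)
            ds.treatments.append(spec)
            ds.phenology[label] = PhenologyRecord(treatment=spec, **dates)
        return ds

    if schema == "responses":
        _require_columns(df, _RESPONSE_COLUMNS, path)
        labels = [str(v).strip() for v in df["treatment"]]
        resp = pd.DataFrame(
            np.nan,
            index=pd.Index(labels, name="treatment"),
            columns=list(_RESPONSE_COLUMNS[1:]),
        )
        for idx, row in df.iterrows():
            for col in _RESPONSE_COLUMNS[1:]:
                cell = row[col]
                if pd.isna(cell) or str(cell).strip() == "":
                    continue
                try:
                    mean, _ = parse_value_cell(cell)
                except ValueError as exc:
                    raise ValueError(
                        f"{path} row {idx}, column {col}: {exc}"
                    ) from None
                resp.loc[labels[idx], col] = mean
        ds.treatments = [
            TreatmentSpec(label=l, spacing_cm=SPACING_MIN_CM, pruning_code=1)
            for l in labels
        ]
        ds.responses = resp
        return ds

    # indicators
    if "treatment" not in df.columns:
        raise ValueError(f"{path}: schema mismatch; missing 'treatment' column")
    labels = [str(v).strip() for v in df["treatment"]]
    value_cols = [c for c in df.columns if c != "treatment"]
    means = pd.DataFrame(
        index=pd.Index(labels, name="treatment"), columns=value_cols, dtype=float
    )
    sds = pd.DataFrame(
        index=pd.Index(labels, name="treatment"), columns=value_cols, dtype=float
    )
    any_sd = False
    for idx, row in df.iterrows():
        for col in value_cols:
            try:
                mean, sd = parse_value_cell(row[col])
            except ValueError as exc:
                raise ValueError(f"{path} row {idx}, column {col}: {exc}") from None
            means.loc[labels[idx], col] = mean
            if sd is not None:
                sds.loc[labels[idx], col] = sd
                any_sd = True
    ds.treatments = [
        TreatmentSpec(label=l, spacing_cm=SPACING_MIN_CM, pruning_code=1)
        for l in labels
    ]
    ds.indicators = means
    ds.indicator_sds = sds if any_sd else None
    return ds


def write_trial_table(ds: TrialDataset, path: str | Path, schema: str) -> None:
    """Write one table kind back to CSV (dates in ISO 8601; means only)."""
    if schema not in _TABLE_KINDS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {_TABLE_KINDS}")
    path = Path(path)
    if schema == "design":
        df = pd.DataFrame(
            {
                "treatment": [t.label for t in ds.treatments],
                "spacing_cm": [t.spacing_cm for t in ds.treatments],
                "pruning": [t.pruning_label for t in ds.treatments],
            }
        )
        df.to_csv(path, index=False)
    elif schema == "phenology":
        rows = []
        for label, rec in ds.phenology.items():
            row = {"treatment": label}
            row.update(
                {s: getattr(rec, s).isoformat() for s in _PHENOLOGY_STAGES}
            )
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    elif schema == "responses":
        resp = ds.ensure_responses()
        resp.reset_index().to_csv(path, index=False)
    else:
        if ds.indicators is None:
            raise ValueError("dataset has no indicator table")
        ds.indicators.reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_dataset(ds: TrialDataset) -> ValidationReport:
    """Check every dataset invariant; violations become issues, not raises."""
    issues: list[ValidationIssue] = []

    seen: set[str] = set()
    for t in ds.treatments:
        if t.label in seen:
            issues.append(
                ValidationIssue("error", f"duplicate label {t.label!r}", "treatments")
            )
        seen.add(t.label)
        for msg in t.check():
            issues.append(ValidationIssue("error", msg, f"treatment {t.label}"))

    for label, rec in ds.phenology.items():
        for msg in rec.check():
            issues.append(ValidationIssue("error", msg, f"phenology {label}"))

    if ds.indicators is not None:
        if ds.indicators.isna().any().any():
            issues.append(
                ValidationIssue("error", "missing indicator cells", "indicators")
            )

    if ds.responses is not None:
        r = ds.responses
        bad_yield = r.index[(r["yield_t_hm2"].notna()) & (r["yield_t_hm2"] <= 0)]
        for lab in bad_yield:
            issues.append(
                ValidationIssue("error", f"non-positive yield for {lab}", "responses")
            )
        bad_dur = r.index[(r["duration_days"].notna()) & (r["duration_days"] < 1)]
        for lab in bad_dur:
            issues.append(
                ValidationIssue("error", f"duration < 1 day for {lab}", "responses")
            )

    return ValidationReport(issues=tuple(issues))


# ---------------------------------------------------------------------------
# Built-in trial fixtures (2023 Tumushuke netted-melon experiment)
# ---------------------------------------------------------------------------

#: Treatment design: label -> (spacing cm, pruning label).
_DESIGN: dict[str, tuple[int, str]] = {
    "CK": (55, "1V1F"),
    "T1": (55, "2V2F"),
    "T2": (55, "3V3F"),
    "T3": (55, "3V2F"),
    "T4": (65, "2V2F"),
    "T5": (65, "3V3F"),
    "T6": (65, "3V2F"),
    "T7": (75, "2V2F"),
    "T8": (75, "3V3F"),
    "T9": (75, "3V2F"),
}

_SOWING = "2023-03-18"

#: label -> (emergence, vine elongation, female flower, fruit set,
#:            enlargement, maturity) in the trial year.
_PHENOLOGY: dict[str, tuple[str, ...]] = {
    "CK": ("2023/4/2", "2023/5/1", "2023/5/19", "2023/5/25", "2023/6/10", "2023/6/26"),
    "T1": ("2023/4/1", "2023/5/1", "2023/5/22", "2023/5/27", "2023/6/17", "2023/7/5"),
    "T2": ("2023/4/2", "2023/5/1", "2023/5/22", "2023/5/28", "2023/6/25", "2023/7/14"),
    "T3": ("2023/4/1", "2023/4/29", "2023/5/23", "2023/5/29", "2023/6/23", "2023/7/14"),
    "T4": ("2023/3/30", "2023/4/30", "2023/5/21", "2023/5/27", "2023/6/16", "2023/7/4"),
    "T5": ("2023/3/30", "2023/4/26", "2023/5/21", "2023/5/28", "2023/6/23", "2023/7/13"),
    "T6": ("2023/3/31", "2023/4/28", "2023/5/19", "2023/5/27", "2023/6/21", "2023/7/12"),
    "T7": ("2023/3/31", "2023/4/30", "2023/5/21", "2023/5/27", "2023/6/16", "2023/7/2"),
    "T8": ("2023/3/30", "2023/4/30", "2023/5/21", "2023/5/29", "2023/6/23", "2023/7/13"),
    "T9": ("2023/3/31", "2023/4/26", "2023/5/20", "2023/5/28", "2023/6/22", "2023/7/13"),
}

#: Printed duration columns (fruit development days, total growth days).
PRINTED_DURATIONS: dict[str, tuple[int, int]] = {
    "CK": (33, 101),
    "T1": (40, 110),
    "T2": (48, 119),
    "T3": (47, 119),
    "T4": (39, 109),
    "T5": (47, 118),
    "T6": (47, 117),
    "T7": (37, 107),
    "T8": (46, 118),
    "T9": (47, 118),
}

#: Nine quality-indicator means (±sd) per treatment, in INDICATOR_NAMES order.
_QUALITY: dict[str, tuple[tuple[float, float], ...]] = {
    "CK": ((2.51, 0.08), (1.45, 0.03), (89.14, 0.40), (2.63, 0.32), (37.49, 0.59),
           (14.13, 0.64), (1.02, 0.03), (13.43, 0.14), (3.15, 0.86)),
    "T1": ((2.37, 0.12), (1.41, 0.12), (88.78, 0.25), (2.17, 0.12), (34.39, 2.21),
           (13.50, 1.57), (0.97, 0.05), (12.58, 0.92), (2.54, 0.12)),
    "T2": ((1.99, 0.17), (1.39, 0.02), (87.65, 1.25), (2.43, 0.12), (39.25, 1.86),
           (13.10, 0.66), (0.95, 0.06), (12.48, 0.33), (2.41, 0.07)),
    "T3": ((2.79, 0.13), (1.45, 0.05), (89.39, 1.74), (2.50, 0.10), (37.35, 3.94),
           (12.73, 0.06), (0.98, 0.04), (12.97, 0.22), (2.71, 0.20)),
    "T4": ((2.51, 0.13), (1.34, 0.11), (87.87, 2.77), (2.80, 0.26), (40.28, 1.04),
           (14.03, 1.30), (1.04, 0.05), (13.52, 0.66), (3.65, 0.33)),
    "T5": ((2.13, 0.23), (1.35, 0.03), (84.50, 5.19), (2.37, 0.32), (34.67, 2.27),
           (12.87, 0.85), (1.03, 0.11), (13.47, 0.16), (3.54, 0.14)),
    "T6": ((2.39, 0.22), (1.34, 0.05), (87.98, 1.06), (2.50, 0.17), (41.46, 1.59),
           (13.27, 0.81), (1.14, 0.12), (13.65, 0.44), (3.69, 0.31)),
    "T7": ((2.32, 0.16), (1.27, 0.06), (88.53, 0.82), (2.73, 0.31), (37.26, 3.55),
           (14.73, 1.10), (1.25, 0.03), (14.39, 0.36), (4.45, 0.35)),
    "T8": ((2.21, 0.09), (1.30, 0.09), (88.37, 1.33), (2.87, 0.15), (40.17, 5.66),
           (14.30, 0.62), (1.21, 0.04), (14.36, 0.27), (4.43, 0.24)),
    "T9": ((2.29, 0.11), (1.28, 0.05), (89.11, 1.86), (2.60, 0.10), (35.16, 3.23),
           (14.83, 0.15), (1.32, 0.09), (14.61, 0.09), (4.49, 0.34)),
}

#: Published comprehensive-quality ranking table: label -> (Di+, Di-, Ci, rank).
PRINTED_TOPSIS: dict[str, tuple[float, float, float, int]] = {
    "CK": (0.214, 0.119, 0.357, 7),
    "T1": (0.310, 0.026, 0.077, 9),
    "T2": (0.331, 0.010, 0.029, 10),
    "T3": (0.283, 0.058, 0.170, 8),
    "T4": (0.137, 0.197, 0.589, 5),
    "T5": (0.157, 0.177, 0.530, 6),
    "T6": (0.129, 0.203, 0.611, 4),
    "T7": (0.023, 0.322, 0.933, 2),
    "T8": (0.029, 0.319, 0.916, 3),
    "T9": (0.023, 0.330, 0.935, 1),
}

#: Published quality ranking, best first.
PRINTED_QUALITY_RANKING: tuple[str, ...] = (
    "T9", "T7", "T8", "T6", "T4", "T5", "CK", "T3", "T1", "T2",
)

#: Published yield ranking, best first (values printed only for T3 and CK).
PRINTED_YIELD_RANKING: tuple[str, ...] = (
    "T3", "T2", "T1", "T6", "T4", "T5", "T9", "T7", "T8", "CK",
)

#: The only two yields printed in the main text, t per hm^2.
PRINTED_YIELDS: dict[str, float] = {"T3": 53.97, "CK": 27.86}

#: Headline optimized configuration reported from the surrogate search.
REPORTED_OPTIMUM: dict[str, object] = {
    "spacing_cm": 70,
    "pruning": "2V2F",
    "duration_days": 107,
    "yield_t_hm2": 48.68,
    "ci": 0.80,
}

FIXTURE_NAMES: tuple[str, ...] = (
    "design_table2",
    "phenology_table3",
    "quality_table4",
    "topsis_table5",
    "yields_text",
)


def _design_specs() -> list[TreatmentSpec]:
    return [
        TreatmentSpec(label=lab, spacing_cm=sp, pruning_code=PRUNING_CODES[pr])
        for lab, (sp, pr) in _DESIGN.items()
    ]


def builtin_fixture(name: str) -> TrialDataset:
    """Return one of the bundled trial tables as a :class:`TrialDataset`.

    Valid names: ``design_table2`` (treatment design), ``phenology_table3``
    (stage dates), ``quality_table4`` (nine indicator means ± sd),
    ``topsis_table5`` (published Di±/Ci/ranks, exposed via ``responses.ci``),
    ``yields_text`` (the two yields printed in the running text; the other
    eight are explicit missing values).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; valid: {FIXTURE_NAMES}")
    ds = TrialDataset(treatments=_design_specs())

    if name == "design_table2":
        return ds

    if name == "phenology_table3":
        sow = parse_date_cell(_SOWING)
        for t in ds.treatments:
            stages = [parse_date_cell(c) for c in _PHENOLOGY[t.label]]
            ds.phenology[t.label] = PhenologyRecord(
                treatment=t,
                sowing_date=sow,
                emergence_date=stages[0],
                vine_elongation_date=stages[1],
                female_flower_date=stages[2],
                fruit_set_date=stages[3],
                enlargement_date=stages[4],
                maturity_date=stages[5],
            )
        resp = ds.ensure_responses()
        for lab, (_, total) in PRINTED_DURATIONS.items():
            resp.loc[lab, "duration_days"] = total
        return ds

    if name == "quality_table4":
        labels = list(_QUALITY)
        means = pd.DataFrame(
            [[m for m, _ in _QUALITY[l]] for l in labels],
            index=pd.Index(labels, name="treatment"),
            columns=list(INDICATOR_NAMES),
        )
        sds = pd.DataFrame(
            [[s for _, s in _QUALITY[l]] for l in labels],
            index=pd.Index(labels, name="treatment"),
            columns=list(INDICATOR_NAMES),
        )
        ds.indicators = means
        ds.indicator_sds = sds
        return ds

    if name == "topsis_table5":
        resp = ds.ensure_responses()
        for lab, (_, _, ci, _) in PRINTED_TOPSIS.items():
            resp.loc[lab, "ci"] = ci
        return ds

    # yields_text
    resp = ds.ensure_responses()
    for lab, y in PRINTED_YIELDS.items():
        resp.loc[lab, "yield_t_hm2"] = y
    return ds
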