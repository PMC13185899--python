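"""Flock-week production records.

One record summarizes a breeder flock's nutrient intake and reproductive
output for one week of hen age.  This module defines the data model, CSV
input/output in two schemas (precomputed daily intakes, or dietary
composition from which intakes are recalculated), unit-standardized intake
recalculation, quality filtering against physiological bounds with an
optional per-phase Tukey fence, and stratification into the three
production phases used throughout the analysis.

Units: feed intake g/bird/day; ME concentration kcal/kg feed and ME intake
kcal/bird/day; amino acid concentrations g per 100 g feed, digestibility
coefficients in [0, 1], digestible amino acid intakes g/bird/day; response
is chicks produced per hen per week.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

#: Production phases: closed age intervals in weeks, disjoint and ordered.
PHASE_BOUNDS: dict[str, tuple[int, int]] = {
    "early": (26, 32),
    "mid": (33, 50),
    "late": (51, 62),
}
PHASE_ORDER: tuple[str, ...] = ("early", "mid", "late")

NUTRIENTS: tuple[str, ...] = ("me", "dlys", "dmet", "dthr")
NUTRIENT_UNITS: dict[str, str] = {
    "me": "kcal/d",
    "dlys": "g/d",
    "dmet": "g/d",
    "dthr": "g/d",
}

INTAKES_COLUMNS = [
    "flock_id",
    "age_weeks",
    "me_intake",
    "dlys_intake",
    "dmet_intake",
    "dthr_intake",
    "chicks_per_hen_week",
]
COMPOSITION_COLUMNS = [
    "flock_id",
    "age_weeks",
    "feed_intake",
    "me_conc",
    "lys_conc",
    "met_conc",
    "thr_conc",
    "dig_lys",
    "dig_met",
    "dig_thr",
    "chicks_per_hen_week",
]
_SCHEMAS = {"intakes": INTAKES_COLUMNS, "composition": COMPOSITION_COLUMNS}

_NONNEGATIVE_FIELDS = (
    "feed_intake",
    "me_conc",
    "lys_conc",
    "met_conc",
    "thr_conc",
    "me_intake",
    "dlys_intake",
    "dmet_intake",
    "dthr_intake",
    "chicks_per_hen_week",
)
_UNIT_INTERVAL_FIELDS = ("dig_lys", "dig_met", "dig_thr")


@dataclass
class FlockWeekRecord:
    """One flock-week observation."""

    flock_id: str
    age_weeks: int
    chicks_per_hen_week: float | None = None
    feed_intake: float | None = None
    me_conc: float | None = None
    lys_conc: float | None = None
    met_conc: float | None = None
    thr_conc: float | None = None
    dig_lys: float | None = None
    dig_met: float | None = None
    dig_thr: float | None = None
    me_intake: float | None = None
    dlys_intake: float | None = None
    dmet_intake: float | None = None
    dthr_intake: float | None = None
    quality_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.age_weeks < 0:
            raise ValidationError(f"age_weeks must be >= 0, got {self.age_weeks}")
        for name in _NONNEGATIVE_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        for name in _UNIT_INTERVAL_FIELDS:
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")

    def intake(self, nutrient: str) -> float | None:
        """Daily intake of one of ``me``, ``dlys``, ``dmet``, ``dthr``."""
        if nutrient not in NUTRIENTS:
            raise ValidationError(f"unknown nutrient {nutrient!r}")
        return getattr(self, f"{nutrient}_intake")


@dataclass(frozen=True)
class Phase:
    label: str
    age_lo: int
    age_hi: int


PHASES: tuple[Phase, ...] = tuple(
    Phase(lbl, *PHASE_BOUNDS[lbl]) for lbl in PHASE_ORDER
)


def assign_phase(age_weeks: int) -> str:
    """Map hen age in weeks to its production phase label.

    Raises ValidationError for ages outside the studied 26-62 week window.
    """
    for phase in PHASES:
        if phase.age_lo <= age_weeks <= phase.age_hi:
            return phase.label
    raise ValidationError(
        f"age {age_weeks} weeks outside the studied range [26, 62]"
    )


def _parse_cell(raw, column: str, row: int) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "" or text.lower() in ("na", "nan"):
        return None
    try:
        return float(text)
    except ValueError:
        raise SchemaError(
            f"non-numeric value {text!r} in column {column!r}, data row {row}"
        ) from None


def read_records(path, schema_mode: str = "intakes") -> list[FlockWeekRecord]:
    """Read flock-week records from CSV.

    ``schema_mode`` selects the expected header: ``intakes`` (precomputed
    daily nutrient intakes) or ``composition`` (feed intake plus dietary
    concentrations and digestibility coefficients).  Empty cells become
    missing values with a ``missing:<column>`` quality flag; a non-numeric
    cell raises rather than being silently coerced.
    """
    if schema_mode not in _SCHEMAS:
        raise ValidationError(f"unknown schema_mode {schema_mode!r}")
    expected = _SCHEMAS[schema_mode]
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except (OSError, pd.errors.ParserError) as exc:
        raise OSError(f"could not read {path}: {exc}") from exc
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise SchemaError(
            f"missing required column(s) {missing_cols} for mode {schema_mode!r}"
        )
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise SchemaError(f"unknown column(s) {unknown} for mode {schema_mode!r}")

    records: list[FlockWeekRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        flags: set[str] = set()
        age_raw = _parse_cell(row_d["age_weeks"], "age_weeks", i)
        if age_raw is None:
            raise SchemaError(f"empty age_weeks in data row {i}")
        kwargs: dict = {
            "flock_id": str(row_d["flock_id"]).strip(),
            "age_weeks": int(age_raw),
        }
        for col in expected:
            if col in ("flock_id", "age_weeks"):
                continue
            value = _parse_cell(row_d[col], col, i)
            if value is None:
                flags.add(f"missing:{col}")
            kwargs[col] = value
        records.append(FlockWeekRecord(**kwargs, quality_flags=flags))
    return records


def write_records(records, path, schema_mode: str = "intakes") -> None:
    """Write records to CSV in one of the documented schemas."""
    if schema_mode not in _SCHEMAS:
        raise ValidationError(f"unknown schema_mode {schema_mode!r}")
    cols = _SCHEMAS[schema_mode]
    rows = []
    for rec in records:
        rows.append({c: getattr(rec, c) for c in cols})
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def compute_intakes(record: FlockWeekRecord, overwrite: bool = False) -> FlockWeekRecord:
    """Recalculate daily nutrient intakes from dietary composition.

    Digestible amino acid intake = feed intake [g/d] x concentration
    [g/100 g feed] / 100 x digestibility coefficient; ME intake = feed
    intake [kg/d] x ME concentration [kcal/kg].  Precomputed intakes are
    preserved unless ``overwrite`` is set; a missing digestibility
    coefficient leaves the intake missing with a quality flag.
    """
    updates: dict = {}
    flags = set(record.quality_flags)
    feed = record.feed_intake
    if feed is None:
        flags.add("missing:feed_intake")
        return replace(record, quality_flags=flags)

    if record.me_intake is None or overwrite:
        if record.me_conc is not None:
            updates["me_intake"] = (feed / 1000.0) * record.me_conc
        else:
            flags.add("missing:me_conc")
    for aa in ("lys", "met", "thr"):
        target = f"d{aa}_intake"
        if getattr(record, target) is not None and not overwrite:
            continue
        conc = getattr(record, f"{aa}_conc")
        dig = getattr(record, f"dig_{aa}")
        if conc is None:
            flags.add(f"missing:{aa}_conc")
            continue
        if dig is None:
            flags.add(f"missing:dig_{aa}")
            continue
        updates[target] = feed * (conc / 100.0) * dig
    return replace(record, quality_flags=flags, **updates)


@dataclass
class RangeFilterConfig:
    """Physiological bounds and the optional per-phase Tukey (IQR) fence.

    ``bounds`` maps field names to closed ``(lower, upper)`` intervals; a
    record with a present value outside its interval is rejected with
    reason ``range:<field>``.  ``required_fields`` missing on a record
    reject it with ``missing:<field>``.  The IQR fence flags values beyond
    ``iqr_multiplier`` x IQR of the per-phase quartiles (linear-interpolated
    quartiles); it rejects only when ``iqr_reject`` is set.
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    required_fields: tuple[str, ...] = ("chicks_per_hen_week",)
    iqr_multiplier: float = 1.5
    iqr_variables: tuple[str, ...] = ()
    iqr_reject: bool = False

    def __post_init__(self) -> None:
        if self.iqr_multiplier <= 0:
            raise ValidationError("iqr_multiplier must be positive")
        for var, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValidationError(f"bounds for {var!r}: lower must be < upper")


#: Default physiological bounds (config-exposed, not asserted as study values).
DEFAULT_FILTER_CONFIG = RangeFilterConfig(
    bounds={
        "age_weeks": (26, 62),
        "feed_intake": (50.0, 250.0),
        "me_intake": (200.0, 700.0),
        "dlys_intake": (0.3, 2.0),
        "dmet_intake": (0.15, 1.2),
        "dthr_intake": (0.2, 1.6),
        "chicks_per_hen_week": (0.0, 7.0),
    },
)


@dataclass
class RejectedRecord:
    record: FlockWeekRecord
    reasons: list[str]


def _tukey_fence(values: np.ndarray, k: float) -> tuple[float, float]:
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def filter_records(
    records, config: RangeFilterConfig = DEFAULT_FILTER_CONFIG
) -> tuple[list[FlockWeekRecord], list[RejectedRecord]]:
    """Partition records into kept and rejected with machine-readable reasons.

    Never raises on data content.  Field values of kept records are
    unchanged; IQR outliers gain an ``iqr:<field>`` quality flag (and are
    rejected only if ``config.iqr_reject``).
    """
    reasons_by_idx: dict[int, list[str]] = {i: [] for i in range(len(records))}
    for i, rec in enumerate(records):
        for var, (lo, hi) in config.bounds.items():
            v = getattr(rec, var, None)
            if v is not None and not lo <= v <= hi:
                reasons_by_idx[i].append(f"range:{var}")
        for var in config.required_fields:
            if getattr(rec, var, None) is None:
                reasons_by_idx[i].append(f"missing:{var}")

    if config.iqr_variables:
        candidates = [i for i, r in reasons_by_idx.items() if not r]
        groups: dict[str, list[int]] = {}
        for i in candidates:
            age = records[i].age_weeks
            try:
                groups.setdefault(assign_phase(age), []).append(i)
            except ValidationError:
                continue
        for var in config.iqr_variables:
            for idxs in groups.values():
                vals = np.array(
                    [getattr(records[i], var) for i in idxs
                     if getattr(records[i], var) is not None]
                )
                if vals.size < 4:
                    continue
                lo, hi = _tukey_fence(vals, config.iqr_multiplier)
                for i in idxs:
                    v = getattr(records[i], var)
                    if v is not None and not lo <= v <= hi:
                        records[i].quality_flags.add(f"iqr:{var}")
                        if config.iqr_reject:
                            reasons_by_idx[i].append(f"iqr:{var}")

    kept, rejected = [], []
    for i, rec in enumerate(records):
        if reasons_by_idx[i]:
            rejected.append(RejectedRecord(rec, reasons_by_idx[i]))
        else:
            kept.append(rec)
    return kept, rejected


def rejection_frame(rejected, schema_mode: str = "intakes") -> pd.DataFrame:
    """Rejection report: original columns plus a ``reject_reason`` column."""
    cols = _SCHEMAS[schema_mode]
    rows = []
    for rr in rejected:
        row = {c: getattr(rr.record, c) for c in cols}
        row["reject_reason"] = ";".join(rr.reasons)
        rows.append(row)
    return pd.DataFrame(rows, columns=cols + ["reject_reason"])


def stratify_by_phase(records) -> dict[str, list[FlockWeekRecord]]:
    """Split records into the three production phases by hen age."""
    out: dict[str, list[FlockWeekRecord]] = {lbl: [] for lbl in PHASE_ORDER}
    for rec in records:
        out[assign_phase(rec.age_weeks)].append(rec)
    return out


def complete_cases(records, nutrient: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract (intake, response) arrays for records with both present."""
    xs, ys = [], []
    for rec in records:
        x = rec.intake(nutrient)
        y = rec.chicks_per_hen_week
        if x is not None and y is not None:
            xs.append(x)
            ys.append(y)
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)
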