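"""Core cohort data model: admission records, eligibility, strata, cleaning.

The unit of analysis is one NICU admission (:class:`NeonateRecord`).  All
modelling is stratified by gestation category; the four strata partition
[26, inf) weeks and are half-open on the right, so 32.0 weeks falls in the
32-34 stratum.  Cleaning follows a fixed protocol: forward filling of daily
nutrition orders, population-mean imputation of continuous covariates, and
exclusion of any covariate with more than 10% imputed entries.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
import warnings
from dataclasses import dataclass, field, fields as dc_fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from nicu_los.orders import DailyNutritionOrder, MedicationOrder

logger = logging.getLogger(__name__)

#: gestation stratum left edges in weeks; the last stratum is unbounded above
DEFAULT_BIN_EDGES: tuple[float, float, float, float] = (26.0, 32.0, 34.0, 37.0)

EXCLUSION_REASONS = frozenset(
    {
        "congenital_anomaly",
        "palliative",
        "discharge_on_request",
        "transfer",
        "death",
        "stay_le_24h",
        "no_nutrition_orders",
    }
)

DIAGNOSIS_FIELDS: tuple[str, ...] = (
    "rds",
    "severe_rds",
    "ttnb",
    "mas",
    "pneumothorax",
    "pphn",
    "sepsis",
    "nnh",
    "asphyxia",
)

BOOLEAN_FIELDS: tuple[str, ...] = (
    "multiple_pregnancy",
    "inborn",
    "maternal_disease",
    "antenatal_infection",
    "antenatal_risk_factor",
    "need_ppv",
    "apgar5_lt5",
) + DIAGNOSIS_FIELDS

CATEGORICAL_LEVELS: Mapping[str, tuple[str, ...]] = {
    "site": ("urban", "rural"),
    "sex": ("male", "female"),
    "delivery_mode": ("cesarean", "vaginal"),
    "antenatal_steroids": ("none", "incomplete", "complete"),
}

CONTINUOUS_FIELDS: tuple[str, ...] = ("gestation_weeks", "birth_weight_g")


class GestationCategory(str, Enum):
    """The four gestation strata used for all modelling."""

    G26_32 = "26-32"
    G32_34 = "32-34"
    G34_37 = "34-37"
    G37_plus = ">=37"

    @property
    def interval(self) -> tuple[float, float]:
        """Half-open [lo, hi) interval in weeks (hi = inf for the last)."""
        edges = DEFAULT_BIN_EDGES
        order = list(GestationCategory)
        i = order.index(self)
        lo = edges[i]
        hi = edges[i + 1] if i + 1 < len(edges) else math.inf
        return (lo, hi)


@dataclass
class NeonateRecord:
    """One NICU admission with antenatal/perinatal covariates and outcome.

    Continuous covariates may be NaN before imputation; categorical fields
    may be None (rendered as an explicit ``unknown`` level downstream).
    """

    patient_id: str
    site: str | None
    gestation_weeks: float
    birth_weight_g: float
    sex: str | None
    delivery_mode: str | None
    multiple_pregnancy: bool
    inborn: bool
    antenatal_steroids: str | None
    maternal_disease: bool
    antenatal_infection: bool
    antenatal_risk_factor: bool
    need_ppv: bool
    apgar5_lt5: bool
    admission_date: dt.date
    los_days: int
    rds: bool = False
    severe_rds: bool = False
    ttnb: bool = False
    mas: bool = False
    pneumothorax: bool = False
    pphn: bool = False
    sepsis: bool = False
    nnh: bool = False
    asphyxia: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        for name, levels in CATEGORICAL_LEVELS.items():
            value = getattr(self, name)
            if value is not None and value not in levels and value != "unknown":
                raise ValueError(f"{name} must be one of {levels}, got {value!r}")
        if not math.isnan(self.gestation_weeks) and not 22.0 <= self.gestation_weeks <= 45.0:
            raise ValueError(
                f"gestation_weeks must lie in [22, 45], got {self.gestation_weeks}"
            )
        if not math.isnan(self.birth_weight_g) and not 300.0 < self.birth_weight_g < 6000.0:
            raise ValueError(
                f"birth_weight_g must lie in (300, 6000), got {self.birth_weight_g}"
            )
        if self.exclusion_reason is not None and self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion_reason {self.exclusion_reason!r}")
        if self.exclusion_reason is None and self.los_days < 1:
            raise ValueError("included records must have los_days >= 1")


@dataclass
class Cohort:
    """Admission records plus their daily order streams and the time split."""

    records: list[NeonateRecord]
    nutrition_orders: list[DailyNutritionOrder] = field(default_factory=list)
    medication_orders: list[MedicationOrder] = field(default_factory=list)
    split_tag: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        ids = {r.patient_id for r in self.records}
        if len(ids) != len(self.records):
            raise ValueError("duplicate patient ids in cohort records")
        los = {r.patient_id: r.los_days for r in self.records}
        for order in list(self.nutrition_orders) + list(self.medication_orders):
            if order.patient_id not in ids:
                raise ValueError(f"order for unknown patient {order.patient_id!r}")
            if not 1 <= order.day_of_life <= los[order.patient_id]:
                raise ValueError(
                    f"order day {order.day_of_life} outside stay of "
                    f"patient {order.patient_id!r} (LOS {los[order.patient_id]})"
                )
        for pid, tag in self.split_tag.items():
            if tag not in {"train", "validate"}:
                raise ValueError(f"split tag for {pid!r} must be train/validate")

    def subset(self, tag: str) -> "Cohort":
        """Records (and their orders) carrying the given split tag."""
        keep = {pid for pid, t in self.split_tag.items() if t == tag}
        return Cohort(
            records=[r for r in self.records if r.patient_id in keep],
            nutrition_orders=[o for o in self.nutrition_orders if o.patient_id in keep],
            medication_orders=[o for o in self.medication_orders if o.patient_id in keep],
            split_tag={pid: t for pid, t in self.split_tag.items() if pid in keep},
        )


# ---------------------------------------------------------------------------
# stratification

def assign_gestation_category(
    gestation_weeks: float,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> GestationCategory:
    """Map a gestational age in weeks onto its stratum.

    Bins are left-closed right-open; 32.0 weeks belongs to the 32-34
    stratum.  Ages in [22, 26) fall below the first stratum and are folded
    into it with a warning; ages outside [22, 45] are rejected.
    """
    if math.isnan(gestation_weeks):
        raise ValueError("gestation_weeks is missing; impute before stratifying")
    if gestation_weeks < 22.0 or gestation_weeks > 45.0:
        raise ValueError(f"gestation_weeks {gestation_weeks} outside plausible [22, 45]")
    cats = list(GestationCategory)
    if gestation_weeks < bin_edges[0]:
        warnings.warn(
            f"gestation {gestation_weeks} weeks below the first stratum; "
            f"binning into {cats[0].value}",
            stacklevel=2,
        )
        return cats[0]
    for cat, lo, hi in zip(cats, bin_edges, list(bin_edges[1:]) + [math.inf]):
        if lo <= gestation_weeks < hi:
            return cat
    raise AssertionError("unreachable: strata partition [26, inf)")


# ---------------------------------------------------------------------------
# eligibility

def apply_eligibility(
    raw_records: Iterable[NeonateRecord],
    nutrition_orders: Iterable[DailyNutritionOrder] | None = None,
) -> tuple[list[NeonateRecord], list[tuple[str, str]]]:
    """Filter admissions to the analysable cohort.

    Retains records with a stay beyond 24 h (``los_days >= 1`` on the
    day-granular model), at least one nutrition order (when order streams
    are supplied), and no exclusion reason (congenital anomaly, palliative
    care, discharge on request, transfer, death).  Returns the retained
    records untouched plus a log of ``(patient_id, reason)`` exclusions.
    """
    raw = list(raw_records)
    seen: set[str] = set()
    for r in raw:
        if r.patient_id in seen:
            raise ValueError(f"duplicate patient_id {r.patient_id!r}")
        seen.add(r.patient_id)

    with_orders: set[str] | None = None
    if nutrition_orders is not None:
        with_orders = {o.patient_id for o in nutrition_orders}

    retained: list[NeonateRecord] = []
    excluded: list[tuple[str, str]] = []
    for r in raw:
        if r.exclusion_reason is not None:
            excluded.append((r.patient_id, r.exclusion_reason))
        elif r.los_days < 1:
            excluded.append((r.patient_id, "stay_le_24h"))
        elif with_orders is not None and r.patient_id not in with_orders:
            excluded.append((r.patient_id, "no_nutrition_orders"))
        else:
            retained.append(r)
    for pid, reason in excluded:
        logger.info("excluded patient %s: %s", pid, reason)
    return retained, excluded


# ---------------------------------------------------------------------------
# missing-data protocol

def forward_fill_orders(
    orders: Iterable[DailyNutritionOrder],
    los_days: int,
) -> tuple[list[DailyNutritionOrder], list[int]]:
    """Fill gaps in one patient's day-indexed nutrition orders.

    A day without an order inherits the most recent prior order (marked
    ``filled_forward``).  Days before the first recorded order cannot be
    filled; they are returned in the second element.  Idempotent.
    """
    by_day: dict[int, DailyNutritionOrder] = {}
    for o in orders:
        if o.day_of_life > los_days:
            raise ValueError(
                f"order on day {o.day_of_life} beyond stay of {los_days} days"
            )
        by_day[o.day_of_life] = o
    if not by_day:
        raise ValueError("no nutrition orders to fill; patient should be excluded")

    filled: list[DailyNutritionOrder] = []
    missing_leading: list[int] = []
    last: DailyNutritionOrder | None = None
    for day in range(1, los_days + 1):
        if day in by_day:
            last = by_day[day]
            filled.append(last)
        elif last is None:
            missing_leading.append(day)
        else:
            filled.append(replace(last, day_of_life=day, filled_forward=True))
    return filled, missing_leading


def impute_covariates(
    records: Sequence[NeonateRecord],
    continuous_fields: Sequence[str] = CONTINUOUS_FIELDS,
    threshold: float = 0.10,
) -> tuple[list[NeonateRecord], list[str]]:
    """Population-mean imputation of continuous covariates.

    Missing (NaN) entries of each continuous field are replaced by the mean
    over the non-missing entries.  A field whose imputed fraction exceeds
    ``threshold`` (or that is entirely missing) is returned in
    ``dropped_fields`` and must not enter downstream models.  Missing
    categorical covariates are never mean-imputed; they are recoded to an
    explicit ``unknown`` level.
    """
    records = list(records)
    n = len(records)
    dropped: list[str] = []
    updates: dict[int, dict[str, float]] = {}
    for fname in continuous_fields:
        values = np.array([getattr(r, fname) for r in records], dtype=float)
        missing = np.isnan(values)
        n_missing = int(missing.sum())
        if n_missing == 0:
            continue
        if n_missing == n:
            dropped.append(fname)
            logger.warning("field %s entirely missing; dropped, not imputed", fname)
            continue
        mean = float(values[~missing].mean())
        for i in np.flatnonzero(missing):
            updates.setdefault(int(i), {})[fname] = mean
        frac = n_missing / n
        logger.info("imputed %d/%d entries of %s with mean %.4g", n_missing, n, fname, mean)
        if frac > threshold:
            dropped.append(fname)
            logger.warning(
                "field %s has %.1f%% imputed entries (> %.0f%%); dropped from modelling",
                fname,
                100 * frac,
                100 * threshold,
            )
    out: list[NeonateRecord] = []
    for i, r in enumerate(records):
        changes: dict[str, object] = dict(updates.get(i, {}))
        for cname in CATEGORICAL_LEVELS:
            if getattr(r, cname) is None:
                changes[cname] = "unknown"
        out.append(replace(r, **changes) if changes else r)
    return out, dropped


# ---------------------------------------------------------------------------
# delimited-text interchange

_RECORD_COLUMNS = [f.name for f in dc_fields(NeonateRecord)]


def records_to_frame(records: Iterable[NeonateRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {name: getattr(r, name) for name in _RECORD_COLUMNS}
        row["admission_date"] = r.admission_date.isoformat()
        rows.append(row)
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def records_from_frame(frame: pd.DataFrame) -> list[NeonateRecord]:
    records = []
    for row in frame.to_dict(orient="records"):
        kwargs = dict(row)
        kwargs["admission_date"] = dt.date.fromisoformat(str(row["admission_date"]))
        for name in BOOLEAN_FIELDS:
            kwargs[name] = bool(row[name])
        for name in CATEGORICAL_LEVELS:
            value = row[name]
            kwargs[name] = None if pd.isna(value) else str(value)
        excl = row.get("exclusion_reason")
        kwargs["exclusion_reason"] = None if pd.isna(excl) else str(excl)
        kwargs["los_days"] = int(row["los_days"])
        kwargs["gestation_weeks"] = float(row["gestation_weeks"])
        kwargs["birth_weight_g"] = float(row["birth_weight_g"])
        records.append(NeonateRecord(**kwargs))
    return records


def write_cohort_tables(cohort: Cohort, out_dir: str | Path, missing_marker: str = "NA") -> None:
    """Write patients, nutrition and medication orders as CSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients = records_to_frame(cohort.records)
    patients["split_tag"] = [
        cohort.split_tag.get(r.patient_id, "train") for r in cohort.records
    ]
    patients.to_csv(out / "patients.csv", index=False, na_rep=missing_marker)
    pd.DataFrame(
        [vars(o) for o in cohort.nutrition_orders],
        columns=["patient_id", "day_of_life", "mode", "energy_kcal_per_kg", "protein_g_per_kg", "filled_forward"],
    ).to_csv(out / "nutrition_orders.csv", index=False, na_rep=missing_marker)
    pd.DataFrame(
        [vars(o) for o in cohort.medication_orders],
        columns=["patient_id", "day_of_life", "drug", "dose_per_kg", "frequency_per_day"],
    ).to_csv(out / "medication_orders.csv", index=False, na_rep=missing_marker)


def read_cohort_tables(in_dir: str | Path, missing_marker: str = "NA") -> Cohort:
    """Load a cohort previously written with :func:`write_cohort_tables`."""
    src = Path(in_dir)
    patients = pd.read_csv(
        src / "patients.csv", na_values=[missing_marker], keep_default_na=False,
        dtype={"patient_id": str}, float_precision="round_trip",
    )
    split = dict(zip(patients["patient_id"], patients.get("split_tag", "train")))
    records = records_from_frame(patients.drop(columns=["split_tag"], errors="ignore"))
    nut = pd.read_csv(src / "nutrition_orders.csv", na_values=[missing_marker], keep_default_na=False, dtype={"patient_id": str}, float_precision="round_trip")
    med = pd.read_csv(src / "medication_orders.csv", na_values=[missing_marker], keep_default_na=False, dtype={"patient_id": str}, float_precision="round_trip")
    nutrition = [
        DailyNutritionOrder(
            patient_id=str(r["patient_id"]),
            day_of_life=int(r["day_of_life"]),
            mode=str(r["mode"]),
            energy_kcal_per_kg=float(r["energy_kcal_per_kg"]),
            protein_g_per_kg=float(r["protein_g_per_kg"]),
            filled_forward=bool(r["filled_forward"]),
        )
        for r in nut.to_dict(orient="records")
    ]
    medication = [
        MedicationOrder(
            patient_id=str(r["patient_id"]),
            day_of_life=int(r["day_of_life"]),
            drug=str(r["drug"]),
            dose_per_kg=float(r["dose_per_kg"]),
            frequency_per_day=int(r["frequency_per_day"]),
        )
        for r in med.to_dict(orient="records")
    ]
    cohort = Cohort(records=records, nutrition_orders=nutrition, medication_orders=medication, split_tag=split)
    cohort.validate()
    return cohort
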