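"""Table-driven nutrition and medication reference engine.

Recommended nutrition values (per kg per day) are looked up by feeding
mode, nutrient, birth-weight class and day of life; medication orders are
classified against per-drug recommended dose-per-kg and daily frequency.
The shipped default tables are editable placeholders with plausible
neonatal ranges -- real deployments load their unit's own reference tables,
and nothing downstream depends on the default numbers, only on the lookup
and classification behaviour.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from nicu_los.orders import MedicationOrder

logger = logging.getLogger(__name__)

#: relative aberration at or above which an order deviates (inclusive)
DEFAULT_MEDICATION_THRESHOLD = 0.10

#: birth-weight boundary between the two nutrition weight classes; the
#: boundary itself belongs to the lighter class (inclusive <= 2500 g)
WEIGHT_CLASS_BOUNDARY_G = 2500.0

NUTRIENTS = ("energy_kcal_per_kg", "protein_g_per_kg")


class MedicationDeviation(str, Enum):
    NO_DEVIATION = "no_deviation"
    DOSE = "dose_deviation"
    FREQUENCY = "frequency_deviation"
    BOTH = "both_deviation"

    @property
    def has_dose_deviation(self) -> bool:
        return self in (MedicationDeviation.DOSE, MedicationDeviation.BOTH)

    @property
    def has_frequency_deviation(self) -> bool:
        return self in (MedicationDeviation.FREQUENCY, MedicationDeviation.BOTH)


@dataclass(frozen=True)
class NutritionGuideline:
    """One cell of the nutrition reference: a per-kg daily recommendation."""

    mode: str  # EN or PN
    nutrient: str
    weight_class: str  # le_2500g or gt_2500g
    day_lo: int
    day_hi: int | None  # inclusive; None = open-ended
    recommended: float

    def covers(self, day_of_life: int) -> bool:
        return self.day_lo <= day_of_life and (self.day_hi is None or day_of_life <= self.day_hi)


@dataclass(frozen=True)
class MedicationReference:
    """Recommended dose per kg and daily frequency for one drug."""

    drug: str
    dose_per_kg: float
    dose_unit: str
    frequency_per_day: int
    is_supplement: bool = False


@dataclass
class GuidelineSet:
    """A validated bundle of nutrition and medication reference tables."""

    nutrition: list[NutritionGuideline]
    medication: list[MedicationReference]
    version: str = "default-0"
    _med_index: Mapping[str, MedicationReference] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        med_index: dict[str, MedicationReference] = {}
        for ref in self.medication:
            if ref.drug in med_index:
                raise ValueError(f"duplicate medication reference for {ref.drug!r}")
            med_index[ref.drug] = ref
        object.__setattr__(self, "_med_index", med_index)
        # nutrition day bands must tile day 1..inf without overlap per cell
        cells: dict[tuple[str, str, str], list[NutritionGuideline]] = {}
        for g in self.nutrition:
            cells.setdefault((g.mode, g.nutrient, g.weight_class), []).append(g)
        for key, rows in cells.items():
            rows = sorted(rows, key=lambda g: g.day_lo)
            expected = 1
            for g in rows:
                if g.day_lo != expected:
                    raise ValueError(f"nutrition day bands for {key} have a gap/overlap at day {expected}")
                if g.day_hi is None:
                    expected = None
                    break
                expected = g.day_hi + 1
            if expected is not None:
                raise ValueError(f"nutrition day bands for {key} do not cover all days (end at {expected - 1})")

    def medication_reference(self, drug: str) -> MedicationReference:
        try:
            return self._med_index[drug]
        except KeyError:
            raise KeyError(f"drug {drug!r} absent from medication reference table") from None

    def is_supplement(self, drug: str) -> bool:
        ref = self._med_index.get(drug)
        return ref is not None and ref.is_supplement


def weight_class(weight_g: float) -> str:
    """Nutrition weight class; 2500 g itself belongs to ``le_2500g``."""
    if math.isnan(weight_g) or weight_g <= 0:
        raise ValueError(f"invalid weight {weight_g}")
    return "le_2500g" if weight_g <= WEIGHT_CLASS_BOUNDARY_G else "gt_2500g"


def recommend_nutrition(
    guidelines: GuidelineSet,
    weight_g: float,
    day_of_life: int,
    mode: str,
    nutrient: str,
) -> float:
    """Recommended per-kg daily intake for the given feeding scenario.

    For a combined EN+PN day the recommendation is the highest of the two
    single-mode recommendations, so a combined-mode order is scored against
    the most demanding target.
    """
    if day_of_life < 1:
        raise ValueError(f"day_of_life must be >= 1, got {day_of_life}")
    if nutrient not in NUTRIENTS:
        raise ValueError(f"unknown nutrient {nutrient!r}")
    if mode == "BOTH":
        return max(
            recommend_nutrition(guidelines, weight_g, day_of_life, "EN", nutrient),
            recommend_nutrition(guidelines, weight_g, day_of_life, "PN", nutrient),
        )
    if mode not in {"EN", "PN"}:
        raise ValueError(f"unknown feeding mode {mode!r}")
    wc = weight_class(weight_g)
    for g in guidelines.nutrition:
        if g.mode == mode and g.nutrient == nutrient and g.weight_class == wc and g.covers(day_of_life):
            return g.recommended
    raise LookupError(
        f"no nutrition guideline for mode={mode}, nutrient={nutrient}, "
        f"weight_class={wc}, day={day_of_life} (version {guidelines.version})"
    )


def _relative_deviation(prescribed: float, recommended: float) -> float:
    return abs(prescribed - recommended) / recommended


def classify_medication_order(
    guidelines: GuidelineSet,
    order: MedicationOrder,
    weight_g: float,
    threshold: float = DEFAULT_MEDICATION_THRESHOLD,
    unknown_drug_policy: str = "error",
) -> MedicationDeviation:
    """Classify one order against the drug reference.

    A relative aberration of at least ``threshold`` (default 10%,
    inclusive) in dose per kg flags a dose deviation; the same rule on
    administrations per day flags a frequency deviation; the two are
    independent.  Supplements (vitamins, iron) never deviate and are
    excluded from medication-required accounting upstream.
    """
    if guidelines.is_supplement(order.drug):
        return MedicationDeviation.NO_DEVIATION
    try:
        ref = guidelines.medication_reference(order.drug)
    except KeyError:
        if unknown_drug_policy == "skip":
            logger.warning("unknown drug %r; order skipped", order.drug)
            return MedicationDeviation.NO_DEVIATION
        raise
    # the tiny slack keeps an order constructed as exactly 110% or 90% of
    # the reference on the deviating side of the inclusive boundary
    eps = 1e-12
    dose_dev = _relative_deviation(order.dose_per_kg, ref.dose_per_kg) >= threshold - eps
    freq_dev = (
        _relative_deviation(order.frequency_per_day, ref.frequency_per_day) >= threshold - eps
    )
    if dose_dev and freq_dev:
        return MedicationDeviation.BOTH
    if dose_dev:
        return MedicationDeviation.DOSE
    if freq_dev:
        return MedicationDeviation.FREQUENCY
    return MedicationDeviation.NO_DEVIATION


# ---------------------------------------------------------------------------
# loading

def _load_nutrition_frame(frame: pd.DataFrame) -> list[NutritionGuideline]:
    rows = []
    for r in frame.to_dict(orient="records"):
        day_hi = r.get("day_hi")
        rows.append(
            NutritionGuideline(
                mode=str(r["mode"]),
                nutrient=str(r["nutrient"]),
                weight_class=str(r["weight_class"]),
                day_lo=int(r["day_lo"]),
                day_hi=None if pd.isna(day_hi) or day_hi == "" else int(day_hi),
                recommended=float(r["recommended"]),
            )
        )
    return rows


def _load_medication_frame(frame: pd.DataFrame) -> list[MedicationReference]:
    return [
        MedicationReference(
            drug=str(r["drug"]),
            dose_per_kg=float(r["dose_per_kg"]),
            dose_unit=str(r.get("dose_unit", "mg/kg/dose")),
            frequency_per_day=int(r["frequency_per_day"]),
            is_supplement=str(r.get("is_supplement", "false")).strip().lower() in {"true", "1", "yes"},
        )
        for r in frame.to_dict(orient="records")
    ]


def load_guidelines(
    nutrition_path: str | Path,
    medication_path: str | Path,
    version: str = "custom",
) -> GuidelineSet:
    """Load a guideline set from two delimited text tables."""
    nutrition = _load_nutrition_frame(pd.read_csv(nutrition_path))
    medication = _load_medication_frame(pd.read_csv(medication_path))
    return GuidelineSet(nutrition=nutrition, medication=medication, version=version)


def load_default_guidelines() -> GuidelineSet:
    """The placeholder reference tables shipped with the package."""
    data = resources.files("nicu_los") / "data"
    with resources.as_file(data / "nutrition_guidelines.csv") as p_nut, resources.as_file(
        data / "medication_references.csv"
    ) as p_med:
        return load_guidelines(p_nut, p_med, version="builtin-placeholder-1")
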