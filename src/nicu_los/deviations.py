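"""Per-patient guideline-deviation statistics and quartile risk coding.

The central statistic is the *deviation factor*: the Euclidean (L2) norm of
the daily order-minus-recommendation gaps, normalised over the length of
stay.  Within each gestation stratum, patients whose deviation factor falls
strictly above the 75th percentile form the top-quartile (Q4) risk group;
everyone else is "remaining".  Medication orders are summarised into a
three-level category (not required / no deviation / deviation) plus a count
of deviation days.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from nicu_los.cohort import (
    Cohort,
    GestationCategory,
    NeonateRecord,
    assign_gestation_category,
    forward_fill_orders,
)
from nicu_los.config import RunConfig
from nicu_los.guidelines import (
    NUTRIENTS,
    GuidelineSet,
    classify_medication_order,
    recommend_nutrition,
)
from nicu_los.orders import DailyNutritionOrder, MedicationOrder

logger = logging.getLogger(__name__)

__all__ = [
    "DailyNutritionOrder",
    "MedicationOrder",
    "DeviationSummary",
    "deviation_factor",
    "daily_nutrition_deviation",
    "quartile_code",
    "quartile_cutpoint",
    "deviation_cutpoints",
    "summarize_medication",
    "compute_deviation_summaries",
    "summaries_to_frame",
]


@dataclass
class DeviationSummary:
    """Deviation statistics for one patient, ready for risk coding."""

    patient_id: str
    category: GestationCategory
    daily_deviations: dict[str, np.ndarray] = field(default_factory=dict)
    deviation_factors: dict[str, float] = field(default_factory=dict)
    quartile_codes: dict[str, str] = field(default_factory=dict)
    medication_category: str = "not_required"
    medication_deviation_days: int = 0


def deviation_factor(
    recommended: Sequence[float],
    ordered: Sequence[float],
    normalization: str = "l2_over_n",
) -> float:
    """Condense daily recommendation-vs-order gaps into one non-negative number.

    With the default ``l2_over_n`` normalisation this is
    ``sqrt(sum_d (x_d - x'_d)^2) / n`` where ``x_d`` is the guideline
    recommendation and ``x'_d`` the prescribed order on day ``d`` of an
    ``n``-day stay: the L2 norm of the daily gaps averaged over the stay.
    ``l2_raw`` omits the division; ``mean_abs`` is the mean absolute gap.
    Over- and under-prescription count alike (gaps enter squared).
    """
    rec = np.asarray(recommended, dtype=float)
    orded = np.asarray(ordered, dtype=float)
    if rec.shape != orded.shape or rec.ndim != 1:
        raise ValueError(f"vectors must be 1-d and equal length, got {rec.shape} vs {orded.shape}")
    n = rec.size
    if n == 0:
        raise ValueError("deviation_factor needs at least one day")
    if not (np.isfinite(rec).all() and np.isfinite(orded).all()):
        raise ValueError("daily values must all be finite")
    gaps = rec - orded
    if normalization == "l2_over_n":
        return float(np.sqrt(np.sum(gaps**2)) / n)
    if normalization == "l2_raw":
        return float(np.sqrt(np.sum(gaps**2)))
    if normalization == "mean_abs":
        return float(np.mean(np.abs(gaps)))
    raise ValueError(f"unknown normalization {normalization!r}")


def daily_nutrition_deviation(
    order: DailyNutritionOrder,
    record: NeonateRecord,
    guidelines: GuidelineSet,
    nutrient: str,
) -> float:
    """Signed gap (recommended minus ordered, per kg per day) for one day.

    The recommendation follows the order's feeding scenario: EN or PN days
    use the matching table, combined days the highest of the two, and
    withheld-feeds days (recorded as PN-only) are scored against the PN
    table.  Birth weight stands in for daily weight throughout.
    """
    rec = recommend_nutrition(
        guidelines, record.birth_weight_g, order.day_of_life, order.mode, nutrient
    )
    return rec - getattr(order, nutrient)


def quartile_cutpoint(values: Sequence[float] | Mapping[str, float]) -> float:
    """Nearest-rank 75th percentile of a stratum's deviation factors."""
    vals = np.array(list(values.values()) if isinstance(values, Mapping) else list(values), dtype=float)
    n = vals.size
    if n < 8:
        raise ValueError(
            f"quartile coding needs at least 8 patients per stratum, got {n}; "
            "consider merging gestation categories"
        )
    return float(np.sort(vals)[math.ceil(0.75 * n) - 1])


def quartile_code(values: Mapping[str, float], cut: float | None = None) -> dict[str, str]:
    """Code patients into the top deviation quartile vs the remaining three.

    The cutpoint is the nearest-rank 75th percentile of the within-stratum
    deviation factors; only values strictly above it are coded ``Q4``, so
    ties at the cutpoint fall into ``remaining`` and Q4 is strictly the
    maximum-deviation group.  An explicit ``cut`` (e.g. learned on the
    training split) may be supplied to code a new, possibly small, batch
    of patients against an existing threshold.
    """
    if cut is None:
        cut = quartile_cutpoint(values)
    return {pid: ("Q4" if v > cut else "remaining") for pid, v in values.items()}


def summarize_medication(
    orders: Iterable[MedicationOrder],
    guidelines: GuidelineSet,
    weight_g: float,
    los_days: int,
    threshold: float = 0.10,
    unknown_drug_policy: str = "error",
) -> tuple[str, int]:
    """Collapse one patient's medication orders into (category, deviation days).

    Patients with no orders beyond supplements (vitamins, iron) are
    ``not_required``.  A deviation day is a distinct day of life with at
    least one dose-deviating order; frequency deviations are classified but
    do not count here, mirroring a dose-only downstream model.
    """
    non_supplement = 0
    deviation_days: set[int] = set()
    for order in orders:
        if order.day_of_life > los_days:
            raise ValueError(
                f"medication order on day {order.day_of_life} beyond stay of {los_days} days"
            )
        if guidelines.is_supplement(order.drug):
            continue
        non_supplement += 1
        cls = classify_medication_order(
            guidelines, order, weight_g, threshold=threshold, unknown_drug_policy=unknown_drug_policy
        )
        if cls.has_dose_deviation:
            deviation_days.add(order.day_of_life)
    if non_supplement == 0:
        return "not_required", 0
    n_days = len(deviation_days)
    return ("deviation" if n_days else "no_deviation"), n_days


def deviation_cutpoints(
    summaries: Mapping[str, "DeviationSummary"],
) -> dict[tuple[str, str], float]:
    """Per-(stratum, nutrient) top-quartile cutpoints of computed factors."""
    by_cell: dict[tuple[str, str], list[float]] = {}
    for s in summaries.values():
        for nutrient, value in s.deviation_factors.items():
            by_cell.setdefault((s.category.value, nutrient), []).append(value)
    return {cell: quartile_cutpoint(vals) for cell, vals in by_cell.items()}


def compute_deviation_summaries(
    cohort: Cohort,
    guidelines: GuidelineSet,
    config: RunConfig | None = None,
    quartile_cuts: Mapping[tuple[str, str], float] | None = None,
) -> dict[str, DeviationSummary]:
    """Run the full deviation pipeline over an eligible cohort.

    Per patient: forward-fill the daily nutrition orders, score each day's
    energy and protein orders against the guideline recommendation for the
    day's feeding scenario, condense the daily gaps into deviation factors,
    and summarise the medication orders.  Quartile codes are then assigned
    within each gestation stratum, either from this cohort's own 75th
    percentiles or against externally supplied ``quartile_cuts`` (keyed by
    ``(stratum value, nutrient)``, e.g. learned on the training split).
    """
    config = config or RunConfig()
    nutrition_by_patient: dict[str, list[DailyNutritionOrder]] = {}
    for o in cohort.nutrition_orders:
        nutrition_by_patient.setdefault(o.patient_id, []).append(o)
    medication_by_patient: dict[str, list[MedicationOrder]] = {}
    for o in cohort.medication_orders:
        medication_by_patient.setdefault(o.patient_id, []).append(o)

    summaries: dict[str, DeviationSummary] = {}
    for record in cohort.records:
        if record.exclusion_reason is not None:
            continue
        category = assign_gestation_category(
            record.gestation_weeks, config.gestation_bin_edges
        )
        summary = DeviationSummary(patient_id=record.patient_id, category=category)
        orders = nutrition_by_patient.get(record.patient_id, [])
        filled, missing = forward_fill_orders(orders, record.los_days)
        if missing:
            logger.info(
                "patient %s: days %s precede the first nutrition order and are not scored",
                record.patient_id,
                missing,
            )
        for nutrient in NUTRIENTS:
            gaps = np.array(
                [daily_nutrition_deviation(o, record, guidelines, nutrient) for o in filled]
            )
            recommended = gaps + np.array([getattr(o, nutrient) for o in filled])
            summary.daily_deviations[nutrient] = gaps
            summary.deviation_factors[nutrient] = deviation_factor(
                recommended,
                np.array([getattr(o, nutrient) for o in filled]),
                normalization=config.deviation_normalization,
            )
        summary.medication_category, summary.medication_deviation_days = summarize_medication(
            medication_by_patient.get(record.patient_id, []),
            guidelines,
            record.birth_weight_g,
            record.los_days,
            threshold=config.medication_threshold,
            unknown_drug_policy=config.unknown_drug_policy,
        )
        summaries[record.patient_id] = summary

    # quartile coding within each gestation stratum
    for nutrient in NUTRIENTS:
        by_category: dict[GestationCategory, dict[str, float]] = {}
        for s in summaries.values():
            by_category.setdefault(s.category, {})[s.patient_id] = s.deviation_factors[nutrient]
        for category, values in by_category.items():
            cut = None
            if quartile_cuts is not None:
                cut = quartile_cuts.get((category.value, nutrient))
            for pid, code in quartile_code(values, cut=cut).items():
                summaries[pid].quartile_codes[nutrient] = code
    return summaries


def summaries_to_frame(
    summaries: Mapping[str, DeviationSummary],
    guideline_version: str | None = None,
) -> pd.DataFrame:
    """One row per patient: factors, quartile codes, medication summary."""
    rows = []
    for pid in sorted(summaries):
        s = summaries[pid]
        row = {
            "patient_id": pid,
            "gestation_category": s.category.value,
            "energy_deviation_factor": s.deviation_factors.get("energy_kcal_per_kg"),
            "protein_deviation_factor": s.deviation_factors.get("protein_g_per_kg"),
            "energy_quartile": s.quartile_codes.get("energy_kcal_per_kg"),
            "protein_quartile": s.quartile_codes.get("protein_g_per_kg"),
            "medication_category": s.medication_category,
            "medication_deviation_days": s.medication_deviation_days,
        }
        if guideline_version is not None:
            row["guideline_version"] = guideline_version
        rows.append(row)
    return pd.DataFrame(rows)
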