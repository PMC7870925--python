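"""End-to-end orchestration: cohort -> deviations -> models -> payloads."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from nicu_los.cohort import Cohort, apply_eligibility, impute_covariates
from nicu_los.config import RunConfig
from nicu_los.deviations import (
    DeviationSummary,
    compute_deviation_summaries,
    deviation_cutpoints,
)
from nicu_los.guidelines import GuidelineSet, load_default_guidelines
from nicu_los.regression import (
    DayEffectTable,
    FittedLOSModel,
    build_design_table,
    compare_families,
    day_effects,
    select_significant,
    validate,
    validate_combinations,
)
from nicu_los.report import BedsidePayload, build_payload

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the fit/validate/report stages produce."""

    deviations_train: pd.DataFrame
    deviations_validate: pd.DataFrame
    family_rankings: dict[str, pd.DataFrame]
    models: dict[str, FittedLOSModel]
    day_tables: dict[str, DayEffectTable]
    validation_metrics: pd.DataFrame
    combination_gaps: pd.DataFrame
    payloads: list[BedsidePayload]
    dropped_fields: list[str] = field(default_factory=list)
    exclusions: list[tuple[str, str]] = field(default_factory=list)


def prepare_split(
    cohort: Cohort,
    guidelines: GuidelineSet,
    config: RunConfig,
    tag: str,
    quartile_cuts: dict[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, dict[str, DeviationSummary], list, list[str]]:
    """Eligibility, imputation and deviation scoring for one time split.

    ``quartile_cuts`` lets the validation split be coded against the
    training split's 75th-percentile thresholds.
    """
    sub = cohort.subset(tag)
    retained, exclusions = apply_eligibility(sub.records, sub.nutrition_orders)
    retained, dropped = impute_covariates(retained, threshold=config.imputation_threshold)
    eligible = Cohort(
        records=retained,
        nutrition_orders=[o for o in sub.nutrition_orders if o.patient_id in {r.patient_id for r in retained}],
        medication_orders=[o for o in sub.medication_orders if o.patient_id in {r.patient_id for r in retained}],
        split_tag={r.patient_id: tag for r in retained},
    )
    summaries = compute_deviation_summaries(eligible, guidelines, config, quartile_cuts=quartile_cuts)
    table = build_design_table(retained, summaries, dropped_fields=dropped)
    return table, summaries, retained, dropped


def run_pipeline(
    cohort: Cohort,
    guidelines: GuidelineSet | None = None,
    config: RunConfig | None = None,
    seed: int = 0,
    families: list[str] | None = None,
    payload_timestamp: str | None = None,
    min_compare_n: int = 20,
) -> PipelineResult:
    """Full analysis on a split cohort.

    Training-split patients drive family selection (repeated 80/20 splits,
    one iteration per patient), the p < 0.05 screen-and-refit, and the
    day-effect tables; validation-split patients are scored through the
    identical deviation pipeline and produce the per-stratum metrics, the
    seven-way factor-set gap grid, and one bedside payload each.  Strata
    too small to compare families fall back to the log family.
    """
    guidelines = guidelines or load_default_guidelines()
    config = config or RunConfig()

    train_table, train_summaries, _, dropped_tr = prepare_split(cohort, guidelines, config, "train")
    cuts = deviation_cutpoints(train_summaries)
    valid_table, valid_summaries, valid_records, _ = prepare_split(
        cohort, guidelines, config, "validate", quartile_cuts=cuts
    )
    _, excl = apply_eligibility(cohort.records, cohort.nutrition_orders)

    rankings: dict[str, pd.DataFrame] = {}
    models: dict[str, FittedLOSModel] = {}
    tables: dict[str, DayEffectTable] = {}
    for category in sorted(train_table["gestation_category"].unique()):
        sub = train_table[train_table["gestation_category"] == category]
        if len(sub) >= min_compare_n:
            ranking = compare_families(sub, families=families, seed=seed)
            rankings[category] = ranking
            best = str(ranking["family"].iloc[0])
        else:
            logger.warning(
                "stratum %s has %d patients; skipping family comparison, using log",
                category,
                len(sub),
            )
            best = "log"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = select_significant(sub, best, category=category)
        models[category] = model
        tables[category] = day_effects(model, grid_cap=config.grid_cap)

    metrics = validate(models, valid_table, unseen_level_policy="fallback")
    combos = validate_combinations(train_table, valid_table)

    summaries_by_pid = valid_summaries
    payloads: list[BedsidePayload] = []
    for record in sorted(valid_records, key=lambda r: r.patient_id):
        s = summaries_by_pid.get(record.patient_id)
        if s is None or s.category.value not in models:
            continue
        payloads.append(
            build_payload(
                record,
                s,
                models[s.category.value],
                day_table=tables[s.category.value],
                other_day_tables=tables,
                guideline_version=guidelines.version,
                timestamp=payload_timestamp,
            )
        )

    return PipelineResult(
        deviations_train=_deviation_frame(train_table, guidelines.version),
        deviations_validate=_deviation_frame(valid_table, guidelines.version),
        family_rankings=rankings,
        models=models,
        day_tables=tables,
        validation_metrics=metrics,
        combination_gaps=combos,
        payloads=payloads,
        dropped_fields=dropped_tr,
        exclusions=excl,
    )


def _deviation_frame(table: pd.DataFrame, version: str) -> pd.DataFrame:
    cols = [
        "patient_id",
        "gestation_category",
        "energy_quartile",
        "protein_quartile",
        "medication_category",
        "medication_deviation_days",
    ]
    out = table[cols].sort_values("patient_id").reset_index(drop=True).copy()
    out["guideline_version"] = version
    return out


def write_reports(result: PipelineResult, out_dir: str | Path) -> None:
    """Write machine-readable model reports as delimited/JSON text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.deviations_train.to_csv(out / "deviations_train.csv", index=False)
    result.deviations_validate.to_csv(out / "deviations_validate.csv", index=False)
    for category, ranking in result.family_rankings.items():
        ranking.to_csv(out / f"family_ranking_{category.replace('>=', 'ge')}.csv", index=False)
    effects = pd.concat(
        [t.effects.assign(gestation_category=c, median_los=t.median_los, iqr_los=t.iqr_los)
         for c, t in result.day_tables.items()],
        ignore_index=True,
    )
    effects.to_csv(out / "day_effects.csv", index=False)
    result.validation_metrics.to_csv(out / "validation_metrics.csv", index=False)
    result.combination_gaps.to_csv(out / "combination_gaps.csv", index=False)
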