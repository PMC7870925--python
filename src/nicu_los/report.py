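"""Bedside payload: predicted LOS with per-risk-factor day weights.

The deliverable of the pipeline is data, not a GUI: one JSON document per
patient carrying the predicted stay, the stratum's median/IQR, and every
modelled risk factor with its effect in days.  Factors belonging to the
patient's own gestation stratum are ``applicable``; factors of the other
strata are included greyed-out (``applicable: false``) so a display can
render the full four-stratum grid with the patient's stratum zoomed.  A
factor is ``highlighted`` when its level or effect changed relative to the
immediately previous payload -- the daily-update alert.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from nicu_los.cohort import NeonateRecord
from nicu_los.deviations import DeviationSummary
from nicu_los.regression import (
    DayEffectTable,
    FittedLOSModel,
    build_design_table,
    day_effects,
    predict_los,
)

__all__ = ["RiskFactorEntry", "BedsidePayload", "build_payload", "render_report", "payload_from_dict"]


@dataclass(frozen=True)
class RiskFactorEntry:
    name: str
    level: str
    effect_days: int
    category: str
    applicable: bool
    highlighted: bool = False


@dataclass
class BedsidePayload:
    patient_id: str
    gestation_category: str
    predicted_los_days: int
    median_los: float
    iqr_los: float
    risk_factors: list[RiskFactorEntry]
    guideline_version: str
    model_id: str
    generated_at: str

    def to_dict(self) -> dict:
        d = asdict(self)
        d["risk_factors"] = [asdict(rf) for rf in self.risk_factors]
        return d

    def validate(self) -> None:
        """Light structural check mirroring the shipped JSON schema."""
        if self.predicted_los_days < 1:
            raise ValueError("predicted_los_days must be >= 1")
        for rf in self.risk_factors:
            if rf.highlighted and not rf.applicable:
                raise ValueError(f"factor {rf.name!r} highlighted but not applicable")
            if rf.applicable and rf.category != self.gestation_category:
                raise ValueError(f"applicable factor {rf.name!r} from foreign stratum")


def payload_from_dict(d: Mapping) -> BedsidePayload:
    return BedsidePayload(
        patient_id=str(d["patient_id"]),
        gestation_category=str(d["gestation_category"]),
        predicted_los_days=int(d["predicted_los_days"]),
        median_los=float(d["median_los"]),
        iqr_los=float(d["iqr_los"]),
        risk_factors=[RiskFactorEntry(**rf) for rf in d["risk_factors"]],
        guideline_version=str(d["guideline_version"]),
        model_id=str(d["model_id"]),
        generated_at=str(d["generated_at"]),
    )


def build_payload(
    patient: NeonateRecord,
    deviations: DeviationSummary,
    model: FittedLOSModel,
    day_table: DayEffectTable | None = None,
    other_day_tables: Mapping[str, DayEffectTable] | None = None,
    previous_payload: BedsidePayload | None = None,
    guideline_version: str = "unknown",
    timestamp: str | None = None,
) -> BedsidePayload:
    """Assemble one patient's bedside payload.

    ``model`` must be fitted for the patient's gestation stratum; its
    day-effect table is computed on the fly unless supplied.  Tables for
    the other strata, when given, contribute the non-applicable (greyed)
    entries.  Highlights compare level and effect against
    ``previous_payload`` only; a first payload carries none.
    """
    if deviations.category.value != model.category:
        raise ValueError(
            f"patient stratum {deviations.category.value} does not match model "
            f"stratum {model.category}"
        )
    day_table = day_table or day_effects(model)
    design_row = build_design_table([patient], {patient.patient_id: deviations})
    predicted = int(round(float(predict_los(model, design_row)[0])))

    prev_by_name: dict[str, RiskFactorEntry] = {}
    if previous_payload is not None:
        prev_by_name = {rf.name: rf for rf in previous_payload.risk_factors if rf.applicable}

    entries: list[RiskFactorEntry] = []
    for t in model.design.terms:
        if t.kind != "categorical":
            continue
        level = design_row[t.name].iloc[0]
        effect = day_table.effect(t.name, level)
        prev = prev_by_name.get(t.name)
        highlighted = prev is not None and (prev.level != str(level) or prev.effect_days != effect)
        entries.append(
            RiskFactorEntry(
                name=t.name,
                level=str(level),
                effect_days=effect,
                category=model.category,
                applicable=True,
                highlighted=highlighted,
            )
        )
    for category, table in sorted((other_day_tables or {}).items()):
        if category == model.category:
            continue
        for _, row in table.effects.iterrows():
            entries.append(
                RiskFactorEntry(
                    name=str(row["factor"]),
                    level=str(row["level"]),
                    effect_days=int(row["effect_days"]),
                    category=category,
                    applicable=False,
                    highlighted=False,
                )
            )

    payload = BedsidePayload(
        patient_id=patient.patient_id,
        gestation_category=model.category,
        predicted_los_days=max(1, predicted),
        median_los=model.median_los,
        iqr_los=model.iqr_los,
        risk_factors=entries,
        guideline_version=guideline_version,
        model_id=f"{model.category}|{model.family.name}|n={model.n}",
        generated_at=timestamp or dt.datetime.now(dt.timezone.utc).isoformat(),
    )
    payload.validate()
    return payload


def _render_text(payloads: Iterable[BedsidePayload]) -> str:
    lines: list[str] = []
    for p in payloads:
        lines.append("=" * 64)
        lines.append(f"Patient {p.patient_id} — stratum {p.gestation_category}")
        lines.append(
            f"Predicted LOS: {p.predicted_los_days} d   "
            f"(stratum median {p.median_los:g} d, IQR {p.iqr_los:g})"
        )
        categories = sorted({rf.category for rf in p.risk_factors})
        if p.gestation_category not in categories:
            categories.append(p.gestation_category)
        for category in categories:
            marker = ">>" if category == p.gestation_category else "  "
            note = "" if category == p.gestation_category else "  (not applicable)"
            lines.append(f"{marker} [{category}]{note}")
            for rf in p.risk_factors:
                if rf.category != category:
                    continue
                flag = " *CHANGED*" if rf.highlighted else ""
                lines.append(
                    f"{marker}   {rf.name}={rf.level}: {rf.effect_days:+d} d{flag}"
                )
        lines.append(f"model: {p.model_id}  guidelines: {p.guideline_version}")
        lines.append(f"generated: {p.generated_at}")
    lines.append("=" * 64)
    return "\n".join(lines) + "\n"


def render_report(
    payloads: Iterable[BedsidePayload],
    format: str = "json",
    out_path: str | Path | None = None,
) -> str:
    """Serialise payloads to canonical JSON or a Fig-style text grid.

    JSON output is stable: keys sorted, fixed separators, trailing
    newline -- identical payloads serialise byte-identically.
    """
    payloads = list(payloads)
    if not payloads:
        raise ValueError("render_report needs at least one payload")
    for p in payloads:
        p.validate()
    if format == "json":
        content = json.dumps(
            [p.to_dict() for p in payloads], sort_keys=True, separators=(",", ":"), indent=1
        ) + "\n"
    elif format == "text":
        content = _render_text(payloads)
    else:
        raise ValueError(f"unknown format {format!r}")
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        Path(out_path).write_text(content)
    return content
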