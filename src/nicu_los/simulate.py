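"""Synthetic NICU cohort generator with known ground truth.

Emulates a two-site cohort of roughly a thousand neonates across the four
gestation strata, with the covariate mix, diagnosis prevalences, nutrition
order streams and medication patterns of a level-III NICU population.
Length of stay is drawn from a known multiplicative model,

    log(LOS) = baseline(category) + sum_k beta_k * x_k + Normal(0, sigma),

rounded up to at least one day, so every downstream stage (deviation
scoring, quartile coding, model-family selection, marginal-means effects)
has a recoverable right answer.  A config switch generates additive
day-scale LOS instead, giving family selection a case where the identity
family is correct.

Daily nutrition orders are built so that the deviation factor the analysis
pipeline computes for a patient equals that patient's drawn deviation
scale *exactly*: the daily gap pattern is rescaled so its L2-over-n norm
hits the target, and gap signs are flipped where needed to keep ordered
intakes non-negative (signs do not affect the squared gaps).  Top-quartile
membership is assigned with the same quartile coder the analyzer uses, so
generator and analyzer share the risk coding.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from nicu_los.cohort import (
    Cohort,
    GestationCategory,
    NeonateRecord,
    write_cohort_tables,
)
from nicu_los.deviations import quartile_code
from nicu_los.guidelines import GuidelineSet, load_default_guidelines, recommend_nutrition
from nicu_los.orders import DailyNutritionOrder, MedicationOrder

CATEGORIES = list(GestationCategory)

#: per-category (mean, sd) of gestational age in weeks and birth weight in g
GESTATION_MOMENTS = ((30.1, 1.5), (33.1, 0.6), (35.5, 0.8), (38.5, 1.0))
BIRTH_WEIGHT_MOMENTS = ((1425.0, 312.0), (1876.0, 348.0), (2236.0, 509.0), (2737.0, 537.0))
_GESTATION_CLIP = ((26.0, 31.95), (32.0, 33.95), (34.0, 36.95), (37.0, 42.0))

#: per-category prevalence of each generated covariate / diagnosis flag
PREVALENCES: Mapping[str, tuple[float, float, float, float]] = {
    "multiple_pregnancy": (0.529, 0.518, 0.221, 0.018),
    "antenatal_infection": (0.023, 0.005, 0.007, 0.009),
    "maternal_disease": (0.317, 0.370, 0.221, 0.062),
    "antenatal_risk_factor": (0.329, 0.218, 0.104, 0.029),
    "cesarean": (0.823, 0.886, 0.794, 0.579),
    "need_ppv": (0.070, 0.031, 0.019, 0.022),
    "apgar5_lt5": (0.011, 0.004, 0.003, 0.007),
    "male": (0.729, 0.602, 0.659, 0.725),
    "inborn": (0.788, 0.654, 0.640, 0.348),
    "steroids_received": (0.541, 0.548, 0.217, 0.018),
    "rds": (0.705, 0.445, 0.367, 0.293),
    "ttnb": (0.188, 0.104, 0.150, 0.102),
    "mas": (0.0, 0.0, 0.007, 0.026),
    "severe_rds": (0.188, 0.047, 0.109, 0.125),
    "pneumothorax": (0.023, 0.013, 0.026, 0.022),
    "pphn": (0.0, 0.0, 0.0, 0.006),
    "sepsis_base": (0.35, 0.05, 0.09, 0.10),
    "nnh": (0.600, 0.327, 0.330, 0.326),
    "asphyxia": (0.0, 0.0, 0.007, 0.073),
    "medication_received": (0.823, 0.322, 0.307, 0.403),
    "medication_deviation_given_received": (0.40, 0.235, 0.232, 0.309),
}

DRUG_PANEL = ("amikacin", "gentamicin", "ampicillin", "caffeine_citrate", "cefotaxime")
SUPPLEMENTS = ("vitamin_d", "iron")


@dataclass
class DeviationProfile:
    """Distribution of order-vs-guideline gaps for one gestation stratum.

    ``energy_scale_meanlog``/``sdlog`` parameterise the lognormal draw of
    each patient's target deviation factor (kcal/kg units for energy,
    g/kg for protein); a scale of ``-inf`` meanlog is never used -- set
    :meth:`zero` profiles for exact-adherence cohorts instead.
    """

    energy_scale_meanlog: float = math.log(6.0)
    energy_scale_sdlog: float = 0.6
    protein_scale_meanlog: float = math.log(0.4)
    protein_scale_sdlog: float = 0.6
    zero_day_prob: float = 0.15
    mode_probs: tuple[float, float, float] = (0.7, 0.1, 0.2)  # EN, PN, BOTH
    order_missing_prob: float = 0.0
    zero_gap: bool = False

    @classmethod
    def zero(cls) -> "DeviationProfile":
        """A profile whose orders match the guideline exactly every day."""
        return cls(zero_gap=True, zero_day_prob=0.0)


def _default_profiles() -> tuple[DeviationProfile, ...]:
    return (
        DeviationProfile(
            energy_scale_meanlog=math.log(12.0),
            protein_scale_meanlog=math.log(0.7),
            mode_probs=(0.3, 0.2, 0.5),
        ),
        DeviationProfile(energy_scale_meanlog=math.log(6.0), protein_scale_meanlog=math.log(0.4)),
        DeviationProfile(energy_scale_meanlog=math.log(5.0), protein_scale_meanlog=math.log(0.35)),
        DeviationProfile(energy_scale_meanlog=math.log(5.0), protein_scale_meanlog=math.log(0.30)),
    )


def _default_true_coefficients() -> dict[str, object]:
    # log-scale effects; per-category tuples follow the stratum order.
    # energy_q4 is calibrated so the top-quartile energy-deviation level
    # shifts predicted LOS by about +5 days in every stratum; explicit
    # zeros are designed null terms for type-I-error checks.
    return {
        "energy_q4": (0.24, 0.80, 1.05, 1.04),
        "protein_q4": 0.10,
        "sepsis": 0.35,
        "male": 0.08,
        "severe_rds": 0.30,
        "medication_deviation": 0.30,
        "cesarean": 0.0,
        "maternal_disease": 0.0,
        "ttnb": 0.0,
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the two-site population the pipeline is designed
    for: ~1,050 admissions over 16 months (12 train + 4 validate), the
    published stratum mix and covariate prevalences, and log-scale LOS
    noise of 0.3.
    """

    n_patients: int = 1047
    site_rural_fraction: float = 0.56
    months_train: int = 12
    months_validate: int = 4
    start_date: dt.date = dt.date(2018, 7, 1)
    category_mix: tuple[float, float, float, float] = (0.102, 0.252, 0.319, 0.327)
    baseline_log_los: tuple[float, float, float, float] = (2.78, 1.48, 1.00, 0.98)
    true_coefficients: dict[str, object] = field(default_factory=_default_true_coefficients)
    noise_sd_log: float = 0.3
    response_scale: str = "log"  # or "identity"
    noise_sd_days: float = 2.0
    deviation_profiles: tuple[DeviationProfile, ...] = field(default_factory=_default_profiles)
    diagnosis_prevalence: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(PREVALENCES)
    )
    sepsis_medication_boost: float = 0.15
    supplement_prob: float = 0.7
    frequency_deviation_prob: float = 0.05
    missingness_rates: Mapping[str, float] = field(default_factory=dict)
    exclusion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        if self.noise_sd_log <= 0:
            raise ValueError("noise_sd_log must be positive")
        if self.response_scale not in {"log", "identity"}:
            raise ValueError("response_scale must be 'log' or 'identity'")
        for name, p in self.diagnosis_prevalence.items():
            if any(not 0.0 <= v <= 1.0 for v in p):
                raise ValueError(f"prevalence for {name} outside [0, 1]")

    def coefficient(self, term: str, category: GestationCategory) -> float:
        value = self.true_coefficients.get(term, 0.0)
        if isinstance(value, (tuple, list)):
            return float(value[CATEGORIES.index(category)])
        return float(value)

    @classmethod
    def zero_deviation(cls, n_patients: int = 400, seed: int = 0, **kw) -> "SimulationConfig":
        """Exact-adherence cohort: no gaps, no medication deviations, null effects."""
        prev = dict(PREVALENCES)
        prev["medication_deviation_given_received"] = (0.0, 0.0, 0.0, 0.0)
        return cls(
            n_patients=n_patients,
            seed=seed,
            true_coefficients={},
            deviation_profiles=tuple(DeviationProfile.zero() for _ in range(4)),
            diagnosis_prevalence=prev,
            sepsis_medication_boost=0.0,
            **kw,
        )


@dataclass
class GroundTruth:
    """What the generator knows and the analysis is meant to recover."""

    baseline_log_los: dict[str, float]
    true_coefficients: dict[str, dict[str, float]]
    noise_sd_log: float
    response_scale: str
    per_patient: pd.DataFrame  # patient_id, category, mu, noiseless_los, flags

    def to_json(self, path: str | Path) -> None:
        payload = {
            "baseline_log_los": self.baseline_log_los,
            "true_coefficients": self.true_coefficients,
            "noise_sd_log": self.noise_sd_log,
            "response_scale": self.response_scale,
            "per_patient": self.per_patient.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------

def _bernoulli(rng: np.random.Generator, p: float) -> bool:
    return bool(rng.random() < p)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def simulate_orders(
    record: NeonateRecord,
    guidelines: GuidelineSet,
    profile: DeviationProfile,
    seed: int | np.random.Generator,
    energy_scale: float | None = None,
    protein_scale: float | None = None,
    medication_deviating: bool = False,
    medication_required: bool = False,
    give_supplements: bool = True,
    frequency_deviation_prob: float = 0.05,
) -> tuple[list[DailyNutritionOrder], list[MedicationOrder]]:
    """Generate one patient's daily nutrition and medication order streams.

    The nutrition gaps are scaled so the downstream deviation factor
    (L2-over-n) equals ``energy_scale`` / ``protein_scale`` exactly; when a
    scale is None it is drawn from the profile.  ``medication_required``
    patients receive 1-2 panel drugs; when ``medication_deviating`` at
    least one day carries a dose at >= 110% or <= 90% of the reference,
    otherwise every dose stays within +/-7%.  Everyone else gets vitamin D
    and iron supplements only ("medication not required").
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = record.los_days
    if profile.zero_gap:
        energy_scale = 0.0
        protein_scale = 0.0
    if energy_scale is None:
        energy_scale = float(rng.lognormal(profile.energy_scale_meanlog, profile.energy_scale_sdlog))
    if protein_scale is None:
        protein_scale = float(rng.lognormal(profile.protein_scale_meanlog, profile.protein_scale_sdlog))

    modes = rng.choice(["EN", "PN", "BOTH"], size=n, p=list(profile.mode_probs))
    rec = {
        nutrient: np.array(
            [
                recommend_nutrition(guidelines, record.birth_weight_g, d, modes[d - 1], nutrient)
                for d in range(1, n + 1)
            ]
        )
        for nutrient in ("energy_kcal_per_kg", "protein_g_per_kg")
    }

    ordered: dict[str, np.ndarray] = {}
    for nutrient, scale in (("energy_kcal_per_kg", energy_scale), ("protein_g_per_kg", protein_scale)):
        if scale == 0.0:
            ordered[nutrient] = rec[nutrient].copy()
            continue
        active = rng.random(n) >= profile.zero_day_prob
        if not active.any():
            active[int(rng.integers(n))] = True
        u = np.where(active, np.abs(rng.normal(size=n)) + 0.1, 0.0)
        u *= scale / (np.sqrt(np.sum(u**2)) / n)  # exact L2-over-n = scale
        sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        vals = rec[nutrient] - sign * u
        vals = np.where(vals < 0, rec[nutrient] + u, vals)  # flip keeps |gap|
        ordered[nutrient] = vals

    nutrition = [
        DailyNutritionOrder(
            patient_id=record.patient_id,
            day_of_life=d,
            mode=str(modes[d - 1]),
            energy_kcal_per_kg=float(ordered["energy_kcal_per_kg"][d - 1]),
            protein_g_per_kg=float(ordered["protein_g_per_kg"][d - 1]),
        )
        for d in range(1, n + 1)
    ]
    if profile.order_missing_prob > 0 and n > 1:
        nutrition = [
            o
            for o in nutrition
            if o.day_of_life == 1 or rng.random() >= profile.order_missing_prob
        ]

    medication: list[MedicationOrder] = []
    if medication_required:
        drugs = list(rng.choice(DRUG_PANEL, size=int(rng.integers(1, 3)), replace=False))
        for drug in drugs:
            if drug not in {r.drug for r in guidelines.medication}:
                raise KeyError(f"drug {drug!r} absent from guideline set")
        dev_days: set[int] = set()
        if medication_deviating:
            n_dev = int(rng.integers(1, max(2, n // 2) + 1))
            dev_days = set(rng.choice(np.arange(1, n + 1), size=min(n_dev, n), replace=False).tolist())
        for drug in drugs:
            ref = guidelines.medication_reference(drug)
            span = int(rng.integers(min(3, n), n + 1))
            for d in range(1, span + 1):
                if d in dev_days and drug == drugs[0]:
                    mult = float(rng.uniform(1.10, 1.35)) if rng.random() < 0.5 else float(rng.uniform(0.65, 0.90))
                else:
                    mult = float(rng.uniform(0.93, 1.07))
                freq = ref.frequency_per_day
                if rng.random() < frequency_deviation_prob:
                    freq += 1
                medication.append(
                    MedicationOrder(
                        patient_id=record.patient_id,
                        day_of_life=d,
                        drug=drug,
                        dose_per_kg=ref.dose_per_kg * mult,
                        frequency_per_day=freq,
                    )
                )
        if medication_deviating:
            # the deviating drug's span may not have covered every flagged
            # day; guarantee at least one deviating order exists
            covered = {o.day_of_life for o in medication if o.drug == drugs[0]}
            if not (dev_days & covered):
                ref = guidelines.medication_reference(drugs[0])
                medication.append(
                    MedicationOrder(
                        patient_id=record.patient_id,
                        day_of_life=min(dev_days),
                        drug=drugs[0],
                        dose_per_kg=ref.dose_per_kg * 1.2,
                        frequency_per_day=ref.frequency_per_day,
                    )
                )
    elif give_supplements:
        for drug in SUPPLEMENTS:
            ref = guidelines.medication_reference(drug)
            for d in range(1, n + 1):
                medication.append(
                    MedicationOrder(
                        patient_id=record.patient_id,
                        day_of_life=d,
                        drug=drug,
                        dose_per_kg=ref.dose_per_kg,
                        frequency_per_day=ref.frequency_per_day,
                    )
                )
    return nutrition, medication


def simulate_cohort(
    config: SimulationConfig,
    guidelines: GuidelineSet | None = None,
) -> tuple[Cohort, GroundTruth]:
    """Draw a full synthetic cohort plus its ground truth.

    Reproducible: the same config (including seed) yields an identical
    cohort.  Raises for cohorts too small to quartile-code.
    """
    if config.n_patients < 40:
        raise ValueError("n_patients must be >= 40 for stable quartile coding")
    guidelines = guidelines or load_default_guidelines()
    rng = np.random.default_rng(config.seed)
    prev = config.diagnosis_prevalence

    counts = rng.multinomial(config.n_patients, list(config.category_mix))
    total_days = round((config.months_train + config.months_validate) * 30.44)
    train_days = round(config.months_train * 30.44)

    records: list[NeonateRecord] = []
    split: dict[str, str] = {}
    meta: list[dict[str, object]] = []  # generator-private per-patient state
    pid_counter = 0

    for ci, category in enumerate(CATEGORIES):
        g_mean, g_sd = GESTATION_MOMENTS[ci]
        w_mean, w_sd = BIRTH_WEIGHT_MOMENTS[ci]
        g_lo, g_hi = _GESTATION_CLIP[ci]
        profile = config.deviation_profiles[ci]
        for _ in range(int(counts[ci])):
            pid_counter += 1
            pid = f"P{pid_counter:05d}"
            gestation = _truncated_normal(rng, g_mean, g_sd, g_lo, g_hi)
            weight = _truncated_normal(rng, w_mean, w_sd, 500.0, 5500.0)
            flags = {
                name: _bernoulli(rng, prev[name][ci])
                for name in (
                    "multiple_pregnancy",
                    "antenatal_infection",
                    "maternal_disease",
                    "antenatal_risk_factor",
                    "cesarean",
                    "need_ppv",
                    "apgar5_lt5",
                    "male",
                    "inborn",
                    "rds",
                    "ttnb",
                    "mas",
                    "pneumothorax",
                    "pphn",
                    "nnh",
                    "asphyxia",
                )
            }
            p_rds = prev["rds"][ci]
            severe = flags["rds"] and _bernoulli(rng, min(1.0, prev["severe_rds"][ci] / p_rds) if p_rds else 0.0)
            if _bernoulli(rng, prev["steroids_received"][ci]):
                steroids = "complete" if rng.random() < 0.6 else "incomplete"
            else:
                steroids = "none"
            med_received = _bernoulli(rng, prev["medication_received"][ci])
            med_deviating = med_received and _bernoulli(
                rng, prev["medication_deviation_given_received"][ci]
            )
            sepsis = _bernoulli(
                rng,
                min(1.0, prev["sepsis_base"][ci] + (config.sepsis_medication_boost if med_deviating else 0.0)),
            )
            if profile.zero_gap:
                e_scale = p_scale = 0.0
            else:
                e_scale = float(rng.lognormal(profile.energy_scale_meanlog, profile.energy_scale_sdlog))
                p_scale = float(rng.lognormal(profile.protein_scale_meanlog, profile.protein_scale_sdlog))
            offset = int(rng.integers(0, total_days))
            meta.append(
                {
                    "patient_id": pid,
                    "category": category,
                    "gestation": gestation,
                    "weight": weight,
                    "flags": flags,
                    "severe_rds": severe,
                    "steroids": steroids,
                    "sepsis": sepsis,
                    "med_received": med_received,
                    "med_deviating": med_deviating,
                    "energy_scale": e_scale,
                    "protein_scale": p_scale,
                    "offset": offset,
                    "noise": float(rng.normal()),
                }
            )

    # quartile flags on the drawn deviation scales, shared with the analyzer
    truth_q4: dict[str, dict[str, bool]] = {"energy_q4": {}, "protein_q4": {}}
    for category in CATEGORIES:
        in_cat = [m for m in meta if m["category"] is category]
        if len(in_cat) >= 8:
            for term, key in (("energy_q4", "energy_scale"), ("protein_q4", "protein_scale")):
                codes = quartile_code({m["patient_id"]: m[key] for m in in_cat})
                for pid, code in codes.items():
                    truth_q4[term][pid] = code == "Q4"
        else:
            for term in truth_q4:
                for m in in_cat:
                    truth_q4[term][m["patient_id"]] = False

    truth_rows: list[dict[str, object]] = []
    nutrition_all: list[DailyNutritionOrder] = []
    medication_all: list[MedicationOrder] = []

    for m in meta:
        category: GestationCategory = m["category"]  # type: ignore[assignment]
        ci = CATEGORIES.index(category)
        pid = str(m["patient_id"])
        x = {
            "energy_q4": truth_q4["energy_q4"][pid],
            "protein_q4": truth_q4["protein_q4"][pid],
            "sepsis": m["sepsis"],
            "male": m["flags"]["male"],
            "severe_rds": m["severe_rds"],
            "medication_deviation": m["med_deviating"],
            "cesarean": m["flags"]["cesarean"],
            "maternal_disease": m["flags"]["maternal_disease"],
            "ttnb": m["flags"]["ttnb"],
            "multiple_pregnancy": m["flags"]["multiple_pregnancy"],
            "nnh": m["flags"]["nnh"],
            "inborn": m["flags"]["inborn"],
        }
        effect = sum(config.coefficient(t, category) * float(x[t]) for t in config.true_coefficients)
        if config.response_scale == "log":
            mu = config.baseline_log_los[ci] + effect
            noiseless = math.exp(mu)
            los = max(1, math.ceil(math.exp(mu + config.noise_sd_log * m["noise"])))
        else:
            mu = math.exp(config.baseline_log_los[ci]) + effect
            noiseless = mu
            los = max(1, math.ceil(mu + config.noise_sd_days * m["noise"]))

        admission = config.start_date + dt.timedelta(days=int(m["offset"]))
        record = NeonateRecord(
            patient_id=pid,
            site="rural" if rng.random() < config.site_rural_fraction else "urban",
            gestation_weeks=float(m["gestation"]),
            birth_weight_g=float(m["weight"]),
            sex="male" if m["flags"]["male"] else "female",
            delivery_mode="cesarean" if m["flags"]["cesarean"] else "vaginal",
            multiple_pregnancy=m["flags"]["multiple_pregnancy"],
            inborn=m["flags"]["inborn"],
            antenatal_steroids=str(m["steroids"]),
            maternal_disease=m["flags"]["maternal_disease"],
            antenatal_infection=m["flags"]["antenatal_infection"],
            antenatal_risk_factor=m["flags"]["antenatal_risk_factor"],
            need_ppv=m["flags"]["need_ppv"],
            apgar5_lt5=m["flags"]["apgar5_lt5"],
            admission_date=admission,
            los_days=int(los),
            rds=m["flags"]["rds"],
            severe_rds=bool(m["severe_rds"]),
            ttnb=m["flags"]["ttnb"],
            mas=m["flags"]["mas"],
            pneumothorax=m["flags"]["pneumothorax"],
            pphn=m["flags"]["pphn"],
            sepsis=bool(m["sepsis"]),
            nnh=m["flags"]["nnh"],
            asphyxia=m["flags"]["asphyxia"],
        )
        nutrition, medication = simulate_orders(
            record,
            guidelines,
            config.deviation_profiles[ci],
            rng,
            energy_scale=float(m["energy_scale"]),
            protein_scale=float(m["protein_scale"]),
            medication_deviating=bool(m["med_deviating"]),
            medication_required=bool(m["med_received"]),
            give_supplements=rng.random() < config.supplement_prob,
            frequency_deviation_prob=config.frequency_deviation_prob,
        )
        # missingness injection (continuous covariates only)
        changes: dict[str, object] = {}
        for fname, rate in config.missingness_rates.items():
            if rate > 0 and rng.random() < rate:
                changes[fname] = float("nan")
        if changes:
            from dataclasses import replace

            record = replace(record, **changes)
        records.append(record)
        nutrition_all.extend(nutrition)
        medication_all.extend(medication)
        split[pid] = "train" if m["offset"] < train_days else "validate"
        truth_rows.append(
            {
                "patient_id": pid,
                "category": category.value,
                "mu": mu,
                "noiseless_los": noiseless,
                "los_days": int(los),
                "energy_scale": float(m["energy_scale"]),
                "protein_scale": float(m["protein_scale"]),
                **{k: bool(v) for k, v in x.items()},
            }
        )

    # optional ineligible admissions appended beyond n_patients
    n_excluded = round(config.exclusion_rate * config.n_patients)
    reasons = ("congenital_anomaly", "palliative", "discharge_on_request", "transfer", "death")
    for _ in range(n_excluded):
        pid_counter += 1
        pid = f"P{pid_counter:05d}"
        records.append(
            NeonateRecord(
                patient_id=pid,
                site="urban",
                gestation_weeks=float(rng.uniform(30, 40)),
                birth_weight_g=float(rng.uniform(1200, 3500)),
                sex="male" if rng.random() < 0.5 else "female",
                delivery_mode="cesarean",
                multiple_pregnancy=False,
                inborn=True,
                antenatal_steroids="none",
                maternal_disease=False,
                antenatal_infection=False,
                antenatal_risk_factor=False,
                need_ppv=False,
                apgar5_lt5=False,
                admission_date=config.start_date,
                los_days=1,
                exclusion_reason=str(rng.choice(reasons)),
            )
        )
        split[pid] = "train"

    cohort = Cohort(
        records=records,
        nutrition_orders=nutrition_all,
        medication_orders=medication_all,
        split_tag=split,
    )
    cohort.validate()
    truth = GroundTruth(
        baseline_log_los={c.value: config.baseline_log_los[i] for i, c in enumerate(CATEGORIES)},
        true_coefficients={
            term: {c.value: config.coefficient(term, c) for c in CATEGORIES}
            for term in config.true_coefficients
        },
        noise_sd_log=config.noise_sd_log,
        response_scale=config.response_scale,
        per_patient=pd.DataFrame(truth_rows),
    )
    return cohort, truth


def write_simulation(
    cohort: Cohort,
    truth: GroundTruth,
    out_dir: str | Path,
    missing_marker: str = "NA",
) -> None:
    """Write cohort tables plus the ground-truth file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_tables(cohort, out, missing_marker=missing_marker)
    truth.to_json(out / "ground_truth.json")
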