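"""Daily order records shared by the cohort model and the deviation pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class DailyNutritionOrder:
    """One day's prescribed nutrition for one patient.

    Values are per kilogram of body weight per day.  ``mode`` is the feeding
    scenario for the day: enteral only (``EN``), parenteral only (``PN``) or
    both (``BOTH``).  ``filled_forward`` marks orders that were copied from
    the most recent prior day to fill a documentation gap.
    """

    patient_id: str
    day_of_life: int
    mode: str
    energy_kcal_per_kg: float
    protein_g_per_kg: float
    filled_forward: bool = False

    def __post_init__(self) -> None:
        if self.day_of_life < 1:
            raise ValueError(f"day_of_life must be >= 1, got {self.day_of_life}")
        if self.mode not in {"EN", "PN", "BOTH"}:
            raise ValueError(f"unknown feeding mode {self.mode!r}")
        for name in ("energy_kcal_per_kg", "protein_g_per_kg"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")


@dataclass(frozen=True)
class MedicationOrder:
    """One day's prescription of one drug: dose per kg and daily frequency."""

    patient_id: str
    day_of_life: int
    drug: str
    dose_per_kg: float
    frequency_per_day: int

    def __post_init__(self) -> None:
        if self.day_of_life < 1:
            raise ValueError(f"day_of_life must be >= 1, got {self.day_of_life}")
        if not math.isfinite(self.dose_per_kg) or self.dose_per_kg <= 0:
            raise ValueError(f"dose_per_kg must be finite and > 0, got {self.dose_per_kg}")
        if self.frequency_per_day < 1:
            raise ValueError("frequency_per_day must be a positive integer")
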