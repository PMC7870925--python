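"""Run configuration shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Knobs that govern cleaning, deviation scoring and modelling.

    Parameters
    ----------
    missing_marker
        Token in delimited input tables that denotes a missing value
        (converted to NaN on read).
    imputation_threshold
        Maximum tolerated fraction of population-mean-imputed entries per
        continuous covariate; fields above it are dropped from modelling.
    gestation_bin_edges
        Left edges (weeks) of the four gestation strata; the last stratum
        is unbounded above.
    deviation_normalization
        How the per-patient deviation factor condenses daily gaps:
        ``l2_over_n`` (Euclidean norm of daily gaps divided by the number
        of days, the default), ``l2_raw`` (plain Euclidean norm) or
        ``mean_abs`` (mean absolute gap).
    medication_threshold
        Relative aberration in dose or frequency at or above which an
        order counts as a deviation (inclusive).
    unknown_drug_policy
        ``error`` raises on a drug absent from the reference table;
        ``skip`` warns and ignores the order.
    smearing
        Apply Duan's smearing factor when back-transforming predictions
        (off by default; effects are reported as plain day differences).
    grid_cap
        Maximum number of reference-grid rows allowed when computing
        ordinary marginal means.
    """

    missing_marker: str = "NA"
    imputation_threshold: float = 0.10
    gestation_bin_edges: tuple[float, float, float, float] = (26.0, 32.0, 34.0, 37.0)
    deviation_normalization: str = "l2_over_n"
    medication_threshold: float = 0.10
    unknown_drug_policy: str = "error"
    smearing: bool = False
    grid_cap: int = 100_000

    def __post_init__(self) -> None:
        if self.deviation_normalization not in {"l2_over_n", "l2_raw", "mean_abs"}:
            raise ValueError(
                f"unknown deviation normalization {self.deviation_normalization!r}"
            )
        if not 0.0 <= self.imputation_threshold <= 1.0:
            raise ValueError("imputation_threshold must lie in [0, 1]")
        if self.medication_threshold <= 0:
            raise ValueError("medication_threshold must be positive")
        if len(self.gestation_bin_edges) != 4:
            raise ValueError("gestation_bin_edges must have exactly four entries")
        if list(self.gestation_bin_edges) != sorted(self.gestation_bin_edges):
            raise ValueError("gestation_bin_edges must be increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "gestation_bin_edges" in raw:
            raw["gestation_bin_edges"] = tuple(raw["gestation_bin_edges"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["gestation_bin_edges"] = list(data["gestation_bin_edges"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
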