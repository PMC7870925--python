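"""Gestation-stratified LOS regression: family selection, screening, marginal means.

Within each gestation stratum the length of stay ``y`` (days) is modelled
as an ordinary least-squares fit on a transformed response ``z = g(y)``
over candidate families (identity, log, square-root, reciprocal).
Families are compared on repeated random 80/20 splits by information
criteria computed on the *original* day scale (the transformation's
Jacobian is folded into the log-likelihood so AICs are comparable across
families) plus out-of-split RMSE in days.  Risk-factor screening keeps
terms with Wald p < 0.05 and refits.  Per-level effects in days come from
ordinary marginal means (OMM): model predictions averaged over the
reference grid with *observed-frequency* weights on the other factors,
which suits unbalanced strata better than uniformly weighted marginal
means.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "ModelFamily",
    "TermSpec",
    "DesignInfo",
    "FittedLOSModel",
    "DayEffectTable",
    "DEFAULT_TERMS",
    "RISK_FACTOR_SETS",
    "build_design_table",
    "compare_families",
    "fit_model",
    "select_significant",
    "ordinary_marginal_means",
    "day_effects",
    "predict_los",
    "validate",
    "validate_combinations",
]


# ---------------------------------------------------------------------------
# model families

@dataclass(frozen=True)
class ModelFamily:
    """A monotone response transformation with its inverse and Jacobian.

    ``log_jacobian(y)`` returns ``log |dz/dy|`` so that log-likelihoods of
    fits on the transformed scale can be mapped back to the day scale and
    compared across families.
    """

    name: str
    transform: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]
    log_jacobian: Callable[[np.ndarray], np.ndarray]

    def back_transform(self, z: np.ndarray) -> np.ndarray:
        """Inverse transform with domain guards, clamped to >= 1 day."""
        z = np.asarray(z, dtype=float)
        if self.name == "log":
            y = np.exp(np.clip(z, -20.0, 20.0))
        elif self.name == "sqrt":
            y = np.clip(z, 0.0, None) ** 2
        elif self.name == "inverse":
            y = 1.0 / np.clip(z, 1e-6, None)
        else:
            y = z
        return np.maximum(y, 1.0)


FAMILIES: dict[str, ModelFamily] = {
    "identity": ModelFamily("identity", lambda y: y, lambda z: z, lambda y: np.zeros_like(y)),
    "log": ModelFamily("log", np.log, np.exp, lambda y: -np.log(y)),
    "sqrt": ModelFamily("sqrt", np.sqrt, lambda z: z**2, lambda y: -(math.log(2.0) + 0.5 * np.log(y))),
    "inverse": ModelFamily("inverse", lambda y: 1.0 / y, lambda z: 1.0 / z, lambda y: -2.0 * np.log(y)),
}


# ---------------------------------------------------------------------------
# design handling

#: canonical level orders (reference level first)
CANONICAL_LEVELS: Mapping[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "delivery_mode": ("vaginal", "cesarean"),
    "site": ("urban", "rural"),
    "antenatal_steroids": ("none", "incomplete", "complete"),
    "energy_quartile": ("remaining", "Q4"),
    "protein_quartile": ("remaining", "Q4"),
    "medication_category": ("not_required", "no_deviation", "deviation"),
}

DEFAULT_TERMS: tuple[str, ...] = (
    "sex",
    "delivery_mode",
    "multiple_pregnancy",
    "maternal_disease",
    "ttnb",
    "sepsis",
    "severe_rds",
    "nnh",
    "energy_quartile",
    "protein_quartile",
    "medication_category",
    "gestation_weeks",
)

RISK_FACTOR_SETS: Mapping[str, tuple[str, ...]] = {
    "antenatal_perinatal": (
        "sex",
        "delivery_mode",
        "multiple_pregnancy",
        "inborn",
        "maternal_disease",
        "antenatal_risk_factor",
        "gestation_weeks",
    ),
    "nutrition": ("energy_quartile", "protein_quartile"),
    "medication": ("medication_category",),
    "diagnoses": ("rds", "ttnb", "sepsis", "severe_rds", "nnh"),
}

#: the seven factor-set combinations used in the observed-vs-predicted grid
FACTOR_SET_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("antenatal_perinatal",),
    ("antenatal_perinatal", "diagnoses"),
    ("antenatal_perinatal", "nutrition"),
    ("antenatal_perinatal", "medication"),
    ("antenatal_perinatal", "nutrition", "diagnoses"),
    ("antenatal_perinatal", "medication", "diagnoses"),
    ("antenatal_perinatal", "nutrition", "medication", "diagnoses"),
)


@dataclass(frozen=True)
class TermSpec:
    name: str
    kind: str  # "categorical" or "continuous"
    levels: tuple | None = None  # reference level first
    mean: float | None = None

    @property
    def reference(self):
        return self.levels[0] if self.levels else None


@dataclass
class DesignInfo:
    """Frozen mapping from a data frame to a model design matrix."""

    terms: list[TermSpec]

    @classmethod
    def fit(
        cls, data: pd.DataFrame, term_names: Sequence[str]
    ) -> tuple["DesignInfo", list[str]]:
        """Infer term specs from fitting data; constant terms are dropped."""
        specs: list[TermSpec] = []
        dropped: list[str] = []
        for name in term_names:
            col = data[name]
            if col.dtype == bool or col.dtype == object or str(col.dtype) == "category":
                observed = list(pd.unique(col))
                if name in CANONICAL_LEVELS:
                    ordered = [lv for lv in CANONICAL_LEVELS[name] if lv in observed]
                    ordered += [lv for lv in observed if lv not in ordered]
                elif col.dtype == bool:
                    ordered = [lv for lv in (False, True) if lv in observed]
                else:
                    ordered = sorted(observed)
                if len(ordered) < 2:
                    dropped.append(name)
                    logger.info("term %s constant in stratum; dropped from model", name)
                    continue
                specs.append(TermSpec(name, "categorical", levels=tuple(ordered)))
            else:
                values = col.astype(float)
                if values.nunique() < 2:
                    dropped.append(name)
                    logger.info("term %s constant in stratum; dropped from model", name)
                    continue
                specs.append(TermSpec(name, "continuous", mean=float(values.mean())))
        return cls(terms=specs), dropped

    @property
    def column_names(self) -> list[str]:
        cols = ["Intercept"]
        for t in self.terms:
            if t.kind == "categorical":
                cols.extend(f"{t.name}[{lv}]" for lv in t.levels[1:])
            else:
                cols.append(t.name)
        return cols

    def term_columns(self, name: str) -> list[str]:
        for t in self.terms:
            if t.name == name:
                if t.kind == "categorical":
                    return [f"{t.name}[{lv}]" for lv in t.levels[1:]]
                return [t.name]
        raise KeyError(f"term {name!r} not in design")

    def build(self, data: pd.DataFrame, unseen_level_policy: str = "error") -> pd.DataFrame:
        """Design matrix (with intercept) for arbitrary rows."""
        n = len(data)
        X = pd.DataFrame({"Intercept": np.ones(n)}, index=data.index)
        for t in self.terms:
            if t.kind == "categorical":
                col = data[t.name]
                known = set(t.levels)
                unseen = [lv for lv in pd.unique(col) if lv not in known]
                if unseen:
                    if unseen_level_policy == "error":
                        raise ValueError(
                            f"unseen level(s) {unseen!r} for factor {t.name!r}; "
                            "refit or enable fallback to the reference level"
                        )
                    warnings.warn(
                        f"unseen level(s) {unseen!r} for factor {t.name!r} mapped to "
                        f"reference {t.reference!r}",
                        stacklevel=2,
                    )
                for lv in t.levels[1:]:
                    X[f"{t.name}[{lv}]"] = (col == lv).astype(float)
            else:
                X[t.name] = data[t.name].astype(float)
        return X


def build_design_table(
    records: Iterable,
    summaries: Mapping[str, object],
    dropped_fields: Sequence[str] = (),
) -> pd.DataFrame:
    """Merge admission covariates with deviation risk codes, one row per patient.

    ``summaries`` maps patient id to a
    :class:`~nicu_los.deviations.DeviationSummary`; records without a
    summary (e.g. excluded admissions) are skipped.  Covariates listed in
    ``dropped_fields`` (imputation overflow) are omitted.
    """
    rows = []
    for r in records:
        s = summaries.get(r.patient_id)
        if s is None:
            continue
        row = {
            "patient_id": r.patient_id,
            "gestation_category": s.category.value,
            "los_days": r.los_days,
            "sex": r.sex,
            "delivery_mode": r.delivery_mode,
            "site": r.site,
            "antenatal_steroids": r.antenatal_steroids,
            "multiple_pregnancy": r.multiple_pregnancy,
            "inborn": r.inborn,
            "maternal_disease": r.maternal_disease,
            "antenatal_infection": r.antenatal_infection,
            "antenatal_risk_factor": r.antenatal_risk_factor,
            "need_ppv": r.need_ppv,
            "apgar5_lt5": r.apgar5_lt5,
            "gestation_weeks": r.gestation_weeks,
            "birth_weight_g": r.birth_weight_g,
            "rds": r.rds,
            "severe_rds": r.severe_rds,
            "ttnb": r.ttnb,
            "mas": r.mas,
            "pneumothorax": r.pneumothorax,
            "pphn": r.pphn,
            "sepsis": r.sepsis,
            "nnh": r.nnh,
            "asphyxia": r.asphyxia,
            "energy_quartile": s.quartile_codes.get("energy_kcal_per_kg"),
            "protein_quartile": s.quartile_codes.get("protein_g_per_kg"),
            "medication_category": s.medication_category,
            "medication_deviation_days": s.medication_deviation_days,
        }
        for fname in dropped_fields:
            row.pop(fname, None)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model-family comparison

def _gaussian_loglik(rss: float, n: int) -> float:
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def compare_families(
    data: pd.DataFrame,
    families: Sequence[str] | None = None,
    n_iterations: int | None = None,
    seed: int | np.random.Generator = 0,
    terms: Sequence[str] = DEFAULT_TERMS,
) -> pd.DataFrame:
    """Rank response families for one stratum by repeated 80/20 splits.

    Each iteration redraws the split, fits every family by OLS on the 80%
    construction part, and records day-scale AIC/BIC, transformed-scale
    R-squared, and back-transformed RMSE in days on the held-out 20%.
    ``n_iterations`` defaults to the number of patients in the stratum.
    Returns a frame ranked by mean AIC, ties broken by mean test RMSE.
    """
    if len(data) < 20:
        raise ValueError(f"need >= 20 patients to compare families, got {len(data)}")
    families = list(families or FAMILIES)
    n_iterations = n_iterations or len(data)
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    data = data.sort_values("patient_id").reset_index(drop=True)  # row-order invariance
    design, _ = DesignInfo.fit(data, [t for t in terms if t in data.columns])
    X_full = design.build(data).to_numpy()
    y_full = data["los_days"].to_numpy(dtype=float)
    n, p = X_full.shape
    rank = np.linalg.matrix_rank(X_full)
    if rank < p:
        _, r = np.linalg.qr(X_full)
        aliased = [design.column_names[j] for j in range(p) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"singular design; aliased columns: {aliased}")

    n_test = max(1, round(0.2 * n))
    metrics: dict[str, dict[str, list[float]]] = {
        f: {"aic": [], "bic": [], "r2": [], "test_rmse": [], "train_rmse": []} for f in families
    }
    for _ in range(n_iterations):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        Xtr, ytr = X_full[train_idx], y_full[train_idx]
        Xte, yte = X_full[test_idx], y_full[test_idx]
        ntr = len(ytr)
        for fname in families:
            fam = FAMILIES[fname]
            z = fam.transform(ytr)
            beta, rss_arr, *_ = np.linalg.lstsq(Xtr, z, rcond=None)
            resid = z - Xtr @ beta
            rss = float(resid @ resid)
            k = Xtr.shape[1] + 1  # coefficients + error variance
            ll = _gaussian_loglik(max(rss, 1e-12), ntr) + float(np.sum(fam.log_jacobian(ytr)))
            tss = float(np.sum((z - z.mean()) ** 2))
            pred_te = fam.back_transform(Xte @ beta)
            pred_tr = fam.back_transform(Xtr @ beta)
            m = metrics[fname]
            m["aic"].append(2.0 * k - 2.0 * ll)
            m["bic"].append(k * math.log(ntr) - 2.0 * ll)
            m["r2"].append(1.0 - rss / tss if tss > 0 else float("nan"))
            m["test_rmse"].append(float(np.sqrt(np.mean((pred_te - yte) ** 2))))
            m["train_rmse"].append(float(np.sqrt(np.mean((pred_tr - ytr) ** 2))))

    rows = [
        {
            "family": fname,
            "mean_aic": float(np.mean(m["aic"])),
            "mean_bic": float(np.mean(m["bic"])),
            "mean_r2": float(np.mean(m["r2"])),
            "mean_test_rmse": float(np.mean(m["test_rmse"])),
            "mean_train_rmse": float(np.mean(m["train_rmse"])),
            "n_iterations": n_iterations,
        }
        for fname, m in metrics.items()
    ]
    ranking = pd.DataFrame(rows).sort_values(
        ["mean_aic", "mean_test_rmse"], kind="mergesort", ignore_index=True
    )
    return ranking


# ---------------------------------------------------------------------------
# fitted model

@dataclass
class FittedLOSModel:
    """One stratum's selected-and-refit LOS model plus everything OMM needs."""

    category: str
    family: ModelFamily
    design: DesignInfo
    results: object  # statsmodels RegressionResults of the refit
    terms: list[str]
    significant_terms: list[str]
    term_pvalues: dict[str, float]
    level_weights: dict[str, dict] = field(default_factory=dict)
    median_los: float = float("nan")
    iqr_los: float = float("nan")
    n: int = 0
    aic: float = float("nan")
    bic: float = float("nan")
    r_squared: float = float("nan")
    smearing_factor: float = 1.0

    @property
    def coefficients(self) -> pd.Series:
        return self.results.params

    def confidence_intervals(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.results.conf_int(alpha)


def _term_pvalue(results, design: DesignInfo, term: str) -> float:
    cols = design.term_columns(term)
    if len(cols) == 1:
        return float(results.pvalues[cols[0]])
    names = list(results.params.index)
    R = np.zeros((len(cols), len(names)))
    for i, c in enumerate(cols):
        R[i, names.index(c)] = 1.0
    return float(results.f_test(R).pvalue)


def _safe_rsquared(results) -> float:
    # a zero-variance response (degenerate stratum) yields NaN, not a warning
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(results.rsquared)


def _ols_fit(data: pd.DataFrame, family: ModelFamily, design: DesignInfo):
    X = design.build(data)
    z = family.transform(data["los_days"].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"singular design for columns {list(X.columns)}")
    return sm.OLS(z, X).fit()


def fit_model(
    data: pd.DataFrame,
    family: ModelFamily | str = "log",
    terms: Sequence[str] = DEFAULT_TERMS,
    alpha: float = 0.05,
    category: str | None = None,
) -> FittedLOSModel:
    """OLS fit of the transformed response on the given terms (no screening).

    Terms constant within the stratum are dropped with a log entry.
    ``significant_terms`` holds the subset with Wald p < ``alpha``; use
    :func:`select_significant` for the screen-and-refit procedure.
    """
    if isinstance(family, str):
        family = FAMILIES[family]
    category = category or (
        str(data["gestation_category"].iloc[0]) if "gestation_category" in data else "all"
    )
    usable = [t for t in terms if t in data.columns]
    design, _dropped = DesignInfo.fit(data, usable)
    # very small strata cannot support the full term list: shed terms from
    # the end of the list (deterministically) until the design is estimable
    while design.terms:
        X = design.build(data)
        if X.shape[0] > X.shape[1] and np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]:
            break
        dropped_term = design.terms[-1].name
        design = DesignInfo(terms=design.terms[:-1])
        logger.warning(
            "stratum %s: design inestimable with %d rows; dropping term %s",
            category,
            len(data),
            dropped_term,
        )
    results = _ols_fit(data, family, design)
    pvalues = {t.name: _term_pvalue(results, design, t.name) for t in design.terms}
    level_weights: dict[str, dict] = {}
    for t in design.terms:
        if t.kind == "categorical":
            freq = data[t.name].value_counts(normalize=True)
            level_weights[t.name] = {lv: float(freq.get(lv, 0.0)) for lv in t.levels}
    y = data["los_days"].to_numpy(dtype=float)
    resid_z = family.transform(y) - np.asarray(results.fittedvalues)
    smear = float(np.mean(np.exp(resid_z))) if family.name == "log" else 1.0
    return FittedLOSModel(
        category=category,
        family=family,
        design=design,
        results=results,
        terms=[t.name for t in design.terms],
        significant_terms=[name for name, p in pvalues.items() if p < alpha],
        term_pvalues=pvalues,
        level_weights=level_weights,
        median_los=float(np.median(y)),
        iqr_los=float(np.percentile(y, 75) - np.percentile(y, 25)),
        n=len(data),
        aic=float(results.aic),
        bic=float(results.bic),
        r_squared=_safe_rsquared(results),
        smearing_factor=smear,
    )


def select_significant(
    data: pd.DataFrame,
    family: ModelFamily | str = "log",
    terms: Sequence[str] = DEFAULT_TERMS,
    alpha: float = 0.05,
    category: str | None = None,
) -> FittedLOSModel:
    """Significance screen and refit for one stratum.

    Fits the full model on all stratum data, keeps terms whose Wald test
    (any coefficient for multi-level factors) has p < ``alpha``, and refits
    on the retained set.  With no significant term an intercept-only model
    is returned with a warning.  Wald p-values are taken from the OLS fit
    with no multiplicity correction; the full-fit p-values are carried on
    the returned model.
    """
    full = fit_model(data, family, terms, alpha=alpha, category=category)
    if not full.significant_terms:
        warnings.warn(
            f"no term significant at p < {alpha} in stratum {full.category}; "
            "returning intercept-only model",
            stacklevel=2,
        )
    refit = fit_model(data, full.family, full.significant_terms, alpha=alpha, category=full.category)
    refit.terms = full.terms
    refit.term_pvalues = full.term_pvalues
    return refit


# ---------------------------------------------------------------------------
# ordinary marginal means and day effects

def ordinary_marginal_means(
    model: FittedLOSModel,
    factor: str,
    grid_cap: int = 100_000,
) -> dict:
    """Frequency-weighted marginal means of one modelled factor.

    Builds the reference grid (all level combinations of the modelled
    categorical factors, continuous covariates pinned at their fitting
    means), predicts each grid row on the transformed scale, and averages
    the predictions for each level of ``factor`` weighting every *other*
    factor's levels by their observed frequency.  Returns
    ``{level: transformed-scale mean}``.
    """
    cat_terms = [t for t in model.design.terms if t.kind == "categorical"]
    if factor not in [t.name for t in cat_terms]:
        raise KeyError(f"factor {factor!r} is not a modelled categorical term")
    sizes = [len(t.levels) for t in cat_terms]
    if np.prod(sizes) > grid_cap:
        raise ValueError(
            f"reference grid would have {int(np.prod(sizes))} rows (> cap {grid_cap}); "
            "reduce the factor set"
        )
    grid_rows = []
    for combo in product(*(t.levels for t in cat_terms)):
        row = {t.name: lv for t, lv in zip(cat_terms, combo)}
        for t in model.design.terms:
            if t.kind == "continuous":
                row[t.name] = t.mean
        grid_rows.append(row)
    grid = pd.DataFrame(grid_rows)
    X = model.design.build(grid)
    z = X.to_numpy() @ model.coefficients.to_numpy()

    omm: dict = {}
    target = next(t for t in cat_terms if t.name == factor)
    for level in target.levels:
        mask = (grid[factor] == level).to_numpy()
        weights = np.ones(int(mask.sum()))
        sub = grid[mask].reset_index(drop=True)
        for t in cat_terms:
            if t.name == factor:
                continue
            w = model.level_weights.get(t.name, {lv: 1.0 / len(t.levels) for lv in t.levels})
            weights *= sub[t.name].map(w).to_numpy(dtype=float)
        total = weights.sum()
        if total <= 0:
            raise ValueError(f"zero total weight for level {level!r} of {factor!r}")
        omm[level] = float(np.sum(z[mask] * weights) / total)
    return omm


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class DayEffectTable:
    """Per-level effects in whole days for one stratum's significant factors."""

    category: str
    median_los: float
    iqr_los: float
    effects: pd.DataFrame  # factor, level, effect_days, p_value, omm

    def effect(self, factor: str, level) -> int:
        rows = self.effects[(self.effects["factor"] == factor) & (self.effects["level"].astype(str) == str(level))]
        if rows.empty:
            raise KeyError(f"no effect for {factor!r} level {level!r}")
        return int(rows["effect_days"].iloc[0])


def day_effects(model: FittedLOSModel, grid_cap: int = 100_000) -> DayEffectTable:
    """Express each significant factor level as whole days of LOS.

    A level's effect is the back-transformed OMM of that level minus the
    back-transformed frequency-weighted grand OMM of its factor, rounded
    half away from zero -- so levels pulling the stay above the stratum's
    weighted centre get positive days.
    """
    rows = []
    for t in model.design.terms:
        if t.kind != "categorical":
            continue
        omm = ordinary_marginal_means(model, t.name, grid_cap=grid_cap)
        weights = model.level_weights.get(t.name, {})
        grand = sum(weights.get(lv, 0.0) * omm[lv] for lv in t.levels)
        grand_days = float(model.family.back_transform(np.array([grand]))[0])
        p = model.term_pvalues.get(t.name, float("nan"))
        for lv in t.levels:
            level_days = float(model.family.back_transform(np.array([omm[lv]]))[0])
            rows.append(
                {
                    "factor": t.name,
                    "level": lv,
                    "effect_days": _round_half_away(level_days - grand_days),
                    "p_value": p,
                    "omm": omm[lv],
                }
            )
    frame = pd.DataFrame(rows, columns=["factor", "level", "effect_days", "p_value", "omm"])
    return DayEffectTable(
        category=model.category,
        median_los=model.median_los,
        iqr_los=model.iqr_los,
        effects=frame,
    )


# ---------------------------------------------------------------------------
# prediction and validation

def predict_los(
    model: FittedLOSModel,
    data: pd.DataFrame,
    unseen_level_policy: str = "error",
    smearing: bool = False,
) -> np.ndarray:
    """Predicted LOS in days (back-transformed, clamped to >= 1).

    ``smearing`` applies Duan's smearing factor (log family only); the
    default is plain inversion so effects read as simple day differences.
    """
    X = model.design.build(data, unseen_level_policy=unseen_level_policy)
    z = X.to_numpy() @ model.coefficients.to_numpy()
    y = model.family.back_transform(z)
    if smearing and model.family.name == "log":
        y = np.maximum(y * model.smearing_factor, 1.0)
    return y


def validate(
    models: Mapping[str, FittedLOSModel],
    validation_data: pd.DataFrame,
    unseen_level_policy: str = "error",
) -> pd.DataFrame:
    """Per-stratum RMSE (days), R-squared and mean/SD of predicted vs observed.

    Strata absent from the validation table (or lacking a model) yield NaN
    metrics rather than zeros.
    """
    rows = []
    for category, model in models.items():
        sub = validation_data[validation_data["gestation_category"] == category]
        if sub.empty:
            rows.append(
                {
                    "gestation_category": category,
                    "n": 0,
                    "rmse_days": float("nan"),
                    "r_squared": float("nan"),
                    "mean_observed": float("nan"),
                    "sd_observed": float("nan"),
                    "mean_predicted": float("nan"),
                    "sd_predicted": float("nan"),
                }
            )
            continue
        obs = sub["los_days"].to_numpy(dtype=float)
        pred = predict_los(model, sub, unseen_level_policy=unseen_level_policy)
        resid = obs - pred
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        rows.append(
            {
                "gestation_category": category,
                "n": len(sub),
                "rmse_days": float(np.sqrt(np.mean(resid**2))),
                "r_squared": 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan"),
                "mean_observed": float(obs.mean()),
                "sd_observed": float(obs.std(ddof=1)) if len(obs) > 1 else float("nan"),
                "mean_predicted": float(pred.mean()),
                "sd_predicted": float(pred.std(ddof=1)) if len(pred) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def validate_combinations(
    train_data: pd.DataFrame,
    validation_data: pd.DataFrame,
    family: ModelFamily | str = "log",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Observed-vs-predicted gap for the seven risk-factor-set combinations.

    For every combination of factor sets (antenatal/perinatal always
    included; nutrition, medication, diagnoses toggled) a model is screened
    and refit per stratum on the training table, and the absolute gap
    between mean observed and mean predicted LOS (days) is evaluated on the
    validation table.
    """
    rows = []
    categories = sorted(train_data["gestation_category"].unique())
    for combo in FACTOR_SET_COMBINATIONS:
        terms: list[str] = []
        for group in combo:
            terms.extend(RISK_FACTOR_SETS[group])
        row: dict[str, object] = {"risk_factor_sets": "+".join(combo)}
        for category in categories:
            tr = train_data[train_data["gestation_category"] == category]
            va = validation_data[validation_data["gestation_category"] == category]
            if tr.empty or va.empty:
                row[category] = float("nan")
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = select_significant(tr, family, terms=terms, alpha=alpha, category=category)
            pred = predict_los(model, va, unseen_level_policy="fallback")
            row[category] = abs(float(va["los_days"].mean()) - float(pred.mean()))
        rows.append(row)
    return pd.DataFrame(rows)
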