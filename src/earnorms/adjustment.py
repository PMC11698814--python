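"""Regression-based demographic adjustment of raw EAR scores.

Raw 0-60 indices are corrected for the demographic predictors that
significantly affect performance in the normative sample, following the
regression-equation approach standard in Italian neuropsychological
norming (Capitani-style).  The published models retain transformed age
(age squared) and sex for both indices:

    adjusted = raw + b * (age**2 - c) + s            (s added for men,
                                                      subtracted for women)

with b = 0.002, c = 1811.257 and s = 0.818 (ER) / 0.420 (EA).  Corrections
are *positive at older ages*: they compensate the age-related decline so
that older respondents are not penalised against the young.  The printed
correction-grid tables carry the opposite sign inside their footnote
equation; the grids themselves are internally consistent with the
decline-compensation convention, so the grids are treated as canonical.

Grid display uses two-stage decimal rounding - the age term is rounded to
3 decimals, the sum to 2 (ties away from zero) - which reproduces every
printable grid cell of the source tables exactly.  ``adjust_score`` itself
always works at full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AdjustmentModel",
    "AgeOutOfRangeError",
    "PUBLISHED_ER",
    "PUBLISHED_EA",
    "adjust_score",
    "correction_grid",
    "select_model",
    "model_to_json",
    "model_from_json",
    "grid_to_csv",
]

GRID_AGES = tuple(range(25, 90, 5))


class AgeOutOfRangeError(ValueError):
    """Age outside the model's validity range: norms not applicable."""


def round_half_away(value: float, decimals: int) -> float:
    """Decimal rounding with ties away from zero (the convention of the
    clinical-statistics software family the published grids come from)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AdjustmentModel:
    """Demographic correction model for one EAR index.

    Coefficients are on the *correction* scale: the adjustment term added
    to the raw score is ``beta_age2 * (age**2 - centering_c)`` plus
    ``sex_offset`` for men / minus ``sex_offset`` for women, plus any
    retained extra terms ``beta * (x - center)``.  A positive ``beta_age2``
    therefore compensates an age-related decline.
    """

    index_name: str
    beta_age2: float
    centering_c: float
    sex_offset: float
    retained_predictors: tuple[str, ...] = ("age2", "sex")
    #: optional extra correction terms: name -> (beta, centering constant)
    extra_terms: dict[str, tuple[float, float]] = field(default_factory=dict)
    validity_age_range: tuple[float, float] = (17, 88)
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.centering_c < 0:
            raise ValueError("centering_c must be >= 0")

    def age_term(self, age: float) -> float:
        return self.beta_age2 * (age**2 - self.centering_c)


#: Published ER-index model (correction-scale constants).
PUBLISHED_ER = AdjustmentModel(
    index_name="ER", beta_age2=0.002, centering_c=1811.257, sex_offset=0.818
)
#: Published EA-index model.
PUBLISHED_EA = AdjustmentModel(
    index_name="EA", beta_age2=0.002, centering_c=1811.257, sex_offset=0.420
)


def adjust_score(
    raw: float,
    age: float,
    sex: str,
    model: AdjustmentModel,
    education: float | None = None,
) -> float:
    """Demographically adjusted score, at full precision.

    Raises :class:`AgeOutOfRangeError` outside the model's validity range
    (17-88 years for the published models).
    """
    lo, hi = model.validity_age_range
    if not lo <= age <= hi:
        raise AgeOutOfRangeError(
            f"age {age} outside the validity range [{lo}, {hi}] of the "
            f"{model.index_name} norms"
        )
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    adjusted = raw + model.age_term(age)
    adjusted += model.sex_offset if sex == "M" else -model.sex_offset
    for name, (beta, center) in model.extra_terms.items():
        if name in ("education", "log_education"):
            if education is None:
                raise ValueError(
                    f"model retains {name!r}; education is required"
                )
            x = np.log(education) if name == "log_education" else education
            adjusted += beta * (x - center)
    return float(adjusted)


def correction_grid(
    model: AdjustmentModel,
    ages: Sequence[float] = GRID_AGES,
    decimals: int = 2,
) -> pd.DataFrame:
    """Adjustment terms by age and sex, rounded for display.

    The age term is rounded to ``decimals + 1`` places before the sex
    offset is added and the sum rounded to ``decimals`` - the two-stage
    decimal rounding that reproduces the published grids cell for cell.
    """
    if len(ages) == 0:
        raise ValueError("ages must be non-empty")
    q_term = Decimal(1).scaleb(-(decimals + 1))
    q_cell = Decimal(1).scaleb(-decimals)
    rows = {}
    for sex in ("M", "F"):
        offset = Decimal(repr(model.sex_offset))
        if sex == "F":
            offset = -offset
        vals = []
        for age in ages:
            # both stages in decimal arithmetic: float addition would nudge
            # exact ties like 0.395 off the rounding boundary
            term = Decimal(repr(float(model.age_term(age)))).quantize(
                q_term, rounding=ROUND_HALF_UP
            )
            cell = (term + offset).quantize(q_cell, rounding=ROUND_HALF_UP)
            vals.append(float(cell) + 0.0)  # normalise -0.0
        rows[sex] = vals
    return pd.DataFrame(rows, index=pd.Index(ages, name="age")).T


# --------------------------------------------------------------------------
# Model selection
# --------------------------------------------------------------------------

_AGE_TRANSFORMS = ("age", "age2", "log_age")
_EDU_TRANSFORMS = ("education", "log_education")


def _design_column(df: pd.DataFrame, name: str) -> np.ndarray:
    age = df["age"].to_numpy(dtype=float)
    edu = df["education"].to_numpy(dtype=float)
    if name == "age":
        return age
    if name == "age2":
        return age**2
    if name == "log_age":
        return np.log(age)
    if name == "education":
        return edu
    if name == "log_education":
        return np.log(edu)
    if name == "sex":
        return np.where(df["sex"].to_numpy() == "M", 0.5, -0.5)
    raise ValueError(f"unknown predictor {name!r}")


def _best_transform(
    df: pd.DataFrame, y: np.ndarray, candidates: Sequence[str]
) -> str:
    """Best-fitting single transform of a collinear family, by R**2 of the
    simple regression.  Age, age**2 and log(age) are near-collinear over
    17-88, so only one of them may enter the multiple model."""
    best, best_r2 = candidates[0], -np.inf
    for name in candidates:
        x = sm.add_constant(_design_column(df, name))
        r2 = sm.OLS(y, x).fit().rsquared
        if r2 > best_r2:
            best, best_r2 = name, r2
    return best


def select_model(
    cohort: pd.DataFrame,
    index_name: str,
    candidates: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> AdjustmentModel:
    """Fit and select the demographic adjustment model on a cohort.

    One transform per collinear predictor family (age family, education
    family) is pre-selected by fit; the multiple regression of the raw
    score on the selected transforms plus sex is fitted, predictors with
    p < ``alpha`` are retained, and the model is refitted on the retained
    set.  Returned coefficients are on the correction scale (negated fit
    coefficients), centred at the cohort means.
    """
    col = f"{index_name.lower()}_raw"
    if col not in cohort.columns:
        raise ValueError(f"cohort has no column {col!r}")
    if len(cohort) < 30:
        raise ValueError("cohort too small for model selection (need >= 30)")
    if cohort[col].isna().any():
        raise ValueError("missing raw scores in cohort")
    y = cohort[col].to_numpy(dtype=float)

    if candidates is None:
        candidates = (*_AGE_TRANSFORMS, *_EDU_TRANSFORMS, "sex")
    candidates = list(candidates)
    age_family = [c for c in candidates if c in _AGE_TRANSFORMS]
    edu_family = [c for c in candidates if c in _EDU_TRANSFORMS]
    chosen: list[str] = []
    if age_family:
        chosen.append(_best_transform(cohort, y, age_family))
    if edu_family:
        chosen.append(_best_transform(cohort, y, edu_family))
    if "sex" in candidates:
        chosen.append("sex")

    def _fit(names: list[str]):
        x = np.column_stack([_design_column(cohort, n) for n in names])
        return sm.OLS(y, sm.add_constant(x)).fit()

    fit = _fit(chosen)
    retained = [
        name for name, p in zip(chosen, fit.pvalues[1:]) if p < alpha
    ]
    diagnostics = {
        "candidates": chosen,
        "screen_pvalues": dict(zip(chosen, fit.pvalues[1:].tolist())),
        "n": int(len(cohort)),
    }
    if retained:
        fit = _fit(retained)
        diagnostics["r_squared"] = float(fit.rsquared)
        diagnostics["pvalues"] = dict(zip(retained, fit.pvalues[1:].tolist()))
    else:
        diagnostics["r_squared"] = 0.0

    beta_age2 = 0.0
    centering = float(np.mean(cohort["age"].to_numpy(dtype=float) ** 2))
    sex_offset = 0.0
    extra: dict[str, tuple[float, float]] = {}
    for name, coef in zip(retained, fit.params[1:]):
        if name in _AGE_TRANSFORMS:
            if name != "age2":
                # non-quadratic age transform retained: store it as an
                # extra term centred at its cohort mean
                center = float(np.mean(_design_column(cohort, name)))
                extra[name] = (-float(coef), center)
            else:
                beta_age2 = -float(coef)
        elif name == "sex":
            sex_offset = -float(coef) / 2.0
        else:
            center = float(np.mean(_design_column(cohort, name)))
            extra[name] = (-float(coef), center)

    age_lo = float(cohort["age"].min())
    age_hi = float(cohort["age"].max())
    return AdjustmentModel(
        index_name=index_name,
        beta_age2=beta_age2,
        centering_c=centering,
        sex_offset=sex_offset,
        retained_predictors=tuple(retained),
        extra_terms=extra,
        validity_age_range=(age_lo, age_hi),
        fit_diagnostics=diagnostics,
    )


# --------------------------------------------------------------------------
# Serialisation
# --------------------------------------------------------------------------


def model_to_json(model: AdjustmentModel, path: str | Path) -> None:
    payload = {
        "index_name": model.index_name,
        "beta_age2": model.beta_age2,
        "centering_c": model.centering_c,
        "sex_offset": model.sex_offset,
        "retained_predictors": list(model.retained_predictors),
        "extra_terms": {k: list(v) for k, v in model.extra_terms.items()},
        "validity_age_range": list(model.validity_age_range),
        "fit_diagnostics": model.fit_diagnostics,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def model_from_json(path: str | Path) -> AdjustmentModel:
    payload = json.loads(Path(path).read_text())
    return AdjustmentModel(
        index_name=payload["index_name"],
        beta_age2=payload["beta_age2"],
        centering_c=payload["centering_c"],
        sex_offset=payload["sex_offset"],
        retained_predictors=tuple(payload["retained_predictors"]),
        extra_terms={k: tuple(v) for k, v in payload["extra_terms"].items()},
        validity_age_range=tuple(payload["validity_age_range"]),
        fit_diagnostics=payload.get("fit_diagnostics", {}),
    )


def grid_to_csv(model: AdjustmentModel, path: str | Path,
                ages: Sequence[float] = GRID_AGES) -> None:
    correction_grid(model, ages).to_csv(path)
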