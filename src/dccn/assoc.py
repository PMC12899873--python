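"""Modified Poisson regression for incidence rate ratios.

A Poisson GLM applied to the binary incident outcome with a log
person-time offset yields incidence rate ratios; because the outcome is
binary rather than a count, variance is estimated with the HC0 sandwich
(robust) estimator. Trend across quartiles is tested by refitting with the
per-quartile median score as a single continuous term and taking a robust
Wald p-value on its coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConvergenceError, DataError, RankDeficiencyError

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")
Z95 = 1.959963984540054  # normal 97.5% quantile


def quartile_assign(scores: pd.Series) -> tuple[pd.Series, dict[str, float]]:
    """Quartile labels (closed-right intervals) and per-quartile medians.

    Cuts at the 25/50/75 linear-interpolation percentiles; values equal to
    a boundary fall in the lower quartile. Raises on fewer than four
    distinct values.
    """
    v = scores.to_numpy(dtype=float)
    if len(np.unique(v)) < 4:
        raise DataError("need at least 4 distinct score values for quartiles")
    cuts = np.quantile(v, [0.25, 0.5, 0.75])
    idx = np.searchsorted(cuts, v, side="left")
    labels = pd.Series(
        pd.Categorical.from_codes(idx, categories=list(QUARTILE_LABELS)),
        index=scores.index,
        name="quartile",
    )
    medians = {
        q: float(np.median(v[idx == i])) if (idx == i).any() else float("nan")
        for i, q in enumerate(QUARTILE_LABELS)
    }
    return labels, medians


@dataclass
class IRRResult:
    """Estimates from one modified Poisson fit."""

    irr: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    robust_se: dict[str, float]
    coef: dict[str, float]
    trend_p: float | None
    n: int
    events: int
    covariates: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "irr": self.irr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "robust_se": self.robust_se,
            "coef": self.coef,
            "trend_p": self.trend_p,
            "n": self.n,
            "events": self.events,
            "covariates": self.covariates,
        }


def build_covariates(
    data: pd.DataFrame,
    adjust: str = "full",
    smoking: str = "indicators",
) -> pd.DataFrame:
    """Covariate design columns for the multivariable model.

    ``full``: age, sex (female=1), higher education, regular exercise,
    smoking (two indicators, never = reference, or a single current-smoker
    flag), alcohol, BMI and total energy. ``age_sex`` keeps only age and
    sex; ``none`` returns an empty frame.
    """
    if adjust == "none":
        return pd.DataFrame(index=data.index)
    cols = {
        "age": data["age"].astype(float),
        "sex_female": (data["sex"] == "female").astype(float),
    }
    if adjust == "full":
        cols["education_high"] = data["education_high"].astype(float)
        cols["exercise_regular"] = data["exercise_regular"].astype(float)
        if smoking == "indicators":
            cols["smoke_former"] = (data["smoking"] == "former").astype(float)
            cols["smoke_current"] = (data["smoking"] == "current").astype(float)
        elif smoking == "current":
            cols["smoke_current"] = (data["smoking"] == "current").astype(float)
        else:
            raise DataError(f"unknown smoking coding {smoking!r}")
        cols["alcohol"] = data["alcohol"].astype(float)
        cols["bmi"] = data["bmi"].astype(float)
        cols["energy_kcal"] = data["energy_kcal"].astype(float)
    elif adjust != "age_sex":
        raise DataError(f"unknown adjustment set {adjust!r}")
    return pd.DataFrame(cols, index=data.index)


def modified_poisson(
    outcome: pd.Series,
    exposure: pd.DataFrame,
    person_years: pd.Series,
    covariates: pd.DataFrame | None = None,
    cov_type: str = "HC0",
) -> IRRResult:
    """Poisson GLM with log person-time offset and sandwich variance.

    IRR = exp(coefficient); 95% CI = exp(coef ± 1.96 × robust SE). The
    exposure block may be quartile indicators (reference omitted) or a
    single continuous column.
    """
    y = outcome.astype(float)
    py = person_years.astype(float)
    if (py <= 0).any() or not np.isfinite(np.log(py)).all():
        raise DataError("person_years must be positive and finite")
    blocks = [exposure.astype(float)]
    if covariates is not None and covariates.shape[1]:
        blocks.append(covariates.astype(float))
    X = pd.concat(blocks, axis=1)
    X = sm.add_constant(X, prepend=True)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank deficient (columns: {list(X.columns)})"
        )
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(py))
    try:
        res = model.fit(cov_type=cov_type, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels failure modes
        raise ConvergenceError(f"modified Poisson fit failed: {exc}") from exc
    if not res.converged:
        raise ConvergenceError("IRLS did not converge within 200 iterations")

    terms = list(exposure.columns)
    coef = {t: float(res.params[t]) for t in terms}
    se = {t: float(res.bse[t]) for t in terms}
    return IRRResult(
        irr={t: float(np.exp(coef[t])) for t in terms},
        ci_low={t: float(np.exp(coef[t] - Z95 * se[t])) for t in terms},
        ci_high={t: float(np.exp(coef[t] + Z95 * se[t])) for t in terms},
        robust_se=se,
        coef=coef,
        trend_p=None,
        n=int(len(y)),
        events=int(y.sum()),
        covariates=[] if covariates is None else list(covariates.columns),
    )


def fit_quartile_irr(
    data: pd.DataFrame,
    scores: pd.Series,
    adjust: str = "full",
    smoking: str = "indicators",
    cov_type: str = "HC0",
) -> tuple[IRRResult, pd.Series]:
    """Quartile IRRs (Q1 reference) plus the median-scored trend test.

    ``data`` must carry the outcome (``incident_t2d``), ``person_years``
    and the adjustment covariates; ``scores`` the per-participant
    differential network score aligned on the same index.
    """
    scores = scores.reindex(data.index)
    if scores.isna().any():
        raise DataError("scores missing for some participants")
    labels, medians = quartile_assign(scores)
    y = data["incident_t2d"].astype(float)
    for q in QUARTILE_LABELS:
        if y[labels == q].sum() == 0:
            raise DataError(f"no events in quartile {q}")
    exposure = pd.get_dummies(labels, prefix="", prefix_sep="").astype(float)
    exposure = exposure[list(QUARTILE_LABELS[1:])]  # Q1 = reference
    cov = build_covariates(data, adjust=adjust, smoking=smoking)
    result = modified_poisson(
        y, exposure, data["person_years"], cov, cov_type=cov_type
    )
    result.trend_p = trend_test(
        data, labels, medians, adjust=adjust, smoking=smoking, cov_type=cov_type
    )
    return result, labels


def trend_test(
    data: pd.DataFrame,
    labels: pd.Series,
    medians: dict[str, float],
    adjust: str = "full",
    smoking: str = "indicators",
    cov_type: str = "HC0",
) -> float:
    """Robust Wald p for the per-quartile-median continuous term."""
    trend = labels.map(medians).astype(float).rename("trend")
    if trend.nunique() < 2:
        raise RankDeficiencyError("trend variable constant across quartiles")
    cov = build_covariates(data, adjust=adjust, smoking=smoking)
    res = modified_poisson(
        data["incident_t2d"].astype(float),
        trend.to_frame(),
        data["person_years"],
        cov,
        cov_type=cov_type,
    )
    zstat = res.coef["trend"] / res.robust_se["trend"]
    return float(2.0 * stats.norm.sf(abs(zstat)))


def fit_continuous_irr(
    data: pd.DataFrame,
    scores: pd.Series,
    standardize: bool = True,
    adjust: str = "full",
    smoking: str = "indicators",
    cov_type: str = "HC0",
) -> IRRResult:
    """IRR per unit (default: per SD) of the continuous score."""
    s = scores.reindex(data.index).astype(float)
    if standardize:
        sd = s.std(ddof=0)
        if sd == 0:
            raise DataError("score has zero variance")
        s = (s - s.mean()) / sd
    cov = build_covariates(data, adjust=adjust, smoking=smoking)
    return modified_poisson(
        data["incident_t2d"].astype(float),
        s.rename("score").to_frame(),
        data["person_years"],
        cov,
        cov_type=cov_type,
    )
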