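"""The nine progression models and the logistic fitting contract.

Predictor blocks:

* ``cov``      — age, gender, BMI (the traditional clinical covariates);
* ``covPlus``  — cov plus race, WOMAC pain and history of knee injury;
* ``KL``       — the radiologist's ordinal KL grade;
* ``KLprob``   — the classifier-derived continuous severity score;
* ``mJSN`` / ``lJSN`` — baseline medial / lateral JSN grades (ordinal,
  entered numerically);
* ``TBT``      — the texture descriptors retained by backward AIC
  selection.

Model_8 (the combined texture + severity-score model) deliberately omits
mJSN: baseline mJSN and KLprob are highly correlated, and mJSN change
defines the outcome.  Model_9 swaps cov for covPlus.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ParameterError, SchemaError, UndefinedMetricError

__all__ = [
    "MODEL_PREDICTORS",
    "ModelSpec",
    "model_spec",
    "resolve_columns",
    "encode_table",
    "FittedModel",
    "fit_logistic",
]

MODEL_PREDICTORS: dict[str, tuple[str, ...]] = {
    "Model_1": ("cov",),
    "Model_2": ("cov", "TBT"),
    "Model_3": ("cov", "mJSN", "lJSN"),
    "Model_4": ("cov", "KL"),
    "Model_5": ("cov", "KLprob"),
    "Model_6": ("cov", "lJSN", "mJSN", "TBT"),
    "Model_7": ("cov", "KLprob", "TBT"),
    "Model_8": ("cov", "KLprob", "lJSN", "TBT"),
    "Model_9": ("covPlus", "KLprob", "lJSN", "TBT"),
}

RACE_LEVELS = ("W", "B", "O")
RACE_DUMMIES = tuple(f"race_{lvl}" for lvl in RACE_LEVELS[1:])

GROUP_COLUMNS: dict[str, tuple[str, ...]] = {
    "cov": ("age", "gender", "bmi"),
    "covPlus": ("age", "gender", "bmi", "womac_pain", "injury_history") + RACE_DUMMIES,
    "KL": ("kl",),
    "KLprob": ("klprob",),
    "mJSN": ("mjsn_baseline",),
    "lJSN": ("ljsn_baseline",),
}


@dataclass(frozen=True)
class ModelSpec:
    """An immutable named predictor set."""

    name: str
    predictors: tuple[str, ...]

    @property
    def uses_tbt(self) -> bool:
        return "TBT" in self.predictors


def model_spec(name: str) -> ModelSpec:
    """Look up one of the nine canonical model specifications."""
    if name not in MODEL_PREDICTORS:
        raise ParameterError(
            f"unknown model {name!r}; valid names: {', '.join(MODEL_PREDICTORS)}"
        )
    return ModelSpec(name=name, predictors=MODEL_PREDICTORS[name])


def encode_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add stable categorical encodings (race one-hot against the 'W'
    reference level); idempotent."""
    out = table.copy()
    if "race" in out.columns:
        for lvl in RACE_LEVELS[1:]:
            col = f"race_{lvl}"
            if col not in out.columns:
                out[col] = (out["race"] == lvl).astype(int)
    return out


def resolve_columns(
    spec: ModelSpec | str,
    tbt_selected: list[str] | None = None,
) -> list[str]:
    """Expand a model spec into concrete feature-table column names."""
    if isinstance(spec, str):
        spec = model_spec(spec)
    cols: list[str] = []
    for group in spec.predictors:
        if group == "TBT":
            if tbt_selected is None:
                raise SchemaError(f"{spec.name} needs a selected TBT descriptor list")
            cols.extend(tbt_selected)
        elif group in GROUP_COLUMNS:
            cols.extend(GROUP_COLUMNS[group])
        else:
            raise ParameterError(f"unknown predictor group {group!r}")
    # preserve order, drop duplicates
    seen: set[str] = set()
    return [c for c in cols if not (c in seen or seen.add(c))]


@dataclass
class FittedModel:
    """A fitted logistic model with coefficients on the original scale.

    Predictors are standardized internally before fitting (location/scale
    stored for reuse on a test cohort); ``coef`` and ``intercept`` are
    mapped back to the raw-column scale.
    """

    columns: list[str]
    intercept: float
    coef: np.ndarray
    mean_: np.ndarray
    scale_: np.ndarray
    converged: bool
    separation_flag: bool
    llf: float
    aic: float
    n_obs: int
    n_cases: int

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.columns].to_numpy(dtype=float)
        return self.intercept + X @ self.coef

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(table))


def fit_logistic(
    table: pd.DataFrame,
    columns: list[str],
    outcome: str = "outcome",
) -> FittedModel:
    """Maximum-likelihood logistic regression (IRLS/Newton).

    Convergence when the max absolute coefficient change drops below 1e-8,
    up to 100 iterations.  Complete separation yields a flagged result
    with a warning rather than an exception.
    """
    sub = table[[outcome] + list(columns)].dropna()
    y = sub[outcome].to_numpy(dtype=float)
    n_cases = int(y.sum())
    if n_cases == 0 or n_cases == len(y):
        raise UndefinedMetricError("need at least one case and one control to fit")
    X = sub[list(columns)].to_numpy(dtype=float)

    mean_ = X.mean(axis=0) if X.size else np.zeros(0)
    scale_ = X.std(axis=0) if X.size else np.zeros(0)
    scale_ = np.where(scale_ > 0, scale_, 1.0)
    Z = (X - mean_) / scale_
    design = sm.add_constant(Z, has_constant="add")

    separation = False
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0
            )
            params = res.params
            llf = float(res.llf)
            converged = bool(res.mle_retvals.get("converged", True))
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            separation = True
            res = sm.Logit(y, design).fit_regularized(
                method="l1", alpha=1e-6, disp=0, maxiter=500
            )
            params = np.asarray(res.params)
            llf = float(sm.Logit(y, design).loglike(params))
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True
    if separation:
        warnings.warn(
            "perfect separation detected; coefficients are unreliable", stacklevel=2
        )

    b0_z, beta_z = float(params[0]), np.asarray(params[1:], dtype=float)
    coef = beta_z / scale_
    intercept = b0_z - float(np.sum(beta_z * mean_ / scale_))
    k = len(params)
    return FittedModel(
        columns=list(columns),
        intercept=intercept,
        coef=coef,
        mean_=mean_,
        scale_=scale_,
        converged=converged and not separation,
        separation_flag=separation,
        llf=llf,
        aic=2.0 * k - 2.0 * llf,
        n_obs=len(y),
        n_cases=n_cases,
    )
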