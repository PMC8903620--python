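"""Eligibility filtering, progression labeling and model-table assembly.

Eligibility mirrors the structure-modification trial entry criteria:
knees with preexisting OA, 2 <= KL < 4, complete covariates and JSN
grades, and no material (metal/prosthesis/screw) in the subchondral zone.
The quality-controlled (QC) subset additionally drops radiographs flagged
for exposure problems; the nonQC subset keeps them, so QC is always a
subset of nonQC.

Progression is defined on the medial OARSI joint-space-narrowing grade:
dmJSN = follow-up minus baseline; > 0 is a case, = 0 a control, and a
decrease is invalid (excluded with a logged reason — the case/control
definitions only cover non-decreasing grades).

KLprob summarises a classifier's five KL-grade probabilities as a linear
combination; the default weights (0, 1, 2, 3, 4) give the expected KL
grade, a continuous severity score.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import MissingDataError, ParameterError, SelectionError
from .fractal import DESCRIPTOR_NAMES

__all__ = [
    "REQUIRED_FIELDS",
    "select_eligible",
    "label_progression",
    "compute_klprob",
    "assemble_feature_table",
    "backward_aic_select",
    "SelectionResult",
    "write_feature_table",
    "write_filter_log",
]

KLPROB_WEIGHTS_DEFAULT = (0.0, 1.0, 2.0, 3.0, 4.0)

REQUIRED_FIELDS = (
    "age",
    "gender",
    "bmi",
    "kl",
    "klp_0",
    "klp_1",
    "klp_2",
    "klp_3",
    "klp_4",
    "mjsn_baseline",
    "mjsn_followup",
    "ljsn_baseline",
)


def select_eligible(cohort: Cohort, quality_group: str = "nonQC") -> tuple[Cohort, dict]:
    """Apply the eligibility and QC filters; return the filtered cohort
    and a reason -> count flowchart log.

    Exclusion reasons, applied in order (each knee counted once):
    ``kl_out_of_range`` (KL not in {2, 3}), ``incomplete_record``,
    ``material``, and — in the QC group only — ``exposure``.
    """
    if quality_group not in ("QC", "nonQC"):
        raise ParameterError(f"quality_group must be QC or nonQC, got {quality_group!r}")
    t = cohort.table
    log: dict[str, int] = {"input": len(t)}

    kl_ok = t["kl"].isin([2, 3])
    log["kl_out_of_range"] = int((~kl_ok).sum())

    present = [c for c in REQUIRED_FIELDS if c in t.columns]
    missing_req = [c for c in REQUIRED_FIELDS if c not in t.columns]
    complete = t[present].notna().all(axis=1) if present else pd.Series(True, index=t.index)
    if missing_req:
        complete &= False
    log["incomplete_record"] = int((kl_ok & ~complete).sum())

    material = t.get("qc_material", pd.Series(0, index=t.index)).fillna(0).astype(bool)
    keep = kl_ok & complete
    log["material"] = int((keep & material).sum())
    keep &= ~material

    if quality_group == "QC":
        exposure = t.get("qc_exposure", pd.Series(0, index=t.index)).fillna(0).astype(bool)
        log["exposure"] = int((keep & exposure).sum())
        keep &= ~exposure

    log["eligible"] = int(keep.sum())
    out = Cohort(
        table=t.loc[keep].reset_index(drop=True),
        horizon_months=cohort.horizon_months,
        config=cohort.config,
        filter_log=log,
    )
    return out, log


def label_progression(mjsn_baseline, mjsn_followup=None) -> str:
    """Classify one knee as ``case`` (dmJSN > 0), ``control`` (= 0) or
    ``invalid`` (< 0).  Accepts a record-like object with
    ``mjsn_baseline``/``mjsn_followup`` fields, or the two grades."""
    if mjsn_followup is None:
        record = mjsn_baseline
        try:
            mjsn_baseline = record["mjsn_baseline"]
            mjsn_followup = record["mjsn_followup"]
        except (KeyError, TypeError) as exc:
            raise MissingDataError("record lacks mJSN grades") from exc
    if pd.isna(mjsn_baseline) or pd.isna(mjsn_followup):
        raise MissingDataError("mJSN grade missing")
    delta = mjsn_followup - mjsn_baseline
    if delta > 0:
        return "case"
    if delta == 0:
        return "control"
    return "invalid"


def compute_klprob(kl_probs, weights=KLPROB_WEIGHTS_DEFAULT) -> float:
    """Linear combination of the five KL-grade probabilities.

    The default weights are the grade values themselves, so a one-hot
    vector reproduces the integer KL grade and a general vector gives the
    expected grade under the classifier's distribution.
    """
    p = np.asarray(kl_probs, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape[-1] != 5 or w.shape != (5,):
        raise ParameterError("kl_probs and weights must have 5 entries")
    if np.any(p < 0):
        raise ParameterError("kl_probs must be nonnegative")
    total = p.sum(axis=-1)
    if np.any(np.abs(total - 1.0) > 1e-6):
        raise ParameterError("kl_probs must sum to 1 within 1e-6")
    return float(p @ w) if p.ndim == 1 else p @ w


def assemble_feature_table(
    cohort: Cohort, klprob_weights=KLPROB_WEIGHTS_DEFAULT
) -> pd.DataFrame:
    """One modeling row per eligible, labelable knee.

    Adds the binary ``outcome`` (1 = case) and the continuous ``klprob``;
    knees whose dmJSN decreases are dropped with a logged reason.
    Descriptor slots that could not be computed stay NaN — each model later
    uses the rows complete for its own predictors (complete-case per
    model), so a knee with invalid texture slots still serves the
    TBT-free models.
    """
    t = cohort.table
    if len(t) == 0:
        import warnings

        warnings.warn("assembling an empty cohort", stacklevel=2)
    delta = t["mjsn_followup"] - t["mjsn_baseline"]
    valid = delta >= 0
    n_invalid = int((~valid).sum())

    t = t.loc[valid].reset_index(drop=True)
    klp = t[[f"klp_{k}" for k in range(5)]].to_numpy(dtype=float)
    klprob = compute_klprob(klp, klprob_weights) if len(t) else np.empty(0)

    lead = [
        "knee_id",
        "subject_id",
        "laterality",
        "modality",
        "age",
        "gender",
        "bmi",
        "race",
        "womac_pain",
        "injury_history",
        "kl",
        "mjsn_baseline",
        "ljsn_baseline",
    ]
    lead = [c for c in lead if c in t.columns]
    out = t[lead].copy()
    out.insert(0, "outcome", (delta.loc[valid].to_numpy() > 0).astype(int))
    out["klprob"] = klprob
    for name in DESCRIPTOR_NAMES:
        out[name] = t[name].to_numpy() if name in t.columns else np.nan
    out.attrs["n_mjsn_decrease_dropped"] = n_invalid
    out.attrs["horizon_months"] = cohort.horizon_months
    return out


@dataclass
class SelectionResult:
    """Outcome of backward AIC elimination over the texture descriptors."""

    kept: list[str]
    dropped: list[tuple[str, float]]  # (name, AIC after the accepted drop)
    final_aic: float
    start_aic: float

    @property
    def aic_trace(self) -> list[float]:
        return [self.start_aic] + [a for _, a in self.dropped]


def backward_aic_select(
    table: pd.DataFrame,
    forced: list[str],
    candidates: list[str],
    outcome: str = "outcome",
) -> SelectionResult:
    """Backward elimination of ``candidates`` by AIC on a logistic model.

    Starts from the full model (forced + all candidates).  At each step the
    single candidate whose removal yields the lowest AIC is dropped, iff
    that AIC improves on the current one; forced predictors are never
    removed; equal-AIC removals resolve by descriptor name order.  AIC is
    2 * (fitted coefficients) - 2 * maximized log-likelihood.
    """
    from .models import fit_logistic

    candidates = sorted(candidates)
    cols = forced + candidates
    sub = table[[outcome] + cols].dropna()
    if len(sub) <= len(cols) + 1:
        raise SelectionError(
            f"{len(sub)} complete rows cannot support {len(cols)} predictors"
        )

    current = fit_logistic(sub, cols, outcome=outcome)
    if not current.converged:
        raise SelectionError("full model fit did not converge (step: full model)")
    current_aic = current.aic
    start_aic = current_aic
    kept = list(candidates)
    dropped: list[tuple[str, float]] = []

    while kept:
        best_name, best_aic = None, np.inf
        for name in kept:  # sorted order makes ties deterministic
            trial_cols = forced + [c for c in kept if c != name]
            fit = fit_logistic(sub, trial_cols, outcome=outcome)
            if not fit.converged:
                raise SelectionError(f"fit did not converge (step: drop {name})")
            if fit.aic < best_aic:
                best_name, best_aic = name, fit.aic
        if best_aic < current_aic:
            kept.remove(best_name)
            dropped.append((best_name, best_aic))
            current_aic = best_aic
        else:
            break
    return SelectionResult(
        kept=kept, dropped=dropped, final_aic=current_aic, start_aic=start_aic
    )


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV plus a ``<path>.yaml`` column
    dictionary describing each field's role."""
    from pathlib import Path

    import yaml

    path = Path(path)
    table.to_csv(path, index=False)
    roles = {}
    for col in table.columns:
        if col in DESCRIPTOR_NAMES:
            roles[col] = "texture descriptor (fractal dimension)"
        elif col == "outcome":
            roles[col] = "progression label (1 = dmJSN > 0 case)"
        elif col == "klprob":
            roles[col] = "expected KL grade from the 5-probability vector"
        elif col.startswith("klp_"):
            roles[col] = f"probability of KL grade {col[-1]}"
        elif col.startswith("true_"):
            roles[col] = "generator ground truth (not a predictor)"
        elif col in ("mjsn_baseline", "mjsn_followup", "ljsn_baseline"):
            roles[col] = "OARSI joint-space-narrowing grade 0-3"
        else:
            roles[col] = "clinical / administrative field"
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(roles, sort_keys=False))


def write_filter_log(log: dict, path) -> None:
    """Line-oriented reason=count log reproducing the selection flowchart
    in numbers."""
    from pathlib import Path

    lines = [f"{k}={v}" for k, v in log.items()]
    Path(path).write_text("\n".join(lines) + "\n")
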