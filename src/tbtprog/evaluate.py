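"""Repeated cross-validation, model batteries and cross-cohort transfer.

The headline protocol evaluates each model by stratified 10-fold
cross-validation repeated 300 times: within each repeat the out-of-fold
predicted probabilities are pooled and a single AUC computed; the reported
AUC is the mean over repeats and its interval the 2.5/97.5 percentiles of
the repeat distribution.  Backward AIC selection of the texture
descriptors runs once on the full training table before cross-validation
(the leakage-safe nested variant is available as an option).

Cross-cohort transfer freezes everything on the training cohort —
descriptor selection, standardization, coefficients and the accuracy
threshold — and only scores the test cohort; the test AUC gets a DeLong
confidence interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import SchemaError, UndefinedMetricError
from .fractal import DESCRIPTOR_NAMES
from .metrics import acc_dor, auc, delong_compare, delong_variance
from .models import (
    MODEL_PREDICTORS,
    ModelSpec,
    encode_table,
    fit_logistic,
    model_spec,
    resolve_columns,
)
from .pipeline import SelectionResult, backward_aic_select

__all__ = [
    "EvalResult",
    "repeated_cv",
    "cross_cohort_eval",
    "select_tbt",
    "evaluate_models",
    "pairwise_delong",
]


@dataclass
class EvalResult:
    """Performance summary of one model under one protocol."""

    model: str
    auc: float
    auc_ci: tuple[float, float]
    acc: float
    dor: float
    threshold: float
    n_cases: int
    n_controls: int
    per_repeat_auc: list[float] = field(default_factory=list)
    selection: SelectionResult | None = None
    #: first-repeat out-of-fold scores (indexed like the source table, so
    #: models fitted on different complete-case subsets stay comparable)
    oof_scores: pd.Series | None = None
    oof_outcome: pd.Series | None = None

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "acc": self.acc,
            "dor": self.dor,
            "threshold": self.threshold,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }


def _candidate_descriptors(table: pd.DataFrame) -> list[str]:
    """Descriptor columns usable as selection candidates: present, fully
    observed and non-constant on the table's complete rows."""
    out = []
    for name in DESCRIPTOR_NAMES:
        if name in table.columns:
            col = table[name]
            if col.notna().all() and col.nunique() > 1:
                out.append(name)
    return out


def select_tbt(
    table: pd.DataFrame,
    spec: ModelSpec,
    candidates: list[str] | None = None,
) -> SelectionResult:
    """Backward-AIC selection of the TBT descriptors for one model, with
    the model's clinical predictors forced (never removable)."""
    table = encode_table(table)
    forced = resolve_columns(
        ModelSpec(spec.name, tuple(p for p in spec.predictors if p != "TBT"))
    )
    if candidates is None:
        candidates = _candidate_descriptors(table)
    return backward_aic_select(table, forced=forced, candidates=candidates)


def repeated_cv(
    table: pd.DataFrame,
    spec: ModelSpec | str | list[str],
    k: int = 10,
    repeats: int = 300,
    seed: int = 0,
    threshold_rule="youden",
    tbt_selected: list[str] | None = None,
    nested_selection: bool = False,
) -> EvalResult:
    """Stratified k-fold cross-validation repeated ``repeats`` times.

    ``spec`` may be a model name/spec or an explicit column list.  For TBT
    models the descriptor set must either be supplied (``tbt_selected``,
    the once-on-the-full-table protocol) or — with
    ``nested_selection=True`` — re-selected inside every training fold,
    the leakage-safe variant.
    """
    table = encode_table(table)
    if isinstance(spec, (ModelSpec, str)):
        spec = model_spec(spec) if isinstance(spec, str) else spec
        name = spec.name
        if spec.uses_tbt and tbt_selected is None and not nested_selection:
            tbt_selected = select_tbt(table, spec).kept
        columns = resolve_columns(spec, tbt_selected=tbt_selected or [])
    else:
        name = "custom"
        columns = list(spec)
        spec = None

    sub = table[["outcome"] + columns].dropna()
    y = sub["outcome"].to_numpy(dtype=int)
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if min(n_cases, n_controls) < k:
        raise UndefinedMetricError(
            f"smallest class ({min(n_cases, n_controls)}) cannot be split into {k} folds"
        )
    if len(sub) < 2 * k:
        raise UndefinedMetricError(f"n={len(sub)} too small for {k}-fold CV")

    states = np.random.SeedSequence(seed).generate_state(repeats)
    aucs, accs, dors, thrs = [], [], [], []
    first_oof: np.ndarray | None = None
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(states[r] % (2**32 - 1)))
        oof = np.empty(len(sub))
        for train_idx, test_idx in skf.split(np.zeros(len(sub)), y):
            train = sub.iloc[train_idx]
            fold_cols = columns
            if nested_selection and spec is not None and spec.uses_tbt:
                fold_sel = select_tbt(train, spec)
                fold_cols = resolve_columns(spec, tbt_selected=fold_sel.kept)
            fit = fit_logistic(train, fold_cols)
            oof[test_idx] = fit.predict_proba(sub.iloc[test_idx])
        aucs.append(auc(y, oof))
        a, d, t = acc_dor(y, oof, threshold_rule)
        accs.append(a)
        dors.append(d)
        thrs.append(t)
        if first_oof is None:
            first_oof = oof
    aucs = np.asarray(aucs)
    ci = (float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5)))
    return EvalResult(
        model=name,
        auc=float(aucs.mean()),
        auc_ci=ci,
        acc=float(np.mean(accs)),
        dor=float(np.mean(dors)),
        threshold=float(np.mean(thrs)),
        n_cases=n_cases,
        n_controls=n_controls,
        per_repeat_auc=aucs.tolist(),
        oof_scores=pd.Series(first_oof, index=sub.index),
        oof_outcome=pd.Series(y, index=sub.index),
    )


def cross_cohort_eval(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    spec: ModelSpec | str,
    threshold_rule="youden",
    tbt_candidates: list[str] | None = None,
) -> EvalResult:
    """Train on one cohort, test on the other.

    Descriptor selection (for TBT models), coefficient estimation and the
    accuracy threshold all come from the training cohort only.  With
    ``test_table is train_table`` this degenerates to resubstitution.
    """
    spec = model_spec(spec) if isinstance(spec, str) else spec
    train_table = encode_table(train_table)
    test_table = encode_table(test_table)

    selection = None
    tbt_selected: list[str] = []
    if spec.uses_tbt:
        selection = select_tbt(train_table, spec, candidates=tbt_candidates)
        tbt_selected = selection.kept
    columns = resolve_columns(spec, tbt_selected=tbt_selected)

    missing = [c for c in columns if c not in test_table.columns]
    if missing:
        raise SchemaError(f"test cohort lacks predictor columns: {missing}")

    train_sub = train_table[["outcome"] + columns].dropna()
    test_sub = test_table[["outcome"] + columns].dropna()
    fit = fit_logistic(train_sub, columns)
    train_scores = fit.predict_proba(train_sub)
    if threshold_rule == "youden":
        from .metrics import youden_threshold

        thr = youden_threshold(train_sub["outcome"].to_numpy(), train_scores)
    else:
        thr = float(threshold_rule)

    y_test = test_sub["outcome"].to_numpy(dtype=int)
    scores = fit.predict_proba(test_sub)
    a, var = delong_variance(y_test, scores)
    half = 1.959963984540054 * np.sqrt(var)
    acc, dor, _ = acc_dor(y_test, scores, threshold_rule=thr)
    return EvalResult(
        model=spec.name,
        auc=float(a),
        auc_ci=(float(max(a - half, 0.0)), float(min(a + half, 1.0))),
        acc=acc,
        dor=dor,
        threshold=thr,
        n_cases=int(y_test.sum()),
        n_controls=int((1 - y_test).sum()),
        selection=selection,
        oof_scores=pd.Series(scores, index=test_sub.index),
        oof_outcome=pd.Series(y_test, index=test_sub.index),
    )


def evaluate_models(
    table: pd.DataFrame,
    model_names: list[str] | None = None,
    k: int = 10,
    repeats: int = 300,
    seed: int = 0,
    threshold_rule="youden",
) -> tuple[pd.DataFrame, dict[str, EvalResult]]:
    """Run the model battery under repeated CV on one feature table.

    Descriptor selection runs once per TBT model on the full table; all
    models share the CV seed, hence the fold assignments.  Returns the
    summary table (one row per model) and the per-model results.
    """
    model_names = model_names or list(MODEL_PREDICTORS)
    table = encode_table(table)
    results: dict[str, EvalResult] = {}
    rows = []
    selection_cache: SelectionResult | None = None
    for name in model_names:
        spec = model_spec(name)
        tbt_selected = None
        if spec.uses_tbt:
            if selection_cache is None:
                selection_cache = select_tbt(table, spec)
            tbt_selected = selection_cache.kept
        res = repeated_cv(
            table,
            spec,
            k=k,
            repeats=repeats,
            seed=seed,
            threshold_rule=threshold_rule,
            tbt_selected=tbt_selected,
        )
        if spec.uses_tbt:
            res.selection = selection_cache
        results[name] = res
        rows.append(res.to_row())
    return pd.DataFrame(rows), results


def pairwise_delong(results: dict[str, EvalResult]) -> pd.DataFrame:
    """All-pairs DeLong comparisons on the shared out-of-fold scores.

    Only rows scored by both models (their complete-case intersection)
    enter a comparison.
    """
    names = list(results)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra, rb = results[a], results[b]
            if ra.oof_scores is None or rb.oof_scores is None:
                continue
            common = ra.oof_scores.index.intersection(rb.oof_scores.index)
            labels = ra.oof_outcome.reindex(common)
            cmp = delong_compare(
                labels.to_numpy(),
                ra.oof_scores.reindex(common).to_numpy(),
                rb.oof_scores.reindex(common).to_numpy(),
            )
            rows.append(
                {
                    "model_a": a,
                    "model_b": b,
                    "auc_a": cmp.auc_a,
                    "auc_b": cmp.auc_b,
                    "auc_diff": cmp.auc_diff,
                    "p_value": cmp.p_value,
                }
            )
    return pd.DataFrame(rows)
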