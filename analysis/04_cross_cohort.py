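#!/usr/bin/env python
"""Cross-cohort transfer of the combined texture + severity model.

Model_8 (clinical covariates + KLprob + lateral JSN + selected texture
descriptors) is trained on one cohort — descriptor selection,
standardization, coefficients and the accuracy threshold all frozen on the
training side — and scored on the other, in both directions.  The
transferred AUC is compared with each cohort's own cross-validated AUC.

Writes results/cross_cohort.csv.
"""
from pathlib import Path

import pandas as pd

from tbtprog.cohort import Cohort
from tbtprog.evaluate import cross_cohort_eval, repeated_cv, select_tbt
from tbtprog.models import model_spec
from tbtprog.pipeline import assemble_feature_table, select_eligible

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
OUT = ROOT / "results"


def main() -> None:
    tables = {
        name: assemble_feature_table(
            select_eligible(Cohort.from_csv(DATA / f"{name}.csv"), "nonQC")[0]
        )
        for name in ("cohort_a", "cohort_b")
    }
    rows = []
    for train_name, test_name in (("cohort_a", "cohort_b"), ("cohort_b", "cohort_a")):
        res = cross_cohort_eval(tables[train_name], tables[test_name], "Model_8")
        sel = select_tbt(tables[test_name], model_spec("Model_8"))
        within = repeated_cv(tables[test_name], "Model_8", k=10, repeats=5,
                             seed=17, tbt_selected=sel.kept)
        rows.append({
            "train": train_name, "test": test_name,
            "auc_cross": res.auc, "auc_ci_low": res.auc_ci[0],
            "auc_ci_high": res.auc_ci[1], "acc": res.acc, "dor": res.dor,
            "auc_within_cv": within.auc,
            "gap": abs(res.auc - within.auc),
            "n_tbt_kept_train": len(res.selection.kept),
        })
        print(f"train {train_name} -> test {test_name}: "
              f"AUC {res.auc:.3f} ({res.auc_ci[0]:.3f}-{res.auc_ci[1]:.3f}) "
              f"ACC {res.acc:.3f} DOR {res.dor:.1f} | "
              f"within-CV AUC {within.auc:.3f} (gap {abs(res.auc-within.auc):.3f})")
    pd.DataFrame(rows).to_csv(OUT / "cross_cohort.csv", index=False)


if __name__ == "__main__":
    main()
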