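#!/usr/bin/env python
"""Validate the imaging arm: render radiographs and re-extract descriptors.

A small imaging subset (12 knees) of the first cohort is rendered as
16-bit radiographs with the planted per-ROI trabecular textures, then run
through the full landmark -> baseline -> patchwork -> variogram -> FD
chain.  The check is that the extracted micro-band FD per ROI tracks the
planted 3 - H ground truth.

Writes results/extraction_check.csv (one row per knee x ROI).
"""
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from click.testing import CliRunner

from tbtprog.cli import main as cli

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    runner = CliRunner()
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        res = runner.invoke(cli, ["simulate", "--out", str(tmp), "--n", "12",
                                  "--seed", "33", "--images"])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli, ["extract", "--data", str(tmp),
                                  "--out", str(tmp / "features.csv")])
        assert res.exit_code == 0, res.output
        feats = pd.read_csv(tmp / "features.csv")
        truth = pd.read_csv(tmp / "truth.csv")
    merged = feats.merge(truth, on="knee_id")
    rows = []
    for _, r in merged.iterrows():
        for i in range(1, 17):
            planted = 3.0 - r[f"true_hurst_roi{i:02d}"]
            rows.append({
                "knee_id": r["knee_id"],
                "roi": i,
                "planted_fd": planted,
                "micro_fd_h": r[f"roi{i:02d}_h_micro_fd"],
                "micro_fd_v": r[f"roi{i:02d}_v_micro_fd"],
                "milli_fd_h": r[f"roi{i:02d}_h_milli_fd"],
                "abs_err_micro_h": abs(r[f"roi{i:02d}_h_micro_fd"] - planted),
            })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "extraction_check.csv", index=False)
    mae = table["abs_err_micro_h"].mean()
    print(f"12 knees x 16 ROIs extracted; micro-band FD mean abs error vs "
          f"planted texture: {mae:.3f} (written to results/extraction_check.csv)")


if __name__ == "__main__":
    main()
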