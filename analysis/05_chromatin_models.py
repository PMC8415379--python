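#!/usr/bin/env python
"""PCA of chromatin features at joint PRDM9-DSB sites and forward-selected
linear models for DSB activity and crossover likelihood.  Runs the whole
pipeline end-to-end and summarises the model section of the report."""

import warnings
from pathlib import Path

from meiorec.pipeline import RunConfig, run_all
from meiorec.simulate import SimConfig

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "models"


def main():
    cfg = RunConfig(outdir=str(OUT), simulate=SimConfig(seed=0), seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_all(cfg)
    pca = report["stages"]["pca"]
    print("explained variance (%):",
          [round(x, 1) for x in pca["explained_variance_pct"]])
    for name, fit in report["stages"]["models"].items():
        print(f"{name}: selected {fit['selected']}  "
              f"R2 {100 * fit['r2']:.1f}% (naive {100 * fit['naive_r2']:.1f}%)")
    print(f"full report: {OUT}/results.json")


if __name__ == "__main__":
    main()
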