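#!/usr/bin/env python
"""Compartment-masked P(s) curves and loop-length estimates across seeds:
does the derivative-maximum procedure recover the injected threefold A/B
loop-size difference?  Writes per-seed estimates to results/loops.tsv."""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from meiorec import binning, hic
from meiorec.simulate import SimConfig, simulate_contacts, simulate_genome

ROOT = Path(__file__).resolve().parent.parent
N_SEEDS = 10


def main():
    rows = []
    for seed in range(N_SEEDS):
        cfg = SimConfig(seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bins, truth, chromhmm, _ = simulate_genome(cfg)
            states = binning.chromhmm_overlap_tracks(chromhmm, bins)
            ref = binning.BinnedTrack(
                "ref",
                np.sum([states[s].values for s in binning.ACTIVE_STATES], axis=0),
            )
            comp = hic.fine_grain_compartment(
                simulate_contacts(bins, truth, cfg, "ES"), ref
            )
            cm = simulate_contacts(bins, truth, cfg, "zygonema")
            curves = hic.ps_curves_by_compartment(cm, comp.values)
            a = hic.loop_length_estimate(curves["A"])
            b = hic.loop_length_estimate(curves["B"])
        rows.append({"seed": seed, "loop_A_mb": a / 1e6, "loop_B_mb": b / 1e6,
                     "ratio": b / a})
        print(f"seed {seed}: A = {a/1e6:.2f} Mb, B = {b/1e6:.2f} Mb, "
              f"B/A = {b/a:.2f}")
    df = pd.DataFrame(rows)
    out = ROOT / "results" / "loops.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, sep="\t", index=False)
    print(f"mean B/A ratio over {N_SEEDS} seeds: {df['ratio'].mean():.2f} "
          f"(injected: 2.1/0.7 = 3.0)")


if __name__ == "__main__":
    main()
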